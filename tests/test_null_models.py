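import itertools

import numpy as np
import pandas as pd
import pytest

from assemblage import (
    aggregate_partition,
    beta_mntd,
    beta_nti,
    cophenetic_distances,
    partition_processes,
    rc_bray,
    read_tree,
    simulate_tree,
)
from assemblage.null_models import PROCESSES, _pair_rng

from conftest import make_cm


class TestCopheneticDistances:
    def test_three_taxon_hand_values(self, three_taxon_tree):
        dm = cophenetic_distances(read_tree(three_taxon_tree))
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["B", "C"] == pytest.approx(4.0)

    def test_two_taxon_pair(self, tmp_path):
        p = tmp_path / "p.nwk"
        p.write_text("(A:0.5,B:0.5);")
        dm = cophenetic_distances(read_tree(p))
        assert dm["A", "B"] == pytest.approx(1.0)

    def test_star_tree_equal_lengths(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:2,B:2,C:2,D:2);")
        dm = cophenetic_distances(read_tree(p))
        off = dm.data[np.triu_indices(4, 1)]
        assert np.allclose(off, 4.0)

    def test_missing_tips_listed(self, three_taxon_tree):
        tree = read_tree(three_taxon_tree)
        with pytest.raises(ValueError, match="X.*Y|missing"):
            cophenetic_distances(tree, ["A", "X", "Y"])


class TestBetaMntd:
    def test_identical_communities_are_zero(self):
        D = np.array([[0, 2.0], [2.0, 0]])
        assert beta_mntd([1, 1], [1, 1], D) == 0.0

    def test_hand_example(self):
        # comm_a = {A, B} equal, comm_b = {C}; d(A,C)=2, d(B,C)=4
        D = np.array([[0, 1, 2.0], [1, 0, 4.0], [2.0, 4.0, 0]])
        val = beta_mntd([1, 1, 0], [0, 0, 1], D)
        assert val == pytest.approx(0.5 * ((2 + 4) / 2 + 2))  # 2.5

    def test_weighted_equals_unweighted_for_equal_abundances(self):
        rng = np.random.default_rng(0)
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        a = np.array([2, 2, 2, 0, 0, 0])
        b = np.array([0, 0, 3, 3, 3, 0])
        assert beta_mntd(a, b, D, True) == pytest.approx(beta_mntd(a, b, D, False))

    def test_empty_community_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            beta_mntd([0, 0], [1, 1], D)


def brute_force_bmntd(va, vb, D):
    """Independent loop-based βMNTD for the enumeration oracle."""
    ia = [i for i, v in enumerate(va) if v > 0]
    ib = [j for j, v in enumerate(vb) if v > 0]
    fa = [va[i] / sum(va[i] for i in ia) for i in ia]
    fb = [vb[j] / sum(vb[j] for j in ib) for j in ib]
    left = sum(f * min(D[i][j] for j in ib) for f, i in zip(fa, ia))
    right = sum(f * min(D[j][i] for i in ia) for f, j in zip(fb, ib))
    return 0.5 * (left + right)


class TestPicanteCrossCheck:
    def test_beta_mntd_matches_picante_comdistnt(self, tmp_path):
        """Independent oracle: R picante's abundance-weighted comdistnt."""
        import subprocess

        from assemblage import CommunityMatrix, write_tree

        tree = simulate_tree(12, seed=3)
        ids = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(4)
        tab = rng.integers(0, 8, size=(12, 4))
        tab[0] += 1  # no empty community
        cm = make_cm(tab, otus=ids, samples=list("abcd"))
        D = cophenetic_distances(tree, ids)
        write_tree(tree, tmp_path / "t.nwk")
        pd.DataFrame(tab.T, index=list("abcd"), columns=ids).to_csv(
            tmp_path / "comm.csv")
        script = f"""
suppressMessages(library(picante))
tree <- read.tree("{tmp_path}/t.nwk")
tree$tip.label <- gsub("'", "", tree$tip.label)
comm <- as.matrix(read.csv("{tmp_path}/comm.csv", row.names=1, check.names=FALSE))
out <- as.matrix(comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE))
write.csv(out, "{tmp_path}/out.csv")
"""
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        rres = pd.read_csv(tmp_path / "out.csv", index_col=0)
        counts = cm.counts.astype(float)
        for i in range(4):
            for j in range(i + 1, 4):
                mine = beta_mntd(counts[:, i], counts[:, j], D)
                assert mine == pytest.approx(rres.iloc[i, j], abs=1e-10)


class TestBetaNti:
    def test_star_phylogeny_gives_undefined_flag(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(otu1:1,otu2:1,otu3:1,otu4:1,otu5:1,otu6:1);")
        tree = read_tree(p)
        cm = make_cm([[4, 0], [3, 0], [0, 2], [0, 5], [1, 1], [2, 2]],
                     otus=[f"otu{i+1}" for i in range(6)])
        with pytest.warns(UserWarning, match="zero null spread"):
            out = beta_nti(cm, tree, n_null=99, seed=0)
        assert np.isnan(out["beta_nti"]).all()

    def test_monte_carlo_matches_exhaustive_enumeration(self, tmp_path):
        p = tmp_path / "four.nwk"
        p.write_text("((otu1:1,otu2:2):1.5,(otu3:0.5,otu4:3):1);")
        tree = read_tree(p)
        va, vb = [5, 1, 0, 2], [0, 3, 4, 1]
        cm = make_cm(np.array([va, vb]).T, otus=[f"otu{i+1}" for i in range(4)])
        D = cophenetic_distances(tree, cm.otu_ids).data.tolist()
        # exact null over all 4! tip relabelings
        nulls = []
        for perm in itertools.permutations(range(4)):
            Dp = [[D[perm[i]][perm[j]] for j in range(4)] for i in range(4)]
            nulls.append(brute_force_bmntd(va, vb, Dp))
        obs = brute_force_bmntd(va, vb, D)
        exact = (obs - np.mean(nulls)) / np.std(nulls, ddof=1)
        out = beta_nti(cm, tree, n_null=10_000, seed=3)
        assert out.loc[0, "beta_mntd"] == pytest.approx(obs)
        assert out.loc[0, "beta_nti"] == pytest.approx(exact, abs=0.1)

    def test_identical_communities_never_exceed_null(self):
        tree = simulate_tree(12, seed=5)
        ids = sorted(t.name for t in tree.tips())
        # identical communities occupying half the universe, so the taxa
        # shuffle can move them onto other tips
        col = np.concatenate([np.arange(1, 7), np.zeros(6, dtype=int)])
        cm = make_cm(np.tile(col[:, None], (1, 2)), otus=ids)
        out = beta_nti(cm, tree, n_null=199, seed=1)
        assert (out["beta_nti"].dropna() <= 0).all()

    def test_invariant_under_branch_length_rescaling(self, tmp_path):
        base = "((otu1:{a},otu2:{b}):{c},(otu3:{d},otu4:{e}):{f});"
        p1 = tmp_path / "t1.nwk"
        p2 = tmp_path / "t2.nwk"
        p1.write_text(base.format(a=1, b=2, c=1.5, d=0.5, e=3, f=1))
        p2.write_text(base.format(a=10, b=20, c=15, d=5, e=30, f=10))
        cm = make_cm([[5, 0], [1, 3], [0, 4], [2, 1]],
                     otus=[f"otu{i+1}" for i in range(4)])
        o1 = beta_nti(cm, read_tree(p1), n_null=499, seed=9)
        o2 = beta_nti(cm, read_tree(p2), n_null=499, seed=9)
        assert o1["beta_nti"].tolist() == pytest.approx(o2["beta_nti"].tolist())

    def test_too_few_nulls_rejected(self, three_taxon_tree):
        cm = make_cm([[1, 2], [2, 1], [1, 1]], otus=["A", "B", "C"])
        with pytest.raises(ValueError):
            beta_nti(cm, read_tree(three_taxon_tree), n_null=10)


class TestRcBray:
    def test_identical_communities_hit_the_lower_tail(self):
        rng = np.random.default_rng(2)
        col = rng.multinomial(500, np.full(20, 1 / 20))
        tab = np.stack([col, col] + [rng.multinomial(500, np.full(20, 1 / 20))
                                     for _ in range(4)], 1)
        cm = make_cm(tab)
        out = rc_bray(cm, n_null=199, seed=0)
        first = out[(out.sample_a == "s1") & (out.sample_b == "s2")]
        assert float(first["rc_bray"].iloc[0]) <= -0.95

    def test_values_bounded(self):
        rng = np.random.default_rng(3)
        tab = rng.integers(0, 30, (15, 6)) + 1
        out = rc_bray(make_cm(tab), n_null=99, seed=1)
        assert out["rc_bray"].between(-1, 1).all()

    def test_disjoint_communities_from_large_pool_approach_plus_one(self):
        # two disjoint 40-taxon communities inside a 500-taxon pool whose
        # occupancy spreads the null across the pool
        rng = np.random.default_rng(8)
        S = 500
        tab = np.zeros((S, 8), dtype=int)
        blocks = rng.permutation(S)
        for j in range(8):
            pool = blocks[j * 60:(j + 1) * 60]
            tab[pool, j] = rng.multinomial(800, np.full(60, 1 / 60))
        cm = make_cm(tab).drop_empty_otus()
        out = rc_bray(cm, n_null=299, seed=4)
        assert out["rc_bray"].median() > 0.95

    def test_tiny_case_matches_exact_tie_arithmetic(self):
        # two singleton-richness samples on a 2-taxon universe: the null
        # picks one taxon per sample with equal occurrence weight, so
        # P(same taxon) = 1/2 -> RC' = P(null < obs) + ties/2 rescaled = 0
        cm = make_cm([[3, 0], [0, 3]])
        out = rc_bray(cm, n_null=4000, seed=6)
        # obs BC = 1; null BC is 0 w.p. 1/2 (same taxon) else 1 (tie)
        # RC = (0.5 + 0.5*0.5) -> RC' = 2*0.75 - 1 = 0.5
        sigma = np.sqrt(0.25 / 4000) * 3  # 3 sigma on the tie fraction
        assert float(out["rc_bray"].iloc[0]) == pytest.approx(0.5, abs=3 * sigma)

    def test_zero_richness_sample_rejected(self):
        cm = make_cm([[1, 0], [1, 0]])
        with pytest.raises(ValueError):
            rc_bray(cm, n_null=99, seed=0)


class TestPartitionRule:
    @pytest.mark.parametrize(
        "nti,rc,expected",
        [
            (2.5, 0.1, "heterogeneous_selection"),
            (1.0, 0.97, "dispersal_limitation"),
            (-1.0, 0.0, "undominated"),
            (-2.01, 0.99, "homogeneous_selection"),  # selection precedence
            (0.0, -0.99, "homogenizing_dispersal"),
        ],
    )
    def test_threshold_examples(self, nti, rc, expected):
        assert partition_processes(nti, rc) == expected

    def test_undefined_inputs_rejected(self):
        with pytest.raises(ValueError):
            partition_processes(float("nan"), 0.0)


class TestAggregatePartition:
    def test_single_process_fraction_one(self):
        df = pd.DataFrame({"process": ["undominated"] * 10})
        part = aggregate_partition(df)
        assert part.fractions["undominated"] == 1.0
        assert part.n_pairs == 10

    def test_mixed_fractions(self):
        df = pd.DataFrame(
            {"process": ["heterogeneous_selection"] * 4 + ["dispersal_limitation"] * 6}
        )
        part = aggregate_partition(df)
        assert part.fractions["heterogeneous_selection"] == pytest.approx(0.4)
        assert part.fractions["dispersal_limitation"] == pytest.approx(0.6)
        assert part.deterministic_total == pytest.approx(0.4)
        assert part.stochastic_total == pytest.approx(0.6)
        assert sum(part.fractions.values()) == pytest.approx(1.0)

    def test_all_undefined_reports_na(self):
        df = pd.DataFrame({"process": [None, None]})
        part = aggregate_partition(df)
        assert part.is_na
        assert all(np.isnan(v) for v in part.fractions.values())


class TestSeedSubstreams:
    def test_pair_streams_are_deterministic_and_distinct(self):
        a = _pair_rng(5, 0, 0).random(3)
        b = _pair_rng(5, 0, 0).random(3)
        c = _pair_rng(5, 1, 0).random(3)
        assert np.allclose(a, b)
        assert not np.allclose(a, c)
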