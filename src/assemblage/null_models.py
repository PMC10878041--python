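"""Phylogenetic (βMNTD/βNTI) and abundance (Raup-Crick) null models.

For every pair of samples the observed abundance-weighted β-mean nearest
taxon distance (βMNTD) is standardized against a null distribution obtained
by shuffling taxa across the tips of the phylogeny, giving βNTI — the
number of null standard deviations separating observed from expected
phylogenetic turnover.  Pairs with |βNTI| > 2 are attributed to
deterministic selection (heterogeneous if βNTI > +2, homogeneous if
βNTI < −2).  The remaining, stochastic pairs are split with the Bray-Curtis
Raup-Crick metric (RC_bray): the empirical percentile of the observed
Bray-Curtis dissimilarity within a null distribution of probabilistically
assembled communities, rescaled to [−1, 1].  RC > 0.95 indicates dispersal
limitation, RC < −0.95 homogenizing dispersal, and |RC| ≤ 0.95 the
"undominated" fraction.

The RC null preserves each sample's observed richness and total abundance:
taxa are drawn without replacement with probability proportional to their
occurrence frequency across the analysis group, then the remaining
individuals are assigned multinomially with probability proportional to
regional relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io_tables import CommunityMatrix

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)
DETERMINISTIC = PROCESSES[:2]
STOCHASTIC = PROCESSES[2:]

# memory budget for the vectorized null: elements per chunk of shuffles
_CHUNK_ELEMS = 2_000_000


def cophenetic_distances(tree: TreeNode, otu_ids=None) -> DistanceMatrix:
    """Patristic (sum of branch lengths) distances between tips.

    When ``otu_ids`` is given, the matrix is restricted to — and ordered
    by — those tips; absentees raise with the full list of missing ids.
    """
    dm = tree.tip_tip_distances()
    if otu_ids is None:
        return dm
    ids = [str(o) for o in otu_ids]
    missing = sorted(set(ids) - set(dm.ids))
    if missing:
        raise ValueError(f"OTUs missing from the tree: {missing}")
    return dm.filter(ids)


def beta_mntd(comm_a, comm_b, d, abundance_weighted: bool = True) -> float:
    """β-mean nearest taxon distance between two abundance vectors.

    For each taxon present in one community, the distance to its nearest
    relative present in the other community, averaged with relative-
    abundance weights (uniform if ``abundance_weighted=False``) and
    symmetrized.  A taxon present in both communities contributes 0.
    """
    va = np.asarray(comm_a, dtype=float)
    vb = np.asarray(comm_b, dtype=float)
    D = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if va.sum() == 0 or vb.sum() == 0:
        raise ValueError("empty community")
    ia = np.flatnonzero(va)
    ib = np.flatnonzero(vb)
    A = D[np.ix_(ia, ib)]
    if abundance_weighted:
        fa = va[ia] / va[ia].sum()
        fb = vb[ib] / vb[ib].sum()
    else:
        fa = np.full(ia.size, 1.0 / ia.size)
        fb = np.full(ib.size, 1.0 / ib.size)
    return float(0.5 * (fa @ A.min(axis=1) + fb @ A.min(axis=0)))


def _pair_rng(seed: int, pair_index: int, stream: int) -> np.random.Generator:
    """Deterministic per-pair substream so parallel and serial runs agree."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(pair_index, stream))
    )


def _beta_nti_pair(va, vb, D, n_null, rng, abundance_weighted=True):
    ia = np.flatnonzero(va)
    ib = np.flatnonzero(vb)
    if abundance_weighted:
        fa = va[ia] / va[ia].sum()
        fb = vb[ib] / vb[ib].sum()
    else:
        fa = np.full(ia.size, 1.0 / ia.size)
        fb = np.full(ib.size, 1.0 / ib.size)
    A = D[np.ix_(ia, ib)]
    obs = 0.5 * (fa @ A.min(axis=1) + fb @ A.min(axis=0))
    S = D.shape[0]
    nulls = np.empty(n_null)
    chunk = max(1, _CHUNK_ELEMS // max(ia.size * ib.size, 1))
    done = 0
    while done < n_null:
        r = min(chunk, n_null - done)
        perms = np.empty((r, S), dtype=np.intp)
        for k in range(r):
            perms[k] = rng.permutation(S)
        An = D[perms[:, ia][:, :, None], perms[:, ib][:, None, :]]
        nulls[done:done + r] = 0.5 * (An.min(axis=2) @ fa + An.min(axis=1) @ fb)
        done += r
    sd = nulls.std(ddof=1)
    mean = nulls.mean()
    # degenerate null (all shuffles equivalent): spread at the level of
    # floating-point accumulation noise counts as zero
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return float(obs), float("nan")
    return float(obs), float((obs - mean) / sd)


def beta_nti(
    cm: CommunityMatrix,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    pairs=None,
) -> pd.DataFrame:
    """βMNTD and βNTI for sample pairs.

    The null shuffles taxon identities across the phylogeny (equivalently,
    permutes the rows/columns of the cophenetic matrix) independently per
    replicate, holding the abundance vectors fixed.  Pairs whose null
    distribution has zero spread get βNTI = NaN and are excluded from
    process partitioning downstream.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    dm = cophenetic_distances(tree, cm.otu_ids)
    D = dm.data
    counts = cm.counts.astype(float)
    samples = cm.sample_ids
    if pairs is None:
        pairs = [(i, j) for i in range(len(samples)) for j in range(i + 1, len(samples))]
    rows = []
    undefined = 0
    for idx, (i, j) in enumerate(pairs):
        rng = _pair_rng(seed, idx, 0)
        obs, nti = _beta_nti_pair(counts[:, i], counts[:, j], D, n_null, rng,
                                  abundance_weighted)
        if np.isnan(nti):
            undefined += 1
        rows.append((samples[i], samples[j], obs, nti))
    if undefined:
        warnings.warn(
            f"{undefined} pair(s) have zero null spread; βNTI undefined there",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "beta_mntd", "beta_nti"])


def _rc_null_assembly(richness, total, log_occ, reg_p, rng):
    """One null community: occurrence-weighted taxa, abundance-weighted fill."""
    S = log_occ.size
    keys = log_occ + rng.gumbel(size=S)
    sel = np.argpartition(-keys, richness - 1)[:richness]
    counts = np.zeros(S)
    counts[sel] = 1
    w = reg_p[sel]
    tot = w.sum()
    probs = w / tot if tot > 0 else np.full(richness, 1.0 / richness)
    counts[sel] += rng.multinomial(total - richness, probs)
    return counts


def _bray(x, y):
    return 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def rc_bray(
    cm: CommunityMatrix,
    n_null: int = 999,
    seed: int = 0,
    pairs=None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis dissimilarity, rescaled to [−1, 1].

    RC' = 2 · ((#null < obs) + ½·(#null = obs)) / n_null − 1.  Ties take
    half weight, which keeps identical samples from saturating at −1
    artificially.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    richness = (counts > 0).sum(axis=0)
    if np.any(richness == 0):
        empty = [s for s, r in zip(cm.sample_ids, richness) if r == 0]
        raise ValueError(f"samples with zero richness: {empty}")
    occ = (counts > 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore"):
        log_occ = np.where(occ > 0, np.log(occ), -np.inf)
    reg_p = (counts / counts.sum(axis=0)).mean(axis=1)
    totals = counts.sum(axis=0).astype(int)
    samples = cm.sample_ids
    if pairs is None:
        pairs = [(i, j) for i in range(len(samples)) for j in range(i + 1, len(samples))]
    rows = []
    for idx, (i, j) in enumerate(pairs):
        rng = _pair_rng(seed, idx, 1)
        obs = _bray(counts[:, i], counts[:, j])
        below = ties = 0
        for _ in range(n_null):
            na = _rc_null_assembly(int(richness[i]), int(totals[i]), log_occ, reg_p, rng)
            nb = _rc_null_assembly(int(richness[j]), int(totals[j]), log_occ, reg_p, rng)
            d = _bray(na, nb)
            if d < obs:
                below += 1
            elif d == obs:
                ties += 1
        rc = 2 * (below + 0.5 * ties) / n_null - 1
        rows.append((samples[i], samples[j], obs, rc))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "bray_curtis", "rc_bray"])


def partition_processes(beta_nti: float, rc: float) -> str:
    """Assign one sample pair to an assembly process.

    βNTI > +2 → heterogeneous selection; βNTI < −2 → homogeneous selection
    (selection takes precedence over the RC rule); otherwise RC > 0.95 →
    dispersal limitation, RC < −0.95 → homogenizing dispersal, else
    undominated.
    """
    if np.isnan(beta_nti) or np.isnan(rc):
        raise ValueError("undefined beta_nti or rc; exclude the pair upstream")
    if beta_nti > 2:
        return "heterogeneous_selection"
    if beta_nti < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_assembly(
    cm: CommunityMatrix,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """βMNTD, βNTI, RC_bray and the process label for every sample pair."""
    nti = beta_nti(cm, tree, n_null=n_null, seed=seed,
                   abundance_weighted=abundance_weighted)
    rc = rc_bray(cm, n_null=n_null, seed=seed)
    out = nti.merge(rc, on=["sample_a", "sample_b"])
    proc = []
    for _, row in out.iterrows():
        if np.isnan(row["beta_nti"]):
            proc.append(None)
        else:
            proc.append(partition_processes(row["beta_nti"], row["rc_bray"]))
    out["process"] = proc
    return out


@dataclass(frozen=True)
class ProcessPartition:
    """Fractions of sample pairs assigned to each assembly process."""

    group: str
    fractions: dict           # process name -> fraction (NaN if no valid pairs)
    n_pairs: int              # valid (defined) pairs

    @property
    def deterministic_total(self) -> float:
        return sum(self.fractions[p] for p in DETERMINISTIC)

    @property
    def stochastic_total(self) -> float:
        return sum(self.fractions[p] for p in STOCHASTIC)

    @property
    def is_na(self) -> bool:
        return self.n_pairs == 0


def aggregate_partition(pairs: pd.DataFrame, group: str = "") -> ProcessPartition:
    """Process fractions over the valid pairs of one analysis group.

    Pairs with an undefined βNTI (process None/NaN) are excluded; a group
    with no valid pairs is reported as NA (all fractions NaN).
    """
    valid = pairs[pairs["process"].notna()] if "process" in pairs else pairs.iloc[0:0]
    n = len(valid)
    if n == 0:
        return ProcessPartition(group, {p: float("nan") for p in PROCESSES}, 0)
    fracs = {p: float((valid["process"] == p).sum()) / n for p in PROCESSES}
    return ProcessPartition(group, fracs, n)
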