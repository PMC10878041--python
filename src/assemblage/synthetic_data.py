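"""Synthetic microbial communities with known generative assembly processes.

Every inference stage in this package (taxon classification, neutral-model
fitting, βNTI/RC-bray process partitioning) can be exercised end-to-end on
data whose ground truth is known, so parameter recovery and process
recovery are testable without any sequencing data.

The generators cover the canonical assembly scenarios:

* **neutral** — local communities of N individuals following the classic
  death–replacement dynamics: at every step one random individual dies and
  is replaced, with probability m, by an immigrant drawn from the
  metacommunity, otherwise by the offspring of a random local individual.
  m is exactly the migration rate the neutral community model estimates.
* **selection** — taxa carry a Brownian trait evolved on the phylogeny and
  are filtered by a Gaussian environmental filter exp(−(trait−env)²/2σ²);
  contrasting environments with a strong filter (small σ) produce
  heterogeneous selection between samples.
* **dispersal limitation** — each sample is founded from its own disjoint
  slice of the metacommunity (richness capped) and then drifts with m ≈ 0,
  producing abundance turnover far above the Raup-Crick null.

`make_study_like_dataset` combines the three into a survey-shaped data set:
three condition groups × six replicates × two sampling dates, a heavy-
tailed metacommunity with a dedicated pool of taxa that never rise above
0.01% relative abundance (the always-rare biosphere), and a phylogeny over
all OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_tables import CommunityMatrix, SampleMetadata


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the community simulators.

    ``generations`` is the number of death–replacement steps per community;
    ``None`` means 10·N, a burn-in that, combined with initialization at
    the exact stationary marginal, leaves the chain at quasi-stationarity.
    ``selection_strength`` is the Gaussian filter width σ in trait units —
    smaller is stronger; 0 disables selection entirely (neutral sampling).
    """

    n_otus_meta: int = 1000
    meta_distribution: str = "logseries"   # or "lognormal"
    meta_shape: float = 0.999              # logseries p / lognormal sigma
    n_samples: int = 12
    N: int = 1000
    m: float = 0.5
    generations: int | None = None
    selection_strength: float = 0.0
    env_values: tuple | None = None
    trait_rate: float = 1.0
    founder_richness: int = 40
    drift_m: float = 0.001
    seed: int = 0

    @property
    def steps(self) -> int:
        return 10 * self.N if self.generations is None else self.generations


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete simulated survey: counts, tree, metadata and ground truth."""

    community: CommunityMatrix
    tree: TreeNode
    metadata: SampleMetadata
    truth: dict = field(default_factory=dict)


def _otu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"otu_{i:0{width}d}" for i in range(1, n + 1)]


def simulate_metacommunity(config: SimulationConfig) -> np.ndarray:
    """Metacommunity relative abundances (heavy-tailed, sums to 1).

    Log-series (default) produces the many-rare-taxa shape typical of
    amplicon surveys — at the default shape most taxa sit far below 1e-4
    relative abundance, populating the always-rare class.
    """
    if config.n_otus_meta < 10:
        raise ValueError("n_otus_meta must be at least 10")
    rng = np.random.default_rng(config.seed)
    if config.meta_distribution == "logseries":
        if not (0 < config.meta_shape < 1):
            raise ValueError("logseries shape must lie in (0, 1)")
        weights = rng.logseries(config.meta_shape, size=config.n_otus_meta).astype(float)
    elif config.meta_distribution == "lognormal":
        if config.meta_shape <= 0:
            raise ValueError("lognormal sigma must be positive")
        weights = rng.lognormal(0.0, config.meta_shape, size=config.n_otus_meta)
    else:
        raise ValueError(f"unknown meta_distribution {config.meta_distribution!r}")
    return weights / weights.sum()


def _moran(counts: np.ndarray, meta: np.ndarray, m: float, steps: int,
           rng: np.random.Generator) -> np.ndarray:
    """Run `steps` death–replacement events on one community (in place-free)."""
    S = meta.size
    N = int(counts.sum())
    ind = np.repeat(np.arange(S), counts)
    if steps == 0:
        return counts.copy()
    cdf = np.cumsum(meta)
    us = rng.random(steps)
    deaths = rng.integers(0, N, steps)
    births = rng.integers(0, N, steps)
    imm = np.searchsorted(cdf, rng.random(steps))
    for t in range(steps):
        if us[t] < m:
            ind[deaths[t]] = imm[t]
        else:
            ind[deaths[t]] = ind[births[t]]
    return np.bincount(ind, minlength=S)


def _stationary_init(meta: np.ndarray, N: int, m: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw from the exact stationary marginal of the death–replacement chain.

    The stationary law is Dirichlet-multinomial with immigration intensity
    I = m(N−1)/(1−m); at m = 1 the community is a plain multinomial sample
    of the metacommunity.
    """
    if m >= 1:
        return rng.multinomial(N, meta)
    I = m * (N - 1) / (1 - m)
    alpha = np.maximum(I * meta, 1e-12)
    return rng.multinomial(N, rng.dirichlet(alpha))


def simulate_neutral_local(meta: np.ndarray, config: SimulationConfig) -> CommunityMatrix:
    """Independent neutral local communities sampled from one metacommunity.

    Each sample is initialized at the stationary marginal and then run for
    ``config.steps`` death–replacement events (at least 10·N recommended).
    """
    if config.N < 10:
        raise ValueError("N must be at least 10")
    if not (0 < config.m <= 1):
        raise ValueError("m must lie in (0, 1]")
    rng = np.random.default_rng(config.seed)
    cols = []
    for _ in range(config.n_samples):
        c0 = _stationary_init(meta, config.N, config.m, rng)
        cols.append(_moran(c0, meta, config.m, config.steps, rng))
    tab = np.stack(cols, axis=1)
    df = pd.DataFrame(tab, index=_otu_ids(meta.size),
                      columns=[f"s{i+1:02d}" for i in range(config.n_samples)])
    return CommunityMatrix(df)


# ---------------------------------------------------------------------------
# phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, tip_names: list[str] | None = None) -> TreeNode:
    """Pure-birth (Yule) tree with n_tips extant tips.

    Lineages split at unit rate; inter-event waiting times are exponential
    with rate equal to the number of active lineages, and every branch gets
    the resulting positive length (tips share the present time, so the tree
    is ultrametric).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(0, len(active))
        node = active.pop(k)
        node.length = t - birth[id(node)] if node.parent is not None else None
        for _ in range(2):
            child = TreeNode()
            birth[id(child)] = t
            node.append(child)
            active.append(child)
    t += rng.exponential(1.0 / n_tips)  # terminal stretch to the present
    names = tip_names if tip_names is not None else _otu_ids(n_tips)
    if len(names) != n_tips:
        raise ValueError("tip_names length must equal n_tips")
    order = rng.permutation(n_tips)
    for k, tip in enumerate(active):
        tip.length = t - birth[id(tip)]
        tip.name = names[order[k]]
    return root


def evolve_trait(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Brownian-motion trait on the tree: per-branch N(0, rate·length) steps.

    Closely related tips share most of their root-to-tip path and therefore
    end up with similar trait values (phylogenetic signal ≈ 1 by
    construction).
    """
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(rate * node.length)) if node.length else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait")


# ---------------------------------------------------------------------------
# selection and dispersal scenarios
# ---------------------------------------------------------------------------

def simulate_selected_communities(
    tree: TreeNode, traits: pd.Series, config: SimulationConfig,
    meta: np.ndarray | None = None,
) -> CommunityMatrix:
    """Communities filtered by trait–environment matching.

    Sampling weights are w_i ∝ meta_i · exp(−(trait_i − env)² / 2σ²) with
    σ = ``config.selection_strength``; σ → ∞ recovers neutral weights and
    σ = 0 is treated as "no selection" (delegates to neutral sampling).
    ``config.env_values`` supplies one environment scalar per sample.
    """
    tip_names = [t.name for t in tree.tips()]
    traits = traits.reindex(tip_names)
    if traits.isna().any():
        raise ValueError("traits missing for some tips")
    rng = np.random.default_rng(config.seed)
    if meta is None:
        meta = simulate_metacommunity(replace(config, n_otus_meta=len(tip_names)))
    if config.env_values is None:
        raise ValueError("env_values must be supplied per sample")
    envs = np.asarray(config.env_values, dtype=float)
    if envs.size != config.n_samples:
        raise ValueError("need one env value per sample")
    tvals = traits.to_numpy()
    cols = []
    sigma = config.selection_strength
    for e in envs:
        if sigma <= 0:
            w = meta
        else:
            w = meta * np.exp(-((tvals - e) ** 2) / (2 * sigma**2))
            if w.sum() <= 0:
                w = meta
        cols.append(rng.multinomial(config.N, w / w.sum()))
    df = pd.DataFrame(np.stack(cols, 1), index=tip_names,
                      columns=[f"s{i+1:02d}" for i in range(config.n_samples)])
    return CommunityMatrix(df)


def simulate_dispersal_limited(meta: np.ndarray, config: SimulationConfig) -> CommunityMatrix:
    """Dispersal-limited communities: disjoint founder pools plus drift.

    The metacommunity is partitioned at random into per-sample founder
    pools of ``config.founder_richness`` taxa (so local pools do not
    exchange migrants at all — the maximal dispersal-limitation scenario);
    each community is a multinomial draw of N individuals from its pool,
    then drifts for ``config.steps`` events with migration ``drift_m`` ≈ 0.
    """
    if config.n_samples < 4:
        raise ValueError("need at least 4 samples")
    r = config.founder_richness
    if r < 2:
        raise ValueError("founder_richness must be at least 2")
    S = meta.size
    if config.n_samples * r > S:
        raise ValueError(
            f"cannot cut {config.n_samples} disjoint founder pools of {r} "
            f"taxa from {S} metacommunity taxa"
        )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(S)
    steps = 0 if config.generations is None else config.generations
    cols = []
    for i in range(config.n_samples):
        pool = perm[i * r:(i + 1) * r]
        w = np.zeros(S)
        w[pool] = meta[pool] + 1e-12
        c0 = rng.multinomial(config.N, w / w.sum())
        cols.append(_moran(c0, meta, config.drift_m, steps, rng))
    df = pd.DataFrame(np.stack(cols, 1), index=_otu_ids(S),
                      columns=[f"s{i+1:02d}" for i in range(config.n_samples)])
    return CommunityMatrix(df)


# ---------------------------------------------------------------------------
# study-shaped composite data set
# ---------------------------------------------------------------------------

GROUPS = ("unstained", "black_stain", "attenuated")


def make_study_like_dataset(
    seed: int,
    n_otus_core: int = 700,
    n_otus_rare: int = 300,
    N: int = 12_000,
    n_replicates: int = 6,
    n_dates: int = 2,
    singletons_per_sample: int = 40,
    m_neutral: float = 0.5,
    selection_sigma_frac: float = 0.4,
    founder_richness: int = 50,
) -> SyntheticDataset:
    """A three-condition survey with known assembly processes per group.

    * ``unstained`` — neutral, high migration (m = ``m_neutral``);
    * ``black_stain`` — selection-dominated: the abundant portion of the
      metacommunity is filtered by trait–environment matching, with the
      replicate locations split between two contrasting environments;
    * ``attenuated`` — dispersal-limited (disjoint founder pools), with a
      twist: its always-rare taxa are *selected*, drawn from trait-matched
      ends of a dedicated rare-taxon pool.

    Every sample also receives ``singletons_per_sample`` single-read taxa
    from the rare pool (n_otus_rare tips reserved outside the core
    metacommunity), so each sample's always-rare fraction is populated;
    with the default N = 12,000 a single read is 8.3e-5 < 1e-4 relative
    abundance.  Column sums equal N exactly.  The two sampling dates are
    independent draws from the same per-group process.
    """
    S = n_otus_core + n_otus_rare
    rng = np.random.default_rng(seed)
    sub = np.random.SeedSequence(seed, spawn_key=(42,)).generate_state(6)

    ids = _otu_ids(S)
    tree = simulate_tree(S, int(sub[0] % 2**31), tip_names=ids)
    traits = evolve_trait(tree, rate=1.0, seed=int(sub[1] % 2**31))

    core_idx = np.sort(rng.choice(S, n_otus_core, replace=False))
    rare_idx = np.setdiff1d(np.arange(S), core_idx)
    meta = np.zeros(S)
    core_cfg = SimulationConfig(n_otus_meta=n_otus_core, seed=int(sub[2] % 2**31))
    meta[core_idx] = simulate_metacommunity(core_cfg)

    trait_arr = traits.reindex(ids).to_numpy()
    t_sd = trait_arr.std()
    rare_traits = trait_arr[rare_idx]
    rare_low = rare_idx[rare_traits <= np.median(rare_traits)]
    rare_high = rare_idx[rare_traits > np.median(rare_traits)]

    n_samples = n_replicates * n_dates
    n_main = N - singletons_per_sample
    envs = np.where(np.arange(n_replicates) % 2 == 0, -1.5, 1.5) * t_sd

    def add_singletons(col, pool, rng):
        chosen = rng.choice(pool, singletons_per_sample, replace=False)
        col = col.copy()
        col[chosen] += 1
        return col

    columns, names, meta_rows = [], [], []
    # --- unstained: neutral high-m ---------------------------------------
    g_rng = np.random.default_rng(int(sub[3] % 2**31))
    cfg = SimulationConfig(N=n_main, m=m_neutral, n_samples=n_samples,
                           seed=int(sub[3] % 2**31))
    neutral = simulate_neutral_local(meta[core_idx] / meta[core_idx].sum(),
                                     cfg)
    for k in range(n_samples):
        col = np.zeros(S, dtype=np.int64)
        col[core_idx] = neutral.counts[:, k]
        col = add_singletons(col, np.concatenate([rare_low, rare_high]), g_rng)
        columns.append(col)
        rep, date = k % n_replicates, k // n_replicates
        names.append(f"unstained_d{date+1}_r{rep+1}")
        meta_rows.append(("unstained", f"d{date+1}"))

    # --- black stain: selection on the abundant portion ------------------
    g_rng = np.random.default_rng(int(sub[4] % 2**31))
    sigma = selection_sigma_frac * t_sd
    core_mask = meta > 0  # the filter acts on the core metacommunity only;
    for k in range(n_samples):  # the rare singleton pool disperses neutrally
        rep, date = k % n_replicates, k // n_replicates
        e = envs[rep]
        w = meta.copy()
        w[core_mask] *= np.exp(-((trait_arr[core_mask] - e) ** 2) / (2 * sigma**2))
        col = g_rng.multinomial(n_main, w / w.sum())
        col = add_singletons(col, np.concatenate([rare_low, rare_high]), g_rng)
        columns.append(col)
        names.append(f"black_stain_d{date+1}_r{rep+1}")
        meta_rows.append(("black_stain", f"d{date+1}"))

    # --- attenuated: dispersal-limited core, selected always-rare --------
    g_rng = np.random.default_rng(int(sub[5] % 2**31))
    perm = g_rng.permutation(core_idx)
    for k in range(n_samples):
        rep, date = k % n_replicates, k // n_replicates
        pool = perm[k * founder_richness:(k + 1) * founder_richness]
        w = np.zeros(S)
        w[pool] = meta[pool] + 1e-12
        col = g_rng.multinomial(n_main, w / w.sum())
        rare_pool = rare_low if envs[rep] < 0 else rare_high
        col = add_singletons(col, rare_pool, g_rng)
        columns.append(col)
        names.append(f"attenuated_d{date+1}_r{rep+1}")
        meta_rows.append(("attenuated", f"d{date+1}"))

    df = pd.DataFrame(np.stack(columns, 1), index=ids, columns=names)
    md = SampleMetadata(pd.DataFrame(meta_rows, columns=["group", "date"],
                                     index=pd.Index(names, name="sample_id")))
    truth = {
        "unstained": {"process": "neutral", "m": m_neutral},
        "black_stain": {"process": "heterogeneous_selection"},
        "attenuated": {"process": "dispersal_limitation",
                       "always_rare": "heterogeneous_selection"},
    }
    return SyntheticDataset(CommunityMatrix(df), tree, md, truth)
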