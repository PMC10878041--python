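"""End-to-end orchestration: classify → NCM → null models → scenarios.

Runs the whole inference chain for one marker table: abundance categories
are assigned over all samples combined; the neutral community model is fit
per condition group on all taxa; the βNTI/RC-bray process partition is
computed per condition group for the whole community and for each taxon
category large enough (≥ 6 OTUs); and the resulting per-category
deterministic-fraction trajectories across the ordered condition states
(resistant → impacted → resilient) are mapped onto four conceptual
disturbance scenarios:

1. disturbance imposes selection (stochastic → deterministic → relaxing);
2. disturbance relaxes selection (deterministic → stochastic → returning);
3. absence of selection (stochastic throughout);
4. disturbance removal leads to selection (deterministic only in the
   resilient state) — the novel always-rare-taxa scenario.

The scenario rules are an explicit operationalization of a conceptual
continuum; the deterministic-state threshold τ is configuration, not
biology, and is always reported alongside the assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__
from .abundance_classes import (
    AbundanceCategory,
    CategoryAssignment,
    check_min_otus,
    classify_otus,
    subset_by_category,
)
from .io_tables import CommunityMatrix, SampleMetadata, to_relative
from .ncm import NCMFit, fit_ncm
from .null_models import (
    ProcessPartition,
    aggregate_partition,
    pairwise_assembly,
)

logger = logging.getLogger(__name__)

CATEGORIES_ANALYZED = (
    "all",
    AbundanceCategory.DOMINANT.value,
    AbundanceCategory.CONDITIONALLY_RARE.value,
    AbundanceCategory.ALWAYS_RARE.value,
    AbundanceCategory.MODERATE.value,
)


@dataclass(frozen=True)
class ScenarioAssignment:
    """Scenario for one taxon category given its deterministic fractions."""

    det_fractions: tuple       # (resistant, impacted, resilient)
    scenario: int | None       # 1..4, or None when no rule matches / NA input
    tau: float
    reason: str = ""


def assign_scenario(det_fractions, tau: float = 0.5) -> ScenarioAssignment:
    """Map a (resistant, impacted, resilient) deterministic-fraction triple
    onto one of the four disturbance scenarios.

    A state counts as "deterministic" when its deterministic fraction is at
    least ``tau``.  Rules are checked in the order 2, 1, 4, 3:

    * scenario 2 — deterministic, stochastic, deterministic;
    * scenario 1 — resistant stochastic, impacted deterministic, and the
      resilient fraction relaxing below the impacted one;
    * scenario 4 — resistant and impacted stochastic, with selection
      emerging in the resilient state (highest fraction of the three,
      and positive);
    * scenario 3 — stochastic throughout.
    """
    f = tuple(float(x) for x in det_fractions)
    if len(f) != 3:
        raise ValueError("need exactly three fractions")
    if any(np.isnan(x) for x in f):
        return ScenarioAssignment(f, None, tau, "NA fractions")
    if any(not (0 <= x <= 1) for x in f):
        raise ValueError(f"fractions must lie in [0, 1], got {f}")
    res, imp, resil = f
    s_res, s_imp, s_resil = (x >= tau for x in f)
    if s_res and not s_imp and s_resil:
        return ScenarioAssignment(f, 2, tau)
    if not s_res and s_imp and resil < imp:
        return ScenarioAssignment(f, 1, tau)
    if not s_res and not s_imp and resil > res and resil > imp and resil > 0:
        return ScenarioAssignment(f, 4, tau)
    if not (s_res or s_imp or s_resil):
        return ScenarioAssignment(f, 3, tau)
    return ScenarioAssignment(f, None, tau, "no rule matched")


@dataclass(frozen=True)
class AnalysisBundle:
    """Everything `run_full_analysis` computes."""

    assignment: CategoryAssignment
    ncm_fits: dict                      # group -> NCMFit
    partitions: dict                    # (group, category) -> ProcessPartition | None
    partition_reasons: dict             # (group, category) -> reason when None/NA
    pairs: pd.DataFrame = field(repr=False)
    scenarios: dict = field(default_factory=dict)  # category -> ScenarioAssignment
    params: dict = field(default_factory=dict)

    def partition_table(self) -> pd.DataFrame:
        rows = []
        for (g, c), part in self.partitions.items():
            row = {"group": g, "category": c}
            if part is None or part.is_na:
                row["n_pairs"] = 0
                row["note"] = self.partition_reasons.get((g, c), "NA")
            else:
                row["n_pairs"] = part.n_pairs
                row.update(part.fractions)
                row["deterministic_total"] = part.deterministic_total
                row["stochastic_total"] = part.stochastic_total
                row["note"] = ""
            rows.append(row)
        return pd.DataFrame(rows)

    def ncm_table(self) -> pd.DataFrame:
        rows = []
        for g, fit in self.ncm_fits.items():
            rows.append(
                {
                    "group": g,
                    "m": fit.m,
                    "m_prob": fit.m_prob,
                    "N": fit.N,
                    "r_squared": fit.r_squared,
                    "n_otus": fit.n_otus_used,
                    "aic": fit.aic,
                    "bic": fit.bic,
                }
            )
        return pd.DataFrame(rows)

    def scenario_table(self) -> pd.DataFrame:
        rows = []
        for c, sc in self.scenarios.items():
            rows.append(
                {
                    "category": c,
                    "det_resistant": sc.det_fractions[0],
                    "det_impacted": sc.det_fractions[1],
                    "det_resilient": sc.det_fractions[2],
                    "scenario": sc.scenario if sc.scenario is not None else "unassigned",
                    "tau": sc.tau,
                    "note": sc.reason,
                }
            )
        return pd.DataFrame(rows)


def run_full_analysis(
    cm: CommunityMatrix,
    tree: TreeNode,
    metadata: SampleMetadata,
    group_order: tuple | None = None,
    n_null: int = 999,
    seed: int = 0,
    min_otus: int = 6,
    tau: float = 0.5,
    category_trees: dict | None = None,
    out_dir=None,
) -> AnalysisBundle:
    """Run the full assembly analysis for one marker data set.

    ``group_order`` gives the condition groups in disturbance order
    (resistant, impacted, resilient); defaults to the order groups first
    appear in the metadata.  Sample pairs are compared within condition
    group only.  Categories or groups that fail the ≥ ``min_otus`` rule are
    recorded as NA with a reason rather than silently dropped.
    """
    extra = set(cm.sample_ids) - set(metadata.sample_ids)
    if extra:
        raise ValueError(f"samples missing from metadata: {sorted(extra)}")
    groups = list(group_order) if group_order is not None else metadata.groups
    unknown = set(groups) - set(metadata.groups)
    if unknown:
        raise ValueError(f"groups not present in metadata: {sorted(unknown)}")

    assignment = classify_otus(to_relative(cm))

    ncm_fits: dict = {}
    partitions: dict = {}
    reasons: dict = {}
    pair_tables = []

    for gi, group in enumerate(groups):
        g_samples = [s for s in metadata.samples_in_group(group) if s in set(cm.sample_ids)]
        g_cm = cm.select_samples(g_samples).drop_empty_otus()
        ncm_fits[group] = fit_ncm(g_cm)
        for ci, category in enumerate(CATEGORIES_ANALYZED):
            if category == "all":
                sub = g_cm
            else:
                sub = subset_by_category(cm, assignment, category)
                sub = sub.select_samples(g_samples).drop_empty_otus()
                nonempty = sub.sample_sums()[sub.sample_sums() > 0].index.tolist()
                if len(nonempty) < sub.n_samples:
                    logger.warning(
                        "%s/%s: dropping %d empty sample(s)",
                        group, category, sub.n_samples - len(nonempty),
                    )
                    sub = sub.select_samples(nonempty)
            if not check_min_otus(sub, min_otus):
                partitions[(group, category)] = None
                reasons[(group, category)] = f"fewer than {min_otus} OTUs"
                continue
            if sub.n_samples < 2:
                partitions[(group, category)] = None
                reasons[(group, category)] = "fewer than 2 non-empty samples"
                continue
            use_tree = tree
            if category_trees and category in category_trees:
                use_tree = category_trees[category]
            sub_seed = int(
                np.random.SeedSequence(seed, spawn_key=(gi, ci)).generate_state(1)[0]
                % 2**31
            )
            pairs = pairwise_assembly(sub, use_tree, n_null=n_null, seed=sub_seed)
            pairs.insert(0, "category", category)
            pairs.insert(0, "group", group)
            pair_tables.append(pairs)
            part = aggregate_partition(pairs, group=f"{group}:{category}")
            partitions[(group, category)] = part
            if part.is_na:
                reasons[(group, category)] = "no valid pairs"

    pairs_df = (
        pd.concat(pair_tables, ignore_index=True)
        if pair_tables
        else pd.DataFrame(
            columns=["group", "category", "sample_a", "sample_b",
                     "beta_mntd", "beta_nti", "bray_curtis", "rc_bray", "process"]
        )
    )

    scenarios = {}
    if len(groups) == 3:
        for category in CATEGORIES_ANALYZED:
            triple = []
            for group in groups:
                part = partitions.get((group, category))
                triple.append(
                    float("nan") if part is None or part.is_na else part.deterministic_total
                )
            scenarios[category] = assign_scenario(triple, tau=tau)

    params = {
        "n_null": n_null,
        "seed": seed,
        "min_otus": min_otus,
        "tau": tau,
        "groups": groups,
        "version": __version__,
    }
    bundle = AnalysisBundle(
        assignment=assignment,
        ncm_fits=ncm_fits,
        partitions=partitions,
        partition_reasons=reasons,
        pairs=pairs_df,
        scenarios=scenarios,
        params=params,
    )
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: AnalysisBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.partition_table().to_csv(out / "partitions.tsv", sep="\t", index=False)
    bundle.ncm_table().to_csv(out / "ncm.tsv", sep="\t", index=False)
    bundle.scenario_table().to_csv(out / "scenarios.tsv", sep="\t", index=False)
    bundle.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    cat = bundle.assignment.table.copy()
    cat.index.name = "otu_id"
    cat.to_csv(out / "categories.tsv", sep="\t")
    (out / "provenance.json").write_text(json.dumps(bundle.params, indent=2))
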