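"""Classification of OTUs into rare/abundant categories.

Four categories, defined on per-sample relative abundances with two cutoffs
(0.01% and 1%) applied across all samples (both sampling dates combined):

* **always_rare** — below 0.01% in every sample;
* **conditionally_rare** — below 1% everywhere, and below 0.01% in some
  but at most one third of the samples;
* **moderate** — between 0.01% and 1% in every sample;
* **dominant** — at or above 1% in every sample, or fluctuating strongly
  (below 0.01% in some samples yet reaching 1% in others).

The four published rules do not cover every abundance profile (for example
an OTU below 0.01% in half the samples that never reaches 1%); such OTUs
are placed in an explicit ``unclassified`` bucket rather than silently
forced into a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io_tables import CommunityMatrix, RelAbundanceMatrix

DEFAULT_MIN_OTUS = 6


class AbundanceCategory(str, Enum):
    ALWAYS_RARE = "always_rare"
    CONDITIONALLY_RARE = "conditionally_rare"
    MODERATE = "moderate"
    DOMINANT = "dominant"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CategoryAssignment:
    """Per-OTU category labels plus the thresholds that produced them.

    ``table`` has one row per OTU with columns ``category``, ``min_abund``,
    ``max_abund`` and ``frac_samples_below_rare_cut``.
    """

    table: pd.DataFrame
    rare_cut: float
    abundant_cut: float
    max_rare_fraction: float

    def category_of(self, otu_id) -> AbundanceCategory:
        return AbundanceCategory(self.table.loc[otu_id, "category"])

    def otus_in(self, category: AbundanceCategory | str) -> list:
        category = AbundanceCategory(category)
        mask = self.table["category"] == category.value
        return list(self.table.index[mask])

    def counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(
            [c.value for c in AbundanceCategory], fill_value=0
        )


def classify_otus(
    ra: RelAbundanceMatrix,
    rare_cut: float = 1e-4,
    abundant_cut: float = 1e-2,
    max_rare_fraction: float = 1 / 3,
) -> CategoryAssignment:
    """Assign each OTU to one abundance category.

    Decision order (first match wins):

    1. always_rare  — max abundance < ``rare_cut``;
    2. dominant     — min ≥ ``abundant_cut``, or (min < ``rare_cut`` and
       max ≥ ``abundant_cut``), the "fluctuates strongly" clause;
    3. moderate     — all abundances in [``rare_cut``, ``abundant_cut``);
    4. conditionally_rare — max < ``abundant_cut`` and the fraction of
       samples below ``rare_cut`` lies in (0, ``max_rare_fraction``];
    5. unclassified otherwise.

    The dominant "strong fluctuation" clause is tested before
    conditionally-rare so an OTU that spikes to ≥1% always counts as
    dominant.
    """
    vals = ra.values
    if vals.size == 0:
        raise ValueError("empty relative-abundance matrix")
    vmin = vals.min(axis=1)
    vmax = vals.max(axis=1)
    frac_below = (vals < rare_cut).mean(axis=1)

    cats = np.full(len(ra.otu_ids), AbundanceCategory.UNCLASSIFIED.value, dtype=object)
    always = vmax < rare_cut
    dominant = ~always & ((vmin >= abundant_cut) | ((vmin < rare_cut) & (vmax >= abundant_cut)))
    moderate = ~always & ~dominant & (vmin >= rare_cut) & (vmax < abundant_cut)
    cond = (
        ~always
        & ~dominant
        & ~moderate
        & (vmax < abundant_cut)
        & (frac_below > 0)
        & (frac_below <= max_rare_fraction)
    )
    cats[always] = AbundanceCategory.ALWAYS_RARE.value
    cats[dominant] = AbundanceCategory.DOMINANT.value
    cats[moderate] = AbundanceCategory.MODERATE.value
    cats[cond] = AbundanceCategory.CONDITIONALLY_RARE.value

    table = pd.DataFrame(
        {
            "category": cats,
            "min_abund": vmin,
            "max_abund": vmax,
            "frac_samples_below_rare_cut": frac_below,
        },
        index=pd.Index(ra.otu_ids, name="otu_id"),
    )
    return CategoryAssignment(table, rare_cut, abundant_cut, max_rare_fraction)


def subset_by_category(
    cm: CommunityMatrix,
    assignment: CategoryAssignment,
    category: AbundanceCategory | str,
) -> CommunityMatrix:
    """Restrict a count table to the OTUs carrying ``category``.

    Raises if the assignment was derived from a different OTU universe.
    Samples whose column sum drops to zero are kept but flagged with a
    warning attribute-free log message; callers decide whether to drop them.
    """
    category = AbundanceCategory(category)
    universe = set(assignment.table.index)
    if set(cm.otu_ids) - universe:
        missing = sorted(set(cm.otu_ids) - universe)[:5]
        raise ValueError(
            f"assignment does not cover this matrix's OTUs (e.g. {missing})"
        )
    otus = [o for o in cm.otu_ids if o in set(assignment.otus_in(category))]
    sub = CommunityMatrix(cm.data.loc[otus])
    empty = sub.sample_sums()[sub.sample_sums() == 0].index.tolist()
    if empty:
        import warnings

        warnings.warn(
            f"samples with no {category.value} OTUs: {empty}", stacklevel=2
        )
    return sub


def check_min_otus(cm: CommunityMatrix, min_otus: int = DEFAULT_MIN_OTUS) -> bool:
    """True when the table is large enough for the phylogenetic null models.

    Categories with fewer than ``min_otus`` OTUs (default 6) are excluded
    from the null-model analyses; the boundary is inclusive (exactly 6 OTUs
    pass).
    """
    return cm.n_otus >= min_otus
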