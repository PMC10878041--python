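"""Alpha-diversity indices and Bray-Curtis dissimilarity.

Thin, validated wrappers over scikit-bio and scipy: Chao-1 richness
(bias-corrected by default), Shannon's H' (natural log), Simpson's 1−D,
and the Bray-Curtis sample-by-sample distance matrix that underlies the
abundance-based Raup-Crick null model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as _alpha

from .io_tables import CommunityMatrix


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero count vector: index undefined")
    return c


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao-1 richness estimate.

    Bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default, which stays
    defined when there are no doubletons; the classic form F1²/(2 F2) is
    available with ``bias_corrected=False``.
    """
    c = _check_counts(counts)
    return float(_alpha.chao1(c, bias_corrected=bias_corrected))


def shannon(counts) -> float:
    """Shannon's H' = −Σ p ln p (natural logarithm)."""
    c = _check_counts(counts)
    return float(_alpha.shannon(c, base=np.e))


def simpson(counts) -> float:
    """Simpson's 1 − D = 1 − Σ p²."""
    c = _check_counts(counts)
    return float(_alpha.simpson(c))


def alpha_diversity_table(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-sample Chao-1, Shannon and Simpson indices."""
    rows = {}
    for s in cm.sample_ids:
        col = cm.data[s].to_numpy()
        rows[s] = {
            "chao1": chao1(col),
            "shannon": shannon(col),
            "simpson": simpson(col),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def bray_curtis(cm: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(a, b) = 1 − 2 Σ min(x_ia, x_ib) / (Σ x_ia + Σ x_ib), in [0, 1].
    """
    if cm.n_samples < 2:
        raise ValueError("need at least two samples")
    sums = cm.sample_sums()
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    mat = cm.counts.T.astype(float)  # samples x otus
    dm = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(dm, ids=[str(s) for s in cm.sample_ids])
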