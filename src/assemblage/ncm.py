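"""Sloan's neutral community model (NCM) for occurrence-frequency data.

The model relates the frequency at which a taxon occurs across a set of
local communities to its mean relative abundance in the metacommunity,
through a single migration parameter m and the community size N (here the
rarefaction depth):

    Freq_i = 1 − I(1/N | N·m·p_i, N·m·(1−p_i))

with I the regularized incomplete beta function (the beta CDF evaluated at
the detection threshold 1/N).  m is estimated by nonlinear least squares on
(p_i, Freq_i) pairs; fit quality is the generalized R² = 1 − SS_err/SS_total.

Two migration estimates are reported:

* ``m`` — the Sloan-scale parameter minimizing the least-squares objective
  above.  This is the number conventionally reported in the literature.
* ``m_prob`` — the per-death immigration probability obtained by fitting
  the exact stationary occupancy of the underlying birth–death process.
  For a local community of N individuals in which each death is replaced
  by an immigrant with probability m, the stationary abundance law is
  beta-binomial with immigration intensity I = m(N−1)/(1−m); the Sloan
  approximation replaces I by N·m (valid for small m) and a continuous
  detection threshold.  ``m_prob`` undoes both approximations and is the
  quantity to compare against a mechanistic simulation's migration rate.

The neutral fit is compared against two purely statistical sampling models
(binomial draws from the metacommunity and its Poisson limit) by AIC/BIC
over bootstrap resamples of the OTU set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc, gammaln
from statsmodels.stats.proportion import proportion_confint

from .io_tables import CommunityMatrix

_M_GRID = np.logspace(-4, 0, 200)  # multi-start grid for the Sloan fit


def ncm_predict(p, N: int, m: float):
    """Expected occurrence frequency under the neutral model.

    Vectorized over ``p``.  ``p`` must lie in (0, 1), ``N`` ≥ 2,
    ``m`` in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundances must lie strictly in (0, 1)")
    if N < 2:
        raise ValueError("N must be at least 2")
    if not (0 < m <= 1):
        raise ValueError("m must lie in (0, 1]")
    a = N * m * p
    b = N * m * (1 - p)
    return 1 - betainc(a, b, 1.0 / N)


def occupancy_exact(p, N: int, m_prob: float):
    """Exact stationary occurrence probability of the birth–death process.

    P(count ≥ 1) for a beta-binomial(N, I·p, I·(1−p)) abundance with
    immigration intensity I = m_prob (N−1)/(1−m_prob).
    """
    p = np.asarray(p, dtype=float)
    if not (0 < m_prob < 1):
        raise ValueError("m_prob must lie strictly in (0, 1)")
    I = m_prob * (N - 1) / (1 - m_prob)
    a = I * p
    b = I * (1 - p)
    log_p0 = gammaln(b + N) + gammaln(a + b) - gammaln(a + b + N) - gammaln(b)
    return 1 - np.exp(log_p0)


def occurrence_frequency_table(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-OTU (p_i, Freq_i): mean relative abundance and occupancy.

    ``p`` is the mean of the per-sample proportions (zeros included);
    ``freq`` is the fraction of samples with count ≥ 1.  OTUs absent from
    every sample are dropped.
    """
    if cm.n_samples < 2:
        raise ValueError("need at least two samples")
    counts = cm.counts.astype(float)
    rel = counts / counts.sum(axis=0)
    p = rel.mean(axis=1)
    freq = (counts > 0).mean(axis=1)
    tab = pd.DataFrame(
        {"p": p, "freq": freq}, index=pd.Index(cm.otu_ids, name="otu_id")
    )
    return tab[tab["freq"] > 0]


def wilson_interval(freq_hat: float, n: int, confidence: float = 0.95):
    """Wilson score interval for an observed proportion."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0 <= freq_hat <= 1):
        raise ValueError("freq_hat must lie in [0, 1]")
    if freq_hat == 0.0:
        lo, hi = 0.0, proportion_confint(0, n, alpha=1 - confidence, method="wilson")[1]
    elif freq_hat == 1.0:
        lo, hi = proportion_confint(n, n, alpha=1 - confidence, method="wilson")[0], 1.0
    else:
        lo, hi = proportion_confint(freq_hat * n, n, alpha=1 - confidence,
                                    method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class NCMFit:
    """Fitted neutral community model."""

    m: float                 # Sloan-scale migration parameter
    m_prob: float            # per-death immigration probability (exact fit)
    N: int                   # individuals per community (rarefaction depth)
    r_squared: float
    n_otus_used: int
    n_samples: int
    aic: float
    bic: float
    table: pd.DataFrame = field(repr=False)  # per-OTU p, freq, predicted, CI, band
    detection_threshold: float = 0.0

    @property
    def predicted(self) -> pd.Series:
        return self.table["predicted"]


def _sloan_sse(m, p, freq, N):
    return float(np.sum((freq - (1 - betainc(N * m * p, N * m * (1 - p), 1.0 / N))) ** 2))


def _fit_sloan_m(p: np.ndarray, freq: np.ndarray, N: int) -> float:
    """Deterministic multi-start LSQ for the Sloan m; ties broken low."""
    sse = [_sloan_sse(m, p, freq, N) for m in _M_GRID]
    best_idx = int(np.argmin(sse))  # argmin returns the first (smallest m) tie
    lo = _M_GRID[max(best_idx - 1, 0)]
    hi = _M_GRID[min(best_idx + 1, len(_M_GRID) - 1)]
    if lo == hi:
        return float(lo)
    res = minimize_scalar(
        _sloan_sse, bounds=(lo, hi), args=(p, freq, N), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"NCM fit failed to converge: {res.message}")
    # keep whichever of the refined point / grid point is better
    return float(res.x) if res.fun <= sse[best_idx] else float(_M_GRID[best_idx])


def _fit_exact_m_prob(p: np.ndarray, freq: np.ndarray, N: int) -> float:
    def sse(mp):
        return float(np.sum((freq - occupancy_exact(p, N, mp)) ** 2))

    grid = 1.0 / (1.0 + np.exp(-np.linspace(-9.5, 7.0, 80)))  # logit-spaced
    vals = [sse(m) for m in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def _gaussian_ic(resid: np.ndarray, k_model: int):
    """AIC/BIC from a Gaussian residual likelihood with variance profiled out.

    ``k_model`` counts the model's structural parameters; the residual
    standard deviation adds one more.
    """
    n = resid.size
    sse = float(np.sum(resid**2))
    sigma2 = max(sse / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    k = k_model + 1
    return 2 * k - 2 * loglik, k * np.log(n) - 2 * loglik


def fit_ncm(cm: CommunityMatrix, N: int | None = None, confidence: float = 0.95) -> NCMFit:
    """Fit the neutral model to a count table.

    ``N`` defaults to the (common) sample column sum, i.e. the rarefaction
    depth.  The fit is deterministic: multi-start over a fixed log-spaced
    m grid followed by bounded refinement.
    """
    if N is None:
        sums = cm.sample_sums()
        N = int(sums.iloc[0])
        if not (sums == N).all():
            raise ValueError(
                "column sums differ; rarefy first or pass N explicitly"
            )
    tab = occurrence_frequency_table(cm)
    p = tab["p"].to_numpy()
    freq = tab["freq"].to_numpy()
    informative = int(((freq > 0) & (freq < 1)).sum())
    if informative < 10:
        warnings.warn(
            f"only {informative} OTUs with 0 < Freq < 1; the fit may be "
            "poorly constrained",
            stacklevel=2,
        )
    m_hat = _fit_sloan_m(p, freq, N)
    m_prob = _fit_exact_m_prob(p, freq, N)
    pred = ncm_predict(p, N, m_hat)
    resid = freq - pred
    ss_err = float(np.sum(resid**2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1 - ss_err / ss_tot if ss_tot > 0 else (1.0 if ss_err == 0 else -np.inf)
    aic, bic = _gaussian_ic(resid, k_model=1)

    n_samples = cm.n_samples
    ci = np.array([wilson_interval(f, n_samples, confidence) for f in pred])
    band = np.where(freq > ci[:, 1], "above", np.where(freq < ci[:, 0], "below", "within"))
    out = tab.copy()
    out["predicted"] = pred
    out["ci_lower"] = ci[:, 0]
    out["ci_upper"] = ci[:, 1]
    out["band"] = band
    return NCMFit(
        m=m_hat,
        m_prob=m_prob,
        N=N,
        r_squared=r2,
        n_otus_used=len(tab),
        n_samples=n_samples,
        aic=aic,
        bic=bic,
        table=out,
        detection_threshold=1.0 / N,
    )


# ---------------------------------------------------------------------------
# model competition: neutral vs binomial vs Poisson sampling
# ---------------------------------------------------------------------------

def binomial_predict(p, N: int):
    """Occupancy under pure binomial sampling of the metacommunity:
    P(≥1 of N draws) = 1 − (1 − p)^N."""
    p = np.asarray(p, dtype=float)
    return 1 - (1 - p) ** N


def poisson_predict(p, N: int):
    """Poisson-sampling occupancy: 1 − exp(−N p)."""
    p = np.asarray(p, dtype=float)
    return 1 - np.exp(-N * p)


@dataclass(frozen=True)
class ModelComparison:
    """Bootstrap AIC/BIC comparison of the neutral, binomial and Poisson fits."""

    aic_mean: dict
    bic_mean: dict
    aic_boot: pd.DataFrame = field(repr=False)
    bic_boot: pd.DataFrame = field(repr=False)
    best_model: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"aic_mean": self.aic_mean, "bic_mean": self.bic_mean})


def compare_models(
    cm: CommunityMatrix,
    N: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ModelComparison:
    """Compare neutral vs binomial vs Poisson occupancy models.

    OTUs are resampled with replacement ``n_boot`` times; the neutral m is
    refit on every replicate (binomial and Poisson have no free structural
    parameter), and AIC/BIC are computed from the Gaussian residual
    likelihood.  The best model minimizes mean BIC, ties broken by AIC.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if N is None:
        N = int(cm.sample_sums().iloc[0])
    tab = occurrence_frequency_table(cm)
    p = tab["p"].to_numpy()
    freq = tab["freq"].to_numpy()
    n = len(p)
    rng = np.random.default_rng(seed)
    models = ("neutral", "binomial", "poisson")
    aic = {mname: np.empty(n_boot) for mname in models}
    bic = {mname: np.empty(n_boot) for mname in models}
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        pb, fb = p[idx], freq[idx]
        m_b = _fit_sloan_m(pb, fb, N)
        preds = {
            "neutral": ncm_predict(pb, N, m_b),
            "binomial": binomial_predict(pb, N),
            "poisson": poisson_predict(pb, N),
        }
        ks = {"neutral": 1, "binomial": 0, "poisson": 0}
        for mname in models:
            a, c = _gaussian_ic(fb - preds[mname], ks[mname])
            aic[mname][b] = a
            bic[mname][b] = c
    aic_mean = {mname: float(aic[mname].mean()) for mname in models}
    bic_mean = {mname: float(bic[mname].mean()) for mname in models}
    best = min(models, key=lambda mname: (bic_mean[mname], aic_mean[mname]))
    return ModelComparison(
        aic_mean=aic_mean,
        bic_mean=bic_mean,
        aic_boot=pd.DataFrame(aic),
        bic_boot=pd.DataFrame(bic),
        best_model=best,
    )


def plot_fit(fit: NCMFit, path) -> None:
    """Occupancy-vs-abundance scatter with the fitted curve and Wilson band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = fit.table.sort_values("p")
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"within": "0.4", "above": "tab:green", "below": "tab:red"}
    for band, grp in tab.groupby("band"):
        ax.semilogx(grp["p"], grp["freq"], ".", ms=4, color=colors.get(band, "k"),
                    label=band)
    ax.semilogx(tab["p"], tab["predicted"], "b-", lw=1.5)
    ax.semilogx(tab["p"], tab["ci_lower"], "b--", lw=0.8)
    ax.semilogx(tab["p"], tab["ci_upper"], "b--", lw=0.8)
    ax.set_xlabel("mean relative abundance")
    ax.set_ylabel("occurrence frequency")
    ax.set_title(f"m = {fit.m:.3f}, R² = {fit.r_squared:.3f}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
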