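# Methods

This note documents the models implemented in `assemblage`, the choices
made where the standard methods leave room, and what the simulators do and
do not emulate.

## Community data and normalization

The central object is an OTU × sample table of integer sequence counts.
Counts are normalized by rarefaction — multivariate hypergeometric
subsampling without replacement to a common per-sample depth — with the
seed an explicit argument (never global state). Samples below the depth
are dropped with a warning rather than upsampled, mirroring common
amplicon practice. Typical depths for the kind of cave-swab survey this
package was designed around (12,105 / 6,209 / 31,981 / 25,821 reads for
bacterial 16S, archaeal 16S, microeukaryotic 18S and fungal ITS markers)
ship as documented presets only; any positive depth works.

## Abundance categories

OTUs are classified on per-sample relative abundances pooled over all
samples (both sampling dates combined), with cutoffs r = 0.01% and
a = 1%:

| category | rule |
|---|---|
| always_rare | max < r |
| dominant | min ≥ a, **or** min < r and max ≥ a ("strong fluctuation") |
| moderate | all abundances in [r, a) |
| conditionally_rare | max < a and the fraction of samples below r in (0, 1/3] |
| unclassified | anything else |

Decisions taken where the conventional definitions are ambiguous: the
strong-fluctuation clause is tested before conditionally-rare, so a spike
to ≥ 1% always wins; the "at most a third of samples" bound is inclusive;
strict/inclusive inequalities follow the wording of the published
definitions ("< 0.01%" strict, "≥ 1%" inclusive). The four published
rules do not tile the profile space (e.g. an OTU below 0.01% in half the
samples that never reaches 1%), hence the explicit `unclassified` bucket —
forcing a label silently would make the downstream per-category analyses
unauditable. Categories with fewer than six OTUs are excluded from the
phylogenetic null models; the boundary is inclusive (six OTUs pass).

## Neutral community model

The Sloan formulation models the local abundance x of a taxon with
metacommunity relative abundance p as a beta variable,
x ~ Beta(N·m·p, N·m·(1−p)), and its expected occurrence frequency across
local communities of N individuals as P(x > 1/N), i.e.
`1 − I(1/N | N·m·p, N·m·(1−p))` with I the regularized incomplete beta
(the CDF — a density evaluated at a point could not yield a frequency in
[0, 1]). N is fixed to the rarefaction depth rather than co-estimated.
Observed (p_i, Freq_i) pairs use the mean of per-sample proportions
(zeros included) and presence = count ≥ 1; OTUs observed nowhere are
excluded, OTUs at frequency 1 are retained.

The least-squares fit is deterministic: a 200-point log-spaced m grid in
[1e-4, 1] followed by bounded scalar refinement between the best grid
point's neighbours, ties resolved toward smaller m. Fit quality is the
generalized R² = 1 − SS_err/SS_total about the mean observed frequency,
and each predicted frequency carries a 95% Wilson score interval at the
number of samples.

### Two migration scales

For the death–replacement process that motivates the model (each death
replaced by an immigrant with probability m, otherwise by a local birth),
the exact stationary law of a community is Dirichlet-multinomial with
immigration intensity I = m(N−1)/(1−m). Sloan's beta form replaces I by
N·m — a small-m approximation — and replaces the discrete detection event
(count ≥ 1) by the continuous threshold x > 1/N. Both approximations bias
the fitted Sloan parameter upward as an estimate of the mechanistic
replacement probability: in our simulations at N = 1000 with 30 samples
the Sloan m̂ overshoots by ~13% at m = 0.05, ~75% at m = 0.2, and pins at
its upper bound for m = 0.5. The fit therefore reports both:

* `m` — the Sloan-scale parameter (comparable with published values);
* `m_prob` — the per-death immigration probability obtained by the same
  least-squares criterion applied to the *exact* beta-binomial stationary
  occupancy `P(count ≥ 1 | N, I·p)`. This estimator recovers the
  mechanistic m essentially unbiasedly (median within a few percent at
  m ∈ {0.05, 0.2, 0.5} over 20 seeds) and is the quantity compared with
  simulator ground truth.

### Model competition

The neutral fit is compared against pure random-sampling nulls: binomial
occupancy 1 − (1−p)^N and its Poisson limit 1 − exp(−N·p). AIC/BIC use a
Gaussian residual likelihood with the variance profiled out; structural
parameter counts are 1 (m) for neutral and 0 for the sampling models, plus
one for the residual scale. Scores are aggregated over bootstrap
resamples of the OTU set (m refit each replicate; 1,000 replicates by
default) and the best model minimizes mean BIC, ties broken by AIC. The
likelihood family is a modeling choice — the occupancy data are not
literally Gaussian — but it is the conventional way to score nonlinear
least-squares fits of this kind and is applied identically to all three
models.

## Phylogenetic and abundance null models

βMNTD between two samples is the abundance-weighted mean, symmetrized,
of each present taxon's distance to its nearest relative present in the
other sample (patristic distances from the tree; a shared taxon
contributes zero). Weighting by relative abundance is the default since
the analyses here are abundance-based; presence/absence weighting is a
flag.

βNTI standardizes the observed βMNTD against a null in which taxon
identities are shuffled across the tips of the phylogeny (equivalently the
rows/columns of the cophenetic matrix), abundances held fixed — 999
replicates by default, independently per replicate. Pairs whose null
distribution has (numerically) zero spread — e.g. a star phylogeny, or two
samples jointly containing every taxon in the analysis set — are reported
as undefined and excluded from partitioning with a warning; spread below
1e-12 of the null mean counts as zero, since dot-product accumulation
noise of order 1e-16 would otherwise manufacture a finite z-score.

RC_bray compares the observed Bray-Curtis dissimilarity of a pair with a
null distribution of probabilistically assembled communities that preserve
each sample's observed richness and total count: taxa enter without
replacement with probability proportional to their occurrence frequency
across the analysis group (Gumbel top-k sampling), each receives one
individual, and the remaining individuals are assigned multinomially in
proportion to regional (group-mean) relative abundance. The empirical
percentile, with ties at half weight to avoid artificial saturation at ±1,
is rescaled to [−1, 1]. Occurrence and regional abundances are computed
within the analysis group, because that is the species pool the null is
meant to randomize.

Pairs partition as: βNTI > +2 heterogeneous selection; βNTI < −2
homogeneous selection; otherwise RC > 0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else undominated. Selection takes
precedence — RC is only interpreted for |βNTI| ≤ 2. Per-group process
fractions are counts over valid pairs; groups with no valid pairs are NA.

Sample pairs are compared within condition group only (the process
partition is displayed per condition); per-category analyses prune the
full tree to the category's OTUs unless a category-specific tree is
supplied. Reproducibility: one master seed; per-pair substreams are
spawned deterministically so serial and parallel evaluation orders agree.

## Simulators

The simulators exist to close the inference loop: every claim the
estimators make is checked against data whose generating process is known.

* **Metacommunity** — log-series (default shape 0.999 over 1,000 OTUs) or
  log-normal relative abundances. The log-series default puts hundreds of
  taxa below 1e-4 relative abundance, so the always-rare class is
  populated, matching the heavy tails of real amplicon surveys.
* **Neutral local communities** — the classic death–replacement chain: one
  random individual dies per step; with probability m it is replaced by an
  immigrant drawn from the metacommunity, otherwise by the offspring of a
  random local individual. Communities are initialized at the exact
  stationary marginal (Dirichlet-multinomial with α = I·p) and then run
  for 10·N further steps. Initializing from a plain multinomial draw
  instead would require far longer than 10·N steps to forget the start at
  small m (the relaxation time scales as N/m events) and measurably biases
  migration estimates upward.
* **Phylogeny and traits** — pure-birth (Yule) trees with exponential
  waiting times, tip labels assigned in random order; Brownian traits
  accumulated branch-wise, so trait similarity tracks shared ancestry
  (phylogenetic signal ≈ 1 by construction).
* **Selection** — sampling weights meta_i · exp(−(trait_i − env)²/2σ²).
  σ is the filter width in trait units (smaller = stronger); σ → ∞ is the
  neutral limit and σ = 0 is treated as "no selection". Samples split
  between environments at ±1.5 trait SD with σ = 0.4 SD produce
  essentially all between-environment pairs as heterogeneous selection.
* **Dispersal limitation** — the metacommunity is partitioned into
  disjoint per-sample founder pools (richness capped at the founder size),
  each sample drawn from its own pool and optionally drifted with m ≈ 0.
  Disjoint pools are the operative ingredient: with overlapping random
  founder subsets the observed and null assemblies share the same overlap
  distribution and RC_bray cannot exceed 0.95, no matter how the drift
  phase is tuned. Detectability also requires the null to have taxa to
  overlap on: per-sample realized richness r and occupied pool size S
  should satisfy roughly r²/S ≳ 4, which the defaults used in the tests
  (log-normal metacommunity, 60 founders from a 750-taxon pool at
  N = 1000) do.
* **Study-shaped data set** — three condition groups × six replicates ×
  two sampling dates at N = 12,000 (single reads sit at 8.3e-5 < 1e-4
  relative abundance, so singletons are always-rare by construction).
  Group one is neutral with high migration; group two filters the core
  metacommunity by trait–environment matching with environments split
  between replicate locations; group three is dispersal-limited in its
  core community while its always-rare taxa are drawn from trait-matched
  halves of a dedicated rare pool — selection acting only on the rare
  biosphere of the "recovered" state. Each sample receives 40 single-read
  rare taxa; dates are independent draws from the same group process.

What the simulators do *not* emulate: sequencing error, chimeras, OTU
clustering artifacts, compositional biases of PCR, temporal
autocorrelation between dates, or taxon-specific detection efficiency.
Passing recovery tests therefore demonstrates the estimators' correctness
under the stated generative models, not robustness to those measurement
processes.

## Scenario mapping

Per taxon category, the deterministic fractions (heterogeneous +
homogeneous selection) across the ordered condition states (resistant,
impacted, resilient) map onto four conceptual disturbance scenarios. A
state counts as deterministic when its fraction reaches τ (default 0.5,
explicit config, always reported). Rules, checked in the order 2, 1, 4, 3:

1. resistant stochastic, impacted deterministic, resilient relaxing below
   the impacted fraction — disturbance imposes selection;
2. deterministic, stochastic, deterministic — disturbance relaxes
   selection, recovery restores it;
3. stochastic throughout — absence of selection;
4. resistant and impacted stochastic with the resilient fraction positive
   and highest — disturbance removal leads to selection, the pattern
   characteristic of always-rare taxa.

The rule set is an interpretation layer over a qualitative continuum, and
borderline cases are τ-sensitive: a trajectory like (0.07, 0.47, 0.20)
reads as scenario 1 for τ ≤ 0.45 but falls through to scenario 3 at the
default τ = 0.5. Fractions unavailable for a category (NA) yield
"unassigned" rather than a guess.

## Problem sizes and numerical choices

Default analysis sizes: 999 null replicates (minimum 99) for βNTI and
RC_bray; 1,000 bootstrap replicates for model competition; NCM fit grid of
200 log-spaced points refined to ~1e-10. The bundled tests and the
acceptance script run scaled versions chosen to finish in seconds to
minutes on one core: 20-seed × 30-community recovery studies at N = 1000,
12-sample scenario runs with 499 nulls, and a reduced study-shaped data
set (360 OTUs, 3 replicates × 2 dates per group, 199 nulls). The βNTI
null is evaluated in vectorized chunks capped at ~2e6 matrix elements to
bound memory. Exact tie handling, seed derivation and degenerate-input
behavior (zero-spread nulls, empty categories, samples below rarefaction
depth) are described above with their rationale.

## Known limitations

* The Sloan-scale m is reported for comparability but is not a consistent
  estimator of the mechanistic replacement probability at large m; use
  `m_prob` when comparing with process-level quantities.
* βNTI is undefined (and reported as such) when the taxa shuffle cannot
  change nearest-taxon distances; very small or fully-overlapping
  communities are the practical cases.
* The RC_bray null model follows one specific, widely used
  richness-and-abundance-preserving assembly; other null choices shift
  the dispersal/undominated boundary and results should be read relative
  to this null.
* Scenario assignment is a thresholded reading of a conceptual figure;
  report τ alongside any assignment.
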