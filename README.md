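# assemblage

Inference of microbial community assembly processes from OTU count tables
and phylogenies: is a community shaped by deterministic selection or by
stochastic dispersal and drift — and does the answer differ between the
abundant taxa and the rare biosphere?

`assemblage` implements the standard quantitative chain used in microbial
ecology to answer that question, plus simulators that generate communities
with *known* assembly processes so every inference step can be validated by
parameter recovery:

* **Rare/abundant taxon classes** — OTUs are classified from per-sample
  relative abundances with the conventional 0.01% and 1% cutoffs into
  always-rare, conditionally rare, moderate and dominant taxa (plus an
  explicit `unclassified` bucket for profiles the four published rules do
  not cover).
* **Sloan's neutral community model (NCM)** — the occurrence frequency of
  taxon *i* across local communities of *N* individuals is related to its
  mean relative abundance *p_i* through the migration rate *m*:

  `Freq_i = 1 − I(1/N | N·m·p_i, N·m·(1−p_i))`

  with `I` the regularized incomplete beta function. *m* is estimated by
  nonlinear least squares; fit quality is the generalized
  R² = 1 − SS_err/SS_total, predictions carry 95% Wilson score bands, and
  the neutral fit competes against binomial and Poisson sampling models by
  bootstrap AIC/BIC.
* **βNTI / RC_bray process partitioning** — pairwise abundance-weighted
  β-mean nearest taxon distances are standardized against a
  taxa-shuffling null (βNTI); |βNTI| > 2 indicates selection
  (heterogeneous > +2, homogeneous < −2), and the stochastic remainder is
  split with the Bray-Curtis Raup-Crick null (RC > 0.95 dispersal
  limitation, RC < −0.95 homogenizing dispersal, otherwise undominated).
* **Simulators** — a heavy-tailed metacommunity, Hubbell-style
  death–replacement neutral dynamics, Brownian traits on a Yule phylogeny
  with Gaussian environmental filtering (selection), disjoint founder
  pools (dispersal limitation), and a composite "survey-shaped" data set of
  three condition groups × six replicates × two sampling dates.
* **Pipeline** — classify → NCM per condition group → process partition per
  group × taxon category (categories under 6 OTUs reported as NA) → mapping
  of deterministic-fraction trajectories onto four conceptual disturbance
  scenarios.

## Worked example

Fit the neutral model to 30 simulated neutral communities (N = 1000
individuals each, true migration rate m = 0.2):

```python
import assemblage as A

cfg = A.SimulationConfig(N=1000, m=0.2, n_samples=30, seed=11)
meta = A.simulate_metacommunity(cfg)
cm = A.simulate_neutral_local(meta, cfg).drop_empty_otus()

fit = A.fit_ncm(cm)
print(f"Sloan m = {fit.m:.3f}   migration probability = {fit.m_prob:.3f}")
print(f"R^2 = {fit.r_squared:.3f}   OTUs used = {fit.n_otus_used}   N = {fit.N}")

comp = A.compare_models(cm, n_boot=200, seed=0)
print("best model:", comp.best_model)
```

```
Sloan m = 0.378   migration probability = 0.208
R^2 = 0.945   OTUs used = 667   N = 1000
best model: neutral
```

Two migration numbers are reported deliberately. `fit.m` is the
conventional Sloan-scale least-squares parameter — the number reported in
the literature — which systematically overshoots the mechanistic
replacement probability at high migration because the model's N·m
approximates the immigration intensity I = m(N−1)/(1−m). `fit.m_prob`
refits the exact stationary occupancy of the death–replacement process and
recovers the simulator's true m = 0.2 (here 0.208). The high R² and the
bootstrap BIC preferring the neutral curve over binomial/Poisson sampling
complete the picture. See `docs/methods.md` for the details.

The same chain runs from the shell:

```sh
assemblage simulate --scenario study-like --seed 1 --out-dir data/
assemblage run --otu-table data/otu_table.tsv --tree data/tree.nwk \
    --metadata data/metadata.tsv --groups unstained,black_stain,attenuated \
    --n-null 999 --seed 1 --out-dir results/
```

which writes `categories.tsv`, `ncm.tsv`, `pairs.tsv`, `partitions.tsv`,
`scenarios.tsv` and a `provenance.json` with every parameter and seed.

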