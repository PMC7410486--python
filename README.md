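# stochglv

Stochastic generalized Lotka-Volterra (gLV) and logistic models for
microbial community time series: simulation, noise characterization, and
neutrality testing.

Daily-sampled microbial time series — gut microbiota, plankton, body
sites — share a set of stochastic fingerprints: heavy-tailed rank
abundance profiles that stay stable while individual species fluctuate
wildly; successive-difference magnitudes that scale almost linearly with
mean abundance; successive-abundance ratios whose lognormal width is of
order one and independent of abundance; noise colors in the white-pink
band uncorrelated with abundance; and neutrality tests that come out on
the niche side.  This package implements the modeling result that *all*
of these fingerprints are reproduced by a stochastic **logistic** model —
no interspecies interactions — provided the noise is large and linear in
abundance (environmental/growth-rate noise) and the self-interaction
strengths span several orders of magnitude.

## The model

The community evolves by the stochastic gLV equations

    dx_i = (λ_i + g_i x_i + Σ_j ω_ij x_i x_j) dt
           + σ_lin,i  x_i      dW_i      (linear: growth-rate fluctuations)
           + σ_sqrt,i √x_i     dW'_i     (square-root: demographic birth/death)
           + σ_add,i           dW''_i    (additive: immigration fluctuations)

integrated by Euler-Maruyama.  The logistic special case has diagonal
ω: each species relaxes to its carrying capacity x*_i = g_i/|ω_ii| at
rate g_i.  A prescribed rank abundance profile is imposed exactly by
choosing the growth rates ĝ = −ω x*.  Three analysis layers sit on top:

- **Characterization** — periodogram slope on log-log axes after a
  one-decade low-frequency cutoff (noise color: white 0, pink −1, brown
  −2, black −3); cross-species regression of log₁₀⟨|Δx|⟩ on log₁₀⟨x⟩
  (slope 1 ⇒ linear noise, ≈2/3 ⇒ demographic, 0 ⇒ additive); lognormal
  width of successive ratios x(t+δt)/x(t); rank abundance.
- **Neutrality** — the Kullback-Leibler divergence from the Gaussian
  summary (μ, K) of a series to its exchangeable ("all species equal")
  projection, in closed form; and a neutral covariance test: a
  grouping-invariance statistic calibrated against simulated
  Wright-Fisher drift, rejecting when per-group drift-rate estimates
  disagree more than neutral drift allows.
- **Inference** — for logistic dynamics the noise color depends only on
  g·δt = |ω_ii|·⟨x⟩·δt, monotonically (an Ornstein-Uhlenbeck spectrum
  observed through the sampling window); inverting a simulated
  calibration curve estimates per-species self-interactions from color
  and abundance alone.

## A worked example

```sh
python examples/characterize_series.py
```

simulates the default stool-like blueprint (100 species, lognormal
steady states spanning ~7 decades, growth rates log-uniform in
[0.5, 5]/day, pure linear noise σ=1.4 at daily sampling) and prints:

```
difference-scaling slope: 0.994  (linear noise gives 1)
median PSD slope:         -0.46  (57 white / 41 pink / 2 brown / 0 black)
color-abundance rank corr: +0.26  (weak, as in real data)
median ratio width:       1.25  (order one)
width vs log10 abundance:  slope -0.05 per decade (widths similar across 7 decades of abundance)
```

The slope near 1 identifies the noise as linear in abundance; the colors
sit in the white-pink band with only a weak abundance trend; ratio
widths are of order one and nearly abundance-independent — the
fingerprints of the experimental series.  `examples/neutrality_tests.py`
shows that the same interaction-free community is classified *niche* by
both neutrality measures (KL ≈ 664, NCT p ≈ 0.01) while a genuine
Wright-Fisher community is not rejected (p ≈ 0.42).  The other examples
cover community generation, the noise-mix scan and self-interaction
recovery.

There is also a CLI mirroring the library
(`stochglv simulate|characterize|neutrality|scan-color|scan-noise|reproduce|infer`),
reading and writing TSV with YAML sidecar configs for exact replay.

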