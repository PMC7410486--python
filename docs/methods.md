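# Methods

## Model and integrator

The deterministic skeleton is the generalized Lotka-Volterra system
`dx_i/dt = λ_i + g_i x_i + Σ_j ω_ij x_i x_j` with strictly negative
self-interactions ω_ii.  Off-diagonal interactions are sampled i.i.d.
Normal(0, α²); α = 0 gives the logistic model.  Growth rates are imposed
as ĝ = −ω x*, which makes any prescribed abundance vector x* an exact
interior fixed point and is how heavy-tailed rank abundance profiles are
built in (random interaction matrices do not produce them on their own).
Stability is checked through the Jacobian `J = diag(g + ωx*) + x* ∘ ω`
(the first term vanishes at an interior fixed point without
immigration); unstable random draws are rejected and resampled with a
capped retry count.  Immigration is carried in the types but the shipped
experiments set λ = 0 throughout: the modeled system (the colon at
steady state) receives a negligible flux of immigrants compared with its
standing population.

Integration is Euler-Maruyama with a fixed step, dt = δt/100 by default
where δt is the sampling interval.  Noise-free trajectories converge to
the closed-form logistic solution at the expected first order in dt
(verified in the tests).  Each of the three noise channels draws an
independent Wiener increment per species and per step.  Negative
excursions are clipped to zero after every step ("clip" policy;
a "reject-step" policy that redraws the offending increments is
available — with large noise both reduce to an absorbing boundary unless
additive noise re-injects).  The square-root (demographic) channel is
suppressed for abundances below one individual: its derivation rests on
Poisson counting statistics, which are meaningless below a single
individual.  Simulations start at the fixed point by default (the object
of study is stationary fluctuation, not transient relaxation), so no
transient is discarded.

## Blueprint defaults (the study conditions)

The default "stool-like" community emulates a dense gut community under
daily 16S sampling, on the sequencing-count abundance scale:

| parameter | default | rationale |
|---|---|---|
| species S | 100 | typical number of abundant taxa tracked in daily series |
| steady states x* | lognormal, log₁₀ median 2, log₁₀ sd 1.5 | heavy tail spanning ≥ 4 (typically ~7) decades, rare tail at single individuals |
| growth rates g | log-uniform [0.5, 5] /day | the band whose colors at δt = 1 day are white-to-pink, as observed |
| self-interactions ω_ii | −g/x* | imposed fixed point; spans many decades because x* does |
| interaction strength α | 0 | the central claim concerns the interaction-free model |
| σ_lin | 1.4 /√day | ratio widths of order one: the linearized log-process gives width σ√((1−e^(−gδt))/g) ≈ 1 at the median g |
| σ_sqrt | 3.5 √ind/√day | √(division + death rate) with total turnover ≈ 12 events/individual/day (hours-scale doubling mostly balanced by death/washout) |
| σ_add | 1.0 ind/√day | immigration noise of order one individual per day |
| δt, T | 1 day, 1000 samples | daily sampling; length comparable to (somewhat exceeding) long experimental series |

Replicates and grid points derive child RNGs from one integer seed via
`SeedSequence(seed, spawn_key=...)`, so any single replicate is
reproducible in isolation.

The generator emulates the *shape* of real communities, not any
particular dataset: species are statistically independent by default,
abundances are continuous (no sequencing depth, compositional zeros or
measurement error), and sampling is perfectly uniform with no missing
time points.  Passing tests therefore demonstrate properties of the
model under clean observation, not robustness to the pathologies of real
sequencing data.

## Characterization choices

**Noise color.**  Mean-removed straight periodogram (no taper by
default; a Hann taper is available).  The slope is an ordinary
least-squares fit of log₁₀ power on log₁₀ frequency after discarding the
lowest decade of frequencies, where the finite observation window biases
the spectrum.  Color labels are cosmetic (nearest anchor, bin edges at
−0.5/−1.5/−2.5); the slope is the primitive.  A smoothing-spline
minimum-derivative estimator is provided as an experimental alternative;
it reports darker values when the spectrum bends, by construction.

**Difference scaling.**  Per-species ⟨|x(t+δt)−x(t)|⟩ and ⟨x⟩, with an
equal-weight OLS fit across species on log₁₀ axes.  Species with zero
mean or zero fluctuation carry no information about the scaling and are
excluded with a warning.  The channel fingerprints: linear noise has
jump size proportional to x (slope 1); additive noise is
abundance-blind (slope 0).  The square-root channel is regime-dependent:
species with many individuals live in the Gaussian regime (jump ∝ √x*),
while the rare tail at few individuals fluctuates at the scale of its
own abundance; across a heavy-tailed community spanning the
single-individual scale the mixed regression settles near 2/3, which is
also where real communities' demographic component would sit on the
count scale.  The reference strengths used for channel comparisons are
recorded in `CHANNEL_REFERENCE_SIGMA`.

**Ratio widths.**  Successive ratios r = x(t+δt)/x(t) are fitted by a
one-parameter lognormal *centered at one*: log-location fixed to 0, so
the maximum-likelihood width is σ̂² = mean(ln²r) in closed form, and
goodness of fit is the plain two-sided Kolmogorov-Smirnov p-value
against the fitted lognormal.  Centering deserves a note: a stationary
multiplicative process has E[ln r] = 0 while E[r] ≈ e^(σ²/2) ≫ 1 for
widths of order one, so pinning the lognormal's *arithmetic* mean at one
shifts the fit off the data and makes the KS test reject even ideal
series.  Centering at one (median/log-location) is the convention under
which strong-noise series are well fitted, matching how these widths are
reported in practice.

**Relative abundances.**  A row-normalizing transform supports
compositional analyses.  For the logistic model with linear noise the
community total fluctuates less than typical members (independent
species average out), so colors and scalings survive normalization
approximately; this is verified as a property test rather than assumed.

## Neutrality measures

**KL distance to neutrality.**  The series is summarized by its sample
mean vector and covariance matrix.  The "neutral" counterpart is the
exchangeable projection: all means replaced by the grand mean, variances
by the mean variance, covariances by the mean covariance.  The distance
is the closed-form Gaussian KL divergence; ε = 1e−8 × mean diagonal is
added before inversion to stabilize near-collinear covariances.  The
projection is idempotent and permutation-invariant, the divergence is
non-negative and zero exactly on exchangeable summaries; for i.i.d.
identical species it vanishes as the series grows.  Absolute abundances
are used by default with a flag for relative ones.  No universal niche
cutoff is imposed; the raw divergence is reported and any labeling
threshold is the caller's (a matched-null quantile is the recommended
choice).

**Neutral covariance test.**  Implemented as a grouping-invariance test
against Wright-Fisher drift.  In a neutral community of effective size
N, any aggregate of species with relative abundance f has increment
variance f(1−f)/N — the per-capita drift rate cannot depend on how
species are grouped.  The statistic is the standard deviation, across
~64 random species bipartitions, of log v_G where
v_G = mean_t[(Δf_G)²/(f_G(1−f_G))]; steps at which an aggregate is
absorbed (f = 0 or 1) are masked, and groups with fewer than 5
segregating steps are dropped.  The null distribution comes from
simulated Wright-Fisher communities (multinomial resampling at fixed
total) matched on species number, series length, *initial* composition
and effective size; N is estimated from the observed segregating
increments by the same masked estimator.  Two matching details matter
and were found empirically: absorbed steps must be masked (not clipped)
everywhere, and nulls must launch from the observed first sample rather
than the time-mean, otherwise species that went extinct early produce
near-zero starting frequencies with mismatched extinction dynamics.
With both in place the null rejection rate is nominal (≈ 4–7% at level
0.05) and p-values are consistent with uniformity across series lengths
150–600; power against stool-like linear-noise logistic communities is
roughly 60–80% per replicate.  The p-value is the standard
`(1 + #{null ≥ observed})/(n_null + 1)`.  This statistic is a
reimplementation of the grouping-invariance idea, not a line-by-line
port of the original test; its null calibration is the binding contract
and its power against specific alternatives may differ.

## Color calibration and self-interaction inference

For a logistic species the linearized fluctuation is an
Ornstein-Uhlenbeck process with relaxation rate g = |ω_ii| x*, so the
observed spectrum depends only on g·δt: flat (white) when relaxation is
faster than sampling, 1/f² (brown) when slower.  The calibration
simulates a grid of log₁₀(g·δt) values — all grid points and replicates
integrated as one noninteracting community — fits each species' color,
and smooths the grid means with an isotonic (monotone non-decreasing)
regression, which the OU limit behavior justifies.  Inversion
interpolates the monotone curve; the reported uncertainty is the grid
dispersion divided by the local curve steepness, so the flat white and
brown ends report inflated uncertainties and slopes outside the
calibrated range are withheld as NaN.  Because single-series color
estimates carry ~0.1–0.2 of slope noise, recovery experiments average
fitted slopes over replicate simulations of the same community before
inverting; with 20 replicates the recovered log-magnitudes rank-correlate
with truth above 0.9 over three generated decades.

The σ-invariance of color is a statement about fluctuations around
steady state: it is exact in the linearized (small relative fluctuation)
regime and is tested there.  At widths of order one a weak darkening
with σ appears (excursions to low abundance relax more slowly); this is
a real nonlinear effect of the model, within the error bars at the
strengths scanned.

## Numerical and scale choices

Default problem sizes (50–100 species, 600–1000 samples, 5–40
replicates, 99-trajectory NCT nulls, 200-replicate null calibrations)
were chosen so the full experiment suite completes in minutes on one
core while keeping Monte-Carlo error comfortably inside the asserted
tolerances; they are stated in each test and can be scaled up freely.
Degenerate inputs (constant series, zero rows, sub-minimum lengths) are
rejected with explicit errors rather than coerced.  Known limitations:
no Gillespie-type individual-based integration (the Langevin
approximation is the model, not an approximation target here); no
uneven-sampling spectral estimation; interaction strength α must be
chosen against May's stability bound relative to the abundance range,
which for heavy-tailed communities means α much smaller than
1/(√S·max x*) — the generator rejects unstable draws rather than
rescaling silently.
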