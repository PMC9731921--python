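# Methods

This note documents the statistical machinery implemented in
`camtrap_community`, the choices made where conventions differ, and what
the synthetic validation does and does not establish.

## Event processing

Camera-trap photographs of the same species at the same station are
notoriously autocorrelated (an animal lingering in front of a camera). The
standard remedy, implemented in `events.filter_independent_events`, keeps a
record only if it falls at least 30 minutes (configurable) after the last
*kept* record of the same (station, species) stream. Measuring from the
last kept event — rather than the last raw photograph — is the common
camera-trap convention and makes the filter idempotent; with it, a
minute-spaced burst of 100 photographs collapses to events at 0, 30, 60 and
90 minutes. The filter is applied unconditionally: distinguishing
individual animals from images is out of scope, so no sub-window events are
retained on identity grounds.

Effort is counted in trap-nights. A deployment contributes the nights in
`[start_date, end_date)` minus any malfunction nights; the sampling
occasion for the detection matrix is one calendar trap-night, so a station
active ~31 nights yields K_j ≈ 31 binomial trials. Multiple same-night
events collapse to a single detection. The trapping rate is
`100 × events / trap-nights`, a relative activity index, not an abundance
estimate. Report rounding follows the conventional table precision:
proportions to 2 decimals, trapping rates to 1.

## The occupancy model

The community model is the Dorazio–Royle zero-augmented multi-species
occupancy model (MSOM). The observed n-species matrix is padded with `nz`
all-zero rows; each of the M = n + nz rows has an inclusion indicator
w_i ~ Bernoulli(Ω), and conditional on inclusion

    logit(ψ_i) ~ Normal(μ_ψ, σ_ψ),   logit(p_i) ~ Normal(μ_p, σ_p),
    z_ij | w_i ~ Bernoulli(w_i ψ_i),  y_ij | z_ij ~ Binomial(K_j, z_ij p_i).

Species richness is N = Σ w_i and station richness Σ_i z_ij. Because the
model is the null (constant-p) model, the occasion-level Bernoulli
likelihood collapses exactly to the binomial form above, which is what the
sampler evaluates. Priors are the standard community-model choices:
Ω ~ Uniform(0,1), μ ~ Normal(0, 1.5) on the logit scale, σ ~ Uniform(0, 5);
all configurable through `msom.Priors`.

### Sampler

`msom.fit_msom` is a self-contained Metropolis-within-Gibbs sampler:

- z_ij, w_i and Ω are drawn from their exact full conditionals. The w
  update marginalises z analytically (P(y_i = 0 | w_i = 1) =
  Π_j [ψ(1−p)^{K_j} + 1 − ψ]) and z is redrawn immediately afterwards,
  a standard blocked update. Ω is conjugate Beta.
- Each logit(ψ_i), logit(p_i) uses a per-species random-walk Metropolis
  step. Species currently excluded (w_i = 0), or with no occupied
  stations for the detection effect, have no likelihood contribution and
  are refreshed from their community prior.
- μ_ψ, μ_p are drawn from their conjugate normal conditionals (an exact
  draw is used instead of a random-walk step because it is available and
  strictly better mixing); σ_ψ, σ_p use random-walk Metropolis on the log
  scale against the Uniform(0,5) prior.
- Proposal scales adapt toward 44% acceptance during burn-in only and are
  frozen afterwards, preserving detailed balance for all stored draws.

Logit values are clamped at |35| (probabilities are saturated to machine
precision far before that). Fixed seeds give bit-identical chains; each
chain draws from an independent spawned substream.

Two presets are shipped: `paper` (7 chains of 1,000,000 post-burn-in
iterations, burn-in 5,000, thinned by 100 — the headline configuration,
hours-scale) and `desk` (3 × 20,000, burn-in 2,000, thinned by 10), which
is what the test-suite and default pipeline runs use.

### Validation oracle

`msom.exact_posterior_small` computes the richness posterior on tiny
instances (M ≤ 4, J ≤ 3, K ≤ 3) with *fixed* community hyperparameters by
enumerating every (w, z) configuration, integrating each species'
logit-normal effects with 10-point Gauss–Hermite quadrature, and
integrating Ω analytically through the Beta function. Running the sampler
with the same hyperparameters fixed gives a like-for-like comparison; the
acceptance suite requires total-variation distance ≤ 0.03 between the two
richness distributions. The quadrature error of a 10-node rule on these
smooth integrands is far below that tolerance.

### Diagnostics and summaries

`gelman_rubin` implements the classic (non-split, non-rank-normalised)
potential scale reduction factor R̂ = sqrt(((L−1)/L·W + B/L)/W); values
below 1.1 are taken as converged. It is computed for Ω, the four
hyperparameters, N, and the per-species logit effects of observed species;
parameters that are constant by construction (w of observed species) are
excluded because W = 0 leaves R̂ undefined.

Richness is summarised by the lower median (ties on an even draw count take
the lower order statistic) and the empirical 2.5/97.5 percentiles with
linear interpolation. Two community-occupancy functionals are reported and
labelled distinctly, because they answer different questions: the mean of
the per-species posterior occupancy means (dominated by the observed
community) and the posterior mean of logit⁻¹(μ_ψ) (the hyper-level typical
species, including the undetected tail). Ω itself is the inclusion
probability of an augmented row, reported separately.

## Activity patterns

Clock times map to angles by `2π · seconds-since-midnight / 86400`
(midnight = 0). The von Mises fit uses the trigonometric-moment estimators:
μ̂ = atan2(ΣS, ΣC), R̄ = resultant/n, and κ̂ = A⁻¹(R̄) with A = I₁/I₀,
inverted by the Best–Fisher starting value plus Newton refinement to
|A(κ)−R̄| < 1e−9, capped at κ = 500 (R̄ within 1/(2·500) of 1 is already
past the cap, which also guards the cancellation-prone region near R̄ = 1).
Antipodal data give R̄ = 0; the mean direction is then reported as 0 by the
atan2(0,0) convention with a `degenerate` flag. The Rayleigh uniformity
test uses Z = nR̄² with the standard fourth-order series p-value.

Day and night are clock-based, not solar: day is [06:00, 18:00), night the
complement, twilight [05:00, 07:00) ∪ [17:00, 19:00). The four-way
classification is a declared, configurable rule — crepuscular if the
twilight fraction ≥ 0.50, else diurnal/nocturnal if the corresponding
fraction ≥ 0.60, else cathemeral; fewer than 5 events is
"insufficient-data". No numeric thresholds exist in common field practice
(the assignment is usually judgment over rose diagrams), so these defaults
make the assignment reproducible and are echoed in every output.

## Elevation analysis

Box-plot statistics use linear-interpolation (type-7) quantiles with Tukey
1.5·IQR whiskers. The physiographic zones are half-open intervals
[lower, upper): Terai below 300 m, Churia 300–700, middle mountain
700–2000, high mountain 2000–2500, high Himal above — published zone
tables give touching bounds (e.g. "301–700" next to "<300"), and the
half-open convention restores a true partition without moving any
published boundary by more than a metre. Elevations strictly above 2000 m
also raise a `high_altitude_range` flag. A collapsed three-band scheme
(<300, 300–700, >700) supports range-wide capture summaries. Refugia
overlap takes the refugia layer as *input* — either a per-station boolean
or lon/lat polygons evaluated by even-odd ray casting — because deriving
the climatic-refugia surface itself is a GIS modelling exercise outside
this package.

## Synthetic communities

`synthetic.simulate_community` draws a community exactly from the MSOM's
generative assumptions, so the latent truth (ψ_i, p_i, z, the undetected
rows) is available for recovery tests. Defaults mirror the motivating
survey design: 62 stations on a 2×2 km grid with an elevation gradient
over 418–2547 m, 31 nominal occasions with Binomial(31, 2/31) malfunction
nights per station (≈ 2 lost nights each, so total effort lands near 1800
trap-nights), and a 30-species pool with logit-occupancy ~ Normal(−2.5,
2.0) and logit-detection ~ Normal(−2.9, 0.4). The occupancy
hyperparameters were chosen from the analytic inclusion identity
E[n_observed] = n·(1 − E[(1 − ψ(1−(1−p)^K))^J]) so that the expected
observed community is ≈ 23.8 species with per-species occupancy spanning
~0.02–0.8 and detection near 0.05 per night — the regime of a real
mid-hills survey, where the regional pool exceeds the observed list by a
handful of rare species.

Event-level simulation (`simulate_capture_events`) adds Poisson event
counts per occupied station-night and von Mises (or mixture) clock times,
so the independence filter and the activity analysis can run on the same
fixture. The generator does **not** emulate: behavioural attraction/
avoidance of cameras, temporal autocorrelation within a visit (events are
generated independently, so the 30-min filter's effect on synthetic data
is mild), detection heterogeneity across occasions or stations, spatial
autocorrelation of occupancy, or observation/identification error. Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's own assumptions — not robustness to their violation in field
data.

## Problem sizes used in validation

The desk preset (3 × 20,000 thinned by 10) is used everywhere a fit is
needed; at the default design this yields 6,000 stored draws per fit with
max R̂ ≈ 1.00–1.06. The richness-recovery experiment runs 20 replicate
surveys with augmentation nz = 20 — a recovery experiment must let the
augmented pool comfortably exceed the plausible number of undetected
species, otherwise truncation at M = n + nz biases μ̂_ψ upward (with
nz = 10 the bias is ≈ +0.35 logit units at these conditions; with nz = 20
it drops to ≈ +0.10). Headline-style single-survey runs keep nz = 10. The
enumeration cross-check uses M = 3, J = 2, K = 2 with 80,000 sampler
draws.

## Known limitations

- The sampler is plain NumPy; the `paper` preset is hours-scale. For the
  null model this is acceptable; covariate models are out of scope (the
  motivating analysis also dropped covariates due to non-convergence).
- R̂ is the classic formula; rank-normalised/split variants would be more
  sensitive to some pathologies.
- The activity classification is threshold-based by design and will not
  reproduce judgment calls near class boundaries.
- Omega is reported as the augmented-row inclusion probability; it is not
  the mean community occupancy, although field reports sometimes conflate
  the two labels. Both occupancy functionals are therefore written out
  explicitly.
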