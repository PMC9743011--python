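# Methods

This note documents the models, conventions and numerical choices behind
`rootdyn`, and what the synthetic-data tests do and do not establish about
real data.

## Observation model for root demography

A minirhizotron tube is photographed at sessions `t_1 < t_2 < …` roughly
three weeks apart. Each root's status trajectory follows the grammar
`absent* live+ dead* disappeared*`; its length is recorded only while
live. Two censorings follow:

* **Appearance** is known only to lie in `(last absent session, first
  live session]`. Root age is measured from the *midpoint* of that
  interval by default — symmetric and unbiased when appearance is uniform
  within the interval. The alternative `first-live` origin is a flag, and
  the choice is recorded on every derived interval set.
* **Death** is known only to lie in `(last live session, first
  dead-or-disappeared session]`; roots live at the final session are
  right-censored (`R = ∞`). Roots that disappear without ever being scored
  dead are treated as events at the disappearance session, not as
  censored: disappearance ends visibility, and calling it censoring would
  bias longevity upward.

A caveat of the midpoint convention worth knowing: roots that appear *and*
die within a single imaging interval are never photographed live and
cannot enter the data. For short-lived roots this truncation interacts
with the midpoint origin — under an exponential lifetime the observed-root
age distribution is shifted upward by about half an imaging interval
(memorylessness makes `death − first-live` exponential again, and the
midpoint origin adds half the appearance gap). The recovery scenarios in
the tests therefore anchor appearance at a session day, where the origin
is exact; on staggered-appearance data the midpoint convention carries
this mild attenuation, which the `first-live` flag avoids for lifetimes
with near-constant hazard.

## Dynamics statistics

Standing length `l_area` divides the summed live length by the imaged
area (default 46 frames × 13 × 18 mm² = 0.010764 m²). Mortality enters at
a root's *last live length*: the disintegrating root's measured length is
unreliable, so the last reliable measurement is used. The mortality share
uses cumulative dead length from the growing-season start (resetting each
season; `accumulate` available), so the share is 0 before any death and
tends to 1 if everything dies. On fully observed synthetic data the
conservation identity `Δ standing length = production − mortality` holds
to machine precision and is asserted in the tests.

## Turnbull NPMLE

For intervals `(L_i, R_i]` the NPMLE places mass only on maximal
intersections (Turnbull intervals), found by the left-endpoint/
right-endpoint adjacency scan after nudging the open left bounds up by an
epsilon far smaller than any gap between distinct endpoints (exact event
times, `L = R`, stay degenerate atoms). Masses are fitted by the
self-consistency EM

    p_j ← mean_i [ α_ij p_j / Σ_k α_ik p_k ],

`α_ij` = containment of Turnbull interval `j` in observation `i`.
Convergence is `max |Δp| < 1e-8` (tighter on request) with a 10 000-
iteration cap and a non-decreasing log-likelihood asserted at every step.
The estimator provably reduces to the empirical survivor function on
exact times and to Kaplan–Meier on right-censored data; both reductions
are enforced in the test suite against independent implementations
(lifelines' Kaplan–Meier, a literal-loop EM oracle).

Between Turnbull intervals the curve is a step function; *inside* a
positive-width Turnbull interval the NPMLE is non-unique. Those regions
are flagged and evaluated as straight descending slopes (the usual
plotting convention), which makes `survival_at`, the median and the mean
well-defined everywhere:

* median — smallest `t` with `S(t) < 0.5`, strict, so a plateau exactly at
  0.5 defers to the next drop; within a slope the 0.5-crossing is
  returned; undefined (`nan`) under heavy censoring.
* mean — `∫ S dt` to a horizon defaulting to the last finite Turnbull
  boundary. With a censored tail this is a *restricted* mean and is
  flagged as such.

## Logrank scores and the permutation test

Each subject receives the expected classical logrank score given its
interval under the pooled NPMLE:

    c_i = Σ_j α_ij p_j (1 − Λ_j) / Σ_j α_ij p_j,
    Λ_j = Σ_{l≤j} d_l / n_l,  d_l = p_l,  n_l = 1 − Σ_{m<l} p_m,

the discrete Nelson–Aalen hazard estimated from the Turnbull masses
(sample size cancels in d/n). On exact/right-censored data this is
*exactly* `1 − Λ̂(t)` for an event and `−Λ̂(c)` for a censoring — the
classical logrank scores — which the tests verify; it is the natural
grouped-data (Sun-type) generalization. The grouped proportional-hazards
alternative `(S_L log S_L − S_R log S_R)/(S_L − S_R)` is available as
`scores="finkelstein"`. The exact score variant used by older
interval-censoring software differs between sources; the implemented
formula is documented here and checked against a brute-force permutation
distribution on tiny inputs rather than against any one package.

The k-sample statistic is the permutation-form quadratic
`Σ_g U_g²/n_g / s²` with `U_g` the centered group score sums and `s²` the
score variance; `p = (1 + #{T* ≥ T}) / (n_perm + 1)` over label
permutations (default 9999), or a χ²(k−1) reference in asymptotic mode.
Calibration at study-like conditions (two groups of 50, 21-d grid,
999 permutations, 1000 simulations) gives a 5.1–5.2% rejection rate at
α = 0.05.

## Bootstrap

CIs are percentile intervals over B root-level resamples (default
B = 3000; the seedling-level cluster bootstrap is a flag). Percentile
intervals for quantile-type statistics are known to be slightly
anticonservative at moderate n: measured coverage for the grid-censored
NPMLE median at n = 200 is ≈0.91–0.92 rather than 0.95. The test suite
asserts this characterized behavior; users needing strict coverage
should increase n or prefer the mean, whose restricted integral is
smoother.

## Phenology detectors

The 5% thresholds compare per-interval *net increments* against 5% of the
season's summed positive increments — not per-day rates against a sum of
rates, which would be dimensionally incoherent; a `rule="rate"` toggle
provides the other reading. All detections are invariant to uniform
scaling (so proportioned shoot series give identical event days), ties
break toward the earlier interval, undefined events propagate as `nan`,
and a season that never slows down is marked as ceasing at the last
interval with an explicit flag. When growth has no positive increment at
all, every interval counts as slowed, so cessation lands in the second
interval. Degree-days accumulate `max(0, T − 5 °C)` per calendar day with
optional day/night duty-cycle weighting.

## CLAFIC

Feature vectors are one impedance quantity (`Z_Re`, `Z_Im`, `δ`, or
`|Z|`) on the 150 Hz–150 kHz window, unit-norm and *uncentered* — the
classical subspace method, and the reason a k = 1 subspace approximates a
class's mean spectrum. Class bases are top-k eigenvectors of
`XᵀX/n` (`numpy.linalg.eigh`); classification maximizes the squared
projection length, exact ties are reported as ambiguous with all argmax
classes rather than an arbitrary winner, and k equal to the feature
dimension is degenerate by construction (all projections 1). Leave-one-out
requires k ≤ smallest class size − 1; the pipeline caps its k-range
accordingly.

## Fluxes

Chamber concentrations are fitted by OLS over the full 6–8-min record
(optional dead-band trim for placement artifacts); ppm is mole fraction
× 10⁻⁶, so the flux equation's units close to g m⁻² h⁻¹ with
`Pa·m³ = J`. The HPFM correction takes temperatures in °C — the reading
that reproduces the ~43% reduction for a 2 °C measurement against a 22 °C
calibration — and is monotone increasing in measurement temperature.

## Synthetic-data generator

The generator emulates the measurement processes, not the biology in
full:

* root appearance is an inhomogeneous Poisson process with one truncated-
  Gaussian bump per growing season (production in such experiments is
  usually unimodal per season); lifetimes are Weibull with
  treatment-dependent scale (study-like medians 180–240 d; shape 1.5 by
  default, shape 1 = exponential for closed-form checks); per-interval
  elongation is a saturating random increment;
* shoots are logistic curves sampled every 5–9 d with Gaussian noise;
* spectra are Cole–Cole curves `R∞ + (R0 − R∞)/(1 + (jωτ)^α)` per
  treatment with independent Gaussian noise on both parts (α = 1 is the
  Debye case with its imaginary-part peak at ωτ = 1);
* chamber records are linear drifts plus noise over 6–8 min.

Every generator takes an explicit seed, uses one private Generator, and
returns the latent truth (death days, inflection day, true slope, class
labels). Same seed ⇒ bit-identical output.

What passing tests show — and don't. Recovery tests demonstrate that the
estimators invert the *simulated* observation process (interval censoring
on a 21-d grid, right-censoring, unobserved one-interval roots). Real
minirhizotron data add effects the generator does not model: tracing
error in root lengths, delayed visual recognition of death (the scored
death lags true death), tube-installation artifacts, spatial correlation
among roots of one seedling, and non-Weibull hazards. Conclusions about
those failure modes cannot be drawn from the synthetic suite.

## Problem sizes and defaults

Scenario defaults: 16 seedlings × 4 treatments, ~40 roots per seedling,
21-d imaging from day −168 to 126 (day 0 = treatment-season start),
bootstrap B = 3000 for reported tables (200 in the quick pipeline
config), 9999 permutations for reported p-values (999 in simulation
studies), 36 frequencies, 8 spectra per class. Calibration and recovery
studies in the tests and acceptance script use 500 roots (recovery),
1000 × 999 (logrank null), and 200 datasets × B = 300 (bootstrap
coverage) — sizes at which each check's sampling noise is well inside its
assertion band.
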