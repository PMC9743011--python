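# rootdyn

Quantitative machinery for soil-temperature × root-dynamics experiments on
tree seedlings: minirhizotron fine-root demography, interval-censored
survival and turnover estimation, threshold-based growth phenology,
subspace classification of electrical impedance spectra, and closed-form
chamber-flux / hydraulic-conductance computations — plus a synthetic-data
generator that emulates the whole measurement design with known ground
truth.

## Who this is for

Root ecologists and biostatisticians analysing repeated minirhizotron
imaging of individual roots. Such data are doubly interval-censored: a
root's appearance and its death are each known only to lie between two
imaging sessions (~3 weeks apart). The package turns per-session root
trajectories into defensible demography, longevity and turnover numbers,
and bundles the companion analyses such experiments typically carry
(shoot phenology and root–shoot growth offsets, impedance fingerprinting
of treatments, soil trace-gas fluxes).

## What it computes

**Root dynamics.** Standing root length per unit image area
`l_area = Σ live length / frame area` (m m⁻²), its per-interval net
elongation rate `Δl_area` (m m⁻² d⁻¹), per-interval mortality (each dead
root contributes its length at its last live session), and the mortality
share `cumulative dead / (live + cumulative dead)`.

**Survival.** Death ages are intervals `(L, R]` (right-censored when the
root outlives the last session). The survival function is the Turnbull
NPMLE: probability mass lives only on maximal intersections of the
observation intervals and is found by self-consistency (EM) iteration,
with non-unique regions flagged and rendered as descending slopes. The
median is the first time S(t) drops below 0.5; the mean is the (restricted)
integral of S. Treatments are compared with a k-sample weighted-logrank
score test for interval-censored data (label-permutation p-values, 95% CIs
by root-level bootstrap). Fine-root turnover is the inverse longevity:
`FRT = 365 d / longevity` (yr⁻¹), computed from either the median
(FRT_inv_med) or the mean (FRT_inv_mean).

**Phenology.** Relative-threshold detectors on irregularly sampled growth
series: initiation = midpoint of the first interval whose increment
reaches 5% of the season's positive growth; cessation = midpoint of the
second of the first two consecutive sub-5% intervals; plus max-standing
and max-rate days, root-minus-shoot peak offsets, and degree-day sums
(5 °C threshold, day/night duty-cycle weighting).

**Impedance spectra (EIS/CLAFIC).** From 36-frequency complex impedance
spectra (90 Hz–200 kHz): magnitude `|Z| = √(Z_Re² + Z_Im²)` and loss
factor `δ = arctan(Z_Im/Z_Re)`. CLAFIC classification assigns a unit-norm
spectrum to the treatment class whose principal subspace (top-k
eigenvectors of the uncentered class second-moment matrix) captures the
largest squared projection; evaluated by resubstitution and leave-one-out.

**Fluxes.** Static-chamber gas flux
`F_A = dC/dt · (P·M·V)/(R·A·T)` (g m⁻² h⁻¹, negative = soil sink) from the
OLS concentration slope, and the HPFM hydraulic-conductance temperature
correction `K_r = K_raw · (0.554 + 0.0225·T)/(0.554 + 0.0225·T_c)`.

## Worked example

Simulate 500 roots with exponential(200 d) longevities observed on a 21-d
imaging schedule, then recover the longevity through the full pipeline:

```python
import numpy as np
from rootdyn import derive_intervals, turnbull_npmle, median_longevity, \
    mean_longevity, turnover
from rootdyn.records import ImagingSchedule
from rootdyn.simulate import DemographyParams, gaussian_season_intensity, \
    simulate_root_demography

schedule = ImagingSchedule(session_days=np.arange(0, 841, 21),
                           seasons={"GS": (0, 840)})
params = DemographyParams(
    n_seedlings=1, schedule=schedule,
    appearance_intensity=gaussian_season_intensity(0.0, 0.01, 500, -21, 840),
    longevity_weibull={"Cool": (1.0, 200.0)},   # exponential, median 138.6 d
    treatment_of_seedling=lambda s: "Cool", seed=0)
obs, truth = simulate_root_demography(params)
curve = turnbull_npmle(derive_intervals(obs))
print(f"median longevity {median_longevity(curve):.1f} d")
print(f"turnover {turnover(median_longevity(curve))} per year")
```

prints

```
median longevity 134.6 d
turnover 2.7 per year
```

i.e. the NPMLE recovers the true 138.6-d median to within 3% despite every
death being observed only to within a 21-d window. The same machinery from
the shell, including the cold-soil hydraulic correction:

```sh
$ rootdyn hpfm --k-raw 0.1 --temperature-c 2
k_r=0.057102 factor=0.5710 change=-42.9%
```

A measurement taken in 2 °C soil against a 22 °C calibration is reduced by
~43%.

## Analysis drivers

`analysis/01_simulate.py` … `06_fluxes.py` run the study-like scenario end
to end (16 seedlings in 4 soil-temperature treatments — constant Cool,
constant Warm, and the mid-season switches ECLW/EWLC — two growing seasons
of 21-d imaging, treatment-dependent longevity medians of 200–235 d) and
write their tables under `results/analysis/`. `rootdyn run-all --config
cfg.yaml` produces the same bundle from a single config with every seed
recorded in the output headers and a manifest that reproduces every
number.

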