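"""Synthetic data generators with known ground truth.

The study's raw measurements are not deposited, so every pipeline stage is
exercised on simulated inputs that emulate the measurement processes:

* root demography — roots appear during a growing season (unimodal
  truncated-Gaussian intensity, matching the usually unimodal production
  the experiment reports), live a Weibull-distributed span whose scale may
  depend on the soil-temperature treatment, and are observed only at
  ~3-week imaging sessions, which interval-censors both appearance and
  death;
* shoot growth — logistic height/diameter curves sampled every 5–9 days
  with additive Gaussian noise;
* impedance spectra — Cole–Cole relaxation curves per treatment class at
  36 log-spaced frequencies between 90 Hz and 200 kHz, with independent
  Gaussian noise on the real and imaginary parts;
* chamber gas series — linear concentration drift over 6–8 minutes plus
  noise.

Every generator takes an explicit seed and uses a single private
:class:`numpy.random.Generator`; the same seed reproduces bit-identical
output.  Ground-truth parameters (latent death days, true inflection day,
true slope, class labels) are returned alongside the observables so each
downstream estimator has a recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .dynamics import GrowthSeries
from .eis import EISpectrum
from .records import ImagingSchedule, RootObservationSet

__all__ = [
    "DemographyParams",
    "ShootSimParams",
    "EISimParams",
    "gaussian_season_intensity",
    "simulate_root_demography",
    "simulate_shoot_growth",
    "simulate_eis",
    "simulate_chamber_series",
    "cole_cole",
]


def gaussian_season_intensity(center: float, width: float, total: float,
                              lo: float, hi: float) -> Callable[[np.ndarray], np.ndarray]:
    """Truncated-Gaussian appearance intensity over ``[lo, hi]`` (days).

    ``total`` is the expected number of roots per seedling over the season.
    Unimodal with two shape parameters, mirroring the usually unimodal
    root-production pattern seen through minirhizotrons.
    """
    def intensity(day: np.ndarray) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        bump = np.exp(-0.5 * ((day - center) / width) ** 2)
        bump[(day < lo) | (day > hi)] = 0.0
        return bump

    # normalize on a daily grid so the integral equals `total`
    grid = np.arange(np.floor(lo), np.ceil(hi) + 1)
    norm = intensity(grid).sum()
    if norm <= 0:
        raise ValueError("appearance intensity vanishes on the season window")
    return lambda day: intensity(day) * (total / norm)


@dataclass
class DemographyParams:
    """Scenario for the root-demography generator.

    ``longevity_weibull`` maps treatment label to ``(shape, scale_days)``;
    the study-scale scenario uses medians around 180–240 d.  ``schedule``
    is the imaging timeline; ``disappearance_lag`` is the number of
    sessions between a root being scored dead and vanishing from view.
    """

    n_seedlings: int
    schedule: ImagingSchedule
    appearance_intensity: Callable[[np.ndarray], np.ndarray]
    longevity_weibull: dict[str, tuple[float, float]]
    treatment_of_seedling: Callable[[int], str]
    elongation_rate_mm: float = 6.0
    disappearance_lag: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_seedlings < 0:
            raise ValueError("n_seedlings must be >= 0")
        for trt, (shape, scale) in self.longevity_weibull.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"treatment {trt!r}: Weibull shape and scale must be > 0")


def simulate_root_demography(params: DemographyParams):
    """Simulate interval-observed root demography.

    Returns ``(obs, truth)`` where ``obs`` is a validated
    :class:`RootObservationSet` and ``truth`` a DataFrame with one row per
    *simulated* root: ``root_id, seedling_id, treatment, appearance_day,
    death_day, observed`` (``observed`` is False for roots that appeared
    and died within a single imaging interval and were therefore never
    photographed live; they carry no observation rows).  Roots alive at the
    final session have their latent death day recorded but appear
    right-censored in ``obs``.
    """
    sched = params.schedule
    days = sched.session_days
    rng = np.random.default_rng(params.seed)
    day_grid = np.arange(days[0] - (days[1] - days[0] if days.size > 1 else 21), days[-1] + 1)
    rate = np.clip(params.appearance_intensity(day_grid), 0.0, None)

    obs_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for s in range(params.n_seedlings):
        trt = params.treatment_of_seedling(s)
        shape, scale = params.longevity_weibull[trt]
        n_roots = rng.poisson(rate.sum())
        if n_roots == 0:
            continue
        app = rng.choice(day_grid, size=n_roots, p=rate / rate.sum()) if rate.sum() > 0 else None
        lifespans = scale * rng.weibull(shape, size=n_roots)
        classes = np.where(rng.random(n_roots) < 0.8, "short", "long")
        for r in range(n_roots):
            rid = f"s{s:03d}r{r:04d}"
            a, death = float(app[r]), float(app[r] + lifespans[r])
            first_idx = int(np.searchsorted(days, a, side="left"))
            live_idx = [i for i in range(first_idx, days.size) if days[i] < death]
            observed = len(live_idx) > 0
            truth_rows.append((rid, f"s{s:03d}", trt, a, death, observed))
            if not observed:
                continue
            # saturating growth: big first increment, geometric decay after
            n_live = len(live_idx)
            inc = params.elongation_rate_mm / 1000.0 * rng.uniform(0.5, 1.5, size=n_live)
            inc *= 0.6 ** np.arange(n_live)
            length = np.cumsum(inc)
            for i in range(days.size):
                if i < live_idx[0]:
                    status, ln = "absent", 0.0
                elif i in live_idx:
                    status, ln = "live", float(length[live_idx.index(i)])
                else:
                    sessions_past = i - live_idx[-1]
                    status = "dead" if sessions_past <= params.disappearance_lag else "disappeared"
                    ln = 0.0
                obs_rows.append((rid, f"s{s:03d}", trt, classes[r], days[i], ln, status))

    truth = pd.DataFrame(
        truth_rows,
        columns=["root_id", "seedling_id", "treatment", "appearance_day", "death_day", "observed"],
    )
    obs = pd.DataFrame(
        obs_rows,
        columns=["root_id", "seedling_id", "treatment", "root_class",
                 "session_day", "length_m", "status"],
    )
    return RootObservationSet(obs), truth


@dataclass
class ShootSimParams:
    """Logistic shoot-growth scenario: ``asymptote / (1 + exp(-steepness * (t - midpoint)))``.

    Heights in mm (or proportional units); observations on an irregular
    5–9-day schedule over ``[season_start, season_end]`` with additive
    Gaussian noise of ``noise_sd``.
    """

    asymptote: float = 300.0
    midpoint_day: float = 50.0
    steepness: float = 0.12
    season_start: float = 0.0
    season_end: float = 105.0
    obs_interval: tuple[int, int] = (5, 9)
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.asymptote <= 0:
            raise ValueError("asymptote must be positive")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


def logistic(t, asymptote, midpoint, steepness):
    t = np.asarray(t, dtype=float)
    return asymptote / (1.0 + np.exp(-steepness * (t - midpoint)))


def simulate_shoot_growth(params: ShootSimParams, seed: int = 0):
    """Returns ``(GrowthSeries, true_inflection_day)``."""
    rng = np.random.default_rng(seed)
    lo, hi = params.obs_interval
    days = [params.season_start]
    while days[-1] < params.season_end:
        days.append(days[-1] + int(rng.integers(lo, hi + 1)))
    days = np.array(days, dtype=float)
    days = days[days <= params.season_end]
    values = logistic(days, params.asymptote, params.midpoint_day, params.steepness)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=days.size)
    series = GrowthSeries(days=days, values=values, metadata={"kind": "shoot"})
    return series, params.midpoint_day


@dataclass
class EISimParams:
    """Per-class Cole–Cole scenarios for impedance spectra.

    ``classes`` maps label to ``(R_inf, R_0, tau_s, alpha)`` with
    ``R_0 > R_inf > 0`` and ``0 < alpha <= 1``; 36 log-spaced frequencies
    between 90 Hz and 200 kHz; ``n_per_class`` spectra per class with
    independent Gaussian noise (sd in ohms) on both impedance parts.
    """

    classes: dict[str, tuple[float, float, float, float]]
    n_per_class: int = 8
    noise_sd: float = 1.0
    frequencies_hz: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(90.0), np.log10(200e3), 36)
    )
    seed: int = 0

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        if self.frequencies_hz.size != 36:
            raise ValueError("spectra use exactly 36 frequencies")
        for label, (r_inf, r0, tau, alpha) in self.classes.items():
            if not (r0 > r_inf > 0):
                raise ValueError(f"class {label!r}: need R_0 > R_inf > 0")
            if not (0 < alpha <= 1):
                raise ValueError(f"class {label!r}: alpha must be in (0, 1]")
            if tau <= 0:
                raise ValueError(f"class {label!r}: tau must be positive")


def cole_cole(freq_hz, r_inf, r0, tau, alpha):
    """Cole–Cole impedance ``R_inf + (R_0 - R_inf) / (1 + (j w tau)^alpha)``.

    ``alpha = 1`` is the single-dispersion Debye case, whose imaginary part
    is most negative at ``w tau = 1``.
    """
    w = 2.0 * np.pi * np.asarray(freq_hz, dtype=float)
    return r_inf + (r0 - r_inf) / (1.0 + (1j * w * tau) ** alpha)


def simulate_eis(params: EISimParams) -> list[EISpectrum]:
    """Labelled Cole–Cole spectra with additive Gaussian noise."""
    rng = np.random.default_rng(params.seed)
    out: list[EISpectrum] = []
    for label, (r_inf, r0, tau, alpha) in params.classes.items():
        z = cole_cole(params.frequencies_hz, r_inf, r0, tau, alpha)
        for i in range(params.n_per_class):
            re = z.real + (rng.normal(0, params.noise_sd, z.size) if params.noise_sd > 0 else 0.0)
            im = z.imag + (rng.normal(0, params.noise_sd, z.size) if params.noise_sd > 0 else 0.0)
            out.append(
                EISpectrum(
                    frequencies_hz=params.frequencies_hz.copy(),
                    z_re=np.asarray(re, dtype=float),
                    z_im=np.asarray(im, dtype=float),
                    sample_id=f"{label}-{i:02d}",
                    tissue="root",
                    label=label,
                )
            )
    return out


def simulate_chamber_series(
    slope_ppm_per_h: float,
    intercept_ppm: float = 1.0,
    duration_min: float = 7.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_s: float = 10.0,
):
    """Linear chamber-concentration drift sampled every ``dt_s`` seconds.

    Returns ``(time_s, concentration_ppm, true_slope_ppm_per_h)``; negative
    slopes represent uptake (the soil acting as a sink).
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min * 60.0 + dt_s / 2, dt_s)
    c = intercept_ppm + slope_ppm_per_h * t / 3600.0
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=t.size)
    return t, c, slope_ppm_per_h
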