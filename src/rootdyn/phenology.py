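"""Threshold-based phenology detection for root and shoot growth series.

Event definitions operate on a cumulative growth series sampled at imaging
sessions inside one growing-season window:

* initiation — midpoint of the first imaging interval whose net increment
  reaches 5% of the sum of the season's positive increments;
* cessation — midpoint of the *second* interval of the first pair of
  consecutive intervals both below that same 5% threshold; seasons that
  never slow down are marked as ceasing at the last interval and flagged;
* day of maximum standing value — the session day (interval end) at which
  the series attains its maximum;
* day of maximum rate — midpoint of the interval with the largest per-day
  rate.

All thresholds are relative, so detections are invariant to uniform
scaling of the series.  Ties break toward the earlier interval, and
undefined events propagate as ``nan`` (never sentinel numbers).  The 5%
comparison uses per-interval *net increments* by default (consistent
units); ``rule="rate"`` toggles the per-day-rate interpretation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import GrowthSeries

__all__ = [
    "PhenologyEvents",
    "detect_initiation",
    "detect_cessation",
    "day_of_max_standing",
    "day_of_max_rate",
    "detect_shoot_events",
    "offset",
    "OffsetResult",
    "degree_days",
]


@dataclass
class PhenologyEvents:
    """Event days for one series in one season (``nan`` = undefined)."""

    initiation: float
    cessation: float
    max_standing_day: float
    max_rate_day: float
    ceased_at_last_interval: bool = False

    def __post_init__(self):
        trio = (self.initiation, self.max_rate_day, self.cessation)
        if all(map(math.isfinite, trio)) and not (trio[0] <= trio[1] <= trio[2]):
            warnings.warn(
                f"event ordering violated: initiation {trio[0]} <= "
                f"max-rate {trio[1]} <= cessation {trio[2]} does not hold",
                stacklevel=2,
            )


def _season_series(series: GrowthSeries, season: tuple[float, float]) -> GrowthSeries:
    sub = series.window(*season)
    return sub


def _interval_measures(sub: GrowthSeries, rule: str) -> np.ndarray:
    if rule == "increment":
        return sub.increments
    if rule == "rate":
        return sub.rates
    raise ValueError(f"unknown rule {rule!r}")


def detect_initiation(
    series: GrowthSeries,
    season: tuple[float, float],
    threshold: float = 0.05,
    rule: str = "increment",
) -> float:
    """Growth-initiation day (midpoint of first interval at >= 5% of the
    season's positive growth); ``nan`` if nothing qualifies."""
    sub = _season_series(series, season)
    if sub.days.size < 2:
        raise ValueError("need at least two sessions in the season")
    meas = _interval_measures(sub, rule)
    pos_sum = meas[meas > 0].sum()
    if pos_sum <= 0:
        warnings.warn("no positive growth in season; initiation undefined", stacklevel=2)
        return float("nan")
    qualifying = np.nonzero(meas >= threshold * pos_sum)[0]
    if qualifying.size == 0:
        return float("nan")
    i = qualifying[0]
    return float((sub.days[i] + sub.days[i + 1]) / 2.0)


def detect_cessation(
    series: GrowthSeries,
    season: tuple[float, float],
    threshold: float = 0.05,
    rule: str = "increment",
) -> tuple[float, bool]:
    """Growth-cessation day and a flag for the never-slowed fallback.

    Returns ``(day, at_last_interval)``: the midpoint of the second
    interval of the first consecutive below-threshold pair, or — if growth
    never slows — the midpoint of the last interval with the flag set.
    """
    sub = _season_series(series, season)
    if sub.days.size < 3:
        raise ValueError("need at least three sessions in the season")
    meas = _interval_measures(sub, rule)
    pos_sum = meas[meas > 0].sum()
    cut = threshold * pos_sum
    # with no positive growth at all, every interval counts as slowed
    below = meas < cut if pos_sum > 0 else np.ones(meas.size, dtype=bool)
    pair = np.nonzero(below[:-1] & below[1:])[0]
    if pair.size:
        j = pair[0] + 1  # midpoint of the latter interval of the pair
        return float((sub.days[j] + sub.days[j + 1]) / 2.0), False
    j = meas.size - 1
    return float((sub.days[j] + sub.days[j + 1]) / 2.0), True


def day_of_max_standing(series: GrowthSeries, season: tuple[float, float]) -> float:
    """Session day (interval end) of the maximum standing value; earliest
    session on ties."""
    sub = _season_series(series, season)
    if sub.days.size == 0:
        return float("nan")
    return float(sub.days[int(np.argmax(sub.values))])


def day_of_max_rate(series: GrowthSeries, season: tuple[float, float]) -> float:
    """Midpoint of the interval with the maximal per-day growth rate;
    earliest interval on ties."""
    sub = _season_series(series, season)
    if sub.days.size < 2:
        return float("nan")
    i = int(np.argmax(sub.rates))
    return float((sub.days[i] + sub.days[i + 1]) / 2.0)


def root_events(
    series: GrowthSeries,
    season: tuple[float, float],
    threshold: float = 0.05,
    rule: str = "increment",
) -> PhenologyEvents:
    """All four root-phenology events for one series."""
    cess, flagged = detect_cessation(series, season, threshold, rule)
    return PhenologyEvents(
        initiation=detect_initiation(series, season, threshold, rule),
        cessation=cess,
        max_standing_day=day_of_max_standing(series, season),
        max_rate_day=day_of_max_rate(series, season),
        ceased_at_last_interval=flagged,
    )


def detect_shoot_events(
    height_series: GrowthSeries,
    diameter_series: GrowthSeries,
    season: tuple[float, float],
    budburst_day: float | None = None,
    threshold: float = 0.05,
) -> tuple[PhenologyEvents, PhenologyEvents]:
    """Shoot phenology: ``(height_events, diameter_events)``.

    Height growth initiates at budburst (an external observation passed
    through); diameter initiation is the midpoint of the interval where the
    cumulative increment first reaches 5% of the season total.  Cessation
    for both is the midpoint of the interval in which the maximum value is
    reached; max-rate days as for roots.  Both metrics are scale invariant,
    so series proportioned to their season-start value give identical
    event days.
    """
    out = []
    for series, kind in ((height_series, "height"), (diameter_series, "diameter")):
        sub = _season_series(series, season)
        if sub.days.size < 2 or np.allclose(np.diff(sub.values), 0.0):
            warnings.warn(f"flat {kind} series; events undefined", stacklevel=2)
            out.append(PhenologyEvents(*(float("nan"),) * 4))
            continue
        if kind == "height":
            init = float(budburst_day) if budburst_day is not None else float("nan")
        else:
            total = sub.values[-1] - sub.values[0]
            cum = np.cumsum(sub.increments)
            hit = np.nonzero(cum >= threshold * total)[0]
            if hit.size:
                i = hit[0]
                init = float((sub.days[i] + sub.days[i + 1]) / 2.0)
            else:
                init = float("nan")
        k = int(np.argmax(sub.values))
        cess = float((sub.days[k - 1] + sub.days[k]) / 2.0) if k > 0 else float("nan")
        out.append(
            PhenologyEvents(
                initiation=init,
                cessation=cess,
                max_standing_day=day_of_max_standing(series, season),
                max_rate_day=day_of_max_rate(series, season),
            )
        )
    return out[0], out[1]


@dataclass
class OffsetResult:
    """Root-minus-shoot difference of max-rate days.

    Positive = root growth peaked later than shoot growth.
    """

    offset_days: float
    shoot_metric: str
    root_class: str


def offset(
    root_events_: PhenologyEvents,
    shoot_events_: PhenologyEvents,
    shoot_metric: str = "diameter",
    root_class: str = "short",
) -> OffsetResult:
    return OffsetResult(
        offset_days=float(root_events_.max_rate_day - shoot_events_.max_rate_day),
        shoot_metric=shoot_metric,
        root_class=root_class,
    )


def degree_days(
    temperatures_c,
    threshold_c: float = 5.0,
    day_night_hours: tuple[float, float] | None = None,
) -> float:
    """Accumulated degree-days over a daily temperature record.

    ``temperatures_c`` is either a 1-D array of daily temperatures or a
    2-column array of (day, night) temperatures; with the latter,
    ``day_night_hours`` (e.g. ``(18, 6)``) duty-cycle weights the excess
    over ``threshold_c`` within each calendar day.
    """
    temps = np.asarray(temperatures_c, dtype=float)
    if temps.ndim == 1:
        return float(np.sum(np.clip(temps - threshold_c, 0.0, None)))
    if temps.ndim != 2 or temps.shape[1] != 2:
        raise ValueError("expect 1-D daily temps or (n, 2) day/night temps")
    if day_night_hours is None:
        raise ValueError("day/night temperatures require day_night_hours")
    h_day, h_night = day_night_hours
    if h_day + h_night != 24:
        raise ValueError("day and night hours must total 24")
    excess = np.clip(temps - threshold_c, 0.0, None)
    daily = excess[:, 0] * h_day / 24.0 + excess[:, 1] * h_night / 24.0
    return float(daily.sum())
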