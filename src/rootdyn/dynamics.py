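"""Standing-length, growth-rate, mortality and morphology statistics.

Conventions for minirhizotron-derived series:

* standing length ``l_area`` (m m^-2): total live root length per unit
  image area at each session;
* net increment (m m^-2): ``l_area`` minus its value at the growing-season
  start (may go negative when mortality exceeds production);
* elongation rate ``dl_area`` (m m^-2 d^-1): per-interval difference
  divided by interval length — new appearance and old-root elongation are
  both included by construction;
* mortality (m m^-2): per interval, the summed length of roots that died
  in that interval, each entering with its length at its last live session
  (the disintegrating root's measured length is unreliable);
* mortality share: cumulative dead length / (live l_area + cumulative
  dead length), accumulated from the season start (resetting per season by
  default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ImagingSchedule, RootObservationSet, STATUS_ORDER

__all__ = [
    "GrowthSeries",
    "MortalitySeries",
    "MorphologySummary",
    "standing_length",
    "net_increment",
    "elongation_rate",
    "mortality",
    "morphology_summary",
    "ln_transform",
    "logit_transform",
]


@dataclass
class GrowthSeries:
    """Irregularly sampled cumulative growth with per-interval rates."""

    days: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.size != self.values.size:
            raise ValueError("days and values must align")
        if self.days.size >= 2 and not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")

    @property
    def rates(self) -> np.ndarray:
        """Per-interval rates, one element shorter than ``values``."""
        return np.diff(self.values) / np.diff(self.days)

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.values)

    def window(self, lo: float, hi: float) -> "GrowthSeries":
        m = (self.days >= lo) & (self.days <= hi)
        return GrowthSeries(self.days[m], self.values[m], dict(self.metadata))


@dataclass
class MortalitySeries:
    days: np.ndarray
    dead_length: np.ndarray        # per interval ending at days[i]; first entry 0
    mortality_rate: np.ndarray     # dead_length / interval days
    cumulative_dead: np.ndarray
    share: np.ndarray              # cumulative dead / (live + cumulative dead)
    metadata: dict = field(default_factory=dict)


def _live_length_per_session(obs: RootObservationSet, days: np.ndarray) -> np.ndarray:
    df = obs.table
    live = df[df["status"] == "live"]
    sums = live.groupby("session_day")["length_m"].sum()
    return np.array([float(sums.get(d, 0.0)) for d in days])


def standing_length(
    obs: RootObservationSet,
    schedule: ImagingSchedule,
    root_class: str | None = None,
    seedling_id=None,
) -> GrowthSeries:
    """Standing live root length per unit image area at every session."""
    sub = obs.subset(root_class=root_class, seedling_id=seedling_id)
    days = schedule.session_days
    values = _live_length_per_session(sub, days) / schedule.frame_area_m2
    return GrowthSeries(
        days=days.copy(),
        values=values,
        metadata={"quantity": "l_area", "units": "m m-2",
                  "root_class": root_class, "seedling_id": seedling_id},
    )


def net_increment(series: GrowthSeries, season_start: float) -> GrowthSeries:
    """Series minus its value at the season-start session (which must be a
    session day); negative values mean net loss."""
    idx = np.nonzero(series.days == season_start)[0]
    if idx.size == 0:
        raise ValueError(f"season start {season_start} is not a session day")
    base = series.values[idx[0]]
    m = series.days >= season_start
    return GrowthSeries(
        series.days[m], series.values[m] - base,
        {**series.metadata, "quantity": "net_increment", "season_start": season_start},
    )


def elongation_rate(series: GrowthSeries) -> GrowthSeries:
    """Per-interval rate series, indexed by interval-end day."""
    if series.days.size < 2:
        raise ValueError("need at least two sessions")
    return GrowthSeries(
        series.days[1:], series.rates,
        {**series.metadata, "quantity": "dl_area_rate", "units": "m m-2 d-1"},
    )


def mortality(
    obs: RootObservationSet,
    schedule: ImagingSchedule,
    root_class: str | None = None,
    seedling_id=None,
    season_start: float | None = None,
) -> MortalitySeries:
    """Per-interval dead length, mortality rate, and mortality share.

    A root contributes its length at its last live session to the interval
    ending at the first session it was scored dead (or disappeared, if
    never seen dead).  ``season_start`` (default: first session) is where
    cumulative dead length starts accumulating.
    """
    sub = obs.subset(root_class=root_class, seedling_id=seedling_id)
    days = schedule.session_days
    if season_start is None:
        season_start = days[0]
    area = schedule.frame_area_m2
    dead_len = np.zeros(days.size)
    for _, root in sub.table.groupby("root_id", sort=False):
        codes = root["status"].map(STATUS_ORDER).to_numpy()
        ddays = root["session_day"].to_numpy(dtype=float)
        ev = np.nonzero(codes >= 2)[0]
        if ev.size == 0:
            continue
        last_live_len = root["length_m"].to_numpy(dtype=float)[codes == 1][-1]
        sess = np.nonzero(days == ddays[ev[0]])[0]
        if sess.size:
            dead_len[sess[0]] += last_live_len
    dead_len /= area
    with np.errstate(divide="ignore", invalid="ignore"):
        gaps = np.concatenate([[np.nan], np.diff(days)])
        rate = np.where(np.isnan(gaps), 0.0, dead_len / gaps)
    in_season = days >= season_start
    cum = np.cumsum(np.where(in_season, dead_len, 0.0))
    cum[~in_season] = 0.0
    live = _live_length_per_session(sub, days) / area
    denom = live + cum
    share = np.divide(cum, denom, out=np.zeros_like(cum), where=denom > 0)
    return MortalitySeries(
        days=days.copy(), dead_length=dead_len, mortality_rate=rate,
        cumulative_dead=cum, share=share,
        metadata={"root_class": root_class, "seedling_id": seedling_id,
                  "season_start": season_start},
    )


# ---------------------------------------------------------------------------
# Harvest morphology
# ---------------------------------------------------------------------------

DIAMETER_CLASSES = ("d<=0.5", "0.5<d<=1", "1<d<=2", "2<d<=4.5")


@dataclass
class MorphologySummary:
    """Per-diameter-class harvest morphology with derived ratios.

    ``table`` rows are diameter classes with columns ``length_m,
    surface_m2, volume_cm3, tips`` (already upscaled); ``srl_m_per_g`` and
    ``tissue_density_kg_m3`` cover the mass-measured aggregate classes.
    """

    table: pd.DataFrame
    srl_m_per_g: dict[str, float]
    tissue_density_kg_m3: dict[str, float]
    tips_per_cm: float
    upscale_factor: float


def morphology_summary(
    scan_table: pd.DataFrame,
    masses_g: dict[str, float],
    sector_volume_cm3: float = 1.0,
    container_volume_cm3: float = 1.0,
) -> MorphologySummary:
    """Aggregate a WinRHIZO-style scan table and compute SRL / density.

    ``scan_table`` needs columns ``diameter_class, length_m, surface_m2,
    volume_cm3, tips``; ``masses_g`` maps aggregate classes (e.g.
    ``"d<=2"``, ``"2<d<=4.5"``) to dry mass.  Sector measurements are
    upscaled to the container by the volume ratio.  SRL = length / mass
    (m g^-1); tissue density = mass / volume expressed in kg m^-3.
    """
    if sector_volume_cm3 <= 0 or container_volume_cm3 <= 0:
        raise ValueError("volumes must be positive")
    factor = container_volume_cm3 / sector_volume_cm3
    agg = scan_table.groupby("diameter_class")[
        ["length_m", "surface_m2", "volume_cm3", "tips"]
    ].sum() * factor

    def class_total(col: str, agg_class: str) -> float:
        if agg_class == "d<=2":
            members = ["d<=0.5", "0.5<d<=1", "1<d<=2"]
        else:
            members = [agg_class]
        return float(agg.loc[agg.index.intersection(members), col].sum())

    srl, density = {}, {}
    for agg_class, mass in masses_g.items():
        length = class_total("length_m", agg_class)
        volume = class_total("volume_cm3", agg_class)
        if mass <= 0:
            if length > 0:
                raise ValueError(f"class {agg_class!r}: zero mass with nonzero length")
            continue
        srl[agg_class] = length / mass
        if volume > 0:
            density[agg_class] = (mass / 1000.0) / (volume * 1e-6)
    total_tips = float(agg["tips"].sum())
    total_len_cm = float(agg["length_m"].sum()) * 100.0
    tips_per_cm = total_tips / total_len_cm if total_len_cm > 0 else float("nan")
    return MorphologySummary(agg.reset_index(), srl, density, tips_per_cm, factor)


def ln_transform(x):
    """Natural log transform used for l_area/mortality style quantities."""
    x = np.asarray(x, dtype=float)
    return np.log(x)


def logit_transform(p):
    """Logit transform used for share-type quantities in (0, 1)."""
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))
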