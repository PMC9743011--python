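"""Data model and I/O for interval-observed root demography.

Minirhizotron imaging yields, for every root, a status trajectory on a
shared session schedule: the root is ``absent`` until it appears, ``live``
for one or more sessions, and may then be scored ``dead`` (visibly
disintegrated) and/or ``disappeared`` (no longer visible).  Because the
tubes are photographed at roughly three-week intervals, neither the
appearance day nor the death day is observed exactly — both are known only
to lie inside an imaging interval.  This module validates such trajectories
and converts them into the interval-censored death-age records that the
survival machinery consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATUS_ORDER = {"absent": 0, "live": 1, "dead": 2, "disappeared": 3}

OBS_COLUMNS = [
    "root_id",
    "seedling_id",
    "treatment",
    "root_class",
    "session_day",
    "length_m",
    "status",
]


class RootRecordError(ValueError):
    """Raised for malformed observation tables, naming the offending root."""


@dataclass(frozen=True)
class ImagingSchedule:
    """Imaging-session timeline shared by all tubes.

    Parameters
    ----------
    session_days : array-like of int
        Strictly increasing study-timeline days (day 0 = start of the
        treatment growing season; negative days are earlier phases).
    seasons : dict
        Mapping of phase name (e.g. ``"GS1"``, ``"D1"``, ``"GS2"``) to
        ``(start_day, end_day)`` windows.  Windows must not overlap.
    frame_area_m2 : float
        Total imaged area per tube.  The study design is 46 frames of
        13 x 18 mm^2, i.e. 0.010764 m^2.
    """

    session_days: np.ndarray
    seasons: dict[str, tuple[float, float]] = field(default_factory=dict)
    frame_area_m2: float = 46 * 0.013 * 0.018

    def __post_init__(self):
        days = np.asarray(self.session_days, dtype=float)
        if days.size == 0:
            raise RootRecordError("schedule has no sessions")
        if not np.all(np.diff(days) > 0):
            raise RootRecordError("session days must be strictly increasing")
        if self.frame_area_m2 <= 0:
            raise RootRecordError("frame_area_m2 must be positive")
        windows = sorted(self.seasons.values())
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if a1 > b0:
                raise RootRecordError("season windows overlap")
        object.__setattr__(self, "session_days", days)

    def sessions_in(self, season: str | tuple[float, float]) -> np.ndarray:
        """Session days falling inside a named or explicit window (inclusive)."""
        lo, hi = self.seasons[season] if isinstance(season, str) else season
        d = self.session_days
        return d[(d >= lo) & (d <= hi)]


class RootObservationSet:
    """Validated longitudinal per-root, per-session observations.

    Wraps a tidy DataFrame with columns ``root_id, seedling_id, treatment,
    root_class, session_day, length_m, status`` sorted by root and day.
    Construction enforces the trajectory grammar
    ``absent* live+ dead* disappeared*`` and zero length off the live phase.
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        missing = [c for c in OBS_COLUMNS if c not in table.columns]
        if missing:
            raise RootRecordError(f"missing columns: {missing}")
        df = table.loc[:, OBS_COLUMNS].copy()
        df = df.sort_values(["root_id", "session_day"], kind="stable")
        df = df.reset_index(drop=True)
        self.table = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.table
        bad_status = set(df["status"]) - set(STATUS_ORDER)
        if bad_status:
            raise RootRecordError(f"unknown status token(s): {sorted(bad_status)}")
        for rid, sub in df.groupby("root_id", sort=False):
            days = sub["session_day"].to_numpy(dtype=float)
            if np.any(np.diff(days) <= 0):
                raise RootRecordError(f"root {rid!r}: duplicated or decreasing session days")
            codes = sub["status"].map(STATUS_ORDER).to_numpy()
            if np.any(np.diff(codes) < 0):
                raise RootRecordError(
                    f"root {rid!r}: illegal status transition "
                    "(order must be absent -> live -> dead -> disappeared)"
                )
            if not np.any(codes == 1):
                raise RootRecordError(f"root {rid!r}: never observed live")
            lengths = sub["length_m"].to_numpy(dtype=float)
            if np.any(lengths[codes != 1] != 0):
                raise RootRecordError(f"root {rid!r}: nonzero length on a non-live session")
            if np.any(lengths < 0):
                raise RootRecordError(f"root {rid!r}: negative length")
            if sub["root_class"].nunique() > 1:
                raise RootRecordError(
                    f"root {rid!r}: root_class must be constant "
                    "(short->long reclassification is retroactive)"
                )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, source) -> "RootObservationSet":
        df = pd.read_csv(source, comment="#")
        return cls(df)

    def to_csv(self, target=None) -> str | None:
        if target is None:
            buf = io.StringIO()
            self.table.to_csv(buf, index=False)
            return buf.getvalue()
        self.table.to_csv(target, index=False)
        return None

    # -- accessors ---------------------------------------------------------

    @property
    def root_ids(self) -> np.ndarray:
        return self.table["root_id"].unique()

    def __len__(self) -> int:
        return len(self.root_ids)

    def subset(self, root_class: str | None = None, seedling_id=None) -> "RootObservationSet":
        df = self.table
        if root_class is not None:
            df = df[df["root_class"] == root_class]
        if seedling_id is not None:
            df = df[df["seedling_id"] == seedling_id]
        return RootObservationSet(df.copy(), validate=False)


def read_root_table(source) -> RootObservationSet:
    """Read and validate a root-observation CSV (see :data:`OBS_COLUMNS`)."""
    return RootObservationSet.from_csv(source)


@dataclass
class IntervalCensoredSet:
    """Per-root death-age intervals ``(left, right]``.

    ``right`` is ``inf`` for roots still live at the last session
    (right-censored).  ``left == right`` encodes an exactly observed event
    time (used by oracle tests; the imaging process itself never produces
    one).  ``group`` carries the treatment label.
    """

    root_id: np.ndarray
    group: np.ndarray
    left: np.ndarray
    right: np.ndarray
    age_origin: str = "midpoint"

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.root_id = np.asarray(self.root_id)
        self.group = np.asarray(self.group)
        if not (len(self.left) == len(self.right) == len(self.group) == len(self.root_id)):
            raise RootRecordError("interval arrays must have equal length")
        if np.any(self.right < self.left):
            raise RootRecordError("interval right bound below left bound")

    def __len__(self) -> int:
        return len(self.left)

    @property
    def n_censored(self) -> int:
        return int(np.sum(np.isinf(self.right)))

    def for_group(self, label) -> "IntervalCensoredSet":
        m = self.group == label
        return IntervalCensoredSet(
            self.root_id[m], self.group[m], self.left[m], self.right[m], self.age_origin
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "root_id": self.root_id,
                "group": self.group,
                "L_day": self.left,
                "R_day": np.where(np.isinf(self.right), np.nan, self.right),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, age_origin: str = "midpoint") -> "IntervalCensoredSet":
        right = df["R_day"].to_numpy(dtype=float)
        right = np.where(np.isnan(right), np.inf, right)
        return cls(df["root_id"].to_numpy(), df["group"].to_numpy(),
                   df["L_day"].to_numpy(dtype=float), right, age_origin)


def derive_intervals(
    obs: RootObservationSet,
    age_origin: str = "midpoint",
) -> IntervalCensoredSet:
    """Convert observation trajectories to interval-censored death ages.

    For each root the death interval on the study timeline is
    ``(last session seen live, first session seen dead-or-disappeared]``;
    roots live at their final session are right-censored.  Ages subtract an
    appearance reference:

    * ``"midpoint"`` (default) — midpoint of the appearance interval, i.e.
      halfway between the last session the root was absent and the first
      session it was live.  If the root was already live at its first
      recorded session the first-live day is used.
    * ``"first-live"`` — the first session the root was observed live.

    The choice is recorded on the returned set so downstream reports can
    state it.
    """
    if age_origin not in ("midpoint", "first-live"):
        raise RootRecordError(f"unknown age_origin {age_origin!r}")
    ids, groups, lefts, rights = [], [], [], []
    for rid, sub in obs.table.groupby("root_id", sort=False):
        days = sub["session_day"].to_numpy(dtype=float)
        codes = sub["status"].map(STATUS_ORDER).to_numpy()
        live_days = days[codes == 1]
        if live_days.size == 0:
            raise RootRecordError(f"root {rid!r}: never observed live")
        first_live, last_live = live_days[0], live_days[-1]
        absent_before = days[(codes == 0) & (days < first_live)]
        if age_origin == "midpoint" and absent_before.size:
            origin = (absent_before[-1] + first_live) / 2.0
        else:
            origin = first_live
        event_days = days[codes >= 2]  # dead takes precedence: it sorts first
        right = event_days[0] if event_days.size else np.inf
        ids.append(rid)
        groups.append(sub["treatment"].iloc[0])
        lefts.append(last_live - origin)
        rights.append(right - origin if np.isfinite(right) else np.inf)
    return IntervalCensoredSet(
        np.array(ids), np.array(groups), np.array(lefts), np.array(rights), age_origin
    )
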