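"""Telemetry tracks, steps, and track filtering.

A :class:`Track` is a time-ordered sequence of planar locations for one
individual, with time measured in decimal days from a track-local epoch
(midnight of the first fix for datetime input). Coordinates must already be
in a projected planar system in meters; no geographic support is provided.

Steps are consecutive location pairs carrying step length ``sl`` (m),
absolute ``bearing`` (radians, counterclockwise from +x), and turning angle
``ta`` in (-pi, pi] (counterclockwise positive; undefined for the first step
of a track, which has no previous bearing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Location",
    "Track",
    "Step",
    "read_track",
    "steps_from_track",
    "filter_track",
    "steps_to_frame",
    "wrap_angle",
]

TWO_PI = 2.0 * math.pi


def wrap_angle(a):
    """Wrap angle(s) into (-pi, pi]."""
    w = np.asarray(a, dtype=float)
    out = -((-w + math.pi) % TWO_PI - math.pi)
    return float(out) if np.isscalar(a) or out.ndim == 0 else out


@dataclass(frozen=True)
class Location:
    """A single fix: time ``t`` in decimal days, planar ``x``, ``y`` in meters."""

    t: float
    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.t) and math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite location: t={self.t}, x={self.x}, y={self.y}")


@dataclass
class Track:
    """Time-ordered telemetry for one individual.

    ``fix_interval`` is the nominal (median) sampling interval in days; it is
    reported, not enforced per-gap. A Track may be empty (e.g. the result of
    an exhaustive filter); operations that need locations check themselves.
    """

    id: str
    locations: list[Location] = field(default_factory=list)
    fix_interval: Optional[float] = None

    def __post_init__(self):
        ts = [loc.t for loc in self.locations]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"track {self.id!r}: timestamps not strictly increasing")
        if self.fix_interval is None and len(ts) >= 2:
            self.fix_interval = float(np.median(np.diff(ts)))

    def __len__(self) -> int:
        return len(self.locations)

    @property
    def t(self) -> np.ndarray:
        return np.array([loc.t for loc in self.locations])

    @property
    def xy(self) -> np.ndarray:
        return np.array([[loc.x, loc.y] for loc in self.locations]).reshape(-1, 2)

    @property
    def duration(self) -> float:
        if len(self.locations) < 2:
            return 0.0
        return self.locations[-1].t - self.locations[0].t


@dataclass(frozen=True)
class Step:
    """One movement step between consecutive fixes.

    ``ta`` is None for the first step of a track (needs two prior locations).
    ``gap_days`` flags the actual elapsed time so irregular gaps stay visible;
    no interpolation or gap-splitting is performed.
    """

    start: Location
    end: Location
    sl: float
    bearing: float
    ta: Optional[float]

    @property
    def gap_days(self) -> float:
        return self.end.t - self.start.t


def read_track(
    table_path,
    column_map: Optional[dict] = None,
    *,
    track_id: Optional[str] = None,
    delimiter: str = ",",
) -> Track:
    """Read one individual's track from a delimited text table.

    ``column_map`` maps the roles ``id``, ``time``, ``x``, ``y`` to column
    names in the file (defaults to those literal names; ``id`` is optional).
    Timestamps may be ISO-8601 strings or numeric decimal days. Rows are
    sorted by time; times are converted to decimal days from the track-local
    epoch (midnight of the first fix for datetimes, ``floor(t_min)`` for
    numeric input) so hour-of-day is preserved for diel filtering.
    """
    cmap = {"id": "id", "time": "time", "x": "x", "y": "y"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(table_path, delimiter=delimiter)
    for role in ("time", "x", "y"):
        if cmap[role] not in df.columns:
            raise ValueError(f"column {cmap[role]!r} (role {role!r}) not found in {table_path}")

    if cmap["id"] in df.columns:
        ids = df[cmap["id"]].astype(str)
        if track_id is not None:
            df = df[ids == str(track_id)]
            if df.empty:
                raise ValueError(f"no rows with id {track_id!r} in {table_path}")
        elif ids.nunique() > 1:
            raise ValueError(
                f"multiple individuals in {table_path} ({sorted(ids.unique())}); pass track_id"
            )
        the_id = str(df[cmap["id"]].iloc[0])
    else:
        the_id = track_id if track_id is not None else "track"
    if df.empty:
        raise ValueError(f"no rows in {table_path}")

    for role in ("x", "y"):
        col = pd.to_numeric(df[cmap[role]], errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"non-numeric {role!r} value at row index {int(df.index[bad[0]])} in {table_path}"
            )
        df[cmap[role]] = col

    tcol = df[cmap["time"]]
    if pd.api.types.is_numeric_dtype(tcol):
        t = tcol.to_numpy(dtype=float)
        t = t - math.floor(float(np.min(t)))
    else:
        ts = pd.to_datetime(tcol, errors="coerce")
        bad = np.flatnonzero(ts.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"unparseable timestamp at row index {int(df.index[bad[0]])} in {table_path}"
            )
        epoch = ts.min().normalize()
        t = ((ts - epoch) / pd.Timedelta(days=1)).to_numpy(dtype=float)

    order = np.argsort(t, kind="stable")
    t = t[order]
    x = df[cmap["x"]].to_numpy(dtype=float)[order]
    y = df[cmap["y"]].to_numpy(dtype=float)[order]
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        raise ValueError(
            f"duplicate timestamp t={t[dup[0]]!r} days for id {the_id!r} in {table_path}"
        )
    locs = [Location(float(ti), float(xi), float(yi)) for ti, xi, yi in zip(t, x, y)]
    return Track(id=the_id, locations=locs)


def steps_from_track(track: Track) -> list[Step]:
    """Decompose a track into n-1 steps (n locations).

    The first step has no turning angle; thereafter ``ta`` is the signed wrap
    of (current bearing - previous bearing) into (-pi, pi].
    """
    if len(track) < 2:
        raise ValueError(f"track {track.id!r}: need >= 2 locations to form steps, got {len(track)}")
    steps: list[Step] = []
    prev_bearing: Optional[float] = None
    for a, b in zip(track.locations, track.locations[1:]):
        dx, dy = b.x - a.x, b.y - a.y
        sl = math.hypot(dx, dy)
        bearing = math.atan2(dy, dx) if sl > 0 else (prev_bearing if prev_bearing is not None else 0.0)
        ta = None if prev_bearing is None else wrap_angle(bearing - prev_bearing)
        steps.append(Step(start=a, end=b, sl=sl, bearing=bearing, ta=ta))
        prev_bearing = bearing
    return steps


def _hour_of_day(t: np.ndarray) -> np.ndarray:
    return (t - np.floor(t)) * 24.0


def filter_track(
    track: Track,
    t_start: float = -math.inf,
    t_end: float = math.inf,
    diel: str = "all",
    day_hours: tuple[float, float] = (6.0, 18.0),
) -> Track:
    """Retain locations with t in [t_start, t_end), optionally one diel phase.

    ``diel="day"`` keeps hours inside [h0, h1); ``"night"`` keeps the
    complement. Day 0 starts at hour 0 of the track-local epoch. Idempotent;
    an empty result is a valid empty Track, not an error.
    """
    if t_start > t_end:
        raise ValueError(f"t_start ({t_start}) > t_end ({t_end})")
    if diel not in ("all", "day", "night"):
        raise ValueError(f"diel must be all|day|night, got {diel!r}")
    h0, h1 = day_hours
    kept = []
    for loc in track.locations:
        if not (t_start <= loc.t < t_end):
            continue
        if diel != "all":
            h = (loc.t - math.floor(loc.t)) * 24.0
            is_day = h0 <= h < h1
            if (diel == "day") != is_day:
                continue
        kept.append(loc)
    return Track(id=track.id, locations=kept, fix_interval=track.fix_interval)


def steps_to_frame(steps: Sequence[Step], track_id: str = "track") -> pd.DataFrame:
    """Flatten steps into the standard steps table."""
    return pd.DataFrame(
        {
            "id": track_id,
            "t_start": [s.start.t for s in steps],
            "t_end": [s.end.t for s in steps],
            "x1": [s.start.x for s in steps],
            "y1": [s.start.y for s in steps],
            "x2": [s.end.x for s in steps],
            "y2": [s.end.y for s in steps],
            "sl": [s.sl for s in steps],
            "ta": [s.ta if s.ta is not None else np.nan for s in steps],
            "bearing": [s.bearing for s in steps],
            "gap_days": [s.gap_days for s in steps],
        }
    )
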