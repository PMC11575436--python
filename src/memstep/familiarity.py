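"""Familiarity covariates: occurrence distributions, TSLV grids, migration predictors.

Spatial memory enters a step-selection model as an exponential familiarity
weight exp(beta_f * f(s)) multiplied into the habitat-selection function. The
covariates f(s) built here are the field's standard choices:

* **Occurrence distribution (OD)** — a normalized surface of the relative
  intensity of past space use over a stated time window (Gaussian kernel
  density of windowed fixes evaluated at cell centers). Windowing implements
  an abrupt memory-decay assumption: locations inside the window count
  equally, older ones are forgotten.
* **Contour indicator** — binary surface marking the smallest-density set of
  cells holding a stated fraction (e.g. 95%) of OD mass, for analyses that
  use previous-season range membership rather than intensity.
* **Diel-stratified short/long ODs** — long-term (all history) and short-term
  (last few days) ODs, optionally restricted to the day or night fixes
  matching the focal step's diel phase.
* **TSLV** — time since the animal last visited a grid cell, a cell-level
  revisitation clock ("visits" count anywhere within the cell, i.e. within
  perceptual vicinity). Never-visited cells report a default (365 days),
  i.e. they are treated as if last visited a year before the record begins.
* **Migration predictors** — minimum distance from a candidate endpoint to
  the previous season's migratory path, and the cosine of the angle between
  a candidate step and the direction to a remembered range centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trajectory import Location, Track, filter_track

__all__ = [
    "GridSpec",
    "RasterGrid",
    "TSLVState",
    "occurrence_distribution",
    "od_contour_indicator",
    "stratified_ods",
    "tslv_advance",
    "tslv_lookup",
    "burn_in_initialize",
    "min_distance_to_path",
    "directional_bias",
    "centroid",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: lower-left corner (x0, y0), square cells of ``res`` m.

    A point maps to cell column floor((x - x0)/res), row floor((y - y0)/res);
    cells are half-open [edge, edge + res). Values are stored row-major with
    row 0 at the bottom (southernmost) so array index [row, col] follows (y, x).
    """

    x0: float
    y0: float
    res: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.res <= 0:
            raise ValueError(f"res must be > 0, got {self.res}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid needs at least one row and column")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return (self.x0, self.x0 + self.n_cols * self.res, self.y0, self.y0 + self.n_rows * self.res)

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) < xmax) & (np.asarray(y) >= ymin) & (np.asarray(y) < ymax)

    def cell_of(self, x, y, check: bool = True):
        """Map coordinates to (row, col) arrays; errors on out-of-grid points if check."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.res).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.res).astype(int)
        if check:
            bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
            if np.any(bad):
                i = int(np.argmax(bad))
                bx = np.atleast_1d(np.asarray(x, dtype=float))[i if np.ndim(x) else 0]
                by = np.atleast_1d(np.asarray(y, dtype=float))[i if np.ndim(y) else 0]
                raise ValueError(f"point ({bx}, {by}) falls outside the grid extent {self.extent}")
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(cx, cy) arrays of shape (n_rows, n_cols)."""
        cx = self.x0 + (np.arange(self.n_cols) + 0.5) * self.res
        cy = self.y0 + (np.arange(self.n_rows) + 0.5) * self.res
        return np.meshgrid(cx, cy)


@dataclass
class RasterGrid:
    """A value per grid cell: habitat covariate, OD, or derived indicator."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} != grid ({self.spec.n_rows}, {self.spec.n_cols})"
            )

    def value_at(self, x, y, outside=np.nan):
        """Cell value(s) at coordinates; ``outside`` for out-of-grid points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.spec.contains(x, y)
        row, col = self.spec.cell_of(np.where(inside, x, self.spec.x0), np.where(inside, y, self.spec.y0), check=False)
        row = np.clip(row, 0, self.spec.n_rows - 1)
        col = np.clip(col, 0, self.spec.n_cols - 1)
        out = np.where(inside, self.values[row, col], outside)
        return out

    def is_od(self, tol: float = 1e-9) -> bool:
        return bool(np.all(self.values >= 0) and abs(self.values.sum() - 1.0) <= tol)


def occurrence_distribution(
    track: Track,
    window: tuple[float, float],
    spec: GridSpec,
    bandwidth: float,
) -> RasterGrid:
    """Occurrence distribution over a past window as a normalized KDE raster.

    Isotropic Gaussian kernel density of the locations with t in
    [window[0], window[1]), evaluated at cell centers and normalized to sum
    to 1 over the grid. An empty window is an error — "no information" is
    deliberately distinct from "zero intensity everywhere".
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    t_a, t_b = window
    pts = np.array([[p.x, p.y] for p in track.locations if t_a <= p.t < t_b], dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError(f"no locations in window [{t_a}, {t_b}); cannot form an OD")
    # evaluate only cells within 6 bandwidths of some fix (the Gaussian tail
    # beyond carries < 2e-8 relative mass); distant cells are exactly zero
    mask = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    reach = 6.0 * bandwidth
    for px, py in pts:
        c0 = max(0, int((px - reach - spec.x0) // spec.res))
        c1 = min(spec.n_cols - 1, int((px + reach - spec.x0) // spec.res))
        r0 = max(0, int((py - reach - spec.y0) // spec.res))
        r1 = min(spec.n_rows - 1, int((py + reach - spec.y0) // spec.res))
        if c1 >= 0 and r1 >= 0 and c0 < spec.n_cols and r0 < spec.n_rows:
            mask[r0 : r1 + 1, c0 : c1 + 1] = True
    cx, cy = spec.cell_centers()
    flat_idx = np.flatnonzero(mask.ravel())
    flat_x, flat_y = cx.ravel()[flat_idx], cy.ravel()[flat_idx]
    dens_local = np.zeros(flat_idx.size)
    inv = 1.0 / (2.0 * bandwidth * bandwidth)
    # chunk over points to bound memory at (n_masked_cells x chunk)
    for i in range(0, pts.shape[0], 256):
        chunk = pts[i : i + 256]
        d2 = (flat_x[:, None] - chunk[None, :, 0]) ** 2 + (flat_y[:, None] - chunk[None, :, 1]) ** 2
        dens_local += np.exp(-d2 * inv).sum(axis=1)
    total = dens_local.sum()
    if total <= 0:
        raise ValueError("all OD mass fell numerically outside the grid; widen the grid or bandwidth")
    dens = np.zeros(spec.n_rows * spec.n_cols)
    dens[flat_idx] = dens_local / total
    return RasterGrid(spec=spec, values=dens.reshape(spec.n_rows, spec.n_cols))


def od_contour_indicator(od: RasterGrid, level: float) -> RasterGrid:
    """Binary raster marking the highest-density cells holding >= ``level`` OD mass.

    Cells are accumulated in descending density order (ties broken by
    row-major cell index, so the output is deterministic) until the
    cumulative mass first reaches ``level``. ``level=1`` marks exactly the
    cells with positive density.
    """
    if not (0 < level <= 1):
        raise ValueError(f"level must be in (0, 1], got {level}")
    if not od.is_od():
        raise ValueError("input raster is not a normalized OD (nonnegative, sum 1)")
    v = od.values.ravel()
    pos = np.flatnonzero(v > 0)
    # stable sort on -density keeps row-major order among ties
    order = pos[np.argsort(-v[pos], kind="stable")]
    csum = np.cumsum(v[order])
    k = int(np.searchsorted(csum, level, side="left"))
    k = min(k, order.size - 1)
    out = np.zeros(v.size)
    out[order[: k + 1]] = 1.0
    return RasterGrid(spec=od.spec, values=out.reshape(od.values.shape))


def stratified_ods(
    track: Track,
    t_now: float,
    spec: GridSpec,
    bandwidth: float,
    short_window: float = 3.0,
    day_hours: tuple[float, float] = (6.0, 18.0),
) -> dict[str, Optional[RasterGrid]]:
    """Long/short-term and diel-matched ODs from the history before ``t_now``.

    Returns a dict with keys ``long_all``, ``short_all``, ``long_diel``,
    ``short_diel``. Long windows span [t_first, t_now), short windows
    [t_now - short_window, t_now). The ``*_diel`` surfaces are built only
    from past fixes in the same diel phase (day/night per ``day_hours``) as
    ``t_now`` — a daytime step is paired with daytime history. A stratum with
    no history is flagged unavailable as ``None`` rather than an error.
    """
    if not track.locations:
        return {k: None for k in ("long_all", "short_all", "long_diel", "short_diel")}
    t_first = track.locations[0].t
    h = (t_now - math.floor(t_now)) * 24.0
    phase = "day" if day_hours[0] <= h < day_hours[1] else "night"

    windows = {
        "long_all": ((t_first, t_now), "all"),
        "short_all": ((t_now - short_window, t_now), "all"),
        "long_diel": ((t_first, t_now), phase),
        "short_diel": ((t_now - short_window, t_now), phase),
    }
    out: dict[str, Optional[RasterGrid]] = {}
    for key, ((a, b), diel) in windows.items():
        sub = filter_track(track, a, b, diel=diel, day_hours=day_hours)
        if not sub.locations:
            out[key] = None
            continue
        out[key] = occurrence_distribution(sub, (a, b), spec, bandwidth)
    return out


@dataclass
class TSLVState:
    """Per-cell timestamp of the most recent visit plus the current clock.

    ``last_visit`` holds NaN where a cell has never been visited; such cells
    report ``default_tslv`` (365 days by default) at lookup, treating them as
    if last visited a year before the record starts.
    """

    spec: GridSpec
    last_visit: np.ndarray = None  # type: ignore[assignment]
    clock: float = 0.0
    default_tslv: float = 365.0

    def __post_init__(self):
        if self.last_visit is None:
            self.last_visit = np.full((self.spec.n_rows, self.spec.n_cols), np.nan)
        self.last_visit = np.asarray(self.last_visit, dtype=float)
        if self.default_tslv <= 0:
            raise ValueError(f"default_tslv must be > 0, got {self.default_tslv}")

    def copy(self) -> "TSLVState":
        return TSLVState(
            spec=self.spec,
            last_visit=self.last_visit.copy(),
            clock=self.clock,
            default_tslv=self.default_tslv,
        )


def tslv_advance(state: TSLVState, loc: Location) -> TSLVState:
    """Register a visit: set the clock to loc.t and stamp loc's cell (in place).

    The state is mutated and returned (copy() first if the old state is
    needed). Time must not run backwards; the location must be on the grid.
    """
    if loc.t < state.clock:
        raise ValueError(f"time regression: visit at t={loc.t} before clock {state.clock}")
    row, col = state.spec.cell_of(loc.x, loc.y)
    state.last_visit[int(row), int(col)] = loc.t
    state.clock = loc.t
    return state


def tslv_lookup(state: TSLVState, points, t_query: float) -> np.ndarray:
    """TSLV in days at each point: t_query - last visit, or default if never visited.

    Read-only; values are floored at 0 (a cell visited at t_query has TSLV 0).
    ``points`` is a sequence of Locations or an (n, 2) array of coordinates.
    """
    if isinstance(points, np.ndarray):
        xy = np.asarray(points, dtype=float).reshape(-1, 2)
    else:
        xy = np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
    row, col = state.spec.cell_of(xy[:, 0], xy[:, 1])
    last = state.last_visit[row, col]
    tslv = np.where(np.isnan(last), state.default_tslv, np.maximum(t_query - last, 0.0))
    return tslv


def burn_in_initialize(
    track: Track,
    burn_in: float,
    spec: GridSpec,
    default_tslv: float = 365.0,
) -> tuple[TSLVState, Track]:
    """Build a TSLV state from an initial burn-in period; return (state, remainder).

    The first ``burn_in`` days of the track populate the visit map and are
    sacrificed from model fitting, since the animal's history before the
    record is unknown. Cells untouched during burn-in keep never-visited
    (default) semantics.
    """
    if len(track) == 0:
        raise ValueError("cannot initialize from an empty track")
    t0 = track.locations[0].t
    if burn_in >= track.duration and burn_in > 0:
        raise ValueError(f"burn_in ({burn_in} d) >= track duration ({track.duration} d)")
    cut = t0 + burn_in
    state = TSLVState(spec=spec, clock=t0, default_tslv=default_tslv)
    kept = []
    for loc in track.locations:
        if loc.t < cut:
            tslv_advance(state, loc)
        else:
            kept.append(loc)
    return state, Track(id=track.id, locations=kept, fix_interval=track.fix_interval)


def min_distance_to_path(points, path) -> np.ndarray:
    """Minimum Euclidean distance from each point to a polyline, in meters.

    ``points``: (n, 2) array or sequence of Locations. ``path``: (m, 2) array
    or sequence of Locations (the previous season's migratory fixes in
    order). With a single vertex the point-to-vertex distance is returned.
    """
    P = _as_xy(points)
    V = _as_xy(path)
    if V.shape[0] == 0:
        raise ValueError("path must have at least one vertex")
    if V.shape[0] == 1:
        return np.hypot(P[:, 0] - V[0, 0], P[:, 1] - V[0, 1])
    A = V[:-1]  # (m-1, 2) segment starts
    D = V[1:] - A  # segment vectors
    L2 = (D * D).sum(axis=1)  # (m-1,)
    # project each point on each segment, clamped to [0, 1]
    W = P[:, None, :] - A[None, :, :]  # (n, m-1, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        tproj = np.clip(np.where(L2 > 0, (W * D[None, :, :]).sum(axis=2) / L2, 0.0), 0.0, 1.0)
    closest = A[None, :, :] + tproj[:, :, None] * D[None, :, :]
    d = np.hypot(P[:, None, 0] - closest[:, :, 0], P[:, None, 1] - closest[:, :, 1])
    return d.min(axis=1)


def _as_xy(obj) -> np.ndarray:
    if isinstance(obj, Track):
        return obj.xy
    if isinstance(obj, np.ndarray):
        return np.asarray(obj, dtype=float).reshape(-1, 2)
    arr = []
    for p in obj:
        if isinstance(p, Location):
            arr.append([p.x, p.y])
        else:
            arr.append([p[0], p[1]])
    return np.array(arr, dtype=float).reshape(-1, 2)


def centroid(locations) -> tuple[float, float]:
    """Arithmetic-mean centroid of a set of locations (a remembered range)."""
    xy = _as_xy(locations)
    if xy.shape[0] == 0:
        raise ValueError("cannot take the centroid of no locations")
    return float(xy[:, 0].mean()), float(xy[:, 1].mean())


def directional_bias(step_start, candidate_end, target_centroid):
    """Cosine of the angle between a step and the direction to a remembered target.

    +1 for a step straight toward the target centroid, -1 straight away,
    0 perpendicular. Depends only on the step's direction, not its length.
    ``candidate_end`` may be a single point or an (n, 2) array of candidate
    endpoints (vectorized); the start and centroid are single points.
    """
    s = _as_xy([step_start])[0]
    c = _as_xy([target_centroid])[0]
    single = _is_single_point(candidate_end)
    E = _as_xy([candidate_end] if single else candidate_end)
    v_t = c - s
    nt = math.hypot(v_t[0], v_t[1])
    if nt == 0:
        raise ValueError("target centroid coincides with the step start: direction undefined")
    v_s = E - s[None, :]
    ns = np.hypot(v_s[:, 0], v_s[:, 1])
    if np.any(ns == 0):
        raise ValueError("zero-length step: direction undefined")
    out = np.clip((v_s @ v_t) / (ns * nt), -1.0, 1.0)
    return float(out[0]) if single else out


def _is_single_point(obj) -> bool:
    if isinstance(obj, Location):
        return True
    if isinstance(obj, np.ndarray):
        return obj.ndim == 1
    if isinstance(obj, (tuple, list)) and len(obj) == 2 and np.isscalar(obj[0]):
        return True
    return False
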