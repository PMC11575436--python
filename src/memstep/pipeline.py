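"""Strata assembly: track -> used/available candidates -> replayed covariates.

To fit a memory-informed step-selection model, each observed step becomes a
stratum: the used endpoint plus matched available endpoints drawn from the
tentative movement kernel at the same start and time. Memory covariates
(updating ODs, TSLV) depend on the movement history, so they are *replayed*
along the track by stateful providers: at each step the provider is queried
for covariates at the candidate endpoints given history strictly before the
step's end, then advanced with the step actually taken. The replay uses the
same primitives and conventions as the forward simulator, so covariates
computed here agree exactly with the simulator's internal diagnostics.

Candidates that fall outside the supplied domain are dropped from the
stratum (the simulator gives them zero weight, so the truncated choice set
is the matching likelihood).
"""

from __future__ import annotations

import math
from typing import Optional, Protocol, Sequence

import numpy as np

from .familiarity import (
    GridSpec,
    RasterGrid,
    TSLVState,
    directional_bias,
    min_distance_to_path,
    stratified_ods,
    tslv_advance,
    tslv_lookup,
)
from .movement_kernel import KernelParams, sample_candidates
from .simulator import od_from_history
from .ssf_fit import Stratum
from .trajectory import Location, Track, steps_from_track

__all__ = [
    "CovariateProvider",
    "HabitatProvider",
    "StaticRasterProvider",
    "TSLVProvider",
    "ODWindowProvider",
    "StratifiedODProvider",
    "MigrationProvider",
    "build_strata",
]


class CovariateProvider(Protocol):
    """Stateful covariate source replayed along a track."""

    def covariates(
        self, t_end: float, start_xy: tuple[float, float], ends_xy: np.ndarray
    ) -> Optional[dict[str, np.ndarray]]:
        """Covariates at candidate endpoints, or None if unavailable (skip stratum)."""
        ...

    def advance(self, loc: Location) -> None:
        """Register the fix actually taken."""
        ...


class HabitatProvider:
    """Static environmental raster values at candidate endpoints."""

    def __init__(self, rasters: dict[str, RasterGrid]):
        self.rasters = rasters

    def covariates(self, t_end, start_xy, ends_xy):
        return {
            name: r.value_at(ends_xy[:, 0], ends_xy[:, 1], outside=np.nan)
            for name, r in self.rasters.items()
        }

    def advance(self, loc):
        pass


class StaticRasterProvider(HabitatProvider):
    """A fixed familiarity surface, e.g. a previous-season OD contour indicator."""

    def __init__(self, name: str, raster: RasterGrid):
        super().__init__({name: raster})


class TSLVProvider:
    """Time-since-last-visit replay on a grid-cell visit map.

    The state is advanced with every fix; at query time the TSLV of each
    candidate cell is the stratum end time minus the cell's last visit
    (``default_tslv`` where never visited). Emits the ``tslv`` column; the
    quadratic column comes from a quadratic Term at design time.
    """

    def __init__(self, spec: GridSpec, default_tslv: float = 365.0, state: Optional[TSLVState] = None):
        self.state = state if state is not None else TSLVState(spec=spec, default_tslv=default_tslv)
        self._started = state is not None

    def covariates(self, t_end, start_xy, ends_xy):
        if not self._started:
            return None
        return {"tslv": tslv_lookup(self.state, ends_xy, t_end)}

    def advance(self, loc):
        if not self._started:
            self.state.clock = loc.t
            self._started = True
        tslv_advance(self.state, loc)


class ODWindowProvider:
    """Updating occurrence-distribution covariate (density form).

    Maintains the history buffer and recomputes the OD every ``stride``
    advances over the window [t_now - window, t_now] (all history if window
    is None), mirroring the simulator's update cadence exactly.
    """

    def __init__(
        self,
        spec: GridSpec,
        bandwidth: float,
        window: Optional[float] = None,
        stride: int = 1,
        name: str = "od",
    ):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.spec, self.bandwidth, self.window, self.stride = spec, bandwidth, window, stride
        self.name = name
        self.history: list[Location] = []
        self.od: Optional[RasterGrid] = None
        self._count = -1  # first advance is the track's first fix (count 0)

    def covariates(self, t_end, start_xy, ends_xy):
        if self.od is None:
            return None
        return {self.name: self.od.value_at(ends_xy[:, 0], ends_xy[:, 1], outside=0.0)}

    def advance(self, loc):
        self.history.append(loc)
        self._count += 1
        if self._count % self.stride == 0:
            self.od = od_from_history(self.history, loc.t, self.spec, self.bandwidth, self.window)


class StratifiedODProvider:
    """Long/short-term and diel-matched OD covariates (the four-surface form).

    Emits ``od_long``, ``od_short``, ``od_long_diel``, ``od_short_diel``
    densities at candidate endpoints; the diel surfaces use only past fixes
    in the same day/night phase as the stratum time. Strata whose requested
    surfaces are unavailable (no matching history yet) are skipped. ODs are
    recomputed every ``stride`` strata and reused in between.
    """

    KEYS = {"od_long": "long_all", "od_short": "short_all", "od_long_diel": "long_diel", "od_short_diel": "short_diel"}

    def __init__(
        self,
        spec: GridSpec,
        bandwidth: float,
        short_window: float = 3.0,
        day_hours: tuple[float, float] = (6.0, 18.0),
        which: Sequence[str] = ("od_long", "od_short", "od_long_diel", "od_short_diel"),
        stride: int = 1,
    ):
        unknown = [w for w in which if w not in self.KEYS]
        if unknown:
            raise ValueError(f"unknown OD surfaces {unknown}")
        self.spec, self.bandwidth = spec, bandwidth
        self.short_window, self.day_hours = short_window, day_hours
        self.which = tuple(which)
        self.stride = stride
        self.history: list[Location] = []
        self._cache: Optional[dict[str, Optional[RasterGrid]]] = None
        self._calls = 0

    def covariates(self, t_end, start_xy, ends_xy):
        if not self.history:
            return None
        if self._cache is None or self._calls % self.stride == 0:
            trk = Track(id="odbuf", locations=list(self.history))
            self._cache = stratified_ods(
                trk, t_end, self.spec, self.bandwidth, self.short_window, self.day_hours
            )
        self._calls += 1
        out = {}
        for name in self.which:
            od = self._cache[self.KEYS[name]]
            if od is None:
                return None
            out[name] = od.value_at(ends_xy[:, 0], ends_xy[:, 1], outside=0.0)
        return out

    def advance(self, loc):
        self.history.append(loc)


class MigrationProvider:
    """Previous-path distance and/or centroid directional-bias covariates."""

    def __init__(self, previous_path=None, target_centroid=None):
        if previous_path is None and target_centroid is None:
            raise ValueError("need a previous path and/or a target centroid")
        self.path = None if previous_path is None else np.asarray(previous_path, dtype=float).reshape(-1, 2)
        self.centroid = target_centroid

    def covariates(self, t_end, start_xy, ends_xy):
        out = {}
        if self.path is not None:
            out["dist_path"] = min_distance_to_path(ends_xy, self.path)
        if self.centroid is not None:
            out["dir_bias"] = directional_bias(start_xy, ends_xy, self.centroid)
        return out

    def advance(self, loc):
        pass


def build_strata(
    track: Track,
    kernel: KernelParams,
    providers: Sequence[CovariateProvider],
    n_avail: int = 20,
    seed: int = 0,
    include_movement: bool = True,
    domain: Optional[GridSpec] = None,
    t_min: float = -math.inf,
) -> list[Stratum]:
    """Decompose a track into fitted strata with replayed covariates.

    For each step with a defined turning angle (and end time >= ``t_min``,
    the post-burn-in window), ``n_avail`` available steps are drawn from the
    tentative kernel at the same start and previous bearing; the used
    candidate is row 0. Providers are advanced through *every* fix in order,
    including burned-in and skipped ones, so memory replay stays faithful.
    Movement-adjustment columns log_sl, sl, cos_ta are appended unless
    ``include_movement`` is False. Candidates outside ``domain`` are dropped.
    """
    steps = steps_from_track(track)
    rng = np.random.default_rng(seed)
    for p in providers:
        p.advance(track.locations[0])
    strata: list[Stratum] = []
    prev_bearing = steps[0].bearing
    for i, step in enumerate(steps):
        if i == 0:
            for p in providers:
                p.advance(step.end)
            continue
        eligible = step.end.t >= t_min
        if eligible:
            avail = sample_candidates(
                (step.start.x, step.start.y), prev_bearing, kernel, n_avail, rng
            )
            ends = np.vstack(
                [
                    [step.end.x, step.end.y],
                    np.column_stack([avail.x, avail.y]),
                ]
            )
            sl = np.concatenate([[step.sl], avail.sl])
            ta = np.concatenate([[step.ta], avail.ta])
            keep = np.ones(len(sl), dtype=bool)
            if domain is not None:
                keep = domain.contains(ends[:, 0], ends[:, 1])
                if not keep[0]:
                    raise ValueError(
                        f"used endpoint at t={step.end.t} lies outside the domain {domain.extent}"
                    )
            ends, sl, ta = ends[keep], sl[keep], ta[keep]
            covs: Optional[dict[str, np.ndarray]] = {}
            for p in providers:
                got = p.covariates(step.end.t, (step.start.x, step.start.y), ends)
                if got is None:
                    covs = None
                    break
                covs.update(got)
            if covs is not None and len(sl) >= 2:
                if include_movement:
                    sl_pos = sl.copy()
                    if np.any(sl_pos == 0):
                        sl_pos[sl_pos == 0] = 0.5 * sl_pos[sl_pos > 0].min()
                    covs["log_sl"] = np.log(sl_pos)
                    covs["sl"] = sl
                    covs["cos_ta"] = np.cos(ta)
                strata.append(
                    Stratum(stratum_id=i, t=step.end.t, covariates=covs, used_index=0)
                )
        for p in providers:
            p.advance(step.end)
        prev_bearing = step.bearing
    return strata
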