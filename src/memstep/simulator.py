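"""Forward simulation of memory-informed movement.

Each step the walker draws M candidate endpoints from the selection-free
kernel (an importance sample of the movement kernel, so the kernel factor is
embodied in the proposal), weights them by

    exp( beta_w' r(s) + beta_f' f(s) ),

normalizes, and samples the next location. The memory state — an updating
occurrence-distribution window buffer, a time-since-last-visit grid, or a
remembered migratory path/centroid — is advanced online after every chosen
step, exactly as the fitting-side covariate replay does, so simulate -> fit
parameter recovery closes the loop.

Candidates falling outside the raster domain get zero weight (truncation;
reflecting boundaries would distort the turning-angle distribution). If every
candidate lands outside, the step is redrawn once before erroring.

No forward-simulation protocol is standard in the memory-SSA literature
(models are usually only fitted); the conventions here — kernel-importance
candidates, per-step OD refresh with a configurable stride, truncation at the
boundary — are this package's own, documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .familiarity import (
    GridSpec,
    RasterGrid,
    TSLVState,
    directional_bias,
    min_distance_to_path,
    occurrence_distribution,
    tslv_advance,
    tslv_lookup,
)
from .movement_kernel import AvailableSteps, KernelParams, sample_candidates
from .trajectory import Location, Track

__all__ = [
    "SimConfig",
    "SimState",
    "MigrationSetup",
    "step_probabilities",
    "simulate",
    "simulate_migration",
    "od_from_history",
]

MEMORY_MODES = ("none", "od_window", "tslv", "migration")
FAMILIARITY_NAMES = ("od", "od_indicator", "tslv", "tslv_sq", "dist_path", "dir_bias")


@dataclass
class SimConfig:
    """Generating model and bookkeeping for a forward simulation.

    beta_w maps landscape raster names to habitat coefficients; beta_f maps
    familiarity covariate names (od, od_indicator, tslv, tslv_sq, dist_path,
    dir_bias) to memory coefficients consistent with ``memory_mode``.
    ``window`` (days) bounds the OD buffer (None = all history);``stride``
    recomputes the OD every that many steps; ``n_candidates`` is the size M
    of the discretized choice set approximating the continuous normalizer.
    """

    kernel: KernelParams
    n_steps: int
    memory_mode: str = "none"
    beta_w: dict[str, float] = dc_field(default_factory=dict)
    beta_f: dict[str, float] = dc_field(default_factory=dict)
    window: Optional[float] = None
    stride: int = 1
    bandwidth: Optional[float] = None
    gridspec: Optional[GridSpec] = None
    default_tslv: float = 365.0
    n_candidates: int = 200
    fix_interval: float = 1.0
    start_xy: tuple[float, float] = (0.0, 0.0)
    start_bearing: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.memory_mode not in MEMORY_MODES:
            raise ValueError(f"memory_mode must be one of {MEMORY_MODES}, got {self.memory_mode!r}")
        if self.n_candidates < 10:
            raise ValueError(f"n_candidates must be >= 10, got {self.n_candidates}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        bad = [k for k in self.beta_f if k not in FAMILIARITY_NAMES]
        if bad:
            raise ValueError(f"unknown familiarity coefficients {bad}; allowed: {FAMILIARITY_NAMES}")
        need_grid = {"od": ("od_window",), "tslv": ("tslv",), "tslv_sq": ("tslv",)}
        for name, modes in need_grid.items():
            if name in self.beta_f and self.memory_mode not in modes:
                raise ValueError(f"coefficient {name!r} requires memory_mode in {modes}")
        for name in ("dist_path", "dir_bias"):
            if name in self.beta_f and self.memory_mode != "migration":
                raise ValueError(f"coefficient {name!r} requires memory_mode='migration'")
        if self.memory_mode in ("od_window", "tslv") and self.gridspec is None:
            raise ValueError(f"memory_mode {self.memory_mode!r} requires a gridspec")
        if self.memory_mode == "od_window" and not self.bandwidth:
            raise ValueError("memory_mode 'od_window' requires a bandwidth")


@dataclass
class MigrationSetup:
    """Two-range migration context: where the walker starts and what it remembers."""

    start_xy: tuple[float, float]
    target_centroid: tuple[float, float]


@dataclass
class SimState:
    """Mutable walker state threaded through the simulation."""

    t: float
    x: float
    y: float
    bearing: float
    history: list[Location] = dc_field(default_factory=list)
    od: Optional[RasterGrid] = None
    tslv: Optional[TSLVState] = None
    previous_path: Optional[np.ndarray] = None
    target_centroid: Optional[tuple[float, float]] = None


def _candidate_covariates(
    state: SimState,
    landscape: dict[str, RasterGrid],
    config: SimConfig,
    cands: AvailableSteps,
    familiarity_rasters: Optional[dict[str, RasterGrid]] = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Covariate arrays over candidates plus the inside-domain mask."""
    fam = familiarity_rasters or {}
    x, y = cands.x, cands.y
    inside = np.ones(x.size, dtype=bool)
    for name in config.beta_w:
        if name not in landscape:
            raise ValueError(f"beta_w names raster {name!r} not present in the landscape")
        inside &= landscape[name].spec.contains(x, y)
    if config.memory_mode in ("od_window", "tslv"):
        inside &= config.gridspec.contains(x, y)
    for name in ("od", "od_indicator"):
        if name in config.beta_f and name in fam:
            inside &= fam[name].spec.contains(x, y)

    cov: dict[str, np.ndarray] = {}
    for name in config.beta_w:
        cov[name] = landscape[name].value_at(x, y, outside=0.0)
    t_end = state.t + config.fix_interval
    if "od" in config.beta_f:
        src = state.od if config.memory_mode == "od_window" else fam.get("od")
        if src is None:
            raise ValueError("no OD available for the 'od' coefficient")
        cov["od"] = src.value_at(x, y, outside=0.0)
    if "od_indicator" in config.beta_f:
        if "od_indicator" not in fam:
            raise ValueError("'od_indicator' coefficient requires a static indicator raster")
        cov["od_indicator"] = fam["od_indicator"].value_at(x, y, outside=0.0)
    if "tslv" in config.beta_f or "tslv_sq" in config.beta_f:
        pts = np.column_stack([np.where(inside, x, config.gridspec.x0), np.where(inside, y, config.gridspec.y0)])
        tslv = tslv_lookup(state.tslv, pts, t_end)
        cov["tslv"] = np.where(inside, tslv, 0.0)
        if "tslv_sq" in config.beta_f:
            cov["tslv_sq"] = cov["tslv"] ** 2
    if "dist_path" in config.beta_f:
        cov["dist_path"] = min_distance_to_path(np.column_stack([x, y]), state.previous_path)
    if "dir_bias" in config.beta_f:
        cov["dir_bias"] = directional_bias((state.x, state.y), np.column_stack([x, y]), state.target_centroid)
    return cov, inside


def step_probabilities(
    state: SimState,
    landscape: dict[str, RasterGrid],
    config: SimConfig,
    candidates: AvailableSteps,
    familiarity_rasters: Optional[dict[str, RasterGrid]] = None,
) -> np.ndarray:
    """Choice probabilities over kernel-sampled candidates, summing to 1.

    For kernel-sampled candidates the movement-kernel factor is embodied in
    the proposal, so probabilities are proportional to the exponential of the
    habitat + familiarity linear predictor alone, with zero weight outside
    the raster domain.
    """
    probs, _ = _probs_and_covariates(state, landscape, config, candidates, familiarity_rasters)
    return probs


def _probs_and_covariates(
    state: SimState,
    landscape: dict[str, RasterGrid],
    config: SimConfig,
    candidates: AvailableSteps,
    familiarity_rasters: Optional[dict[str, RasterGrid]] = None,
):
    cov, inside = _candidate_covariates(state, landscape, config, candidates, familiarity_rasters)
    eta = np.zeros(candidates.x.size)
    for name, b in config.beta_w.items():
        eta += b * cov[name]
    for name, b in config.beta_f.items():
        eta += b * cov[name]
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite selection weights")
    eta = np.where(inside, eta, -np.inf)
    if not np.any(inside):
        raise ValueError("all candidates fall outside the domain")
    eta -= eta[inside].max()
    w = np.exp(eta)
    total = w.sum()
    if not (np.isfinite(total) and total > 0):
        raise ValueError("all selection weights are zero or non-finite")
    return w / total, cov


def od_from_history(
    history: Sequence[Location],
    t_now: float,
    spec: GridSpec,
    bandwidth: float,
    window: Optional[float],
    fix_interval: float = 1.0,
) -> RasterGrid:
    """OD from all fixes at t in [t_now - window, t_now] (all history if window None).

    Shared by the simulator and the fitting-side covariate replay so that the
    two see bit-identical memory surfaces.
    """
    t_a = history[0].t if window is None else t_now - window
    buf = Track(id="odbuf", locations=[p for p in history if t_a <= p.t], fix_interval=fix_interval)
    # +eps closes the half-open window at t_now: the fix just taken is remembered
    return occurrence_distribution(buf, (t_a, t_now + 1e-9), spec, bandwidth)


def _refresh_od(state: SimState, config: SimConfig) -> None:
    state.od = od_from_history(
        state.history, state.t, config.gridspec, config.bandwidth, config.window, config.fix_interval
    )


def _init_state(
    config: SimConfig,
    rng: np.random.Generator,
    previous_path=None,
    target_centroid=None,
) -> SimState:
    x0, y0 = config.start_xy
    bearing = rng.uniform(-math.pi, math.pi) if config.start_bearing is None else config.start_bearing
    start = Location(0.0, float(x0), float(y0))
    state = SimState(t=0.0, x=float(x0), y=float(y0), bearing=float(bearing), history=[start])
    if config.memory_mode == "tslv":
        state.tslv = TSLVState(spec=config.gridspec, clock=0.0, default_tslv=config.default_tslv)
        tslv_advance(state.tslv, start)
    elif config.memory_mode == "od_window":
        _refresh_od(state, config)
    elif config.memory_mode == "migration":
        if previous_path is None:
            raise ValueError("memory_mode 'migration' requires a previous path")
        state.previous_path = np.asarray(previous_path, dtype=float).reshape(-1, 2)
        state.target_centroid = target_centroid
        if "dir_bias" in config.beta_f and target_centroid is None:
            raise ValueError("'dir_bias' coefficient requires a target centroid")
    return state


def simulate(
    landscape: Optional[dict[str, RasterGrid]],
    config: SimConfig,
    familiarity_rasters: Optional[dict[str, RasterGrid]] = None,
    previous_path=None,
    target_centroid=None,
) -> tuple[Track, pd.DataFrame]:
    """Run the walk; return the realized Track and per-step memory diagnostics.

    Diagnostics carry, per step, the chosen candidate's covariate values at
    decision time (e.g. the TSLV of the chosen cell *before* the visit resets
    it), which an offline replay over the realized track must reproduce
    exactly. Fully reproducible from ``config.seed``.
    """
    landscape = landscape or {}
    rng = np.random.default_rng(config.seed)
    state = _init_state(config, rng, previous_path, target_centroid)
    records = []
    locs = [state.history[0]]
    for i in range(config.n_steps):
        cands = sample_candidates((state.x, state.y), state.bearing, config.kernel, config.n_candidates, rng)
        try:
            probs, cov = _probs_and_covariates(state, landscape, config, cands, familiarity_rasters)
        except ValueError:
            # one redraw with a fresh stream offset before giving up
            cands = sample_candidates((state.x, state.y), state.bearing, config.kernel, config.n_candidates, rng)
            probs, cov = _probs_and_covariates(state, landscape, config, cands, familiarity_rasters)
        j = int(rng.choice(config.n_candidates, p=probs))
        t_new = state.t + config.fix_interval
        chosen = Location(t_new, float(cands.x[j]), float(cands.y[j]))
        rec = {
            "step": i + 1,
            "t": t_new,
            "x": chosen.x,
            "y": chosen.y,
            "sl": float(cands.sl[j]),
            "ta": float(cands.ta[j]),
            "bearing": float(cands.bearing[j]),
        }
        for name, v in cov.items():
            rec[name] = float(v[j])
        records.append(rec)

        state.t, state.x, state.y, state.bearing = t_new, chosen.x, chosen.y, float(cands.bearing[j])
        state.history.append(chosen)
        if config.memory_mode == "tslv":
            tslv_advance(state.tslv, chosen)
        elif config.memory_mode == "od_window":
            if (i + 1) % config.stride == 0:
                _refresh_od(state, config)
        locs.append(chosen)
    track = Track(id=f"sim-seed{config.seed}", locations=locs, fix_interval=config.fix_interval)
    return track, pd.DataFrame(records)


def simulate_migration(
    setup: MigrationSetup,
    previous_path,
    config: SimConfig,
    landscape: Optional[dict[str, RasterGrid]] = None,
) -> tuple[Track, pd.DataFrame]:
    """Simulate a migrant biased toward a remembered path and/or range centroid.

    A negative ``dist_path`` coefficient pulls the walker onto the previous
    season's route; a positive ``dir_bias`` coefficient biases headings
    toward the remembered range centroid. Records both covariates per step.
    """
    if config.memory_mode != "migration":
        raise ValueError("simulate_migration requires memory_mode='migration'")
    if not any(k in config.beta_f for k in ("dist_path", "dir_bias")):
        raise ValueError("enable at least one of dist_path / dir_bias")
    cfg = config
    if tuple(config.start_xy) != tuple(setup.start_xy):
        from dataclasses import replace

        cfg = replace(config, start_xy=tuple(setup.start_xy))
    return simulate(
        landscape,
        cfg,
        previous_path=previous_path,
        target_centroid=setup.target_centroid,
    )
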