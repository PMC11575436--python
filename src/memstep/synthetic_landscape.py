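"""Seeded synthetic landscapes and case-study-like scenarios.

Real memory-SSA applications run on proprietary telemetry; every pipeline
stage here is instead exercised on generated fixtures with known parameters.
Four scenario archetypes emulate the data *structures* of the canonical case
studies (not their geography or numbers):

* ``crane_like``  — multi-season single-range mover whose familiarity
  covariate is the binary 95% contour of the previous season's OD.
* ``hog_like``    — short-fix forager attracted to its own last-3-days
  occurrence distribution, with a day/night diel structure.
* ``deer_like``   — two-range migrant biased toward the previous year's
  migration path and winter-range centroid.
* ``bear_like``   — multi-year revisitor selecting on time-since-last-visit
  (linear + quadratic, interior optimum) over 2x2 km cells with a 365-day
  default for never-visited cells.

Scale choices (grids <= ~100x100 cells, tracks <= a few thousand steps) keep
the full simulate -> fit recovery suite desk-sized on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .familiarity import GridSpec, RasterGrid, occurrence_distribution, od_contour_indicator
from .movement_kernel import KernelParams
from .simulator import SimConfig, simulate

__all__ = [
    "Scenario",
    "gaussian_random_field",
    "make_scenario",
    "SCENARIO_NAMES",
    "simulate_scenario",
    "scenario_providers",
    "scenario_terms",
    "scenario_true_beta",
    "recover_scenario",
]

SCENARIO_NAMES = ("crane_like", "hog_like", "deer_like", "bear_like")


@dataclass
class Scenario:
    """A regenerable fixture: landscape(s), generating parameters, and context.

    ``extras`` carries scenario-specific objects: a previous-season track or
    path, a target centroid, static familiarity rasters, diel hours.
    Bit-exactly regenerable from (name, seed).
    """

    name: str
    description: str
    seed: int
    landscape: dict[str, RasterGrid]
    config: SimConfig
    extras: dict = field(default_factory=dict)


def gaussian_random_field(
    spec: GridSpec, correlation_range: float, sill: float, seed: int
) -> RasterGrid:
    """Stationary Gaussian random field on the grid (mean 0, variance ~ sill).

    Synthesized by convolving seeded white noise with a Gaussian filter of
    s.d. ``correlation_range`` (in meters) under periodic boundaries, then
    rescaling to the target variance. ``sill = 0`` returns the constant zero
    field; a negative sill or non-positive range is an error.
    """
    if correlation_range <= 0:
        raise ValueError(f"correlation_range must be > 0, got {correlation_range}")
    if sill < 0:
        raise ValueError(f"sill must be >= 0, got {sill}")
    if sill == 0:
        return RasterGrid(spec=spec, values=np.zeros((spec.n_rows, spec.n_cols)))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((spec.n_rows, spec.n_cols))
    sigma_cells = correlation_range / spec.res
    smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd == 0:
        raise ValueError("degenerate field: increase the grid size or decrease the range")
    return RasterGrid(spec=spec, values=smooth * (math.sqrt(sill) / sd))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _wiggly_path(a: tuple[float, float], b: tuple[float, float], n: int, amp: float, seed: int) -> np.ndarray:
    """Previous-season migration route: straight line plus smooth lateral wiggle."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n)
    base = np.outer(1 - t, a) + np.outer(t, b)
    direction = np.array(b) - np.array(a)
    normal = np.array([-direction[1], direction[0]]) / np.hypot(*direction)
    phase = rng.uniform(0, 2 * math.pi)
    lateral = amp * np.sin(2 * math.pi * 2.0 * t + phase) * np.sin(math.pi * t)
    return base + np.outer(lateral, normal)


def make_scenario(name: str, seed: int) -> Scenario:
    """Build one of the named scenarios with known true parameters."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    builder = {
        "crane_like": _crane_like,
        "hog_like": _hog_like,
        "deer_like": _deer_like,
        "bear_like": _bear_like,
    }[name]
    return builder(seed)


def _bear_like(seed: int) -> Scenario:
    """Multi-year revisitor: TSLV linear+quadratic selection, vertex at 180 days."""
    s_land, s_sim = _child_seeds(seed, 2)
    spec = GridSpec(x0=0.0, y0=0.0, res=2000.0, n_rows=60, n_cols=60)
    habitat = gaussian_random_field(spec, correlation_range=6000.0, sill=1.0, seed=s_land)
    vertex = 180.0
    b_quad = -5e-5
    config = SimConfig(
        kernel=KernelParams(gamma_shape=2.0, gamma_scale=600.0, vm_kappa=0.5),
        n_steps=3000,
        memory_mode="tslv",
        beta_w={"habitat": 0.3},
        beta_f={"tslv": -2.0 * b_quad * vertex, "tslv_sq": b_quad},
        gridspec=spec,
        default_tslv=365.0,
        n_candidates=200,
        fix_interval=1.0 / 6.0,  # 4-h fixes
        start_xy=(60000.0, 60000.0),
        seed=s_sim,
    )
    return Scenario(
        name="bear_like",
        description="TSLV revisitor on 2x2 km cells, 4-h fixes, quadratic optimum 180 d",
        seed=seed,
        landscape={"habitat": habitat},
        config=config,
        extras={"tslv_vertex_days": vertex},
    )


def _hog_like(seed: int) -> Scenario:
    """Diel forager attracted to its own last-3-days occurrence distribution."""
    s_land, s_sim = _child_seeds(seed, 2)
    spec = GridSpec(x0=0.0, y0=0.0, res=100.0, n_rows=64, n_cols=64)
    habitat = gaussian_random_field(spec, correlation_range=500.0, sill=1.0, seed=s_land)
    config = SimConfig(
        kernel=KernelParams(gamma_shape=2.0, gamma_scale=75.0, vm_kappa=0.5),
        n_steps=1500,
        memory_mode="od_window",
        beta_w={"habitat": 0.3},
        beta_f={"od": 50.0},
        window=3.0,  # the short-term "last 3 days" memory
        stride=1,
        bandwidth=150.0,
        gridspec=spec,
        n_candidates=200,
        fix_interval=1.0 / 12.0,  # 2-h fixes
        start_xy=(3200.0, 3200.0),
        seed=s_sim,
    )
    return Scenario(
        name="hog_like",
        description="short-term OD attraction over a 3-day window with diel structure",
        seed=seed,
        landscape={"habitat": habitat},
        config=config,
        extras={"short_window_days": 3.0, "day_hours": (6.0, 18.0)},
    )


def _crane_like(seed: int) -> Scenario:
    """Single-range mover attracted to the previous season's 95% OD contour."""
    s_land, s_prev, s_sim = _child_seeds(seed, 3)
    spec = GridSpec(x0=0.0, y0=0.0, res=250.0, n_rows=64, n_cols=64)
    habitat = gaussian_random_field(spec, correlation_range=1000.0, sill=1.0, seed=s_land)
    # previous season: a plain habitat-only walk provides last year's locations
    prev_cfg = SimConfig(
        kernel=KernelParams(gamma_shape=2.0, gamma_scale=150.0, vm_kappa=0.5),
        n_steps=1200,
        memory_mode="none",
        beta_w={"habitat": 0.3},
        n_candidates=100,
        fix_interval=1.0 / 24.0,
        start_xy=(8000.0, 8000.0),
        seed=s_prev,
    )
    prev_track, _ = simulate({"habitat": habitat}, prev_cfg)
    prev_od = occurrence_distribution(
        prev_track, (0.0, prev_track.locations[-1].t + 1e-9), spec, bandwidth=300.0
    )
    indicator = od_contour_indicator(prev_od, level=0.95)
    config = SimConfig(
        kernel=prev_cfg.kernel,
        n_steps=2000,
        memory_mode="none",
        beta_w={"habitat": 0.3},
        beta_f={"od_indicator": 1.0},
        n_candidates=200,
        fix_interval=1.0 / 24.0,
        start_xy=tuple(float(v) for v in prev_track.xy.mean(axis=0)),
        seed=s_sim,
    )
    return Scenario(
        name="crane_like",
        description="previous-season 95% OD-contour membership as a binary familiarity term",
        seed=seed,
        landscape={"habitat": habitat},
        config=config,
        extras={
            "previous_track": prev_track,
            "previous_od": prev_od,
            "familiarity_rasters": {"od_indicator": indicator},
            "contour_level": 0.95,
        },
    )


def _deer_like(seed: int) -> Scenario:
    """Two-range migrant biased toward last year's route and winter centroid."""
    (s_path, s_sim) = _child_seeds(seed, 2)
    winter = (5000.0, 5000.0)
    summer = (45000.0, 45000.0)
    path = _wiggly_path(winter, summer, n=100, amp=3000.0, seed=s_path)
    config = SimConfig(
        kernel=KernelParams(gamma_shape=2.0, gamma_scale=300.0, vm_kappa=1.0),
        n_steps=1500,
        memory_mode="migration",
        beta_f={"dist_path": -0.002, "dir_bias": 1.5},
        n_candidates=200,
        fix_interval=1.0 / 12.0,
        start_xy=summer,
        seed=s_sim,
    )
    return Scenario(
        name="deer_like",
        description="migrant pulled toward the previous year's path and winter centroid",
        seed=seed,
        landscape={},
        config=config,
        extras={
            "previous_path": path,
            "target_centroid": winter,
            "winter_centroid": winter,
            "summer_centroid": summer,
        },
    )


# ---------------------------------------------------------------------------
# Scenario round-trip helpers: simulate -> replay covariates -> fit -> compare
# ---------------------------------------------------------------------------


def simulate_scenario(scenario: Scenario, seed: Optional[int] = None):
    """Run the scenario's generating model; returns (Track, diagnostics).

    ``seed`` overrides the simulation seed (landscape and remembered
    structures stay those of the scenario).
    """
    from dataclasses import replace

    from .simulator import MigrationSetup, simulate_migration

    cfg = scenario.config if seed is None else replace(scenario.config, seed=seed)
    if cfg.memory_mode == "migration":
        setup = MigrationSetup(cfg.start_xy, scenario.extras["target_centroid"])
        return simulate_migration(setup, scenario.extras["previous_path"], cfg, scenario.landscape or None)
    return simulate(
        scenario.landscape or None, cfg, familiarity_rasters=scenario.extras.get("familiarity_rasters")
    )


def scenario_providers(scenario: Scenario):
    """(providers, domain GridSpec or None) matching the scenario's covariates."""
    from .pipeline import (
        HabitatProvider,
        MigrationProvider,
        ODWindowProvider,
        StaticRasterProvider,
        TSLVProvider,
    )

    cfg = scenario.config
    providers = []
    domain = None
    if scenario.landscape:
        providers.append(HabitatProvider(scenario.landscape))
        domain = next(iter(scenario.landscape.values())).spec
    if cfg.memory_mode == "tslv":
        providers.append(TSLVProvider(cfg.gridspec, cfg.default_tslv))
        domain = cfg.gridspec
    elif cfg.memory_mode == "od_window":
        providers.append(ODWindowProvider(cfg.gridspec, cfg.bandwidth, cfg.window, cfg.stride))
        domain = cfg.gridspec
    elif cfg.memory_mode == "migration":
        providers.append(
            MigrationProvider(
                scenario.extras.get("previous_path"), scenario.extras.get("target_centroid")
            )
        )
    for name, raster in (scenario.extras.get("familiarity_rasters") or {}).items():
        providers.append(StaticRasterProvider(name, raster))
    return providers, domain


def scenario_terms(scenario: Scenario, include_movement: bool = True):
    """Model terms matching the scenario's generating coefficients."""
    from .ssf_fit import Term

    cfg = scenario.config
    terms = [Term(name) for name in cfg.beta_w]
    if "tslv" in cfg.beta_f:
        terms.append(Term("tslv", quadratic="tslv_sq" in cfg.beta_f))
    for name in ("od", "od_indicator", "dist_path", "dir_bias"):
        if name in cfg.beta_f:
            terms.append(Term(name))
    if include_movement:
        terms += [Term("log_sl"), Term("sl"), Term("cos_ta")]
    return terms


def scenario_true_beta(scenario: Scenario) -> dict[str, float]:
    """Generating coefficients keyed by design-column name."""
    return {**scenario.config.beta_w, **scenario.config.beta_f}


def recover_scenario(
    scenario: Scenario,
    sim_seed: Optional[int] = None,
    n_avail: int = 20,
    strata_seed: int = 0,
    include_movement: bool = True,
):
    """Full round trip: simulate, fit the tentative kernel, replay covariates,
    fit the conditional-logistic model. Returns (FitResult, true_beta, Track).
    """
    import warnings as _w

    from .movement_kernel import fit_tentative
    from .pipeline import build_strata
    from .ssf_fit import build_design, fit_clogit
    from .trajectory import steps_from_track

    track, _ = simulate_scenario(scenario, seed=sim_seed)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        kernel = fit_tentative(steps_from_track(track))
    providers, domain = scenario_providers(scenario)
    strata = build_strata(
        track, kernel, providers, n_avail=n_avail, seed=strata_seed,
        include_movement=include_movement, domain=domain,
    )
    design = build_design(strata, scenario_terms(scenario, include_movement))
    fit = fit_clogit(design)
    return fit, scenario_true_beta(scenario), track
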