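"""Selection-free movement kernel: gamma step lengths x von Mises turning angles.

The kernel k(s_t | H_{t-1}) describes how the animal would move absent any
habitat or memory preference. Step lengths follow a gamma distribution
(shape, scale in meters); turning angles follow a von Mises distribution with
mean 0 (persistence straight ahead) and concentration kappa. Both are
exponential-family choices so the fitted step-selection model can absorb
kernel corrections through log(sl), sl and cos(ta) adjustment terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, special, stats

from .trajectory import Step, wrap_angle

__all__ = ["KernelParams", "AvailableSteps", "fit_tentative", "sample_available", "kernel_density", "KAPPA_MAX"]

#: cap on the von Mises concentration; beyond this Bessel-function evaluation
#: overflows and the distribution is numerically a point mass anyway.
KAPPA_MAX = 700.0


@dataclass(frozen=True)
class KernelParams:
    """Tentative movement-kernel parameters.

    gamma_shape : dimensionless > 0
    gamma_scale : meters > 0
    vm_kappa    : von Mises concentration >= 0, mean direction fixed at 0
    """

    gamma_shape: float
    gamma_scale: float
    vm_kappa: float

    def __post_init__(self):
        if not (math.isfinite(self.gamma_shape) and self.gamma_shape > 0):
            raise ValueError(f"gamma_shape must be finite and > 0, got {self.gamma_shape}")
        if not (math.isfinite(self.gamma_scale) and self.gamma_scale > 0):
            raise ValueError(f"gamma_scale must be finite and > 0, got {self.gamma_scale}")
        if not (math.isfinite(self.vm_kappa) and self.vm_kappa >= 0):
            raise ValueError(f"vm_kappa must be finite and >= 0, got {self.vm_kappa}")


class AvailableSteps(NamedTuple):
    """Candidate endpoints drawn from the kernel (used for matched availables)."""

    x: np.ndarray
    y: np.ndarray
    sl: np.ndarray
    ta: np.ndarray
    bearing: np.ndarray  # absolute heading of each candidate step


def _a1(kappa: float) -> float:
    # mean resultant length of a von Mises: I1(k)/I0(k), computed with
    # exponentially scaled Bessel functions for stability at large kappa
    return special.i1e(kappa) / special.i0e(kappa)


def fit_tentative(steps: Sequence[Step], kappa_max: float = KAPPA_MAX) -> KernelParams:
    """Fit tentative kernel parameters from observed steps by ML.

    Gamma (shape, scale) on step lengths with location fixed at 0; von Mises
    kappa on turning angles with mean fixed at 0 (solves A1(kappa) = mean
    cos(ta)). Zero step lengths are replaced by half the smallest positive sl
    (keeping strata aligned rather than dropping fixes); the replacement count
    is reported via a warning. A non-positive mean cosine yields kappa = 0;
    a degenerate concentration is capped at ``kappa_max`` with a warning.
    """
    sl = np.array([s.sl for s in steps], dtype=float)
    ta = np.array([s.ta for s in steps if s.ta is not None], dtype=float)
    if np.sum(sl > 0) < 5:
        raise ValueError(f"need >= 5 steps with sl > 0, got {int(np.sum(sl > 0))}")
    if ta.size < 5:
        raise ValueError(f"need >= 5 defined turning angles, got {ta.size}")
    if np.ptp(sl) == 0:
        raise ValueError("all step lengths identical: gamma likelihood is degenerate")

    n_zero = int(np.sum(sl == 0))
    if n_zero:
        sl = sl.copy()
        sl[sl == 0] = 0.5 * sl[sl > 0].min()
        warnings.warn(f"replaced {n_zero} zero step length(s) by half the smallest positive sl")

    shape, _, scale = stats.gamma.fit(sl, floc=0)

    rbar = float(np.mean(np.cos(ta)))
    if rbar <= 0:
        kappa = 0.0
    elif rbar >= _a1(kappa_max):
        warnings.warn(
            f"turning-angle concentration is degenerate (mean cos = {rbar:.6g}); "
            f"kappa capped at {kappa_max}"
        )
        kappa = kappa_max
    else:
        kappa = float(optimize.brentq(lambda k: _a1(k) - rbar, 1e-12, kappa_max))
    return KernelParams(gamma_shape=float(shape), gamma_scale=float(scale), vm_kappa=kappa)


def sample_turning_angles(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw turning angles from von Mises(0, kappa); kappa = 0 is uniform."""
    if kappa == 0:
        return rng.uniform(-math.pi, math.pi, size=n)
    return wrap_angle(rng.vonmises(0.0, kappa, size=n))


def sample_candidates(
    start_xy: tuple[float, float],
    prev_bearing: float,
    params: KernelParams,
    n: int,
    rng: np.random.Generator,
) -> AvailableSteps:
    """Draw n kernel steps from ``start_xy`` given the previous absolute bearing."""
    sl = rng.gamma(params.gamma_shape, params.gamma_scale, size=n)
    ta = sample_turning_angles(params.vm_kappa, n, rng)
    bearing = wrap_angle(prev_bearing + ta)
    x = start_xy[0] + sl * np.cos(bearing)
    y = start_xy[1] + sl * np.sin(bearing)
    return AvailableSteps(x=x, y=y, sl=sl, ta=ta, bearing=bearing)


def sample_available(step: Step, params: KernelParams, n_avail: int, seed) -> AvailableSteps:
    """Generate matched available steps for one observed step.

    Candidate endpoints are the step's start displaced by sl* ~ gamma and an
    absolute heading = previous bearing + ta* ~ von Mises(0, kappa), where the
    previous bearing is recovered as step.bearing - step.ta. The step must
    therefore have a defined turning angle (i.e. not be the first of a track).
    Reproducible given the same seed.
    """
    if step.ta is None:
        raise ValueError("step has no defined turning angle; previous bearing unknown")
    if n_avail < 1:
        raise ValueError(f"n_avail must be >= 1, got {n_avail}")
    rng = np.random.default_rng(seed)
    prev_bearing = wrap_angle(step.bearing - step.ta)
    return sample_candidates((step.start.x, step.start.y), prev_bearing, params, n_avail, rng)


def vonmises_pdf(ta, kappa: float):
    """von Mises density at turning angle(s), mean 0; kappa = 0 is 1/(2 pi)."""
    ta = np.asarray(ta, dtype=float)
    if kappa == 0:
        return np.full(ta.shape, 1.0 / (2.0 * math.pi)) if ta.ndim else 1.0 / (2.0 * math.pi)
    # exp-scaled Bessel keeps this finite up to KAPPA_MAX
    return np.exp(kappa * (np.cos(ta) - 1.0)) / (2.0 * math.pi * special.i0e(kappa))


def kernel_density(sl, ta, params: KernelParams):
    """Joint kernel density: gamma(sl) x von Mises(ta). Requires sl > 0."""
    sl_arr = np.asarray(sl, dtype=float)
    if np.any(sl_arr <= 0):
        raise ValueError("kernel density requires sl > 0")
    g = stats.gamma.pdf(sl_arr, params.gamma_shape, scale=params.gamma_scale)
    return g * vonmises_pdf(ta, params.vm_kappa)
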