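"""Profile-objective identifiability analysis of calibrated PBM parameters.

One parameter is fixed at each value of a grid spanning its calibrated value
and the remaining free parameters are re-optimized; the resulting profile of
minimized objective values IA(theta) is U-shaped for an identifiable
parameter (the objective deteriorates monotonically on both sides of the
optimum) and flat along a collinear direction — the signature that motivates
fixing the classifier scale k rather than estimating it alongside alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .calibration import (
    CalibrationProblem,
    SwarmConfig,
    _pso_minimize,
)
from .errors import InvalidArgumentError

__all__ = ["IAProfile", "ia_profile", "u_shape_verdict", "default_profile_grid",
            "PROFILE_SWARM"]

# Reduced swarm for the inner re-optimizations; the profile needs many of them
PROFILE_SWARM = SwarmConfig(n_particles=15, n_iter=80)

FREE_PARAMS = ("alpha", "gamma", "lam")


@dataclass(frozen=True)
class IAProfile:
    """Minimized objective along a one-parameter slice."""

    parameter: str
    grid: np.ndarray
    ia_values: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, float)
        v = np.asarray(self.ia_values, float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "ia_values", v)
        if len(g) != len(v):
            raise InvalidArgumentError("grid and values must have equal length")
        if np.any(np.diff(g) <= 0):
            raise InvalidArgumentError("profile grid must be strictly increasing")
        if np.any(v < 0):
            raise InvalidArgumentError("objective values must be nonnegative")

    @property
    def argmin(self) -> float:
        return float(self.grid[int(np.argmin(self.ia_values))])


def default_profile_grid(calibrated_value: float, n: int = 11,
                         lo_factor: float = 0.2, hi_factor: float = 5.0) -> np.ndarray:
    """Log-spaced profile grid around a calibrated value (default 0.2x to 5x)."""
    if calibrated_value <= 0:
        raise InvalidArgumentError("calibrated value must be positive for a log grid")
    return np.geomspace(lo_factor * calibrated_value, hi_factor * calibrated_value, n)


def ia_profile(problem: CalibrationProblem, parameter: str, grid: np.ndarray,
               seed: int | None = None, swarm: SwarmConfig | None = None,
               bandwidth: float | None = None) -> IAProfile:
    """Profile the objective over ``parameter``, re-optimizing the others.

    ``parameter`` may be one of the free parameters (alpha, gamma, lam) or
    ``"k"``; profiling k keeps all three of alpha, gamma, lam free, which
    exposes the k-alpha collinearity as a flat valley. Per-grid-point seeds
    are derived from ``seed`` so the whole profile is reproducible.
    """
    if parameter not in FREE_PARAMS and parameter != "k":
        raise InvalidArgumentError(f"cannot profile '{parameter}'")
    grid = np.asarray(grid, float)
    if len(grid) >= 2 and np.any(np.diff(grid) <= 0):
        raise InvalidArgumentError("profile grid must be strictly increasing")
    cfg = swarm or PROFILE_SWARM
    base_seed = problem.seed if seed is None else seed

    if parameter == "k":
        free = list(FREE_PARAMS)
    else:
        free = [p for p in FREE_PARAMS if p != parameter]

    lo, hi = [], []
    for name in free:
        b = problem.bounds[name]
        if name == "alpha":
            lo.append(np.log10(b[0]))
            hi.append(np.log10(b[1]))
        else:
            lo.append(b[0])
            hi.append(b[1])

    values = np.empty(len(grid))
    for idx, value in enumerate(grid):
        if parameter == "k":
            fixed = problem.fixed.with_(k=float(value))
        else:
            fixed = problem.fixed
        local = replace(problem, fixed=fixed)

        def fun(z, _local=local, _value=float(value)):
            kw = {}
            for name, zi in zip(free, z):
                kw[name] = 10.0 ** zi if name == "alpha" else zi
            if parameter != "k":
                kw[parameter] = _value
            return _local.objective(kw["alpha"], kw["gamma"], kw["lam"], bandwidth)

        point_seed = (base_seed * 1000003 + idx * 7919) % (2**31 - 1)
        best_x, best_f, _, _ = _pso_minimize(fun, np.array(lo), np.array(hi),
                                             point_seed, cfg)
        r = minimize(fun, best_x, method="Nelder-Mead",
                     bounds=list(zip(lo, hi)),
                     options={"xatol": 1e-10, "fatol": 1e-18, "maxfev": 2000})
        if np.isfinite(r.fun) and r.fun <= best_f:
            best_f = float(r.fun)
        values[idx] = best_f
    return IAProfile(parameter=parameter, grid=grid, ia_values=values)


def u_shape_verdict(profile: IAProfile, tolerance: float = 0.02) -> bool:
    """True iff the profile falls monotonically to its minimum and rises after.

    ``tolerance`` is the relative slack absorbing optimizer noise: a step in
    the wrong direction smaller than tolerance x (profile range) does not
    break monotonicity, and a profile whose total variation is within
    tolerance of flat (relative to its level) is judged non-identifiable.
    """
    v = profile.ia_values
    if len(v) < 5:
        raise InvalidArgumentError("profile needs at least 5 points for a verdict")
    vrange = float(v.max() - v.min())
    level = float(max(v.max(), 1e-300))
    if vrange <= tolerance * level:
        return False  # flat valley: collinearity signature
    i_min = int(np.argmin(v))
    if i_min == 0 or i_min == len(v) - 1:
        return False  # minimum at the boundary: one-sided, not a U
    slack = tolerance * vrange
    left = v[: i_min + 1]
    right = v[i_min:]
    dec = np.all(np.diff(left) <= slack)
    inc = np.all(np.diff(right) >= -slack)
    return bool(dec and inc)
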