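"""Staged PBM parameter identification and estimation.

Seven parameters would be too many to estimate jointly from one milled PSD,
so identification is staged:

1. the classifier scale ``k`` is fixed by convention (it is collinear with
   the breakage coefficient ``alpha``: only their balance is constrained by
   steady-state data);
2. the classification curve (``mu_c``, ``sigma_c``) is identified from the
   coarse tail of the milled PSD, which the classifier shapes directly;
3. the critical breakage size ``xcrit`` is identified as a low volume
   percentile of the milled product — particles that were produced but no
   longer broke;
4. the remaining (``alpha``, ``gamma``, ``lam``) are estimated by particle
   swarm optimization against the summed maximum mean discrepancy (MMD)
   between simulated and observed PSDs in the volume and the number basis.

The MMD is a kernel two-sample distance; here the squared V-statistic with a
Gaussian kernel on log10 size, so both very fine (number-dominated) and
coarse (volume-dominated) disagreement is penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .errors import EstimationError, InvalidArgumentError
from .pbm_core import PBMParams, ProcessSettings, PSD, steady_state

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "SwarmConfig",
    "mmd",
    "mmd_sum",
    "identify_classifier",
    "identify_xcrit",
    "pso_calibrate",
    "DEFAULT_BOUNDS",
]

# (lower, upper) search bounds for the free parameters
DEFAULT_BOUNDS = {
    "alpha": (1e-4, 1e3),  # 1/s, searched on a log scale
    "gamma": (0.1, 5.0),
    "lam": (0.0, 5.0),
}


def _median_bandwidth(log_sizes: np.ndarray) -> float:
    d = np.abs(log_sizes[:, None] - log_sizes[None, :])
    vals = d[np.triu_indices_from(d, k=1)]
    h = float(np.median(vals))
    if h <= 0:
        raise InvalidArgumentError("degenerate grid: zero median log-size spacing")
    return h


def mmd(psd_a: PSD, psd_b: PSD, basis: str = "volume",
        bandwidth: float | None = None) -> float:
    """Squared MMD (V-statistic) between two PSDs on a common grid.

    Gaussian kernel on log10 size; bandwidth defaults to the median pairwise
    log10-size distance over the grid. Symmetric and zero iff the two
    distributions coincide on the grid.
    """
    if psd_a.grid.n != psd_b.grid.n or not np.allclose(
        psd_a.grid.centers, psd_b.grid.centers
    ):
        raise InvalidArgumentError("PSDs must share a grid")
    if basis == "volume":
        p, q = psd_a.volume_fraction, psd_b.volume_fraction
    elif basis == "number":
        p, q = psd_a.number_fraction, psd_b.number_fraction
    else:
        raise InvalidArgumentError("basis must be 'volume' or 'number'")
    u = np.log10(psd_a.grid.centers)
    h = bandwidth if bandwidth is not None else _median_bandwidth(u)
    K = np.exp(-((u[:, None] - u[None, :]) ** 2) / (2.0 * h * h))
    d = p - q
    return float(max(d @ K @ d, 0.0))


def mmd_sum(model_out: PSD, observed: PSD, bandwidth: float | None = None) -> float:
    """Calibration objective: MMD in the volume basis plus MMD in the number basis."""
    return (mmd(model_out, observed, "volume", bandwidth)
            + mmd(model_out, observed, "number", bandwidth))


def identify_classifier(milled: PSD) -> tuple[float, float]:
    """Fit (mu_c, sigma_c) to the coarse half of the milled cumulative PSD.

    The classifier acts as a virtual screen: the surviving coarse tail of the
    product follows the complement cumulative log-normal. Least-squares fit of
    1 - F(x) = (1/2)(1 - erf((ln x - mu)/(sqrt 2 sigma))) over the classes at
    or above the dv50.
    """
    cum = np.cumsum(milled.volume_fraction)
    if np.count_nonzero(milled.volume_fraction) < 3:
        raise EstimationError("PSD too degenerate to fit a classification curve")
    x = milled.grid.edges[1:]
    mask = cum >= 0.5
    mask &= cum <= 1.0 - 1e-12  # drop the saturated tail, carries no shape
    if mask.sum() < 3:
        # include the last classes before saturation
        mask = cum >= 0.5
        mask[np.searchsorted(cum, 1.0 - 1e-12) + 1:] = False
    if mask.sum() < 2:
        raise EstimationError("coarse tail too short to fit a classification curve")

    def complement_cum(lnx, mu, sigma):
        return 0.5 * (1.0 - erf((lnx - mu) / (np.sqrt(2.0) * sigma)))

    lnx = np.log(x[mask])
    y = 1.0 - cum[mask]
    mu0 = float(np.log(milled.dv50))
    sig0 = max(float(np.log(milled.dv90 / milled.dv50)) / 1.2816, 0.05)
    try:
        popt, _ = curve_fit(complement_cum, lnx, y, p0=(mu0, sig0),
                            bounds=((lnx.min() - 5, 1e-3), (lnx.max() + 5, 5.0)),
                            maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - curve_fit failure path
        raise EstimationError(f"classification-curve fit failed: {exc}") from exc
    mu_c, sigma_c = float(popt[0]), float(popt[1])
    if sigma_c <= 0:
        raise EstimationError("fitted sigma_c not positive")
    return mu_c, sigma_c


def identify_xcrit(milled: PSD, quantile: float = 0.10) -> float:
    """Critical breakage size as a low volume percentile of the milled PSD.

    Particles below this size were produced by breakage but did not break
    further; the default is the dv10 of the milled product.
    """
    return milled.dv(quantile)


@dataclass(frozen=True)
class CalibrationProblem:
    """Inputs for estimating (alpha, gamma, lam) with the rest fixed."""

    unmilled: PSD
    milled_observed: PSD
    settings: ProcessSettings
    fixed: PBMParams  # carries k, mu_c, sigma_c, xcrit; alpha/gamma/lam ignored
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0

    def __post_init__(self):
        if set(self.bounds) != {"alpha", "gamma", "lam"}:
            raise InvalidArgumentError("bounds must cover exactly alpha, gamma, lam")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InvalidArgumentError(f"bounds for {name} must be finite with lower < upper")

    def objective(self, alpha: float, gamma: float, lam: float,
                  bandwidth: float | None = None) -> float:
        params = self.fixed.with_(alpha=alpha, gamma=gamma, lam=lam)
        try:
            _, out = steady_state(self.unmilled, self.settings, params)
        except Exception:
            return np.inf
        return mmd_sum(out, self.milled_observed, bandwidth)


@dataclass
class CalibrationResult:
    params: PBMParams
    objective: float
    trace: np.ndarray  # best objective per iteration, non-increasing
    n_evals: int
    seed: int


@dataclass(frozen=True)
class SwarmConfig:
    """Particle swarm settings (constriction-style defaults, seeded RNG)."""

    n_particles: int = 30
    n_iter: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49


def _pso_minimize(fun, lower, upper, seed, cfg: SwarmConfig):
    """Seeded global-best PSO over a box; reflective bound handling.

    Returns (best_x, best_f, trace, n_evals). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    dim = len(lower)
    span = upper - lower
    np_, ni = cfg.n_particles, cfg.n_iter
    x = lower + rng.random((np_, dim)) * span
    v = (rng.random((np_, dim)) - 0.5) * span * 0.2
    f = np.array([fun(xi) for xi in x])
    n_evals = np_
    if not np.any(np.isfinite(f)):
        raise EstimationError("objective non-finite at every initial particle")
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    trace = [gbest_f]
    for _ in range(ni):
        r1 = rng.random((np_, dim))
        r2 = rng.random((np_, dim))
        v = (cfg.inertia * v
             + cfg.cognitive * r1 * (pbest_x - x)
             + cfg.social * r2 * (gbest_x - x))
        x = x + v
        # reflect at the box boundary and damp the velocity component
        for b, sgn in ((lower, 1.0), (upper, -1.0)):
            out = (x - b) * sgn < 0
            x = np.where(out, 2 * b - x, x)
            v = np.where(out, -0.5 * v, v)
        x = np.clip(x, lower, upper)
        f = np.array([fun(xi) for xi in x])
        n_evals += np_
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace.append(gbest_f)
    return gbest_x, gbest_f, np.asarray(trace), n_evals


def pso_calibrate(problem: CalibrationProblem,
                  swarm: SwarmConfig | None = None,
                  bandwidth: float | None = None,
                  polish: bool = True) -> CalibrationResult:
    """Estimate (alpha, gamma, lam) minimizing the summed MMD.

    alpha is searched on a log10 scale to cover its wide prior range evenly.
    The swarm handles the global search; because the objective valley is
    strongly anisotropic (alpha and lam partially compensate over the narrow
    size window the data constrain), the swarm best is refined by a bounded
    Nelder-Mead simplex (``polish``, on by default). Deterministic for a
    fixed problem seed.
    """
    cfg = swarm or SwarmConfig()
    (a_lo, a_hi) = problem.bounds["alpha"]
    (g_lo, g_hi) = problem.bounds["gamma"]
    (l_lo, l_hi) = problem.bounds["lam"]
    if a_lo <= 0:
        raise InvalidArgumentError("alpha lower bound must be positive (log-scale search)")
    lower = np.array([np.log10(a_lo), g_lo, l_lo])
    upper = np.array([np.log10(a_hi), g_hi, l_hi])

    def fun(z):
        return problem.objective(10.0 ** z[0], z[1], z[2], bandwidth)

    best_x, best_f, trace, n_evals = _pso_minimize(
        fun, lower, upper, problem.seed, cfg
    )
    if polish:
        from scipy.optimize import minimize

        r = minimize(fun, best_x, method="Nelder-Mead",
                     bounds=list(zip(lower, upper)),
                     options={"xatol": 1e-10, "fatol": 1e-18, "maxfev": 4000})
        n_evals += r.nfev
        if np.isfinite(r.fun) and r.fun <= best_f:
            best_x, best_f = np.asarray(r.x), float(r.fun)
        trace = np.append(trace, best_f)
    params = problem.fixed.with_(
        alpha=10.0 ** best_x[0], gamma=best_x[1], lam=best_x[2]
    )
    return CalibrationResult(params=params, objective=best_f, trace=trace,
                             n_evals=n_evals, seed=problem.seed)
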