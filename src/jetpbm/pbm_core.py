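"""Discretized population balance model (PBM) of a self-classifying spiral jet mill.

The mill chamber is modelled as a well-mixed hold-up of powder on a geometric
size grid. Three mechanisms move mass between classes and across the system
boundary:

* feed — the unmilled particle size distribution (PSD) enters at the solids
  mass feed rate;
* classification — the central outlet acts as a static classifier whose
  exit rate per unit hold-up falls with particle size following a complement
  cumulative log-normal curve (parameters ``mu_c``, ``sigma_c``, scale ``k``);
* breakage — particles at or above a critical size ``xcrit`` break at a
  size-dependent specific rate ``alpha * (x / x_n)**lam`` and redistribute
  their mass over smaller classes through a power-law cumulative fragment
  distribution with exponent ``gamma``.

The state variable is mass per class, which makes breakage exactly
mass-conserving; number-based quantities are derived views through the
sphere-volume convention (``x`` is a diameter, v(x) = pi/6 x^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_triangular
from scipy.special import erf

from .errors import InvalidArgumentError, MassTrapError

__all__ = [
    "SizeGrid",
    "PSD",
    "ProcessSettings",
    "PBMParams",
    "MillState",
    "make_grid",
    "sphere_volume",
    "volume_to_number",
    "number_to_volume",
    "inlet_rate",
    "classifier_exit_fraction",
    "breakage_rate",
    "breakage_matrix",
    "derivative",
    "steady_state",
    "integrate_transient",
    "integrate_to_steady",
    "outlet_psd",
    "dv_percentile",
    "DEFAULT_GRID",
]

# Studied operating window of the 50 mm spiral jet mill
GFR_RANGE = (2.2, 9.0)   # m^3/h
MFR_RANGE = (5.0, 15.0)  # g/min


@dataclass(frozen=True)
class SizeGrid:
    """Geometric particle-size grid shared by all PBM quantities.

    Classes are labelled 1..n in interfaces, class 1 holding the smallest
    particles. ``centers`` and ``edges`` are in micrometres.
    """

    centers: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "edges", edges)
        if centers.ndim != 1 or len(centers) < 10:
            raise InvalidArgumentError("grid needs at least 10 size classes")
        if len(edges) != len(centers) + 1:
            raise InvalidArgumentError("edges must have n+1 entries")
        if np.any(np.diff(centers) <= 0) or np.any(np.diff(edges) <= 0):
            raise InvalidArgumentError("centers and edges must be strictly increasing")
        if np.any(centers <= edges[:-1]) or np.any(centers >= edges[1:]):
            raise InvalidArgumentError("every center must lie inside its edge pair")
        ratios = centers[1:] / centers[:-1]
        if np.ptp(ratios) > 1e-9 * ratios[0]:
            raise InvalidArgumentError("grid spacing must be geometric")

    @property
    def n(self) -> int:
        return len(self.centers)

    @property
    def spacing(self) -> float:
        """Constant geometric ratio between adjacent class centers."""
        return float(self.centers[1] / self.centers[0])


def make_grid(x_min: float, x_max: float, n: int = 80) -> SizeGrid:
    """Build a geometric size grid with ``n`` classes spanning [x_min, x_max] um.

    Edges are placed at the geometric midpoints between adjacent centers and
    extrapolated by the same ratio at both ends.
    """
    if x_min <= 0 or x_max <= 0:
        raise InvalidArgumentError("grid bounds must be positive")
    if x_max <= x_min:
        raise InvalidArgumentError("x_max must exceed x_min")
    if n < 10:
        raise InvalidArgumentError("n must be at least 10")
    centers = np.geomspace(x_min, x_max, n)
    half = np.sqrt(centers[1] / centers[0])
    edges = np.concatenate(([centers[0] / half], centers * half))
    return SizeGrid(centers=centers, edges=edges)


DEFAULT_GRID_SPEC = (0.1, 500.0, 80)


def _default_grid() -> SizeGrid:
    return make_grid(*DEFAULT_GRID_SPEC)


DEFAULT_GRID = _default_grid()


def sphere_volume(x_um: np.ndarray | float) -> np.ndarray | float:
    """Volume of a sphere of diameter ``x`` um, in um^3."""
    return (np.pi / 6.0) * np.asarray(x_um, dtype=float) ** 3


def volume_to_number(grid: SizeGrid, volume_fraction: np.ndarray) -> np.ndarray:
    """Convert per-class volume fractions to number fractions."""
    w = np.asarray(volume_fraction, dtype=float) / sphere_volume(grid.centers)
    total = w.sum()
    if total <= 0:
        raise InvalidArgumentError("cannot normalize an all-zero distribution")
    return w / total


def number_to_volume(grid: SizeGrid, number_fraction: np.ndarray) -> np.ndarray:
    """Convert per-class number fractions to volume fractions."""
    w = np.asarray(number_fraction, dtype=float) * sphere_volume(grid.centers)
    total = w.sum()
    if total <= 0:
        raise InvalidArgumentError("cannot normalize an all-zero distribution")
    return w / total


@dataclass(frozen=True)
class PSD:
    """A particle size distribution over a :class:`SizeGrid`.

    Carries both the volume (mass) basis and the number basis; the two are
    linked through the sphere-volume convention. Construct with
    :meth:`from_volume` or :meth:`from_number` unless both bases are already
    consistent.
    """

    grid: SizeGrid
    volume_fraction: np.ndarray
    number_fraction: np.ndarray

    def __post_init__(self):
        vf = np.asarray(self.volume_fraction, dtype=float)
        nf = np.asarray(self.number_fraction, dtype=float)
        object.__setattr__(self, "volume_fraction", vf)
        object.__setattr__(self, "number_fraction", nf)
        if len(vf) != self.grid.n or len(nf) != self.grid.n:
            raise InvalidArgumentError("fraction vectors must match grid size")
        if np.any(vf < -1e-12) or np.any(nf < -1e-12):
            raise InvalidArgumentError("fractions must be nonnegative")
        for name, v in (("volume", vf), ("number", nf)):
            if abs(v.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError(f"{name} fractions must sum to 1")

    @classmethod
    def from_volume(cls, grid: SizeGrid, volume_fraction: np.ndarray) -> "PSD":
        vf = np.clip(np.asarray(volume_fraction, dtype=float), 0.0, None)
        total = vf.sum()
        if total <= 0:
            raise InvalidArgumentError("volume fractions must not be all zero")
        vf = vf / total
        return cls(grid=grid, volume_fraction=vf,
                   number_fraction=volume_to_number(grid, vf))

    @classmethod
    def from_number(cls, grid: SizeGrid, number_fraction: np.ndarray) -> "PSD":
        nf = np.clip(np.asarray(number_fraction, dtype=float), 0.0, None)
        total = nf.sum()
        if total <= 0:
            raise InvalidArgumentError("number fractions must not be all zero")
        nf = nf / total
        return cls(grid=grid, volume_fraction=number_to_volume(grid, nf),
                   number_fraction=nf)

    def dv(self, q: float) -> float:
        """Volume-percentile diameter, e.g. ``dv(0.5)`` is the dv50."""
        return dv_percentile(self, q)

    @property
    def dv10(self) -> float:
        return dv_percentile(self, 0.10)

    @property
    def dv50(self) -> float:
        return dv_percentile(self, 0.50)

    @property
    def dv90(self) -> float:
        return dv_percentile(self, 0.90)


@dataclass(frozen=True)
class ProcessSettings:
    """Mill operating point: gas flow rate, solids feed rate, powder density.

    gfr : grinding gas flow rate, m^3/h
    mfr : solids mass feed rate, g/min
    density : particle (true) density, kg/m^3
    """

    gfr: float
    mfr: float
    density: float = 1300.0

    def __post_init__(self):
        if self.gfr <= 0 or self.mfr <= 0 or self.density <= 0:
            raise InvalidArgumentError("process settings must be strictly positive")
        tol = 1e-9
        if not (GFR_RANGE[0] - tol <= self.gfr <= GFR_RANGE[1] + tol):
            warnings.warn(
                f"GFR {self.gfr} m^3/h outside the studied range {GFR_RANGE}",
                stacklevel=2,
            )
        if not (MFR_RANGE[0] - tol <= self.mfr <= MFR_RANGE[1] + tol):
            warnings.warn(
                f"MFR {self.mfr} g/min outside the studied range {MFR_RANGE}",
                stacklevel=2,
            )

    @property
    def mfr_kg_s(self) -> float:
        """Solids feed rate in kg/s."""
        return self.mfr * 1e-3 / 60.0


@dataclass(frozen=True)
class PBMParams:
    """The seven PBM parameters.

    alpha : breakage rate coefficient, 1/s
    lam : breakage rate size exponent (dimensionless, >= 0)
    gamma : fragment distribution exponent (dimensionless, > 0)
    xcrit : critical breakage size, um; particles below it do not break
    mu_c : classifier log-mean, natural log of size in um
    sigma_c : classifier log-standard deviation (dimensionless, > 0)
    k : classifier exit scale factor, 1/s (fixed by convention; collinear
        with alpha, so only products of the two are constrained by data)
    """

    alpha: float
    lam: float
    gamma: float
    xcrit: float
    mu_c: float
    sigma_c: float
    k: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be >= 0")
        if self.lam < 0:
            raise InvalidArgumentError("lam must be >= 0")
        if self.gamma <= 0:
            raise InvalidArgumentError("gamma must be > 0")
        if self.xcrit < 0:
            raise InvalidArgumentError("xcrit must be >= 0")
        if self.sigma_c <= 0:
            raise InvalidArgumentError("sigma_c must be > 0")
        if self.k <= 0:
            raise InvalidArgumentError("k must be > 0")

    def with_(self, **kwargs) -> "PBMParams":
        return replace(self, **kwargs)


@dataclass
class MillState:
    """Mass hold-up per size class inside the chamber at a given time."""

    grid: SizeGrid
    holdup_mass: np.ndarray  # kg per class
    time: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.holdup_mass, dtype=float)
        self.holdup_mass = m
        if len(m) != self.grid.n:
            raise InvalidArgumentError("holdup vector must match grid size")
        if np.any(m < -1e-15) or not np.all(np.isfinite(m)):
            raise InvalidArgumentError("holdup must be finite and nonnegative")

    @property
    def total_mass(self) -> float:
        return float(self.holdup_mass.sum())


def inlet_rate(unmilled: PSD, settings: ProcessSettings) -> np.ndarray:
    """Per-class mass feed rate (kg/s) of the unmilled material.

    Mass rate into class i is the unmilled volume fraction times the total
    solids feed rate; dividing by rho * v(x_i) recovers the number feed rate.
    """
    return unmilled.volume_fraction * settings.mfr_kg_s


def classifier_exit_fraction(x, params: PBMParams):
    """First-order exit rate factor (1/s) of the classifier at size ``x`` um.

    (k/2) * (1 - erf((ln x - mu_c) / (sqrt(2) sigma_c))): the complement
    cumulative log-normal, strictly decreasing in x, with limit k as x -> 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise InvalidArgumentError("size must be positive")
    z = (np.log(x) - params.mu_c) / (np.sqrt(2.0) * params.sigma_c)
    out = (params.k / 2.0) * (1.0 - erf(z))
    return out if out.ndim else float(out)


def breakage_rate(x, params: PBMParams, x_n: float):
    """Specific breakage rate S(x) (1/s): zero below xcrit, else a power law
    alpha * (x / x_n)**lam normalized at the largest grid size x_n."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or x_n <= 0:
        raise InvalidArgumentError("sizes must be positive")
    s = np.where(x >= params.xcrit, params.alpha * (x / x_n) ** params.lam, 0.0)
    return s if s.ndim else float(s)


def breakage_matrix(grid: SizeGrid, gamma: float) -> np.ndarray:
    """Mass-closed fragment distribution matrix b[i, j] (0-based indices).

    Column j holds the mass fractions of the fragments produced by breaking a
    parent in class j. The cumulative distribution is B[i, j] = (x_i/x_j)^gamma;
    differencing gives the per-class fractions, and the mass the power law
    leaves unassigned below class j (1 - B[j-1, j]) is added to the largest
    daughter class j-1, so every column with j >= 1 sums to exactly 1.
    Column 0 is all zero: the smallest class has no daughters on the grid.
    """
    if gamma <= 0:
        raise InvalidArgumentError("gamma must be > 0")
    x = grid.centers
    n = grid.n
    b = np.zeros((n, n))
    for j in range(1, n):
        B = (x[: j + 1] / x[j]) ** gamma  # cumulative over i = 0..j
        col = np.empty(j)
        col[0] = B[0]
        col[1:] = np.diff(B[: j])
        col[j - 1] += 1.0 - B[j - 1]  # close the parent's mass
        b[:j, j] = col
    return b


def _rate_vectors(grid: SizeGrid, params: PBMParams):
    """Classifier rate c_i and breakage rate S_i per class; S is forced to
    zero in the smallest class, which has no daughter classes on the grid."""
    c = classifier_exit_fraction(grid.centers, params)
    x_n = float(grid.centers[-1])
    S = breakage_rate(grid.centers, params, x_n)
    S = np.asarray(S, dtype=float).copy()
    S[0] = 0.0
    return np.asarray(c, dtype=float), S


def derivative(state: MillState, params: PBMParams, inlet: np.ndarray) -> np.ndarray:
    """Right-hand side dM_i/dt (kg/s) of the mass-based population balance:

    dM_i/dt = Min_i - c_i M_i - S_i M_i + sum_{j>i} b_{i,j} S_j M_j
    """
    inlet = np.asarray(inlet, dtype=float)
    if len(inlet) != state.grid.n:
        raise InvalidArgumentError("inlet vector must match grid size")
    c, S = _rate_vectors(state.grid, params)
    b = breakage_matrix(state.grid, params.gamma)
    M = state.holdup_mass
    return inlet - (c + S) * M + b @ (S * M)


def _system_matrix(grid: SizeGrid, params: PBMParams):
    """A such that dM/dt = inlet - A M. Upper triangular (fragments only move
    to smaller classes), with diagonal c_i + S_i."""
    c, S = _rate_vectors(grid, params)
    b = breakage_matrix(grid, params.gamma)
    A = np.diag(c + S) - b * S[np.newaxis, :]
    return A, c, S


def steady_state(
    unmilled: PSD, settings: ProcessSettings, params: PBMParams
) -> tuple[MillState, PSD]:
    """Directly solve the steady mass balance A M = Min.

    The balance is linear in the hold-up for fixed parameters and the coupling
    is triangular (breakage only creates smaller fragments), so the hold-up
    follows from one back-substitution from the largest class down. Returns the
    steady hold-up and the outlet PSD (per-class outlet mass rate c_i M_i,
    normalized; both bases populated).
    """
    inlet = inlet_rate(unmilled, settings)
    A, c, S = _system_matrix(unmilled.grid, params)
    dead = (c + S) <= 0.0
    if np.any(dead & (inlet > 0)):
        idx = int(np.argmax(dead & (inlet > 0)))
        raise MassTrapError(idx + 1, float(unmilled.grid.centers[idx]))
    if np.any(dead):
        # Classes with no throughput and no feed stay empty; regularize so the
        # triangular solve is well posed.
        A = A + np.diag(np.where(dead, 1.0, 0.0))
    M = solve_triangular(A, inlet, lower=False)
    M = np.clip(M, 0.0, None)
    outlet_rate = c * M
    outlet = PSD.from_volume(unmilled.grid, outlet_rate)
    return MillState(grid=unmilled.grid, holdup_mass=M, time=np.inf), outlet


def integrate_transient(
    unmilled: PSD,
    settings: ProcessSettings,
    params: PBMParams,
    t_end: float,
    initial: MillState | None = None,
    n_report: int = 50,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> list[MillState]:
    """Integrate the transient balance dM/dt = inlet - A M with a stiff solver.

    Starts from an empty chamber unless ``initial`` is given. Returns the
    trajectory as a list of states at ``n_report`` times; the final state
    approaches the direct steady-state solution as ``t_end`` grows.
    """
    if t_end < 0:
        raise InvalidArgumentError("t_end must be nonnegative")
    grid = unmilled.grid
    M0 = (initial.holdup_mass if initial is not None
          else np.zeros(grid.n))
    if t_end == 0:
        return [MillState(grid=grid, holdup_mass=M0.copy(), time=0.0)]
    inlet = inlet_rate(unmilled, settings)
    A, _, _ = _system_matrix(grid, params)

    def rhs(_t, M):
        return inlet - A @ M

    def jac(_t, _M):
        return -A

    t_eval = np.linspace(0.0, t_end, n_report + 1)
    sol = solve_ivp(rhs, (0.0, t_end), M0, method="BDF", jac=jac,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"transient integration failed: {sol.message} "
            f"(nfev={sol.nfev}, njev={sol.njev}, last t={sol.t[-1] if len(sol.t) else 0.0:.4g})"
        )
    return [
        MillState(grid=grid, holdup_mass=np.clip(sol.y[:, i], 0.0, None), time=float(t))
        for i, t in enumerate(sol.t)
    ]


def integrate_to_steady(
    unmilled: PSD,
    settings: ProcessSettings,
    params: PBMParams,
    tol: float = 1e-6,
    max_time: float = 1e9,
) -> MillState:
    """Integrate the transient balance until the outlet PSD settles.

    Stopping rule: the sup-norm change of the outlet volume PSD over one mean
    residence time falls below ``tol``. The residence-time scale is taken
    from the slowest throughput rate min(c_i + S_i) over classes; chunks
    double until the rule fires or ``max_time`` is reached.
    """
    c, S = _rate_vectors(unmilled.grid, params)
    rates = (c + S)[(c + S) > 0]
    if rates.size == 0:
        raise MassTrapError(1, float(unmilled.grid.centers[0]))
    tau = 1.0 / float(rates.min())
    state = MillState(grid=unmilled.grid, holdup_mass=np.zeros(unmilled.grid.n))
    elapsed = 0.0
    chunk = tau
    prev = None
    while elapsed < max_time:
        traj = integrate_transient(unmilled, settings, params, chunk,
                                   initial=state, n_report=1)
        state = traj[-1]
        elapsed += chunk
        state.time = elapsed
        cur = outlet_psd(state, params).volume_fraction
        if prev is not None and np.max(np.abs(cur - prev)) < tol:
            return state
        prev = cur
        chunk *= 2.0
    return state


def outlet_psd(state: MillState, params: PBMParams) -> PSD:
    """Outlet PSD implied by a hold-up state: per-class rate c_i M_i, normalized."""
    c, _ = _rate_vectors(state.grid, params)
    return PSD.from_volume(state.grid, c * state.holdup_mass)


def dv_percentile(psd: PSD, q: float) -> float:
    """Diameter (um) at which the cumulative volume distribution reaches ``q``.

    Log-linear interpolation of the cumulative curve across class edges.
    """
    if not (0.0 < q < 1.0):
        raise InvalidArgumentError("q must lie strictly between 0 and 1")
    cum = np.concatenate(([0.0], np.cumsum(psd.volume_fraction)))
    cum = cum / cum[-1]
    log_edges = np.log(psd.grid.edges)
    # Collapse flat runs so interpolation is well defined within empty classes
    return float(np.exp(np.interp(q, cum, log_edges)))
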