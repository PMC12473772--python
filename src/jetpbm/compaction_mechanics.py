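"""In-die mechanical and energy properties from compaction-simulator traces.

A single load-unload compaction cycle is segmented into particle
rearrangement, compaction, and decompression phases. The decompression
(unloading) segment is treated as elastic deformation of a confined compact,
from which two relations yield the elastic constants:

* radial-axial stress transmission,  d(sigma_z) = (1 - nu)/nu * d(sigma_r),
  giving the Poisson ratio nu from the slope of sigma_z against sigma_r;
* the constrained-modulus relation,
  d(sigma_z) = E (1 - nu) / ((1 + nu)(1 - 2 nu)) * d(eps_z),
  giving Young's modulus E once nu is known, with the axial strain
  eps_z = ln(rho / rho0) computed from the in-die density.

Energy parameters come from areas under the force-displacement curve: the
decompression area is the elastic work, the loading area from compaction
onset to peak is the total compression work, and their difference is the
(plastic) work of compaction. Elastic recovery is the elastic share in
percent; specific work of compaction is plastic work per gram of tablet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguousCycleError, EstimationError, InvalidArgumentError

__all__ = [
    "CompactionTrace",
    "MechProps",
    "axial_strain",
    "segment_phases",
    "estimate_poisson",
    "estimate_young",
    "energy_parameters",
    "analyze_trace",
    "percent_change",
    "PUNCH_DIAMETER_MM",
]

PUNCH_DIAMETER_MM = 6.0  # flat-faced round punches
PHASE_REARRANGEMENT = "rearrangement"
PHASE_COMPACTION = "compaction"
PHASE_DECOMPRESSION = "decompression"


@dataclass
class CompactionTrace:
    """One load-unload compaction cycle.

    time : s
    punch_separation : mm (distance between punch faces; in-die tablet height)
    axial_force : N
    radial_stress : MPa (mean of the two die-wall sensors)
    tablet_mass : g
    initial_density : rho0 of the powder bed before compression, kg/m^3
    die_diameter : mm (defaults to the punch diameter)
    """

    time: np.ndarray
    punch_separation: np.ndarray
    axial_force: np.ndarray
    radial_stress: np.ndarray
    tablet_mass: float
    initial_density: float
    die_diameter: float = PUNCH_DIAMETER_MM

    def __post_init__(self):
        for name in ("time", "punch_separation", "axial_force", "radial_stress"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        for name in ("punch_separation", "axial_force", "radial_stress"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError("trace series must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if np.any(self.punch_separation <= 0):
            raise InvalidArgumentError("punch separation must stay positive")
        if np.any(self.axial_force < 0) or np.any(self.radial_stress < 0):
            raise InvalidArgumentError("stresses must be nonnegative")
        if self.tablet_mass <= 0 or self.initial_density <= 0:
            raise InvalidArgumentError("tablet mass and initial density must be positive")

    @property
    def punch_area_mm2(self) -> float:
        return np.pi * (PUNCH_DIAMETER_MM / 2.0) ** 2

    @property
    def axial_stress(self) -> np.ndarray:
        """Axial stress in MPa (N / mm^2)."""
        return self.axial_force / self.punch_area_mm2

    @property
    def in_die_density(self) -> np.ndarray:
        """Powder density (kg/m^3) from tablet mass and in-die volume."""
        area_m2 = np.pi * (self.die_diameter * 1e-3 / 2.0) ** 2
        volume_m3 = area_m2 * self.punch_separation * 1e-3
        return self.tablet_mass * 1e-3 / volume_m3


@dataclass(frozen=True)
class MechProps:
    """Derived in-die properties of one material.

    young_modulus in GPa; energies in J; elastic_recovery in percent;
    swc (specific work of compaction) in J/g.
    """

    young_modulus: float
    poisson_ratio: float
    w_elastic: float = np.nan
    w_compact: float = np.nan
    w_compress: float = np.nan
    elastic_recovery: float = np.nan
    swc: float = np.nan

    def __post_init__(self):
        if not (0.0 < self.poisson_ratio < 0.5):
            raise InvalidArgumentError("poisson_ratio must lie in (0, 0.5)")
        if self.young_modulus <= 0:
            raise InvalidArgumentError("young_modulus must be positive")


def axial_strain(rho0: float, rho) -> np.ndarray | float:
    """Logarithmic axial strain ln(rho / rho0) of the confined compact."""
    rho = np.asarray(rho, dtype=float)
    if rho0 <= 0 or np.any(rho <= 0):
        raise InvalidArgumentError("densities must be positive")
    out = np.log(rho / rho0)
    return out if out.ndim else float(out)


def segment_phases(trace: CompactionTrace, onset_fraction: float = 0.01) -> np.ndarray:
    """Label each sample rearrangement / compaction / decompression.

    Compaction starts when the axial force first exceeds ``onset_fraction`` of
    the peak; decompression starts at the force peak. A trace whose force has
    two well-separated near-maximal peaks is rejected as more than one cycle.
    """
    f = trace.axial_force
    peak = f.max()
    if peak <= 0:
        raise InvalidArgumentError("trace carries no load")
    near_peak = np.flatnonzero(f >= 0.95 * peak)
    if np.any(np.diff(near_peak) > max(3, len(f) // 20)):
        raise AmbiguousCycleError("multiple force peaks detected; expected one cycle")
    i_peak = int(np.argmax(f))
    i_onset = int(np.argmax(f > onset_fraction * peak))
    labels = np.full(len(f), PHASE_COMPACTION, dtype=object)
    labels[:i_onset] = PHASE_REARRANGEMENT
    labels[i_peak:] = PHASE_DECOMPRESSION
    return labels


def _decompression_slice(trace: CompactionTrace) -> slice:
    labels = segment_phases(trace)
    start = int(np.argmax(labels == PHASE_DECOMPRESSION))
    return slice(start, len(labels))


def estimate_poisson(trace: CompactionTrace) -> float:
    """Poisson ratio from the unloading segment.

    Ordinary least squares of axial on radial stress over decompression gives
    the transmission slope m = (1 - nu)/nu, hence nu = 1/(1 + m).
    """
    sl = _decompression_slice(trace)
    sz = trace.axial_stress[sl]
    sr = trace.radial_stress[sl]
    if len(sz) < 5:
        raise EstimationError("decompression segment too short (need >= 5 samples)")
    if np.ptp(sr) <= 0:
        raise EstimationError("radial stress constant during decompression")
    m = np.polyfit(sr, sz, 1)[0]
    nu = 1.0 / (1.0 + m)
    if not (0.0 < nu < 0.5 - 1e-9):
        import warnings

        warnings.warn(f"estimated Poisson ratio {nu:.4f} outside (0, 0.5)", stacklevel=2)
    return float(nu)


def estimate_young(trace: CompactionTrace, nu: float) -> float:
    """Young's modulus (GPa) from the unloading stress-strain slope.

    The axial stress is regressed on the logarithmic strain from the in-die
    density over decompression; the constrained-modulus factor
    (1 + nu)(1 - 2 nu)/(1 - nu) converts the slope to E.
    """
    if not (0.0 < nu < 0.5):
        raise InvalidArgumentError("nu must lie in (0, 0.5) for the constrained modulus")
    sl = _decompression_slice(trace)
    sz = trace.axial_stress[sl]
    eps = axial_strain(trace.initial_density, trace.in_die_density[sl])
    if np.ptp(eps) <= 0:
        raise EstimationError("strain constant during decompression")
    s = np.polyfit(eps, sz, 1)[0]  # MPa per unit strain
    e_gpa = s * (1.0 + nu) * (1.0 - 2.0 * nu) / (1.0 - nu) * 1e-3
    return float(e_gpa)


def energy_parameters(trace: CompactionTrace) -> dict:
    """Work terms (J) from the force-displacement curve, plus ER (%) and SWC (J/g).

    Displacement is punch travel (decreasing separation). The loading branch
    from compaction onset to peak integrates to the compression work; the
    unloading branch integrates to the elastic work; compaction (plastic)
    work is their difference, so the additivity
    w_compress = w_compact + w_elastic is exact by construction.
    """
    segment_phases(trace)  # validates a single load-unload cycle
    f = trace.axial_force  # N
    x = -trace.punch_separation * 1e-3  # m, increasing with punch travel
    i_peak = int(np.argmax(f))
    w_compress = float(np.trapezoid(f[: i_peak + 1], x[: i_peak + 1]))
    w_elastic = float(-np.trapezoid(f[i_peak:], x[i_peak:]))
    w_compress = max(w_compress, 0.0)
    w_elastic = min(max(w_elastic, 0.0), w_compress) if w_compress > 0 else 0.0
    w_compact = w_compress - w_elastic
    er = 100.0 * w_elastic / w_compress if w_compress > 0 else 0.0
    swc = w_compact / trace.tablet_mass
    return {
        "w_elastic": w_elastic,
        "w_compact": w_compact,
        "w_compress": w_compress,
        "elastic_recovery": er,
        "swc": swc,
    }


def analyze_trace(trace: CompactionTrace) -> MechProps:
    """Full per-trace analysis: nu, E, and the energy parameters."""
    nu = estimate_poisson(trace)
    e = estimate_young(trace, nu)
    energies = energy_parameters(trace)
    return MechProps(young_modulus=e, poisson_ratio=nu, **energies)


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``; reporting utility for
    comparing a property measured at two size grades."""
    if before <= 0:
        raise InvalidArgumentError("baseline value must be positive")
    return 100.0 * (after - before) / before
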