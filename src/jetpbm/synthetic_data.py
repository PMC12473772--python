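"""Synthetic inputs with known ground truth for the whole pipeline.

Real milling campaigns of this kind are material-limited: a handful of API
grades, a 2x2 factorial with centerpoints per grade, laser-diffraction PSDs
and compaction traces. This module emulates such a campaign end to end so
that every estimator in the package can be exercised against a known answer:

* unmilled PSDs are discretized log-normals spanning the studied grade
  envelope (median diameters roughly 10-105 um);
* compaction traces are three-phase load-unload cycles whose unloading
  segment satisfies the radial-transmission and constrained-modulus
  relations exactly for a chosen (E, nu);
* milled PSDs come from the forward PBM at parameters produced by a
  material-and-settings link rule with the mechanistic directions observed
  in jet milling (higher gas flow lowers the critical breakage size and the
  classifier cut; stiffer materials break faster), plus multiplicative
  measurement noise;
* DoE tables assemble the factorial responses with their generating truth.

Noise is multiplicative log-normal on per-class volume fractions followed by
renormalization, mimicking replicate scatter of laser-diffraction data. All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compaction_mechanics import CompactionTrace, MechProps, PUNCH_DIAMETER_MM
from .doe_stats import DoETable, code_factor, full_factorial_design
from .errors import InvalidArgumentError
from .pbm_core import (
    DEFAULT_GRID,
    PBMParams,
    ProcessSettings,
    PSD,
    SizeGrid,
    steady_state,
)

__all__ = [
    "MaterialSpec",
    "LinkRule",
    "DEFAULT_LINK",
    "default_material_library",
    "gen_unmilled_psd",
    "gen_compaction_trace",
    "gen_milled_psd",
    "gen_doe_dataset",
]


@dataclass(frozen=True)
class LinkRule:
    """Rule mapping (settings, material mechanics) to PBM parameters.

    The directions encode the studied mechanisms: the critical breakage size
    and the classifier cut shrink log-linearly with coded gas flow rate
    (more kinetic energy per particle), the breakage coefficient grows
    log-linearly with Young's modulus (stiffer particles store and release
    fracture energy more efficiently), and a weak choking term lets high
    feed rate push the cut size up. Magnitudes are package choices, exposed
    here for configuration.
    """

    xcrit_base_um: float = 3.0
    xcrit_gfr_slope: float = 0.6    # ln(xcrit) drop per unit coded GFR
    cut_base_um: float = 12.0
    cut_gfr_slope: float = 0.5      # ln(cut) drop per unit coded GFR
    cut_mfr_slope: float = 0.1      # ln(cut) rise per unit coded MFR (choking)
    sigma_c: float = 0.5
    alpha_base: float = 30.0        # 1/s at the reference modulus
    alpha_e_slope: float = 0.35     # ln(alpha) rise per GPa above reference
    e_ref_gpa: float = 5.0
    k: float = 1.0

    def params(self, settings: ProcessSettings, mech: MechProps,
               gamma: float, lam: float) -> PBMParams:
        g = code_factor(settings.gfr, "GFR")
        m = code_factor(settings.mfr, "MFR")
        xcrit = self.xcrit_base_um * np.exp(-self.xcrit_gfr_slope * g)
        cut = self.cut_base_um * np.exp(-self.cut_gfr_slope * g + self.cut_mfr_slope * m)
        alpha = self.alpha_base * np.exp(
            self.alpha_e_slope * (mech.young_modulus - self.e_ref_gpa)
        )
        return PBMParams(alpha=float(alpha), lam=lam, gamma=gamma,
                         xcrit=float(xcrit), mu_c=float(np.log(cut)),
                         sigma_c=self.sigma_c, k=self.k)


DEFAULT_LINK = LinkRule()


@dataclass(frozen=True)
class MaterialSpec:
    """Ground-truth description of one API grade.

    psd_median_um / psd_gsd : log-normal volume PSD of the unmilled powder.
    Measured unmilled PSDs are often skewed in log size, so an optional
    ``psd_gsd_upper`` turns the shape into a split log-normal: ``psd_gsd``
    governs the half below the median, ``psd_gsd_upper`` the half above.
    true_mech : in-die mechanical ground truth
    gamma, lam : material-specific breakage shape constants
    density : particle density, kg/m^3
    """

    name: str
    psd_median_um: float
    psd_gsd: float
    true_mech: MechProps
    psd_gsd_upper: float | None = None
    gamma: float = 0.8
    lam: float = 1.0
    density: float = 1300.0
    link: LinkRule = DEFAULT_LINK

    def __post_init__(self):
        if not (5.0 <= self.psd_median_um <= 150.0):
            raise InvalidArgumentError(
                "unmilled median must lie in the studied 5-150 um envelope"
            )
        if self.psd_gsd < 1.0 or (self.psd_gsd_upper is not None
                                  and self.psd_gsd_upper < 1.0):
            raise InvalidArgumentError("geometric standard deviation must be >= 1")

    def pbm_params(self, settings: ProcessSettings) -> PBMParams:
        return self.link.params(settings, self.true_mech, self.gamma, self.lam)


_Z90 = 1.281552  # standard-normal quantile at 90 %


def _gsds_from_dv(dv10: float, dv50: float, dv90: float) -> tuple[float, float]:
    # each tail's geometric sd chosen so the split log-normal hits all three
    # dv targets: dv10 = dv50 * gsd_lo^-z90, dv90 = dv50 * gsd_hi^z90
    return (float(np.exp(np.log(dv50 / dv10) / _Z90)),
            float(np.exp(np.log(dv90 / dv50) / _Z90)))


def _mech(e_gpa, nu, er_pct, swc) -> MechProps:
    return MechProps(young_modulus=e_gpa, poisson_ratio=nu,
                     elastic_recovery=er_pct, swc=swc)


def default_material_library() -> list[MaterialSpec]:
    """Eight synthetic grades spanning the studied unmilled-size envelope.

    Names and dv targets mirror the kind of grade set used in jet-milling
    campaigns (two habits each of two APIs, three habits of a third, one
    grade of a fourth); the mechanical values are synthetic but plausible,
    with the stiffer grades carrying the coarser unmilled sizes.
    """
    rows = [
        # name,      dv10, dv50, dv90,  E GPa,  nu,   ER %, SWC J/g
        ("KetH1",      28,   52,   88,   6.65, 0.26,  18.0,  9.0),
        ("KetOG",       3,   10,   21,   3.83, 0.33,  26.0, 12.0),
        ("MetH1",      46,   99,  171,  11.00, 0.20,  30.0,  7.0),
        ("MetH2",      57,  105,  170,  11.50, 0.19,  31.0,  7.5),
        ("MetH3",      21,   84,  170,  10.20, 0.21,  28.0,  8.0),
        ("DompH1",     12,   36,   79,   5.90, 0.28,  20.0, 10.0),
        ("DompOG",      4,   10,   28,   4.40, 0.31,  22.0, 11.0),
        ("IndOG",      12,   40,  117,   5.20, 0.29,  24.0, 10.5),
    ]
    out = []
    for name, dv10, dv50, dv90, e, nu, er, swc in rows:
        gsd_lo, gsd_hi = _gsds_from_dv(dv10, dv50, dv90)
        out.append(MaterialSpec(name=name, psd_median_um=dv50, psd_gsd=gsd_lo,
                                psd_gsd_upper=gsd_hi,
                                true_mech=_mech(e, nu, er, swc)))
    return out


def _apply_psd_noise(grid: SizeGrid, volume_fraction: np.ndarray,
                     noise_sd: float, rng: np.random.Generator) -> PSD:
    vf = volume_fraction
    if noise_sd > 0:
        vf = vf * np.exp(rng.normal(0.0, noise_sd, size=len(vf)))
    return PSD.from_volume(grid, vf)


def gen_unmilled_psd(spec: MaterialSpec, grid: SizeGrid = DEFAULT_GRID,
                     seed: int = 0, noise_sd: float = 0.0) -> PSD:
    """Discretized log-normal volume PSD of the unmilled material."""
    med = spec.psd_median_um
    gsd_lo = spec.psd_gsd
    gsd_hi = spec.psd_gsd_upper if spec.psd_gsd_upper is not None else gsd_lo
    if not (grid.edges[0] < med < grid.edges[-1]):
        raise InvalidArgumentError("material median outside the grid span")
    if gsd_lo <= 1.0 + 1e-12 and gsd_hi <= 1.0 + 1e-12:
        vf = np.zeros(grid.n)
        vf[np.searchsorted(grid.edges, med) - 1] = 1.0
    else:
        from scipy.stats import norm

        lx = np.log(grid.edges) - np.log(med)
        z = np.where(lx < 0, lx / np.log(gsd_lo), lx / np.log(gsd_hi))
        vf = np.diff(norm.cdf(z))
    rng = np.random.default_rng(seed)
    return _apply_psd_noise(grid, vf, noise_sd, rng)


def gen_compaction_trace(
    true_mech: MechProps,
    peak_force_kn: float = 10.0,
    tablet_mass_g: float = 0.12,
    initial_density: float = 600.0,
    true_density: float = 1300.0,
    n_per_phase: int = 120,
    radial_residual_frac: float = 0.05,
    elastic_only: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CompactionTrace:
    """Three-phase compaction cycle consistent with a known (E, nu).

    The unloading branch is built so axial stress is exactly linear in both
    the radial stress (slope (1-nu)/nu) and the logarithmic strain (slope
    equal to the constrained modulus), making the mechanical estimators
    invertible at zero noise. With ``elastic_only`` the loading branch
    retraces the elastic unloading path, so the cycle closes and the elastic
    recovery is 100 percent. ``noise_sd`` adds multiplicative Gaussian noise
    to force and radial stress.
    """
    nu, e_gpa = true_mech.poisson_ratio, true_mech.young_modulus
    area_mm2 = np.pi * (PUNCH_DIAMETER_MM / 2.0) ** 2
    area_m2 = area_mm2 * 1e-6
    h0_mm = tablet_mass_g * 1e-3 / (initial_density * area_m2) * 1e3
    h_peak_mm = h0_mm * initial_density / true_density

    sz_peak = peak_force_kn * 1e3 / area_mm2  # MPa
    s_mpa = e_gpa * 1e3 * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    eps_peak = np.log(true_density / initial_density)
    eps_end = eps_peak - sz_peak / s_mpa  # unload to zero axial stress
    if eps_end <= 0:
        raise InvalidArgumentError(
            "elastic rebound exceeds total densification; raise the modulus "
            "or lower the peak force"
        )
    ratio = nu / (1 - nu)
    sr_res = radial_residual_frac * sz_peak

    # decompression: axial stress linear in strain and in radial stress
    eps_down = np.linspace(eps_peak, eps_end, n_per_phase)
    sz_down = np.maximum(sz_peak + s_mpa * (eps_down - eps_peak), 0.0)
    sr_down = sr_res + ratio * sz_down
    h_down = h0_mm * np.exp(-eps_down)

    if elastic_only:
        eps_up = eps_down[::-1]
        sz_up = sz_down[::-1]
        sr_up = sr_down[::-1]
        h_up = h_down[::-1]
        h = np.concatenate((h_up, h_down[1:]))
        sz = np.concatenate((sz_up, sz_down[1:]))
        sr = np.concatenate((sr_up, sr_down[1:]))
    else:
        # rearrangement: die filling collapses loosely packed powder at ~zero load
        h_re = np.linspace(h0_mm, h0_mm * 0.9, n_per_phase // 3)
        sz_re = np.linspace(0.0, 0.005 * sz_peak, len(h_re))
        sr_re = 0.5 * ratio * sz_re
        # compaction: quadratic force rise; loading ends at the peak-stress
        # point of the elastic branch so the unload joins continuously
        frac = np.linspace(0.0, 1.0, n_per_phase)
        h_co = np.linspace(h_re[-1], h_down[0], n_per_phase)[1:]
        sz_co = 0.005 * sz_peak + (sz_peak - 0.005 * sz_peak) * frac[1:-1] ** 2
        sz_co = np.append(sz_co, sz_peak)
        # radial stress proportional to axial so the loading branch meets the
        # elastic unloading line exactly at the force peak
        sr_co = (sr_res + ratio * sz_peak) * sz_co / sz_peak
        h = np.concatenate((h_re, h_co, h_down[1:]))
        sz = np.concatenate((sz_re, sz_co, sz_down[1:]))
        sr = np.concatenate((sr_re, sr_co, sr_down[1:]))

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sz = sz * (1.0 + rng.normal(0.0, noise_sd, len(sz)))
        sr = sr * (1.0 + rng.normal(0.0, noise_sd, len(sr)))
        sz = np.clip(sz, 0.0, None)
        sr = np.clip(sr, 0.0, None)

    t = np.arange(len(h), dtype=float) * 1e-3
    return CompactionTrace(
        time=t,
        punch_separation=h,
        axial_force=sz * area_mm2,
        radial_stress=sr,
        tablet_mass=tablet_mass_g,
        initial_density=initial_density,
    )


def gen_milled_psd(
    spec: MaterialSpec,
    settings: ProcessSettings,
    grid: SizeGrid = DEFAULT_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    unmilled: PSD | None = None,
) -> tuple[PSD, PBMParams]:
    """Milled PSD by forward steady-state simulation at the link parameters.

    Returns the noisy observed PSD and the generating parameters, the ground
    truth for calibration-recovery tests.
    """
    if unmilled is None:
        unmilled = gen_unmilled_psd(spec, grid, seed=seed)
    params = spec.pbm_params(settings)
    _, outlet = steady_state(unmilled, settings, params)
    rng = np.random.default_rng(seed + 1)
    observed = _apply_psd_noise(grid, outlet.volume_fraction, noise_sd, rng)
    return observed, params


def gen_doe_dataset(
    materials: list[MaterialSpec],
    n_center: int = 1,
    grid: SizeGrid = DEFAULT_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoETable:
    """Full-factorial milling campaign over a material library.

    One row per (material, run): factor settings in physical and coded units,
    unmilled and milled dv-values, performance ratios, material ground truth,
    and the generating PBM parameters.
    """
    if not materials:
        raise InvalidArgumentError("need at least one material")
    design = full_factorial_design(n_center=n_center)
    rows = []
    run_seed = seed
    for mat in materials:
        unmilled = gen_unmilled_psd(mat, grid, seed=run_seed)
        for _, run in design.iterrows():
            settings = ProcessSettings(gfr=run["GFR"], mfr=run["MFR"],
                                       density=mat.density)
            milled, params = gen_milled_psd(mat, settings, grid,
                                            noise_sd=noise_sd, seed=run_seed,
                                            unmilled=unmilled)
            rows.append({
                "material": mat.name,
                "GFR": run["GFR"], "MFR": run["MFR"],
                "GFR_coded": run["GFR_coded"], "MFR_coded": run["MFR_coded"],
                "dv10_unmilled": unmilled.dv10,
                "dv50_unmilled": unmilled.dv50,
                "dv90_unmilled": unmilled.dv90,
                "dv10": milled.dv10, "dv50": milled.dv50, "dv90": milled.dv90,
                "ratio_dv10": unmilled.dv10 / milled.dv10,
                "ratio_dv50": unmilled.dv50 / milled.dv50,
                "ratio_dv90": unmilled.dv90 / milled.dv90,
                "E": mat.true_mech.young_modulus,
                "nu": mat.true_mech.poisson_ratio,
                "ER": mat.true_mech.elastic_recovery,
                "SWC": mat.true_mech.swc,
                "alpha_true": params.alpha,
                "lam_true": params.lam,
                "gamma_true": params.gamma,
                "xcrit_true": params.xcrit,
                "mu_c_true": params.mu_c,
                "sigma_c_true": params.sigma_c,
            })
            run_seed += 1
    return DoETable(data=pd.DataFrame(rows))
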