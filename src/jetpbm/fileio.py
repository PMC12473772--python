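"""Readers, writers, and run configuration.

PSD CSVs follow the two dialects laser-diffraction software exports:
``size_um, cum_volume_pct`` (cumulative, 0-100) or ``size_um, vol_frac``
(per-bin density). Measured PSDs are rebinned onto the model grid by
proportional allocation in log size, which conserves total volume exactly.
Compaction traces are CSVs with a YAML sidecar for scalar metadata. Results
are JSON with the configuration hash embedded for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import SwarmConfig
from .compaction_mechanics import CompactionTrace
from .errors import FormatError, InvalidArgumentError
from .pbm_core import DEFAULT_GRID_SPEC, PSD, SizeGrid, make_grid

__all__ = [
    "RunConfig",
    "read_psd",
    "write_psd",
    "read_compaction_trace",
    "write_compaction_trace",
    "rebin_volume_fractions",
    "psd_to_json_dict",
    "write_json",
]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults."""

    grid_x_min: float = DEFAULT_GRID_SPEC[0]   # um
    grid_x_max: float = DEFAULT_GRID_SPEC[1]   # um
    grid_n: int = DEFAULT_GRID_SPEC[2]
    k: float = 1.0                             # classifier scale, 1/s
    pso: SwarmConfig = field(default_factory=SwarmConfig)
    mmd_bandwidth: float | None = None         # None = median heuristic
    xcrit_quantile: float = 0.10
    phase_onset_fraction: float = 0.01
    seed: int = 0
    output_dir: str = "results"

    def grid(self) -> SizeGrid:
        return make_grid(self.grid_x_min, self.grid_x_max, self.grid_n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pso" in d and isinstance(d["pso"], dict):
            d["pso"] = SwarmConfig(**d["pso"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def rebin_volume_fractions(src_edges: np.ndarray, src_fractions: np.ndarray,
                           grid: SizeGrid) -> np.ndarray:
    """Proportionally allocate per-bin volume onto the model grid in log size.

    Each source bin's volume is split over the target classes it overlaps,
    weighted by the overlapped width in log size; total volume is conserved.
    """
    s_lo, s_hi = np.log(src_edges[:-1]), np.log(src_edges[1:])
    t_lo, t_hi = np.log(grid.edges[:-1]), np.log(grid.edges[1:])
    overlap = np.maximum(
        0.0,
        np.minimum(s_hi[:, None], t_hi[None, :])
        - np.maximum(s_lo[:, None], t_lo[None, :]),
    )
    width = (s_hi - s_lo)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(width > 0, overlap / width, 0.0)
    out = src_fractions @ weights
    lost = src_fractions.sum() - out.sum()
    if lost > 1e-9 * max(src_fractions.sum(), 1e-300):
        raise InvalidArgumentError(
            "source PSD extends beyond the model grid; widen the grid"
        )
    return out


def read_psd(path, grid: SizeGrid | None = None,
             dialect: str = "auto") -> PSD:
    """Read a PSD CSV in either the cumulative or the density dialect.

    Cumulative files give ``cum_volume_pct`` at the upper edge of each bin
    (0-100, non-decreasing); density files give per-bin ``vol_frac``. The
    first size row of a cumulative file may carry the lower edge with 0 %.
    The result is rebinned onto ``grid`` (default model grid) and normalized.
    """
    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "size_um" not in cols:
        raise FormatError(f"{path}: missing 'size_um' column")
    size = df[cols["size_um"]].to_numpy(float)
    if np.any(size <= 0) or np.any(np.diff(size) <= 0):
        raise FormatError(f"{path}: sizes must be positive and increasing")
    if dialect == "auto":
        # prefer the density column: it is lossless and rides on bin centers
        if "vol_frac" in cols:
            dialect = "density"
        elif "cum_volume_pct" in cols:
            dialect = "cumulative"
        else:
            raise FormatError(
                f"{path}: expected a 'cum_volume_pct' or 'vol_frac' column"
            )
    if dialect == "cumulative":
        cum = df[cols["cum_volume_pct"]].to_numpy(float) / 100.0
        bad = np.flatnonzero(np.diff(cum) < -1e-12)
        if bad.size:
            # +3: header line, 1-based numbering, and the decrease shows at
            # the second row of the offending pair
            raise FormatError(
                f"{path}: cumulative column decreases at row {bad[0] + 3}"
            )
        if cum[0] > 1e-12:
            # first row is already a filled bin; treat a synthetic lower edge
            size = np.concatenate(([size[0] ** 2 / size[1]], size))
            cum = np.concatenate(([0.0], cum))
        edges = size
        fractions = np.diff(cum)
    else:
        frac = df[cols["vol_frac"]].to_numpy(float)
        if np.any(frac < 0):
            raise FormatError(f"{path}: negative volume fraction")
        # density rows are bin centers; rebuild geometric edges around them
        half = np.sqrt(size[1] / size[0])
        edges = np.concatenate(([size[0] / half], size * half))
        fractions = frac
    if np.any(fractions < -1e-12):
        raise FormatError(f"{path}: negative bin volume after differencing")
    fractions = np.clip(fractions, 0.0, None)
    grid = grid or make_grid(*DEFAULT_GRID_SPEC)
    vf = rebin_volume_fractions(edges, fractions, grid)
    return PSD.from_volume(grid, vf)


def write_psd(psd: PSD, path) -> None:
    """Write a PSD CSV carrying both dialects (density and cumulative)."""
    cum = np.cumsum(psd.volume_fraction)
    df = pd.DataFrame({
        "size_um": psd.grid.centers,
        "vol_frac": psd.volume_fraction,
        "cum_volume_pct": 100.0 * cum / cum[-1],
    })
    df.to_csv(path, index=False)


def write_compaction_trace(trace: CompactionTrace, csv_path,
                           meta_path=None) -> None:
    df = pd.DataFrame({
        "time_s": trace.time,
        "separation_mm": trace.punch_separation,
        "force_N": trace.axial_force,
        "radial_stress_MPa": trace.radial_stress,
    })
    df.to_csv(csv_path, index=False)
    meta = {
        "tablet_mass_g": trace.tablet_mass,
        "initial_density_kg_m3": trace.initial_density,
        "die_diameter_mm": trace.die_diameter,
    }
    meta_path = meta_path or Path(csv_path).with_suffix(".yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_compaction_trace(csv_path, meta_path=None) -> CompactionTrace:
    df = pd.read_csv(csv_path, comment="#")
    required = {"time_s", "separation_mm", "force_N", "radial_stress_MPa"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{csv_path}: missing columns {sorted(missing)}")
    meta_path = meta_path or Path(csv_path).with_suffix(".yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    return CompactionTrace(
        time=df["time_s"].to_numpy(float),
        punch_separation=df["separation_mm"].to_numpy(float),
        axial_force=df["force_N"].to_numpy(float),
        radial_stress=df["radial_stress_MPa"].to_numpy(float),
        tablet_mass=float(meta["tablet_mass_g"]),
        initial_density=float(meta["initial_density_kg_m3"]),
        die_diameter=float(meta.get("die_diameter_mm", 6.0)),
    )


def psd_to_json_dict(psd: PSD) -> dict:
    return {
        "size_um": psd.grid.centers.tolist(),
        "volume_fraction": psd.volume_fraction.tolist(),
        "number_fraction": psd.number_fraction.tolist(),
        "dv10": psd.dv10,
        "dv50": psd.dv50,
        "dv90": psd.dv90,
    }


def write_json(obj: dict, path, config: RunConfig | None = None) -> None:
    """Write a results JSON, embedding provenance when a config is given."""
    out = dict(obj)
    if config is not None:
        out["_provenance"] = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "package": "jetpbm 0.1.0",
        }

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=default)
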