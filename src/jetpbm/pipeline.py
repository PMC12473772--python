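"""End-to-end orchestration: mechanics, per-experiment calibration, DoE stats.

The pipeline consumes a campaign directory (as produced by ``jetpbm synth``
or assembled from measured exports): per-material unmilled PSD CSVs and
compaction trace CSVs, plus a DoE table with one milling experiment per row.
It derives mechanical properties per material, calibrates the PBM per
experiment, fits the MLR response models, and runs PCA on the material
properties and PLS linking material properties and process settings to the
calibrated PBM parameters. All randomness derives from the single seed in
the run configuration.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import compaction_mechanics as mech
from . import doe_stats
from .errors import JetPBMError
from .fileio import RunConfig, read_compaction_trace, read_psd, write_json
from .pbm_core import PBMParams, ProcessSettings, PSD, steady_state
from .synthetic_data import gen_milled_psd  # noqa: F401 (re-export convenience)

log = logging.getLogger("jetpbm.pipeline")

__all__ = ["run_pipeline", "calibrate_experiment"]


def calibrate_experiment(unmilled: PSD, milled: PSD, settings: ProcessSettings,
                         config: RunConfig, seed: int) -> dict:
    """Staged identification + PSO estimation for one experiment."""
    mu_c, sigma_c = cal.identify_classifier(milled)
    xcrit = cal.identify_xcrit(milled, config.xcrit_quantile)
    fixed = PBMParams(alpha=1.0, lam=1.0, gamma=1.0, xcrit=xcrit,
                      mu_c=mu_c, sigma_c=sigma_c, k=config.k)
    problem = cal.CalibrationProblem(unmilled=unmilled, milled_observed=milled,
                                     settings=settings, fixed=fixed, seed=seed)
    result = cal.pso_calibrate(problem, config.pso, config.mmd_bandwidth)
    return {
        "mu_c": mu_c, "sigma_c": sigma_c, "xcrit": xcrit, "k": config.k,
        "alpha": result.params.alpha, "gamma": result.params.gamma,
        "lam": result.params.lam, "objective": result.objective,
        "seed": seed,
    }


def run_pipeline(config: RunConfig, data_dir) -> dict:
    """Run the full chain on a campaign directory; returns the results bundle.

    Expects ``doe.csv`` plus ``<material>_unmilled.csv`` and
    ``<material>_trace.csv`` per material. Writes per-stage JSON/CSV outputs
    under ``config.output_dir``.
    """
    data_dir = Path(data_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    doe_path = data_dir / "doe.csv"
    if not doe_path.exists():
        raise JetPBMError(f"missing input file: {doe_path}")
    table = doe_stats.DoETable(pd.read_csv(doe_path))
    bundle: dict = {}

    # Stage 1: mechanics per material
    t0 = time.perf_counter()
    mech_rows = {}
    for name in table.data["material"].unique():
        trace_path = data_dir / f"{name}_trace.csv"
        if not trace_path.exists():
            raise JetPBMError(f"missing input file: {trace_path}")
        props = mech.analyze_trace(read_compaction_trace(trace_path))
        mech_rows[name] = props.__dict__
    bundle["mechanics"] = mech_rows
    log.info("mechanics stage: %.2f s", time.perf_counter() - t0)

    # Stage 2: per-experiment PBM calibration (needs milled PSD columns or files)
    t0 = time.perf_counter()
    calibs = []
    unmilled_cache = {}
    for idx, row in table.data.iterrows():
        name = row["material"]
        if name not in unmilled_cache:
            upath = data_dir / f"{name}_unmilled.csv"
            if not upath.exists():
                raise JetPBMError(f"missing input file: {upath}")
            unmilled_cache[name] = read_psd(upath, grid)
        milled_path = data_dir / f"milled_{idx}.csv"
        if milled_path.exists():
            milled = read_psd(milled_path, grid)
        else:
            # regenerate the forward-simulated milled PSD from the table truth
            truth_cols = {"alpha_true", "gamma_true", "lam_true", "xcrit_true",
                          "mu_c_true", "sigma_c_true"}
            if not truth_cols <= set(table.data.columns):
                raise JetPBMError(
                    f"missing input file: {milled_path} (and no ground-truth "
                    "columns to regenerate it)"
                )
            params = PBMParams(alpha=row["alpha_true"], gamma=row["gamma_true"],
                               lam=row["lam_true"], xcrit=row["xcrit_true"],
                               mu_c=row["mu_c_true"], sigma_c=row["sigma_c_true"],
                               k=config.k)
            settings = ProcessSettings(gfr=row["GFR"], mfr=row["MFR"])
            _, milled = steady_state(unmilled_cache[name], settings, params)
        settings = ProcessSettings(gfr=row["GFR"], mfr=row["MFR"])
        res = calibrate_experiment(unmilled_cache[name], milled, settings,
                                   config, seed=config.seed + int(idx))
        res["material"] = name
        res["GFR"], res["MFR"] = row["GFR"], row["MFR"]
        calibs.append(res)
    calib_df = pd.DataFrame(calibs)
    calib_df.to_csv(outdir / "calibrations.csv", index=False)
    bundle["calibrations"] = calib_df
    log.info("calibration stage: %.2f s", time.perf_counter() - t0)

    # Stage 3: MLR response models per material
    t0 = time.perf_counter()
    mlr = {}
    for name, sub in table.data.groupby("material"):
        sub_table = doe_stats.DoETable(sub.reset_index(drop=True))
        for response in ("dv10", "dv50", "dv90"):
            if response not in sub.columns:
                continue
            fit = doe_stats.fit_mlr(sub_table, response, ["GFR", "MFR"])
            mlr[f"{name}/{response}"] = {
                "coefficients": fit.coefficients, "r2": fit.r2, "q2": fit.q2,
            }
    bundle["mlr"] = mlr
    log.info("MLR stage: %.2f s", time.perf_counter() - t0)

    # Stage 4: PCA on material properties; PLS settings+properties -> PBM params
    t0 = time.perf_counter()
    prop_cols = ["E", "nu", "ER", "SWC"]
    mat_props = table.data.groupby("material")[prop_cols].first()
    if len(mat_props) >= 3:
        bundle["pca"] = doe_stats.fit_pca(mat_props, n_components=2)
    X = calib_df.merge(
        table.data[["material", "GFR", "MFR", "E", "nu", "ER", "SWC"]]
        .drop_duplicates(),
        on=["material", "GFR", "MFR"], how="left",
    )
    predictors = X[["GFR", "MFR", "E", "nu", "ER", "SWC"]]
    responses = np.column_stack([
        np.log(X["alpha"].to_numpy(float)),
        X["lam"].to_numpy(float),
        np.log(X["xcrit"].to_numpy(float)),
    ])
    responses = pd.DataFrame(responses, columns=["log_alpha", "lam", "log_xcrit"])
    bundle["pls"] = doe_stats.fit_pls(predictors, responses, n_components=2)
    bundle["vip"] = doe_stats.variable_importance(bundle["pls"])
    log.info("latent-variable stage: %.2f s", time.perf_counter() - t0)

    write_json({
        "mechanics": mech_rows,
        "mlr": mlr,
        "pls_r2_cumulative": bundle["pls"].r2_cumulative,
        "vip": dict(bundle["vip"]),
    }, outdir / "summary.json", config)
    return bundle
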