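"""DoE regression and latent-variable analysis of milling experiments.

A 2x2 full factorial in gas flow rate (GFR) and solids feed rate (MFR) with
centerpoints is the experimental backbone. Per-response multiple linear
regression on coded factors quantifies main, interaction, and curvature
effects; goodness of prediction is the leave-one-out Q^2 = 1 - PRESS/TSS.
PCA summarizes the in-die material-property block, and PLS links material
properties plus process settings to milling performance or to calibrated PBM
parameters, with variable-importance-in-projection (VIP) scores ranking the
predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import EstimationError, InvalidArgumentError

__all__ = [
    "FACTOR_LEVELS",
    "DoETable",
    "MLRResult",
    "LatentModel",
    "code_factor",
    "full_factorial_design",
    "performance_ratio",
    "fit_mlr",
    "fit_pca",
    "fit_pls",
    "variable_importance",
]

# Physical factor levels of the milling DoE: low / center / high
FACTOR_LEVELS = {
    "GFR": (2.2, 5.6, 9.0),   # m^3/h
    "MFR": (5.0, 10.0, 15.0),  # g/min
}


def code_factor(value, name: str) -> np.ndarray | float:
    """Map a physical factor value onto the coded -1..+1 scale."""
    lo, _, hi = FACTOR_LEVELS[name]
    out = (2.0 * np.asarray(value, float) - (hi + lo)) / (hi - lo)
    return out if out.ndim else float(out)


def full_factorial_design(n_center: int = 1) -> pd.DataFrame:
    """2^2 full factorial with ``n_center`` centerpoints, coded and physical units."""
    if n_center < 0:
        raise InvalidArgumentError("n_center must be >= 0")
    rows = []
    for g in (-1, 1):
        for m in (-1, 1):
            rows.append((g, m))
    rows += [(0, 0)] * n_center
    df = pd.DataFrame(rows, columns=["GFR_coded", "MFR_coded"])
    for name in ("GFR", "MFR"):
        lo, _, hi = FACTOR_LEVELS[name]
        df[name] = (hi + lo) / 2.0 + df[f"{name}_coded"] * (hi - lo) / 2.0
    return df


@dataclass
class DoETable:
    """One milling experiment per row: coded factors, responses, material properties."""

    data: pd.DataFrame

    def __post_init__(self):
        for col in ("GFR_coded", "MFR_coded"):
            if col not in self.data.columns:
                raise InvalidArgumentError(f"DoE table missing column {col}")
            if self.data[col].isna().any():
                raise InvalidArgumentError(f"missing factor values in {col}")
            levels = set(np.round(self.data[col].to_numpy(float), 9))
            if not levels <= {-1.0, 0.0, 1.0}:
                raise InvalidArgumentError(f"{col} must be coded in {{-1, 0, +1}}")

    def validate_factorial(self):
        """Check the 4 corners and at least one centerpoint are present."""
        pts = set(map(tuple, self.data[["GFR_coded", "MFR_coded"]].to_numpy(float)))
        corners = {(-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (1.0, 1.0)}
        if not corners <= pts:
            raise InvalidArgumentError("design lacks one or more factorial corners")
        if (0.0, 0.0) not in pts:
            raise InvalidArgumentError("design lacks a centerpoint")


def performance_ratio(unmilled_dv: float, milled_dv: float) -> float:
    """Milling performance indicator: unmilled/milled dv; > 1 means size reduction."""
    if unmilled_dv <= 0 or milled_dv <= 0:
        raise InvalidArgumentError("dv values must be positive")
    return unmilled_dv / milled_dv


_TERM_BUILDERS = {
    "GFR": lambda g, m: g,
    "MFR": lambda g, m: m,
    "GFR^2": lambda g, m: g * g,
    "MFR^2": lambda g, m: m * m,
    "MFR*GFR": lambda g, m: m * g,
    "GFR*MFR": lambda g, m: m * g,
}


def _design_matrix(table: DoETable, terms: list[str]) -> np.ndarray:
    g = table.data["GFR_coded"].to_numpy(float)
    m = table.data["MFR_coded"].to_numpy(float)
    cols = [np.ones_like(g)]
    for t in terms:
        try:
            cols.append(_TERM_BUILDERS[t](g, m))
        except KeyError:
            raise InvalidArgumentError(f"unknown model term '{t}'") from None
    return np.column_stack(cols)


@dataclass
class MLRResult:
    response: str
    terms: list[str]
    coefficients: dict  # term -> coefficient on coded factors
    r2: float
    q2: float
    log_transformed: bool
    residuals: np.ndarray = field(repr=False, default=None)


def fit_mlr(table: DoETable, response: str, terms: list[str],
            log_transform: bool = False) -> MLRResult:
    """Least-squares response model on coded factors with leave-one-out Q^2.

    ``terms`` lists the non-intercept terms, e.g. ["GFR", "GFR^2"]. With
    ``log_transform`` the natural log of the response is modelled (used when
    the response distribution is skewed); coefficients then live on the log
    scale and predictions must be back-transformed for reporting.
    """
    if response not in table.data.columns:
        raise InvalidArgumentError(f"response column '{response}' not in table")
    y = table.data[response].to_numpy(float)
    if log_transform:
        if np.any(y <= 0):
            raise InvalidArgumentError("log transform requires positive responses")
        y = np.log(y)
    X = _design_matrix(table, terms)
    n, p = X.shape
    if n <= p:
        raise InvalidArgumentError("need more rows than model terms")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # report which added terms are aliased with earlier ones
        aliased = []
        for j in range(1, p):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append((["intercept"] + terms)[j])
        raise EstimationError(f"design is rank deficient; aliased terms: {aliased}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    # leave-one-out PRESS via the hat matrix identity e_i / (1 - h_ii)
    H = X @ np.linalg.solve(X.T @ X, X.T)
    h = np.diag(H)
    loo = resid / np.maximum(1.0 - h, 1e-12)
    press = float(loo @ loo)
    q2 = 1.0 - press / tss if tss > 0 else -np.inf
    coefs = dict(zip(["intercept"] + list(terms), beta))
    return MLRResult(response=response, terms=list(terms), coefficients=coefs,
                     r2=r2, q2=q2, log_transformed=log_transform, residuals=resid)


@dataclass
class LatentModel:
    """Fitted PCA or PLS model on autoscaled data."""

    kind: str  # "PCA" | "PLS"
    n_components: int
    scores: np.ndarray
    loadings: np.ndarray  # X-loadings, (n_features, n_components)
    r2_per_component: np.ndarray
    q2_per_component: np.ndarray
    x_columns: list[str]
    y_columns: list[str] | None = None
    y_loadings: np.ndarray | None = None
    x_weights: np.ndarray | None = None  # PLS weights, for VIP
    y_variance_per_component: np.ndarray | None = None

    @property
    def r2_cumulative(self) -> np.ndarray:
        return np.cumsum(self.r2_per_component)

    @property
    def q2_cumulative(self) -> np.ndarray:
        return np.cumsum(self.q2_per_component)


def _autoscale(X: np.ndarray, cols) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = [cols[i] for i in bad]
        raise EstimationError(f"constant column(s) cannot be autoscaled: {names}")
    return (X - mean) / sd, mean, sd


def _as_matrix(X, default_prefix: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(map(str, X.columns))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"{default_prefix}{i + 1}" for i in range(X.shape[1])]


def fit_pca(X, n_components: int = 2) -> LatentModel:
    """PCA by SVD on the autoscaled matrix.

    R^2 per component is the explained share of total variance; Q^2 per
    component is one minus the leave-one-out reconstruction PRESS ratio of the
    model grown to that component (each held-out row is projected onto
    loadings fitted without it).
    """
    Xm, cols = _as_matrix(X, "x")
    n, p = Xm.shape
    if n < 3:
        raise InvalidArgumentError("PCA needs at least 3 rows")
    n_components = min(n_components, min(n - 1, p))
    Z, _, _ = _autoscale(Xm, cols)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    total = float(np.sum(Z**2))
    r2 = (s[:n_components] ** 2) / total

    # Row-wise leave-one-out reconstruction PRESS
    press = np.zeros(n_components)
    denom = np.zeros(n_components)
    for i in range(n):
        Zi = np.delete(Z, i, axis=0)
        # rescale the training fold itself: held-out row judged in its frame
        mu = Zi.mean(axis=0)
        Zi = Zi - mu
        _, _, Vt_i = np.linalg.svd(Zi, full_matrices=False)
        z = Z[i] - mu
        for a in range(n_components):
            V_a = Vt_i[: a + 1].T
            resid = z - V_a @ (V_a.T @ z)
            press[a] += float(resid @ resid)
            denom[a] += float(z @ z)
    q2_cum = 1.0 - press / np.maximum(denom, 1e-300)
    q2 = np.diff(np.concatenate(([0.0], q2_cum)))
    return LatentModel(kind="PCA", n_components=n_components, scores=scores,
                       loadings=loadings, r2_per_component=r2,
                       q2_per_component=q2, x_columns=cols)


def fit_pls(X, Y, n_components: int = 2) -> LatentModel:
    """PLS (NIPALS) on autoscaled X and Y with leave-one-out Q^2.

    R^2 per component is the share of Y-variance explained when the model
    grows by that component; Q^2 per component is the matching increment of
    1 - PRESS/TSS under row-wise leave-one-out refitting.
    """
    Xm, xcols = _as_matrix(X, "x")
    Ym, ycols = _as_matrix(Y, "y")
    n, p = Xm.shape
    if Ym.shape[0] != n:
        raise InvalidArgumentError("X and Y must have the same number of rows")
    if n < 3:
        raise InvalidArgumentError("PLS needs at least 3 rows")
    n_components = min(n_components, min(n - 1, p))
    Zx, _, _ = _autoscale(Xm, xcols)
    Zy, ymean, ysd = _autoscale(Ym, ycols)
    tss = float(np.sum(Zy**2))

    r2 = np.zeros(n_components)
    press_cum = np.zeros(n_components)
    fitted = None
    for a in range(1, n_components + 1):
        pls = PLSRegression(n_components=a, scale=False)
        pls.fit(Zx, Zy)
        rss = float(np.sum((Zy - pls.predict(Zx)) ** 2))
        r2[a - 1] = 1.0 - rss / tss
        if a == n_components:
            fitted = pls
        # leave-one-out PRESS at this model size
        press = 0.0
        for i in range(n):
            Zx_i = np.delete(Zx, i, axis=0)
            Zy_i = np.delete(Zy, i, axis=0)
            fold = PLSRegression(n_components=a, scale=False)
            fold.fit(Zx_i, Zy_i)
            e = Zy[i] - fold.predict(Zx[i][None, :])[0]
            press += float(e @ e)
        press_cum[a - 1] = press
    q2_cum = 1.0 - press_cum / tss
    r2_inc = np.diff(np.concatenate(([0.0], r2)))
    q2_inc = np.diff(np.concatenate(([0.0], q2_cum)))

    # Per-component explained Y-variance for VIP weighting
    T = fitted.x_scores_
    Q = fitted.y_loadings_
    y_var = np.array([
        float(np.sum(T[:, a] ** 2) * (Q[:, a] @ Q[:, a]))
        for a in range(n_components)
    ])
    return LatentModel(kind="PLS", n_components=n_components,
                       scores=T, loadings=fitted.x_loadings_,
                       r2_per_component=r2_inc, q2_per_component=q2_inc,
                       x_columns=xcols, y_columns=ycols,
                       y_loadings=fitted.y_loadings_,
                       x_weights=fitted.x_weights_,
                       y_variance_per_component=y_var)


def variable_importance(model: LatentModel) -> pd.Series:
    """VIP scores per predictor of a fitted PLS model.

    Standard weighted-sum-of-squares form: the squared normalized weights of
    each component, weighted by the Y-variance that component explains; the
    mean of the squared VIPs equals 1.
    """
    if model.kind != "PLS":
        raise InvalidArgumentError("VIP is defined for PLS models only")
    W = model.x_weights
    ssy = model.y_variance_per_component
    p = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.x_columns, name="VIP")
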