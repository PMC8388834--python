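"""Linear regression and correlation between fluorescence and growth.

Validating fluorescence as a growth proxy means regressing optical-density
summary metrics (AUC, maximum, final OD) on the corresponding fluorescence
metrics across conditions and inspecting adjusted R-squared and Pearson's
correlation for each of the nine metric pairs — the correlation grid.

Two fit methods are available:

* ``ols`` — ordinary least squares.
* ``huber`` — Huber-weighted iteratively reweighted least squares
  (tuning constant 1.345 on MAD-standardized residuals, at most 50
  iterations, 1e-8 convergence on the coefficients).  This is a robust
  M-estimator; on clean growth data it coincides with OLS because no
  residual leaves the Huber band.

Cell-count (CFU) correlations are conventionally computed on log10-scale
counts; :func:`log10_transform` enforces positivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    FluoGrowthError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationGrid",
    "LinearFit",
    "OD_METRICS",
    "RFU_METRICS",
    "correlation_grid",
    "fit_linear",
    "log10_transform",
    "pearson_r",
]

HUBER_C = 1.345          # 95% efficiency at the normal
HUBER_MAX_ITER = 50
HUBER_TOL = 1e-8         # max abs change of (slope, intercept)
_MAD_TO_SIGMA = 1.4826   # 1/Phi^-1(3/4), normal-consistent MAD scale

OD_METRICS = ("AUC OD", "Max OD", "Final OD")
RFU_METRICS = ("AUC RFU", "Max RFU", "Final RFU")
_METRIC_COL = {"AUC": "auc", "Max": "max", "Final": "final"}


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    adjusted_r2: float
    pearson_r: float
    n: int
    p_value_slope: float
    method: str


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"need >=3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    return x, y


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation of two sequences."""
    x, y = _check_xy(x, y)
    return float(stats.pearsonr(x, y).statistic)


def log10_transform(values) -> np.ndarray:
    """log10 of positive values; non-positive input is an error."""
    v = np.asarray(values, dtype=float)
    if np.any(v[np.isfinite(v)] <= 0):
        raise FluoGrowthError("log10 transform of non-positive value")
    return np.log10(v)


def _adjust_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def _ols(x, y) -> LinearFit:
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adjusted_r2=float(_adjust_r2(r2, len(x))),
        pearson_r=float(res.rvalue),
        n=int(len(x)),
        p_value_slope=float(res.pvalue),
        method="ols",
    )


def _huber(x, y) -> LinearFit:
    # IRLS from the OLS start; scale re-estimated each iteration from the
    # MAD of the current residuals.
    n = len(x)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = np.ones(n)
    for iteration in range(1, HUBER_MAX_ITER + 1):
        resid = y - X @ beta
        scale = _MAD_TO_SIGMA * np.median(np.abs(resid - np.median(resid)))
        if scale <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            w = np.ones(n)  # (near-)perfect fit: Huber reduces to OLS
            break
        u = np.abs(resid / scale)
        w = np.where(u <= HUBER_C, 1.0, HUBER_C / u)
        Xw = X * w[:, np.newaxis]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < HUBER_TOL:
            break
    else:
        raise ConvergenceError(
            f"Huber IRLS did not converge in {HUBER_MAX_ITER} iterations",
            iterations=HUBER_MAX_ITER,
        )
    # Weighted-OLS slope inference and R² using the final weights.
    resid = y - X @ beta
    sw = float(np.sum(w))
    ybar_w = float(np.sum(w * y) / sw)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    XtWX_inv = np.linalg.inv(X.T @ (X * w[:, np.newaxis]))
    sigma2 = ss_res / (n - 2)
    se_slope = float(np.sqrt(sigma2 * XtWX_inv[1, 1]))
    if se_slope == 0:
        p = np.finfo(float).tiny
    else:
        t = beta[1] / se_slope
        p = float(2 * stats.t.sf(np.abs(t), df=n - 2))
    return LinearFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        adjusted_r2=float(_adjust_r2(r2, n)),
        pearson_r=float(stats.pearsonr(x, y).statistic),
        n=int(n),
        p_value_slope=max(p, np.finfo(float).tiny),
        method="huber",
    )


def fit_linear(x, y, method: str = "ols") -> LinearFit:
    """Simple linear regression of ``y`` on ``x``.

    ``method="ols"`` is ordinary least squares; ``method="huber"`` is Huber
    IRLS (see module docstring).  Adjusted R² is 1 − (1−R²)(n−1)/(n−2); the
    slope p-value comes from its t statistic (for Huber, with the final
    IRLS weights).
    """
    x, y = _check_xy(x, y)
    if method == "ols":
        return _ols(x, y)
    if method == "huber":
        return _huber(x, y)
    raise FluoGrowthError(f"unknown fit method {method!r}")


@dataclass
class CorrelationGrid:
    """3x3 grid of fits: OD metric (response) vs RFU metric (explanatory)."""

    cells: dict[tuple[str, str], LinearFit]

    def __post_init__(self):
        expected = [(r, c) for r in OD_METRICS for c in RFU_METRICS]
        if list(self.cells) != expected:
            raise FluoGrowthError("correlation grid must have the 9 canonical cells")

    def best_pair(self) -> tuple[str, str]:
        """Cell with the highest Pearson correlation."""
        return max(self.cells, key=lambda k: self.cells[k].pearson_r)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "response": r,
                "explanatory": c,
                "adjusted_r2": f.adjusted_r2,
                "pearson": f.pearson_r,
                "slope": f.slope,
                "intercept": f.intercept,
                "n": f.n,
                "p_value_slope": f.p_value_slope,
            }
            for (r, c), f in self.cells.items()
        ]
        return pd.DataFrame(rows)


def correlation_grid(
    metrics: pd.DataFrame,
    od_channel: str,
    fluo_channel: str,
    method: str = "ols",
    average_replicates: bool = False,
) -> CorrelationGrid:
    """Fit all nine (OD metric, RFU metric) pairs across wells.

    ``metrics`` is the long-form table from :func:`fluogrowth.metrics
    .metrics_table`; rows for ``od_channel`` and ``fluo_channel`` are paired
    by well.  With ``average_replicates`` the wells of each condition are
    averaged before fitting (one point per condition instead of per well).
    """
    od = metrics[metrics["channel"] == od_channel].set_index("well")
    fl = metrics[metrics["channel"] == fluo_channel].set_index("well")
    common = od.index.intersection(fl.index)
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >=3 wells with both channels, got {len(common)}"
        )
    cols = ["auc", "max", "final"]
    wide = od.loc[common, cols + ["condition"]].rename(
        columns={c: f"od_{c}" for c in cols}
    )
    for c in cols:
        wide[f"rfu_{c}"] = fl.loc[common, c]
    if average_replicates:
        wide = wide.groupby("condition", sort=True).mean(numeric_only=True)
    cells = {}
    for r in OD_METRICS:
        for c in RFU_METRICS:
            y = wide[f"od_{_METRIC_COL[r.split()[0]]}"].to_numpy()
            x = wide[f"rfu_{_METRIC_COL[c.split()[0]]}"].to_numpy()
            cells[(r, c)] = fit_linear(x, y, method=method)
    return CorrelationGrid(cells=cells)
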