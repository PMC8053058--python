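"""Univariate GEE screening: the filter-one-gene-at-a-time comparator.

Each feature is tested separately in a marginal model with the full
longitudinal outcome vector as response and that feature as the single
covariate (intercept plus one slope shared across time points).  The slope
is estimated by iterated generalized least squares with moment-based
nuisance re-estimation, its standard error by the robust sandwich formula,
and features with a two-sided Wald p-value below the threshold (0.05 by
default, no multiple-testing correction) are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .longitudinal_data import LongitudinalDataset
from .working_correlation import (
    STRUCTURES,
    VarianceProfile,
    WorkingCorrelation,
    build_matrix,
    estimate_nuisance,
    safe_inverse,
)

__all__ = ["UnivariateGeeFit", "ScreeningResult", "gee_univariate_fit", "screen"]


@dataclass
class UnivariateGeeFit:
    """One feature's marginal GEE fit: slope, robust SE, Wald test."""

    intercept: float
    slope: float
    robust_se: float
    wald: float
    p_value: float
    converged: bool
    n_iter: int


@dataclass
class ScreeningResult:
    """Per-feature screening statistics and the p < threshold selection."""

    table: pd.DataFrame  # one row per feature: slope, robust_se, wald, p_value, converged
    threshold: float
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        p = self.table["p_value"]
        return list(self.table.index[p < self.threshold])


def _weights(kind: str, var: VarianceProfile, wc: WorkingCorrelation) -> np.ndarray:
    Rinv = safe_inverse(build_matrix(wc))
    s = var.sigma
    return (Rinv / s) / s[:, None]


def gee_univariate_fit(
    Y: np.ndarray,
    x: np.ndarray,
    kind: str = "unstructured",
    max_iter: int = 50,
    tol: float = 1e-6,
) -> UnivariateGeeFit:
    """Fit intercept + slope for one covariate against an n x t outcome.

    The design for subject i is the t x 2 matrix with rows ``[1, x_i]`` (the
    covariate is time-invariant and the slope is shared across time points).
    Starting from working independence, the fit alternates a generalized
    least squares solve with moment re-estimation of the nuisance parameters
    until the slope changes by less than ``tol`` or ``max_iter`` iterations;
    non-convergence is flagged, not fatal.  The robust (sandwich) standard
    error pairs the model-based information bread with an empirical score
    outer-product meat over subjects, and the p-value uses the two-sided
    normal reference.
    """
    if kind not in STRUCTURES:
        raise ValueError(f"unknown structure {kind!r}")
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n, t = Y.shape
    if x.shape[0] != n:
        raise ValueError("x and Y disagree on the number of subjects")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; the slope is not identifiable")

    # With design rows [1, x_i] repeated over time, the GLS pieces collapse:
    # Z_i' W Z_i = (1'W1) * [[1, x_i], [x_i, x_i^2]] and Z_i' W y = [1'Wy, x_i 1'Wy]
    W = np.eye(t)  # start from working independence
    coef = np.zeros(2)
    n_iter = 0
    converged = False
    sum_x = x.sum()
    sum_x2 = float(x @ x)
    M2 = np.array([[n, sum_x], [sum_x, sum_x2]])
    for n_iter in range(1, max_iter + 1):
        ones_W = W.sum(axis=0)  # 1'W, length t
        s = float(ones_W.sum())  # 1'W1
        u = Y @ ones_W  # 1'W y_i per subject
        bread = s * M2
        rhs = np.array([u.sum(), float(x @ u)])
        new = np.linalg.solve(bread, rhs)
        delta = abs(new[1] - coef[1])
        coef = new
        if delta < tol:
            converged = True
            break
        resid = Y - (coef[0] + coef[1] * x)[:, None]
        try:
            var, wc = estimate_nuisance(resid, kind)
        except ValueError:
            converged = True  # perfect fit: residual variance degenerate
            break
        W = _weights(kind, var, wc)

    resid = Y - (coef[0] + coef[1] * x)[:, None]
    ones_W = W.sum(axis=0)
    s = float(ones_W.sum())
    bread = s * M2
    c = resid @ ones_W  # scalar score factor 1'W r_i per subject
    meat = np.einsum("i,ij->j", c**2, np.column_stack([np.ones(n), x, x**2]))
    meat = np.array([[meat[0], meat[1]], [meat[1], meat[2]]])
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se > 0:
        wald = float(coef[1] / se)
        p = float(2.0 * stats.norm.sf(abs(wald)))
    else:  # perfect fit: infinitely precise slope
        wald = np.inf if coef[1] != 0 else 0.0
        p = 0.0 if coef[1] != 0 else 1.0
    return UnivariateGeeFit(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        robust_se=se,
        wald=wald,
        p_value=p,
        converged=converged,
        n_iter=n_iter,
    )


def screen(
    data: LongitudinalDataset,
    kind: str = "unstructured",
    threshold: float = 0.05,
) -> ScreeningResult:
    """Filter features one by one; select those with Wald p < ``threshold``.

    Per-feature failures (e.g. constant covariates) are recorded in
    ``errors`` with a NaN row in the table rather than aborting the scan.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rows = []
    errors: dict[str, str] = {}
    for p_idx, name in enumerate(data.feature_names):
        try:
            f = gee_univariate_fit(data.Y, data.X[:, p_idx], kind=kind)
            rows.append(
                {
                    "feature": name,
                    "slope": f.slope,
                    "robust_se": f.robust_se,
                    "wald": f.wald,
                    "p_value": f.p_value,
                    "converged": f.converged,
                }
            )
        except ValueError as exc:
            errors[name] = str(exc)
            rows.append(
                {
                    "feature": name,
                    "slope": np.nan,
                    "robust_se": np.nan,
                    "wald": np.nan,
                    "p_value": np.nan,
                    "converged": False,
                }
            )
    table = pd.DataFrame(rows).set_index("feature")
    return ScreeningResult(table=table, threshold=float(threshold), errors=errors)
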