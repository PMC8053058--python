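"""GEE-TGDR: thresholded gradient descent on a GEE quasilikelihood.

The method selects features relevant to a longitudinal continuous outcome by
combining two ideas.  A GEE marginal model supplies the objective — the
quasilikelihood quadratic form

    QL(beta) = n**-1 * sum_i (Y_i - mu_i(beta)).T @ V_i**-1 @ (Y_i - mu_i(beta)),

with identity link ``mu_ij = x_i @ beta_j`` (time-invariant covariates, one
coefficient vector per time point) and working covariance
``V_i = A**(1/2) R(alpha) A**(1/2)`` built from per-time variances A and a
working correlation structure R.  TGDR supplies the optimizer: starting from
the null model, each iteration moves only the coefficients whose negative
gradient

    g_jp = n**-1 * sum_i X_ip * [V**-1 (Y_i - mu_i)]_j

is within a fraction ``tau`` of the per-time-point maximum, so the selected
features may differ between time points.  Nuisance parameters (variances and
correlations) are re-estimated from residuals by the moment method inside
the loop.  The iteration count ``K`` is the regularization parameter, tuned
by cross-validation on held-out mean squared error.

Under the independence working structure the fitter uses the unweighted
residuals (V = I), which makes GEE-TGDR with t = 1 coincide exactly with
conventional TGDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .longitudinal_data import LongitudinalDataset, StandardizationRecord
from .tgdr import DivergenceError, threshold_select
from .working_correlation import (
    STRUCTURES,
    VarianceProfile,
    WorkingCorrelation,
    build_matrix,
    estimate_nuisance,
    safe_inverse,
)

__all__ = [
    "GeeTgdrModel",
    "SelectionReport",
    "quasi_objective",
    "gee_gradient",
    "threshold_matrix",
    "fit",
    "predict",
    "mse",
    "selected_features",
]


# ---------------------------------------------------------------------------
# weights

def _weight_matrix(
    wc: WorkingCorrelation, var: VarianceProfile, literal_eq5: bool = False
) -> np.ndarray:
    """The t x t residual weight applied inside the gradient and objective.

    The default is the exact objective weight ``V**-1 = A**(-1/2) R**-1
    A**(-1/2)``.  With ``literal_eq5=True`` the asymmetric variant
    ``A**(1/2) R**-1 A**(-1/2)`` is returned instead; the two coincide up to
    a positive scaling whenever the variances are equal across time points,
    but only the former is the gradient of the quasilikelihood objective.
    """
    Rinv = safe_inverse(build_matrix(wc))
    s = var.sigma
    if literal_eq5:
        return (Rinv / s) * s[:, None]
    return (Rinv / s) / s[:, None]


def _as_arrays(data: LongitudinalDataset | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, LongitudinalDataset):
        return data.X, data.Y
    X, Y = data
    return np.asarray(X, dtype=float), np.asarray(Y, dtype=float)


def _check_dims(beta: np.ndarray, X: np.ndarray, Y: np.ndarray, t: int) -> None:
    n, P = X.shape
    if Y.shape != (n, t):
        raise ValueError(f"Y has shape {Y.shape}, expected ({n}, {t})")
    if beta.shape != (t, P):
        raise ValueError(f"beta has shape {beta.shape}, expected ({t}, {P})")


# ---------------------------------------------------------------------------
# objective and gradient

def quasi_objective(
    beta: np.ndarray,
    data: LongitudinalDataset | tuple,
    wc: WorkingCorrelation,
    var: VarianceProfile,
) -> float:
    """Quasilikelihood objective: average V**-1-weighted squared residual.

    Zero iff the model reproduces every outcome exactly.  With the
    independent structure and unit variances this is the plain mean (over
    subjects) of the summed squared residuals across time points.
    """
    X, Y = _as_arrays(data)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    _check_dims(beta, X, Y, wc.t)
    r = Y - X @ beta.T
    W = _weight_matrix(wc, var)
    return float(np.einsum("ij,jl,il->", r, W, r) / X.shape[0])


def gee_gradient(
    beta: np.ndarray,
    data: LongitudinalDataset | tuple,
    wc: WorkingCorrelation,
    var: VarianceProfile,
    literal_eq5: bool = False,
) -> np.ndarray:
    """Negative gradient matrix g (t x P) of the quasilikelihood at ``beta``.

    Equals half the negative partial derivative of `quasi_objective` with the
    nuisance parameters held fixed (the constant 2 is absorbed by the step
    increment).  Row j weights the residuals by V**-1 and correlates them
    with each feature.
    """
    X, Y = _as_arrays(data)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    _check_dims(beta, X, Y, wc.t)
    n = X.shape[0]
    r = Y - X @ beta.T
    W = _weight_matrix(wc, var, literal_eq5=literal_eq5)
    S = r @ W.T
    return (X.T @ S).T / n


def threshold_matrix(g: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise 0/1 threshold indicators: the max runs within each time point.

    Row j of the result is `threshold_select` applied to the j-th gradient
    row, so feature selection proceeds independently per time point and the
    selected sets may differ across time.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    return np.vstack([threshold_select(row, tau) for row in g])


# ---------------------------------------------------------------------------
# fitted model

@dataclass
class GeeTgdrModel:
    """A fitted GEE-TGDR model.

    ``beta`` is the t x P coefficient matrix on the (standardized) training
    scale; ``wc``/``var`` are the nuisance estimates in effect after the last
    iteration; ``objective_trace`` holds K+1 quasilikelihood values starting
    at the null model.  ``checkpoints`` maps requested iteration counts to
    coefficient snapshots (used to read a whole K-grid off one path).
    """

    beta: np.ndarray
    wc: WorkingCorrelation
    var: VarianceProfile
    tau: float
    delta_v: float
    K: int
    objective_trace: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    time_labels: list[str] = field(default_factory=list)
    record: StandardizationRecord | None = None
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def t(self) -> int:
        return self.beta.shape[0]

    @property
    def P(self) -> int:
        return self.beta.shape[1]

    @property
    def selected(self) -> list[np.ndarray]:
        """Per-time-point arrays of feature indices with nonzero coefficients."""
        return [np.flatnonzero(row != 0) for row in self.beta]

    @property
    def selected_union(self) -> np.ndarray:
        """Indices selected at any time point (the reported signature)."""
        return np.flatnonzero((self.beta != 0).any(axis=0))

    def coefficient_frame(self) -> pd.DataFrame:
        """Coefficients as a time-points x features table."""
        return pd.DataFrame(self.beta, index=self.time_labels, columns=self.feature_names)


def fit(
    data: LongitudinalDataset | tuple,
    kind: str = "unstructured",
    tau: float = 1.0,
    delta_v: float = 0.01,
    K: int = 100,
    nuisance_refresh: int = 1,
    literal_eq5: bool = False,
    k_checkpoints: list[int] | None = None,
    record: StandardizationRecord | None = None,
) -> GeeTgdrModel:
    """Fit GEE-TGDR by K thresholded gradient steps from the null model.

    The data must already be standardized (covariate columns mean 0 / SD 1,
    outcomes centered per time point); pass the `standardize` record so that
    `predict` can map raw inputs.  The initial working correlation is the
    identity and initial variances are the marginal outcome variances; the
    moment estimates are refreshed from current residuals every
    ``nuisance_refresh`` iterations (every iteration by default).  Under
    ``kind='independent'`` the residuals enter unweighted (V = I), so with a
    single time point the coefficient path is exactly the conventional TGDR
    path.

    Raises
    ------
    DivergenceError
        If the coefficients become non-finite (``delta_v`` too large).
    """
    if kind not in STRUCTURES:
        raise ValueError(f"unknown structure {kind!r}")
    X, Y = _as_arrays(data)
    n, P = X.shape
    t = Y.shape[1]
    if t == 1 and kind != "independent":
        raise ValueError(f"structure {kind!r} requires at least 2 time points")
    if K < 0:
        raise ValueError("K must be >= 0")
    if nuisance_refresh < 1:
        raise ValueError("nuisance_refresh must be >= 1")
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")

    independent = kind == "independent"
    if independent:
        wc = WorkingCorrelation(kind, None, t)
    elif kind == "unstructured":
        wc = WorkingCorrelation(kind, np.eye(t), t)
    else:
        wc = WorkingCorrelation(kind, 0.0, t)
    if independent:
        var = VarianceProfile(np.ones(t))
        W = None  # V = I: residuals enter unweighted
    else:
        var = VarianceProfile((Y**2).mean(axis=0))
        W = _weight_matrix(wc, var, literal_eq5=literal_eq5)

    want = sorted(set(k_checkpoints)) if k_checkpoints else []
    if want and want[-1] > K:
        raise ValueError("checkpoint iteration exceeds K")
    checkpoints: dict[int, np.ndarray] = {}

    beta = np.zeros((t, P))
    if 0 in want:
        checkpoints[0] = beta.copy()
    trace = [_objective(X, Y, beta, wc, var)]
    g = np.empty((t, P))
    for k in range(1, K + 1):
        r = Y - X @ beta.T
        S = r if W is None else r @ W.T
        for j in range(t):
            g[j] = X.T @ S[:, j] / n
        if not np.all(np.isfinite(g)):
            raise DivergenceError(
                f"non-finite gradient at iteration {k}; reduce delta_v"
            )
        f = threshold_matrix(g, tau)
        beta = beta + delta_v * g * f
        if not np.all(np.isfinite(beta)):
            raise DivergenceError(
                f"non-finite coefficients at iteration {k}; reduce delta_v"
            )
        trace.append(_objective(X, Y, beta, wc, var))
        if k in want:
            checkpoints[k] = beta.copy()
        if not independent and k % nuisance_refresh == 0:
            var, wc = estimate_nuisance(Y - X @ beta.T, kind)
            W = _weight_matrix(wc, var, literal_eq5=literal_eq5)

    names = data.feature_names if isinstance(data, LongitudinalDataset) else []
    times = data.time_labels if isinstance(data, LongitudinalDataset) else []
    return GeeTgdrModel(
        beta=beta,
        wc=wc,
        var=var,
        tau=float(tau),
        delta_v=float(delta_v),
        K=int(K),
        objective_trace=np.asarray(trace),
        feature_names=list(names) or [f"F{p + 1:04d}" for p in range(P)],
        time_labels=list(times) or [f"t{j}" for j in range(t)],
        record=record,
        checkpoints=checkpoints,
    )


def _objective(
    X: np.ndarray,
    Y: np.ndarray,
    beta: np.ndarray,
    wc: WorkingCorrelation,
    var: VarianceProfile,
) -> float:
    r = Y - X @ beta.T
    W = _weight_matrix(wc, var)
    return float(np.einsum("ij,jl,il->", r, W, r) / X.shape[0])


# ---------------------------------------------------------------------------
# prediction and evaluation

def predict(model: GeeTgdrModel, X: np.ndarray) -> np.ndarray:
    """Predicted outcome matrix (m x t) for raw covariate rows ``X``.

    If the model carries a standardization record the covariates are scaled
    onto the training scale and the per-time outcome means are restored, so
    the output lives on the raw outcome scale; otherwise ``X`` is assumed to
    be standardized already.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.P:
        raise ValueError(
            f"feature mismatch: model has {model.P} features, X has {X.shape[1]}"
        )
    if model.record is not None:
        Xs = model.record.apply_to_covariates(X)
        return Xs @ model.beta.T + model.record.outcome_means
    return X @ model.beta.T


def mse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared error averaged over all subject-time entries."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs observed {observed.shape}"
        )
    return float(np.mean((predicted - observed) ** 2))


# ---------------------------------------------------------------------------
# selection reporting

@dataclass
class SelectionReport:
    """Per-time-point selected feature names, their union, and overlaps."""

    by_time: dict[str, list[str]]
    union: list[str]
    overlap: pd.DataFrame  # pairwise intersection sizes between time points

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"time": label, "n_selected": len(names), "features": ";".join(names)}
            for label, names in self.by_time.items()
        ]
        rows.append(
            {"time": "union", "n_selected": len(self.union), "features": ";".join(self.union)}
        )
        return pd.DataFrame(rows)


def selected_features(
    model: GeeTgdrModel, feature_names: list[str] | None = None
) -> SelectionReport:
    """Name the nonzero coefficients per time point, their union and overlaps.

    A feature counts as selected at time point j iff its coefficient is
    exactly nonzero after the K updates (every thresholded update moves a
    coefficient by ``delta_v * g``, so an untouched coefficient stays at 0).
    The overlap table gives Venn-style pairwise intersection counts between
    the per-time selections.
    """
    names = feature_names if feature_names is not None else model.feature_names
    if len(names) != model.P:
        raise ValueError("feature_names length does not match model")
    sets = [set(np.flatnonzero(row != 0)) for row in model.beta]
    by_time = {
        label: [names[p] for p in sorted(s)]
        for label, s in zip(model.time_labels, sets)
    }
    union_idx = sorted(set().union(*sets)) if sets else []
    overlap = pd.DataFrame(
        [[len(a & b) for b in sets] for a in sets],
        index=model.time_labels,
        columns=model.time_labels,
    )
    return SelectionReport(
        by_time=by_time, union=[names[p] for p in union_idx], overlap=overlap
    )
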