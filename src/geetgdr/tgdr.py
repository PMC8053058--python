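"""Conventional threshold gradient descent regularization (TGDR).

TGDR fits a linear model by gradient descent on the mean squared error,
updating at each step only the coefficients whose gradient magnitude is at
least a fraction ``tau`` of the current maximum.  No explicit penalty term
appears: sparsity comes from the thresholded updates, and the iteration
count ``K`` plays the role of the regularization parameter (small K = sparse
model, large K = dense model), tuned by cross-validation.

Starting from ``beta = 0`` (the null model), each iteration computes

    g_p = n**-1 * sum_i X_ip * (y_i - x_i @ beta)          (negative gradient)
    f_p = 1{ |g_p| >= tau * max_l |g_l| }                  (threshold vector)
    beta_p <- beta_p + delta_v * g_p * f_p

The factor 2 from differentiating the squared error is omitted; it is
absorbed by the step increment ``delta_v``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TgdrPath", "threshold_select", "tgdr_fit", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Raised when the coefficient path becomes non-finite (delta_v too large)."""


@dataclass
class TgdrPath:
    """A TGDR coefficient path and the hyperparameters that produced it.

    ``beta_by_iteration`` holds the checkpointed path: row k is the
    coefficient vector after k*stride iterations (row 0 is the zero vector),
    ending with the final iterate.
    """

    beta_by_iteration: np.ndarray
    tau: float
    delta_v: float
    K: int
    stride: int = 1

    @property
    def beta(self) -> np.ndarray:
        """Final coefficient vector (after K iterations)."""
        return self.beta_by_iteration[-1]

    @property
    def selected(self) -> np.ndarray:
        """Indices of features with a nonzero final coefficient."""
        return np.flatnonzero(self.beta != 0)


def threshold_select(g: np.ndarray, tau: float) -> np.ndarray:
    """0/1 indicator of gradient components within ``tau`` of the maximum.

    Component p is 1 iff ``|g_p| >= tau * max_l |g_l|``.  ``tau = 0`` keeps
    every component (plain gradient descent); ``tau = 1`` keeps only the
    maximal component(s), ties included.  An all-zero gradient selects every
    component (the threshold is vacuously met), which leaves the update a
    no-op anyway.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient contains non-finite values")
    cut = tau * np.max(np.abs(g))
    return (np.abs(g) >= cut).astype(float)


def tgdr_fit(
    X: np.ndarray,
    y: np.ndarray,
    tau: float = 1.0,
    delta_v: float = 0.01,
    K: int = 100,
    stride: int = 1,
) -> TgdrPath:
    """Run K thresholded gradient descent iterations from the null model.

    ``X`` should be standardized (columns mean 0, SD 1) and ``y`` centered so
    that gradient magnitudes are comparable across features and no intercept
    is needed.  The path is deterministic given its inputs.

    Parameters
    ----------
    tau : float in [0, 1]
        Threshold fraction; 1 gives the sparsest (pure threshold) selection.
    delta_v : float
        Step increment; must be small enough that the quadratic objective
        descends (below ~1/lambda_max(n**-1 X.T X)).
    K : int
        Number of iterations; the tuning parameter chosen by CV.
    stride : int
        Checkpoint every ``stride`` iterations (the final iterate is always
        recorded); 1 keeps the whole path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, P = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on the number of samples")
    if K < 0:
        raise ValueError("K must be >= 0")
    if delta_v <= 0:
        raise ValueError("delta_v must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    beta = np.zeros(P)
    checkpoints = [beta.copy()]
    for k in range(1, K + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            g = X.T @ (y - X @ beta) / n
        if not np.all(np.isfinite(g)):
            raise DivergenceError(
                f"non-finite gradient at iteration {k}; reduce delta_v"
            )
        f = threshold_select(g, tau)
        beta = beta + delta_v * g * f
        if not np.all(np.isfinite(beta)):
            raise DivergenceError(
                f"non-finite coefficients at iteration {k}; reduce delta_v"
            )
        if k % stride == 0 or k == K:
            checkpoints.append(beta.copy())
    return TgdrPath(np.asarray(checkpoints), float(tau), float(delta_v), int(K), int(stride))


def response_function(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Mean squared error objective n**-1 sum_i (y_i - x_i @ beta)**2."""
    r = y - X @ beta
    return float(r @ r / X.shape[0])
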