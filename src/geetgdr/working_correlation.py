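"""Working correlation structures for GEE-type weighting.

Four structures are supported: ``independent`` (identity), ``exchangeable``
(a single common correlation), ``ar1`` (first-order autoregressive decay
alpha**|j-l|) and ``unstructured`` (a free symmetric unit-diagonal matrix).
Correlation parameters and per-time-point variances are nuisance parameters
estimated from residuals by the moment method, not optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STRUCTURES",
    "WorkingCorrelation",
    "VarianceProfile",
    "build_matrix",
    "estimate_nuisance",
    "safe_inverse",
]

STRUCTURES = ("independent", "exchangeable", "ar1", "unstructured")

# Clipping keeps the realized correlation matrix positive definite: an
# exchangeable matrix is PD iff alpha > -1/(t-1); AR1 iff |alpha| < 1.
_EXCH_MARGIN = 1e-3
_CORR_MAX = 0.99
_EIG_FLOOR = 1e-6


@dataclass
class WorkingCorrelation:
    """A structure kind plus its correlation parameter(s).

    ``alpha`` is ``None`` for independent, a scalar in (-1, 1) for
    exchangeable/ar1, and a symmetric unit-diagonal t x t matrix for
    unstructured.
    """

    kind: str
    alpha: float | np.ndarray | None
    t: int

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURES:
            raise ValueError(f"unknown structure {self.kind!r}; expected one of {STRUCTURES}")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.kind == "independent":
            if self.alpha is not None:
                raise ValueError("independent structure takes no correlation parameter")
        elif self.kind in ("exchangeable", "ar1"):
            a = float(self.alpha)
            if not -1.0 < a < 1.0:
                raise ValueError(f"{self.kind} alpha must lie in (-1, 1), got {a}")
            self.alpha = a
        else:  # unstructured
            A = np.asarray(self.alpha, dtype=float)
            if A.shape != (self.t, self.t):
                raise ValueError(f"unstructured alpha must be {self.t}x{self.t}")
            if not np.allclose(A, A.T, atol=1e-10):
                raise ValueError("unstructured alpha must be symmetric")
            if not np.allclose(np.diag(A), 1.0):
                raise ValueError("unstructured alpha must have unit diagonal")
            if np.any(np.abs(A) > 1.0 + 1e-12):
                raise ValueError("correlations must lie in [-1, 1]")
            self.alpha = A


@dataclass
class VarianceProfile:
    """Per-time-point marginal variances sigma^2_j (all strictly positive)."""

    sigma2: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self) -> None:
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if np.any(self.sigma2 <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)


def build_matrix(wc: WorkingCorrelation) -> np.ndarray:
    """Realize the t x t correlation matrix R(alpha) for a structure."""
    t = wc.t
    if wc.kind == "independent":
        return np.eye(t)
    if wc.kind == "exchangeable":
        R = np.full((t, t), float(wc.alpha))
        np.fill_diagonal(R, 1.0)
        return R
    if wc.kind == "ar1":
        lags = np.abs(np.subtract.outer(np.arange(t), np.arange(t)))
        return float(wc.alpha) ** lags
    return np.array(wc.alpha, dtype=float, copy=True)


def estimate_nuisance(
    residuals: np.ndarray, kind: str
) -> tuple[VarianceProfile, WorkingCorrelation]:
    """Residual-based moment estimates of variances and correlations.

    Given raw residuals ``e`` (n subjects x t time points) the per-time
    variance is ``sigma2_j = mean_i e_ij**2`` and the Pearson residuals
    ``r_ij = e_ij / sigma_j`` feed the correlation moments:

    - exchangeable: average of ``r_ij * r_il`` over subjects and pairs j < l;
    - ar1: average of ``r_ij * r_i,j+1`` over subjects and adjacent pairs;
    - unstructured: ``n**-1 * r.T @ r`` with the diagonal reset to one.

    Denominators use the full count n (no degrees-of-freedom correction: no
    parametric df exists when P >> n).  Estimates are clipped to ranges that
    keep R positive definite.
    """
    if kind not in STRUCTURES:
        raise ValueError(f"unknown structure {kind!r}")
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 2:
        raise ValueError("residuals must be an n x t matrix")
    n, t = e.shape
    if n < 2:
        raise ValueError("at least 2 subjects required to estimate nuisance parameters")
    if t == 1 and kind != "independent":
        raise ValueError(f"structure {kind!r} is undefined for a single time point")

    sigma2 = (e**2).mean(axis=0)
    if np.any(sigma2 == 0):
        j = int(np.argmin(sigma2))
        raise ValueError(f"degenerate fit: zero residual variance at time point {j}")
    var = VarianceProfile(sigma2)

    if kind == "independent":
        return var, WorkingCorrelation("independent", None, t)

    r = e / var.sigma
    if kind == "exchangeable":
        # sum over unordered pairs j<l of r_ij r_il, averaged over n*t(t-1)/2
        total = ((r.sum(axis=1) ** 2 - (r**2).sum(axis=1)) / 2.0).sum()
        alpha = total / (n * t * (t - 1) / 2.0)
        alpha = float(np.clip(alpha, -1.0 / (t - 1) + _EXCH_MARGIN, _CORR_MAX))
        return var, WorkingCorrelation("exchangeable", alpha, t)
    if kind == "ar1":
        alpha = float((r[:, :-1] * r[:, 1:]).sum() / (n * (t - 1)))
        alpha = float(np.clip(alpha, -_CORR_MAX, _CORR_MAX))
        return var, WorkingCorrelation("ar1", alpha, t)

    R = r.T @ r / n
    R = (R + R.T) / 2.0
    off = ~np.eye(t, dtype=bool)
    R[off] = np.clip(R[off], -_CORR_MAX, _CORR_MAX)
    np.fill_diagonal(R, 1.0)
    return var, WorkingCorrelation("unstructured", R, t)


def safe_inverse(R: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Invert a correlation matrix, ridging it first if nearly singular.

    If the smallest eigenvalue is below ``floor`` a ridge is added to raise it
    to ``floor`` before inversion; unstructured moment estimates with n close
    to t are routinely near-singular.  The result is symmetrized.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < floor:
        R = R + (floor - eigmin) * np.eye(R.shape[0])
    Rinv = np.linalg.inv(R)
    return (Rinv + Rinv.T) / 2.0
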