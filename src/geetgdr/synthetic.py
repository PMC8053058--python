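"""Synthetic balanced longitudinal panels with known sparse truth.

The generator emulates the shape of a short treatment-response expression
study: a modest number of subjects (default 30), a handful of time points
(default 4: baseline and three follow-up weeks), several hundred baseline
covariates (default 662), a sparse t x P coefficient matrix linking
covariates to outcomes, and within-subject correlated Gaussian errors drawn
from one of the four working correlation structures.

Covariates are i.i.d. standard normal by default (an optional equicorrelated
variant adds a shared factor across features); outcomes follow

    Y_ij = x_i @ beta_true_j + eps_ij,   eps_i ~ N(0, diag(s) R(alpha) diag(s)).

Everything is reproducible from the seed, and the generating truth (support,
coefficients, correlation, noise scale) is returned alongside the dataset so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .longitudinal_data import LongitudinalDataset
from .working_correlation import STRUCTURES, WorkingCorrelation, build_matrix

__all__ = ["SyntheticTruth", "generate", "generate_null", "psoriasis_like_preset"]

_TIME_LABELS_4 = ["baseline", "week1", "week2", "week4"]


@dataclass
class SyntheticTruth:
    """The generating model behind a synthetic dataset."""

    beta_true: np.ndarray  # t x P
    kind: str
    alpha_true: float | np.ndarray | None
    sigma_true: np.ndarray  # t per-time noise SDs
    n: int
    t: int
    P: int
    seed: int

    @property
    def support(self) -> np.ndarray:
        """Feature indices with a nonzero coefficient at any time point."""
        return np.flatnonzero((self.beta_true != 0).any(axis=0))

    def support_at(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.beta_true[j] != 0)


def _resolve_beta(
    support: int | np.ndarray,
    effect_size: float,
    t: int,
    P: int,
    rng: np.random.Generator,
    time_pattern: str = "window",
) -> np.ndarray:
    """Build the sparse time-varying t x P truth from a support spec.

    ``support`` may be an integer (that many features drawn at random), a 1-d
    array of feature indices, or a full t x P coefficient matrix used
    verbatim.  For the first two forms each signal feature carries the
    coefficient ``effect_size`` on a set of time points given by
    ``time_pattern``:

    - ``"window"`` (default): a random contiguous window of time points, so
      per-time supports differ but overlap across adjacent times — a marker
      relevant during a phase of the treatment response;
    - ``"constant"``: active at every time point;
    - ``"single"``: active at one random time point only.
    """
    spec = np.asarray(support)
    if spec.ndim == 2:
        if spec.shape != (t, P):
            raise ValueError(f"coefficient matrix must be {t}x{P}")
        return spec.astype(float)
    if spec.ndim == 0:
        s = int(spec)
        if not 0 <= s <= P:
            raise ValueError(f"support size must lie in [0, {P}]")
        idx = rng.choice(P, size=s, replace=False)
    else:
        idx = spec.astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= P):
            raise ValueError("support indices out of range")
    beta = np.zeros((t, P))
    for p in idx:
        if time_pattern == "constant":
            beta[:, p] = float(effect_size)
        elif time_pattern == "single":
            beta[rng.integers(t), p] = float(effect_size)
        elif time_pattern == "window":
            a = int(rng.integers(t))
            b = int(rng.integers(a, t))
            beta[a : b + 1, p] = float(effect_size)
        else:
            raise ValueError(f"unknown time_pattern {time_pattern!r}")
    return beta


def generate(
    n: int = 30,
    t: int = 4,
    P: int = 662,
    support: int | np.ndarray = 10,
    effect_size: float = 1.0,
    kind: str = "exchangeable",
    alpha_true: float | np.ndarray | None = 0.5,
    sigma_true: float | np.ndarray = 1.0,
    seed: int = 0,
    x_correlation: float = 0.0,
    time_pattern: str = "window",
) -> tuple[LongitudinalDataset, SyntheticTruth]:
    """Draw a balanced panel with known sparse linear structure.

    Parameters
    ----------
    support, effect_size, time_pattern
        Which features carry signal, how strongly and at which time points;
        see `_resolve_beta`.
    kind, alpha_true
        Error correlation structure and its parameter; must describe a
        positive definite correlation matrix.
    sigma_true
        Per-time-point noise SD (scalar broadcast across time).
    x_correlation
        If nonzero, covariates are equicorrelated at this level via a shared
        subject factor (used to probe robustness to correlated features);
        marginal covariate variance stays 1.
    """
    if kind not in STRUCTURES:
        raise ValueError(f"unknown structure {kind!r}")
    rng = np.random.default_rng(seed)
    beta_true = _resolve_beta(support, effect_size, t, P, rng, time_pattern)
    sigma = np.broadcast_to(np.asarray(sigma_true, dtype=float), (t,)).copy()
    if np.any(sigma < 0):
        raise ValueError("sigma_true must be nonnegative")

    wc = WorkingCorrelation(kind, alpha_true, t)  # validates admissibility
    R = build_matrix(wc)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin <= 0:
        raise ValueError(f"alpha_true gives a non-PD correlation matrix (min eig {eigmin:.3g})")

    if not 0.0 <= x_correlation < 1.0:
        raise ValueError("x_correlation must lie in [0, 1)")
    X = rng.standard_normal((n, P))
    if x_correlation > 0:
        shared = rng.standard_normal((n, 1))
        X = np.sqrt(x_correlation) * shared + np.sqrt(1.0 - x_correlation) * X

    cov = (sigma[:, None] * R) * sigma[None, :]
    if np.all(sigma > 0):
        L = np.linalg.cholesky(cov)
        eps = rng.standard_normal((n, t)) @ L.T
    else:
        eps = np.zeros((n, t))
    Y = X @ beta_true.T + eps

    labels = _TIME_LABELS_4 if t == 4 else [f"t{j}" for j in range(t)]
    data = LongitudinalDataset(
        X=X,
        Y=Y,
        subject_ids=[f"S{i + 1:04d}" for i in range(n)],
        feature_names=[f"F{p + 1:04d}" for p in range(P)],
        time_labels=labels,
    )
    truth = SyntheticTruth(
        beta_true=beta_true,
        kind=kind,
        alpha_true=wc.alpha,
        sigma_true=sigma,
        n=n,
        t=t,
        P=P,
        seed=int(seed),
    )
    return data, truth


def generate_null(
    n: int = 30,
    t: int = 4,
    P: int = 662,
    kind: str = "exchangeable",
    alpha_true: float | np.ndarray | None = 0.5,
    sigma_true: float | np.ndarray = 1.0,
    seed: int = 0,
) -> tuple[LongitudinalDataset, SyntheticTruth]:
    """A panel with no signal at all (beta_true = 0): pure correlated noise.

    Used for type-I-error calibration of the screening comparator and as the
    K=0 baseline in cross-validation checks.
    """
    return generate(
        n=n,
        t=t,
        P=P,
        support=0,
        effect_size=0.0,
        kind=kind,
        alpha_true=alpha_true,
        sigma_true=sigma_true,
        seed=seed,
    )


def psoriasis_like_preset(seed: int = 0) -> tuple[LongitudinalDataset, SyntheticTruth]:
    """The default application-shaped scenario: n=30, t=4, P=662, 10 signals."""
    return generate(n=30, t=4, P=662, support=10, effect_size=1.0, seed=seed)
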