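"""Subject-level k-fold cross-validation over the TGDR tuning parameters.

The iteration count K (and optionally the threshold tau) is chosen by
cross-validating the held-out mean squared error.  Folds split *subjects*,
never individual subject-time observations: within-subject correlation
would otherwise leak between training and test sets.  Standardization
constants are learned on each training fold and applied to its held-out
fold for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gee_tgdr
from .longitudinal_data import LongitudinalDataset, standardize

__all__ = ["CvResult", "make_folds", "cross_validate", "DEFAULT_K_GRID"]

DEFAULT_K_GRID = (10, 20, 50, 100, 200, 500, 1000)


@dataclass
class CvResult:
    """Cross-validation summary over a (K, tau) grid.

    ``per_fold_mse[f, g]`` is the held-out MSE of fold f at grid point g;
    ``mean_mse``/``sd_mse`` aggregate across folds; ``best`` is the grid
    point minimizing the mean, ties broken toward smaller K then smaller
    tau; ``whole_data_mse`` is the training MSE of a final fit on all
    subjects at the chosen point.
    """

    grid: list[tuple[int, float]]
    per_fold_mse: np.ndarray
    mean_mse: np.ndarray
    sd_mse: np.ndarray
    best: tuple[int, float]
    whole_data_mse: float
    fold_assignment: np.ndarray
    seed: int
    model: "gee_tgdr.GeeTgdrModel | None" = None

    @property
    def best_K(self) -> int:
        return self.best[0]

    @property
    def best_tau(self) -> float:
        return self.best[1]

    def summary_frame(self) -> pd.DataFrame:
        """One row per grid point, mirroring a mean/SD-of-MSE results table."""
        return pd.DataFrame(
            {
                "K": [k for k, _ in self.grid],
                "tau": [tau for _, tau in self.grid],
                "mean_mse": self.mean_mse,
                "sd_mse": self.sd_mse,
                "chosen": [g == self.best for g in self.grid],
            }
        )


def make_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Random subject partition into folds of sizes differing by at most 1.

    Returns an array of n fold labels in 0..folds-1, reproducible given the
    seed.  Entire outcome vectors stay together because assignment is by
    subject.
    """
    if not 2 <= folds <= n:
        raise ValueError(f"folds must lie in [2, n={n}], got {folds}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    # first (n % folds) folds get the extra subject
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    start = 0
    for f, size in enumerate(sizes):
        assignment[order[start : start + size]] = f
        start += size
    return assignment


def cross_validate(
    data: LongitudinalDataset,
    kind: str = "unstructured",
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    tau_grid: tuple[float, ...] = (1.0,),
    folds: int = 5,
    seed: int = 0,
    delta_v: float = 0.01,
    nuisance_refresh: int = 1,
    fit_final: bool = True,
) -> CvResult:
    """Grid-search (K, tau) by subject-level k-fold CV on held-out MSE.

    For each fold the model is fitted on the training subjects only
    (standardizing within the fold) and a single coefficient path per tau is
    checkpointed at every K in the grid, so the whole K-grid costs one fit.
    Held-out predictions are back-transformed to the raw outcome scale
    before computing MSE.  A final model on all subjects at the chosen grid
    point supplies the whole-data MSE and the reported selection.
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    k_grid = tuple(sorted(set(int(k) for k in k_grid)))
    tau_grid = tuple(sorted(set(float(tau) for tau in tau_grid)))
    grid = [(K, tau) for tau in tau_grid for K in k_grid]
    assignment = make_folds(data.n, folds, seed)
    K_max = k_grid[-1]

    per_fold = np.empty((folds, len(grid)))
    for f in range(folds):
        train = data.subset(assignment != f)
        test_X = data.X[assignment == f]
        test_Y = data.Y[assignment == f]
        std_train, record = standardize(train)
        for gi_tau, tau in enumerate(tau_grid):
            model = gee_tgdr.fit(
                std_train,
                kind=kind,
                tau=tau,
                delta_v=delta_v,
                K=K_max,
                nuisance_refresh=nuisance_refresh,
                k_checkpoints=list(k_grid),
                record=record,
            )
            Xs = record.apply_to_covariates(test_X)
            for gi_k, K in enumerate(k_grid):
                beta_k = model.checkpoints[K]
                pred = Xs @ beta_k.T + record.outcome_means
                per_fold[f, gi_tau * len(k_grid) + gi_k] = gee_tgdr.mse(pred, test_Y)

    mean_mse = per_fold.mean(axis=0)
    sd_mse = per_fold.std(axis=0, ddof=1)
    # ties toward smaller K then smaller tau: grid is sorted by (tau, K), so
    # pick lexicographically smallest (mse, K, tau)
    order = sorted(range(len(grid)), key=lambda g: (mean_mse[g], grid[g][0], grid[g][1]))
    best = grid[order[0]]

    final_model = None
    whole_mse = np.nan
    if fit_final:
        std_all, record_all = standardize(data)
        final_model = gee_tgdr.fit(
            std_all,
            kind=kind,
            tau=best[1],
            delta_v=delta_v,
            K=best[0],
            nuisance_refresh=nuisance_refresh,
            record=record_all,
        )
        whole_mse = gee_tgdr.mse(gee_tgdr.predict(final_model, data.X), data.Y)

    return CvResult(
        grid=grid,
        per_fold_mse=per_fold,
        mean_mse=mean_mse,
        sd_mse=sd_mse,
        best=best,
        whole_data_mse=float(whole_mse),
        fold_assignment=assignment,
        seed=int(seed),
        model=final_model,
    )
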