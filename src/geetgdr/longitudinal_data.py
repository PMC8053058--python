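"""Balanced longitudinal datasets and their tabular IO.

A dataset couples a subjects x features covariate matrix ``X`` (baseline,
time-invariant values such as expression profiles) with a subjects x
time-points outcome matrix ``Y`` (e.g. PASI severity scores measured
repeatedly under treatment).  Only complete, balanced panels are accepted:
every subject must have a covariate row and an outcome value at every time
point.  Missing entries are an error, never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("geetgdr")

__all__ = [
    "LongitudinalDataset",
    "StandardizationRecord",
    "read_dataset",
    "write_dataset",
    "standardize",
]


@dataclass
class LongitudinalDataset:
    """A balanced panel: time-invariant covariates plus repeated outcomes.

    Parameters
    ----------
    X : ndarray of shape (n, P)
        Covariate values, one row per subject, constant over time.
    Y : ndarray of shape (n, t)
        Outcomes, one column per time point, aligned row-wise with ``X``.
    subject_ids, feature_names, time_labels : sequences of str
        Axis labels; subject order defines the row order of both matrices.
    """

    X: np.ndarray
    Y: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    time_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-d arrays")
        n, P = self.X.shape
        n2, t = self.Y.shape
        if n != n2:
            raise ValueError(f"X has {n} subjects but Y has {n2}")
        if n < 2:
            raise ValueError("at least 2 subjects are required")
        if P < 1 or t < 1:
            raise ValueError("at least one feature and one time point required")
        if not self.subject_ids:
            self.subject_ids = [f"S{i + 1:04d}" for i in range(n)]
        if not self.feature_names:
            self.feature_names = [f"F{p + 1:04d}" for p in range(P)]
        if not self.time_labels:
            self.time_labels = [f"t{j}" for j in range(t)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match X rows")
        if len(self.feature_names) != P:
            raise ValueError("feature_names length does not match X columns")
        if len(self.time_labels) != t:
            raise ValueError("time_labels length does not match Y columns")
        for name, labels in (
            ("subject_ids", self.subject_ids),
            ("feature_names", self.feature_names),
            ("time_labels", self.time_labels),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} contains duplicates")
        _check_finite(self.X, "covariate", self.subject_ids, self.feature_names)
        _check_finite(self.Y, "outcome", self.subject_ids, self.time_labels)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def t(self) -> int:
        return self.Y.shape[1]

    def subset(self, rows: np.ndarray) -> "LongitudinalDataset":
        """Dataset restricted to a boolean mask or index array of subjects."""
        idx = np.arange(self.n)[rows] if np.asarray(rows).dtype == bool else np.asarray(rows)
        return LongitudinalDataset(
            X=self.X[idx].copy(),
            Y=self.Y[idx].copy(),
            subject_ids=[self.subject_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            time_labels=list(self.time_labels),
        )


def _check_finite(M: np.ndarray, what: str, rows: list[str], cols: list[str]) -> None:
    bad = np.argwhere(~np.isfinite(M))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"missing or non-finite {what} value at subject {rows[i]!r}, column {cols[j]!r}"
        )


@dataclass
class StandardizationRecord:
    """Centering/scaling constants needed to undo `standardize`.

    ``feature_means``/``feature_sds`` transform covariate columns to mean 0,
    sample SD 1 (denominator n-1); ``outcome_means`` are the per-time-point
    means removed from the outcomes (zeros when outcomes were not centered).
    """

    feature_means: np.ndarray
    feature_sds: np.ndarray
    outcome_means: np.ndarray

    def apply_to_covariates(self, X: np.ndarray) -> np.ndarray:
        """Scale new raw covariate rows onto the training scale."""
        return (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds

    def destandardize_coefficients(
        self, beta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map coefficients on the standardized scale back to the raw scale.

        Returns ``(beta_raw, intercepts)`` with one intercept per time point
        such that raw-scale predictions ``intercept_j + X @ beta_raw[j]``
        equal standardized-scale predictions plus the stored outcome means.
        """
        beta = np.atleast_2d(np.asarray(beta, dtype=float))
        beta_raw = beta / self.feature_sds
        intercepts = self.outcome_means - beta_raw @ self.feature_means
        return beta_raw, intercepts


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    low = str(path).lower()
    return "," if low.endswith(".csv") else "\t"


def _read_table(path: str, id_column: str, delimiter: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing ID column {id_column!r}")
    ids = df[id_column].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise ValueError(f"{path}: duplicate subject IDs: {', '.join(dup)}")
    df = df.set_index(ids).drop(columns=[id_column])
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: missing or non-numeric value at subject {bad[0]!r}, "
                f"column {col!r}"
            )
        df[col] = vals
    return df


def read_dataset(
    covariate_path: str,
    outcome_path: str,
    id_column: str = "subject",
    delimiter: str | None = None,
) -> LongitudinalDataset:
    """Load and align a covariate table and an outcome table.

    Both files are delimited text (comma for ``.csv``, tab otherwise, unless
    ``delimiter`` overrides) with a header row and a shared subject-ID column.
    Covariate columns are features; outcome columns are ordered time points.
    Subjects present in only one file raise an error naming the offenders;
    constant (zero-variance) covariate columns are logged and dropped because
    they cannot be standardized and carry no signal.
    """
    cov = _read_table(covariate_path, id_column, delimiter)
    out = _read_table(outcome_path, id_column, delimiter)
    only_cov = cov.index.difference(out.index)
    only_out = out.index.difference(cov.index)
    if len(only_cov) or len(only_out):
        parts = []
        if len(only_cov):
            parts.append(f"only in covariate file: {', '.join(only_cov)}")
        if len(only_out):
            parts.append(f"only in outcome file: {', '.join(only_out)}")
        raise ValueError("subject ID mismatch between files; " + "; ".join(parts))
    out = out.loc[cov.index]

    constant = [c for c in cov.columns if cov[c].nunique() == 1]
    if constant:
        logger.warning(
            "dropping %d constant covariate column(s): %s",
            len(constant),
            ", ".join(map(str, constant)),
        )
        cov = cov.drop(columns=constant)
    if cov.shape[1] == 0:
        raise ValueError("no non-constant covariate columns remain")

    return LongitudinalDataset(
        X=cov.to_numpy(dtype=float),
        Y=out.to_numpy(dtype=float),
        subject_ids=list(cov.index),
        feature_names=list(map(str, cov.columns)),
        time_labels=list(map(str, out.columns)),
    )


def write_dataset(
    data: LongitudinalDataset,
    covariate_path: str,
    outcome_path: str,
    id_column: str = "subject",
    delimiter: str | None = None,
) -> None:
    """Write the two-table representation read back by `read_dataset`."""
    cov = pd.DataFrame(data.X, columns=data.feature_names)
    cov.insert(0, id_column, data.subject_ids)
    out = pd.DataFrame(data.Y, columns=data.time_labels)
    out.insert(0, id_column, data.subject_ids)
    cov.to_csv(covariate_path, sep=_delimiter_for(covariate_path, delimiter), index=False)
    out.to_csv(outcome_path, sep=_delimiter_for(outcome_path, delimiter), index=False)


def standardize(
    data: LongitudinalDataset, center_outcomes: bool = True
) -> tuple[LongitudinalDataset, StandardizationRecord]:
    """Scale covariate columns to mean 0, sample SD 1; optionally center outcomes.

    Gradient thresholding compares gradient magnitudes across features, which
    is only meaningful on a common covariate scale; per-time outcome centering
    substitutes for unpenalized time-specific intercepts.  Sample SD uses
    denominator n-1.  Zero-variance covariate columns are an error.
    """
    means = data.X.mean(axis=0)
    sds = data.X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = ", ".join(data.feature_names[p] for p in zero[:5])
        raise ValueError(f"zero-variance covariate column(s): {names}")
    if center_outcomes:
        out_means = data.Y.mean(axis=0)
    else:
        out_means = np.zeros(data.t)
    std = LongitudinalDataset(
        X=(data.X - means) / sds,
        Y=data.Y - out_means,
        subject_ids=list(data.subject_ids),
        feature_names=list(data.feature_names),
        time_labels=list(data.time_labels),
    )
    return std, StandardizationRecord(means, sds, out_means)
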