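"""Per-(parameter, condition, eye) feature tables, imputation and scaling.

Each of the 17 kinetic parameters, measured under each of the 4 stimulus
conditions in each eye, yields one subjects x targets feature matrix
(54 columns for dim conditions, 4 for bright), giving 17 x 4 x 2 = 136
tables for a full cohort.  Each table feeds one classifier.

Preprocessing follows the mean-substitution + min-max recipe: missing
cells are replaced by the training-column mean, then every column is
rescaled to [0, 1] using the training minimum and maximum (held-out values
are imputed and scaled with the training statistics and clipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PARAMETER_NAMES
from .protocol import Condition, Eye, STIMULI

__all__ = [
    "FeatureTable",
    "build_tables",
    "impute_mean",
    "minmax_scale",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Subjects x targets matrix for one (parameter, condition, eye).

    ``matrix`` holds raw (unimputed) values with NaN for missing cells;
    ``labels`` are binary family-history labels (1 = FH+).
    """

    parameter: str
    condition: Condition
    eye: Eye
    matrix: np.ndarray
    labels: np.ndarray
    ages: np.ndarray
    subject_ids: list[str]
    target_indices: list[int]

    @property
    def key(self) -> str:
        return f"{self.parameter}|{self.condition.value}|{self.eye.value}"

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.matrix).sum())

    def __post_init__(self) -> None:
        n, f = self.matrix.shape
        if f not in (54, 4):
            raise ValueError("feature count must be 54 (dim) or 4 (bright)")
        if len(self.labels) != n or len(self.ages) != n or len(self.subject_ids) != n:
            raise ValueError("labels/ages/subject_ids must match the number of rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")


_CONDITION_ORDER = (
    Condition.dim_red,
    Condition.dim_blue,
    Condition.bright_red,
    Condition.bright_blue,
)
_EYE_ORDER = (Eye.right, Eye.left)


def build_tables(
    features: pd.DataFrame, subjects: pd.DataFrame
) -> list[FeatureTable]:
    """Assemble feature tables from long-format extracted features.

    Produces one table per (parameter, condition, eye) present in the
    input, in a deterministic order (condition, eye, parameter); a full
    four-condition cohort yields 136 tables.  Subjects lacking data for
    either eye are excluded with a warning, matching the inclusion rule
    that both eyes must be eligible.
    """
    subjects = subjects.set_index("subject_id")
    eyes_per_subject = features.groupby("subject_id")["eye"].nunique()
    n_eyes = features["eye"].nunique()
    complete = eyes_per_subject[eyes_per_subject >= n_eyes].index
    dropped = sorted(set(features["subject_id"]) - set(complete))
    if dropped:
        log.warning("excluding %d subject(s) missing an eye: %s", len(dropped), dropped)
        features = features[features["subject_id"].isin(complete)]

    subject_order = [s for s in subjects.index if s in set(complete)]
    labels = (subjects.loc[subject_order, "group"] == "FHpos").to_numpy().astype(int)
    ages = subjects.loc[subject_order, "age_years"].to_numpy(dtype=float)

    tables: list[FeatureTable] = []
    for condition in _CONDITION_ORDER:
        sub_c = features[features["condition"] == condition.value]
        if sub_c.empty:
            continue
        n_targets = STIMULI[condition].n_targets
        targets = list(range(1, n_targets + 1))
        for eye in _EYE_ORDER:
            sub = sub_c[sub_c["eye"] == eye.value]
            if sub.empty:
                continue
            for parameter in PARAMETER_NAMES:
                pivot = sub.pivot_table(
                    index="subject_id",
                    columns="target_index",
                    values=parameter,
                    aggfunc="first",
                    dropna=False,
                )
                pivot = pivot.reindex(index=subject_order, columns=targets)
                tables.append(
                    FeatureTable(
                        parameter=parameter,
                        condition=condition,
                        eye=eye,
                        matrix=pivot.to_numpy(dtype=float),
                        labels=labels.copy(),
                        ages=ages.copy(),
                        subject_ids=list(subject_order),
                        target_indices=targets,
                    )
                )
    return tables


def impute_mean(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, int, np.ndarray]:
    """Mean-substitution imputation fit on the training matrix.

    Missing cells are replaced by the training-column mean; held-out rows
    use the training means.  Columns with no observed training value are
    dropped (with a warning) from both matrices.

    Returns ``(train, test, n_imputed, kept_columns)`` where ``n_imputed``
    counts replaced cells across both matrices and ``kept_columns`` is a
    boolean mask over the original columns.
    """
    train = np.array(train, dtype=float)
    test = None if test is None else np.array(test, dtype=float)
    observed = ~np.isnan(train)
    kept = observed.any(axis=0)
    if not kept.all():
        log.warning("dropping %d all-missing column(s)", int((~kept).sum()))
        train = train[:, kept]
        test = None if test is None else test[:, kept]
        observed = observed[:, kept]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(train, axis=0)
    n_imputed = int((~observed).sum())
    train = np.where(observed, train, means)
    if test is not None:
        test_missing = np.isnan(test)
        n_imputed += int(test_missing.sum())
        test = np.where(test_missing, np.broadcast_to(means, test.shape), test)
    return train, test, n_imputed, kept


def minmax_scale(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Min-max rescale columns to [0, 1] using training min/max.

    Constant columns map to 0.5 everywhere (any constant is equally
    uninformative); held-out values are clipped to [0, 1].
    """
    train = np.asarray(train, dtype=float)
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    constant = span == 0
    span = np.where(constant, 1.0, span)
    scaled_train = np.where(constant, 0.5, (train - lo) / span)
    scaled_test = None
    if test is not None:
        test = np.asarray(test, dtype=float)
        scaled_test = np.where(constant, 0.5, np.clip((test - lo) / span, 0.0, 1.0))
    return scaled_train, scaled_test


def preprocess(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, int, np.ndarray]:
    """Imputation followed by min-max scaling, fit on the training rows."""
    train, test, n_imputed, kept = impute_mean(train, test)
    train, test = minmax_scale(train, test)
    return train, test, n_imputed, kept
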