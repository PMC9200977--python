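"""Focal group comparison at the high-weight visual-field targets.

After the bootstrap stage produces an averaged weight map, targets whose
weight exceeds a threshold (0.47 in the reference analysis) are selected,
each subject's focal value is the mean of the parameter over those
targets, and the two family-history groups are compared with a two-sample
t-test (pooled variance by default) and with an age-adjusted general
linear model ``value ~ group + age``.  P-values are Bonferroni-corrected
for the number of selected targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as st
import statsmodels.api as sm

from .protocol import Eye

__all__ = [
    "GroupStats",
    "GroupComparison",
    "FocalComparison",
    "select_discriminative_targets",
    "compare_groups",
    "age_adjusted_comparison",
    "bonferroni",
    "focal_comparison",
]


@dataclass(frozen=True)
class GroupStats:
    """Mean, standard error and 95% CI of one group."""

    n: int
    mean: float
    se: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: per-group stats and the test p-value."""

    fh_neg: GroupStats
    fh_pos: GroupStats
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class FocalComparison:
    """Full focal result for one eye, unadjusted and age-adjusted."""

    eye: Eye
    selected_targets: tuple[int, ...]
    unadjusted: GroupComparison
    age_adjusted: GroupComparison
    bonferroni_m: int
    p_unadjusted_corrected: float
    p_age_adjusted_corrected: float

    @property
    def significant(self) -> bool:
        return self.p_unadjusted_corrected < 0.05

    def to_dict(self) -> dict:
        def grp(c: GroupComparison) -> dict:
            return {
                "FHneg": vars(c.fh_neg) | {"ci95": list(c.fh_neg.ci95)},
                "FHpos": vars(c.fh_pos) | {"ci95": list(c.fh_pos.ci95)},
                "t": c.t_stat,
                "p": c.p_value,
            }

        return {
            "eye": self.eye.value,
            "selected_targets": list(self.selected_targets),
            "unadjusted": grp(self.unadjusted),
            "age_adjusted": grp(self.age_adjusted),
            "bonferroni_m": self.bonferroni_m,
            "p_unadjusted_corrected": self.p_unadjusted_corrected,
            "p_age_adjusted_corrected": self.p_age_adjusted_corrected,
            "significant": self.significant,
        }


def select_discriminative_targets(
    weight_map: np.ndarray,
    threshold: float = 0.47,
    target_indices: list[int] | None = None,
) -> list[int]:
    """Targets whose averaged weight strictly exceeds ``threshold``.

    Returns 1-based target indices sorted by descending weight; the
    selection may be empty.
    """
    w = np.asarray(weight_map, dtype=float)
    idx = target_indices or list(range(1, len(w) + 1))
    chosen = [(float(w[i]), idx[i]) for i in range(len(w)) if w[i] > threshold]
    chosen.sort(key=lambda pair: (-pair[0], pair[1]))
    return [i for _, i in chosen]


def _group_stats(x: np.ndarray) -> GroupStats:
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n) if n > 0 else math.nan
    if n > 1 and se > 0:
        half = float(st.t.ppf(0.975, n - 1)) * se
    else:
        half = 0.0
    return GroupStats(n=n, mean=mean, se=se, ci95=(mean - half, mean + half))


def compare_groups(
    values: np.ndarray, labels: np.ndarray, equal_var: bool = True
) -> GroupComparison:
    """Two-sided two-sample t-test (pooled variance by default).

    ``labels`` are binary with 1 = FH+.  Values that are NaN are dropped
    pairwise.  Degenerate groups (< 2 subjects) are rejected.  When both
    groups are identical constant samples the difference is exactly zero
    and p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    neg, pos = values[labels == 0], values[labels == 1]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("both groups need at least 2 subjects")
    if np.var(neg) == 0 and np.var(pos) == 0:
        same = float(np.mean(pos) - np.mean(neg)) == 0.0
        t_stat, p = 0.0, 1.0 if same else 0.0
    else:
        t_stat, p = st.ttest_ind(pos, neg, equal_var=equal_var)
    return GroupComparison(
        fh_neg=_group_stats(neg),
        fh_pos=_group_stats(pos),
        t_stat=float(t_stat),
        p_value=float(p),
    )


def age_adjusted_comparison(
    values: np.ndarray, labels: np.ndarray, ages: np.ndarray
) -> GroupComparison:
    """General linear model ``value ~ group + age``.

    Adjusted group means are the model predictions at the overall mean age;
    their standard errors come from the coefficient covariance.  The group
    p-value is the Wald p of the group coefficient.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    ages = np.asarray(ages, dtype=float)
    ok = np.isfinite(values) & np.isfinite(ages)
    values, labels, ages = values[ok], labels[ok], ages[ok]
    neg_n, pos_n = int((labels == 0).sum()), int((labels == 1).sum())
    if neg_n < 2 or pos_n < 2:
        raise ValueError("both groups need at least 2 subjects")
    X = sm.add_constant(np.column_stack([labels, ages]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (collinear) design matrix")
    fit = sm.OLS(values, X).fit()
    mean_age = float(ages.mean())

    def adjusted(group: int, n: int) -> GroupStats:
        row = np.array([1.0, float(group), mean_age])
        mean = float(row @ fit.params)
        se = float(math.sqrt(row @ fit.cov_params() @ row))
        half = float(st.t.ppf(0.975, int(fit.df_resid))) * se
        return GroupStats(n=n, mean=mean, se=se, ci95=(mean - half, mean + half))

    return GroupComparison(
        fh_neg=adjusted(0, neg_n),
        fh_pos=adjusted(1, pos_n),
        t_stat=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
    )


def bonferroni(p_values, m: int):
    """Bonferroni correction: p -> min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.minimum(1.0, np.asarray(p_values, dtype=float) * m)
    return float(p) if p.ndim == 0 else p


def focal_comparison(
    values_by_target: np.ndarray,
    labels: np.ndarray,
    ages: np.ndarray,
    weight_map: np.ndarray,
    eye: Eye | str,
    threshold: float = 0.47,
    target_indices: list[int] | None = None,
    equal_var: bool = True,
) -> FocalComparison | None:
    """Select high-weight targets and run both group comparisons.

    ``values_by_target`` is the raw subjects x targets matrix of the focal
    parameter (NaN allowed); each subject's focal value is the NaN-mean over
    the selected targets.  Returns None when no target exceeds the threshold.
    """
    idx = target_indices or list(range(1, values_by_target.shape[1] + 1))
    selected = select_discriminative_targets(weight_map, threshold, idx)
    if not selected:
        return None
    cols = [idx.index(i) for i in selected]
    sub = values_by_target[:, cols]
    counts = np.sum(np.isfinite(sub), axis=1)
    # NaN-mean per subject; subjects with no observed selected target stay NaN
    focal_values = np.where(counts > 0, np.nan_to_num(sub).sum(axis=1)
                            / np.maximum(counts, 1), np.nan)
    unadj = compare_groups(focal_values, labels, equal_var=equal_var)
    adj = age_adjusted_comparison(focal_values, labels, ages)
    m = len(selected)
    return FocalComparison(
        eye=Eye(eye),
        selected_targets=tuple(selected),
        unadjusted=unadj,
        age_adjusted=adj,
        bonferroni_m=m,
        p_unadjusted_corrected=bonferroni(unadj.p_value, m),
        p_age_adjusted_corrected=bonferroni(adj.p_value, m),
    )
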