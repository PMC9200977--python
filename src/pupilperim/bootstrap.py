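"""Stratified bootstrap out-of-bag evaluation of the per-parameter models.

For each feature table the procedure is: (1) draw a stratified bootstrap
sample of subjects — within each family-history class, class-size draws
with replacement; (2) fit preprocessing (mean imputation + min-max) and the
boosted classifier on the in-bag rows; (3) score the out-of-bag subjects
(those never drawn) and record the AUC-ROC and the model's per-target
feature weights; (4) repeat over B replicates (default 2000) and summarise
with the mean, SD, 2.5/97.5 percentile confidence interval and the
replicate-averaged weight map.

Replicates whose out-of-bag set lacks one of the classes are skipped and
counted, not resampled.  Replicate r uses the generator seeded with
``(master_seed, r)``, so results are reproducible and independent of
evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boosting import auc_roc, predict_score, train_adaboost
from .tables import FeatureTable, preprocess

__all__ = [
    "BootstrapResult",
    "stratified_bootstrap_split",
    "bootstrap_auc",
    "aggregate_weight_map",
]

log = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Summary of one table's bootstrap evaluation."""

    key: str
    B: int
    auc_per_replicate: np.ndarray
    auc_mean: float
    auc_sd: float
    ci95: tuple[float, float]
    mean_weight_map: np.ndarray
    mean_oob_size: float
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "key": self.key,
            "B": self.B,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "ci95": list(self.ci95),
            "mean_weight_map": self.mean_weight_map.tolist(),
            "mean_oob_size": self.mean_oob_size,
            "n_skipped": self.n_skipped,
        }


def stratified_bootstrap_split(
    labels: np.ndarray, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified bootstrap draw: (in_bag indices, out_of_bag indices).

    Within each class, class-size indices are drawn with replacement; the
    out-of-bag set contains the subjects never drawn.  The in-bag sample
    therefore always has size n with both classes at their original
    frequencies.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("stratified split requires both classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    in_bag_parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        in_bag_parts.append(rng.choice(idx, size=len(idx), replace=True))
    in_bag = np.concatenate(in_bag_parts)
    oob = np.setdiff1d(np.arange(len(labels)), in_bag)
    return in_bag, oob


def bootstrap_auc(
    table: FeatureTable,
    B: int = 2000,
    rounds: int = 50,
    seed: int = 0,
    global_preprocess: bool = False,
) -> BootstrapResult:
    """Bootstrap out-of-bag AUC-ROC and averaged weight map for one table.

    ``global_preprocess=True`` fits imputation and scaling once on the whole
    table before resampling (a whole-dataset reading of the recipe); the
    default refits both inside every replicate on the in-bag rows only,
    which is leakage-safe.
    """
    if B < 2:
        raise ValueError("at least 2 bootstrap replicates are required")
    n, F = table.matrix.shape
    labels = table.labels
    if global_preprocess:
        matrix, _, _, _ = preprocess(table.matrix)
    else:
        matrix = table.matrix

    aucs: list[float] = []
    weights: list[np.ndarray] = []
    oob_sizes: list[int] = []
    skipped = 0
    for r in range(B):
        rng = np.random.default_rng([seed, r])
        in_bag, oob = stratified_bootstrap_split(labels, rng)
        if len(np.unique(labels[oob])) < 2:
            skipped += 1
            continue
        X_tr, X_te = matrix[in_bag], matrix[oob]
        if not global_preprocess:
            X_tr, X_te, _, kept = preprocess(X_tr, X_te)
        else:
            kept = np.ones(F, dtype=bool)
        model = train_adaboost(X_tr, labels[in_bag], rounds=rounds)
        scores = predict_score(model, X_te)
        aucs.append(auc_roc(scores, labels[oob]))
        w = np.zeros(F)
        w[kept] = model.feature_weights
        weights.append(w)
        oob_sizes.append(len(oob))
    if skipped:
        log.info("%s: skipped %d degenerate replicate(s)", table.key, skipped)
    if not aucs:
        raise ValueError("all bootstrap replicates were degenerate")

    auc_arr = np.asarray(aucs)
    sd = float(auc_arr.std(ddof=1)) if len(auc_arr) > 1 else 0.0
    lo, hi = np.percentile(auc_arr, [2.5, 97.5])
    return BootstrapResult(
        key=table.key,
        B=B,
        auc_per_replicate=auc_arr,
        auc_mean=float(auc_arr.mean()),
        auc_sd=sd,
        ci95=(float(lo), float(hi)),
        mean_weight_map=aggregate_weight_map(np.asarray(weights)),
        mean_oob_size=float(np.mean(oob_sizes)),
        n_skipped=skipped,
    )


def aggregate_weight_map(per_replicate_weights: np.ndarray) -> np.ndarray:
    """Arithmetic mean of per-replicate weight maps, renormalised to sum 1."""
    w = np.asarray(per_replicate_weights, dtype=float)
    if w.ndim != 2 or len(w) == 0:
        raise ValueError("need a (replicates, targets) array with >= 1 row")
    mean = w.mean(axis=0)
    total = mean.sum()
    return mean / total if total > 0 else np.full(w.shape[1], 1.0 / w.shape[1])
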