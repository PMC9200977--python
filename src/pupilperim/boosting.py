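"""Discrete AdaBoost over decision stumps, scores and AUC-ROC.

Each per-parameter classifier is a discrete AdaBoost ensemble of depth-1
threshold stumps trained on one subjects x targets feature table.  The
implementation is fully deterministic: candidate thresholds sit at
midpoints between sorted distinct feature values, and ties in weighted
error break towards the lowest feature index, then the lowest threshold,
then positive polarity.  Per-feature importances are the normalised sums
of |alpha_t| over the stumps that use each feature, which is what the
averaged visual-field weight maps display.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "Stump",
    "BoostedModel",
    "train_adaboost",
    "predict_score",
    "auc_roc",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Stump:
    """One threshold stump: predicts ``polarity`` if x[feature] > threshold."""

    feature: int
    threshold: float
    polarity: int  # +1 or -1
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = np.where(X[:, self.feature] > self.threshold, 1, -1)
        return self.polarity * h


@dataclass
class BoostedModel:
    """A trained stump ensemble over ``n_features`` aligned feature columns."""

    n_features: int
    stumps: list[Stump]

    @property
    def feature_weights(self) -> np.ndarray:
        """Normalised per-feature importance: sum of |alpha| per feature.

        Sums to 1; an empty model returns the uniform map.
        """
        w = np.zeros(self.n_features)
        for s in self.stumps:
            w[s.feature] += abs(s.alpha)
        total = w.sum()
        if total == 0:
            return np.full(self.n_features, 1.0 / self.n_features)
        return w / total

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_features": self.n_features,
                "stumps": [
                    {"feature": s.feature, "threshold": s.threshold,
                     "polarity": s.polarity, "alpha": s.alpha}
                    for s in self.stumps
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BoostedModel":
        obj = json.loads(text)
        return cls(
            n_features=obj["n_features"],
            stumps=[Stump(**s) for s in obj["stumps"]],
        )


def _best_stump(
    Xs: np.ndarray,
    order: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    valid: np.ndarray,
) -> tuple[int, float, int, float]:
    """Exhaustive weighted-error search over all stumps, vectorised.

    ``Xs`` is the column-sorted matrix, ``order`` the per-column argsort and
    ``valid`` marks cut positions between distinct adjacent values.
    Returns (feature, threshold, polarity, weighted_error).
    """
    n, F = Xs.shape
    wy = w[order]  # (n, F) sample weights in sorted order
    is_pos = (y[order] == 1)
    cpos = np.cumsum(np.where(is_pos, wy, 0.0), axis=0)
    cneg = np.cumsum(np.where(is_pos, 0.0, wy), axis=0)
    w_neg = cneg[-1, 0]  # total negative weight (same for every column)
    # Cut after position k (k = 0..n-2); polarity +1 predicts +1 above the cut:
    # err = (positives below or at cut) + (negatives above cut).  Sample
    # weights are kept normalised, so the opposite polarity errs 1 - err.
    err_plus_raw = cpos[:-1] + (w_neg - cneg[:-1])
    err_plus = np.where(valid, err_plus_raw, np.inf)
    err_minus = np.where(valid, 1.0 - err_plus_raw, np.inf)
    # Tie-break order: feature asc, threshold asc, polarity +1 first.
    E = np.stack([err_plus.T, err_minus.T], axis=-1)  # (F, n-1, 2)
    flat = int(np.argmin(E))
    f, rest = divmod(flat, (n - 1) * 2)
    k, p = divmod(rest, 2)
    threshold = 0.5 * (Xs[k, f] + Xs[k + 1, f])
    polarity = 1 if p == 0 else -1
    return f, float(threshold), polarity, float(E[f, k, p])


def train_adaboost(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int = 50,
    seed: int | None = None,
) -> BoostedModel:
    """Train discrete AdaBoost with threshold stumps.

    Parameters
    ----------
    X:
        (n, F) feature matrix (preprocessed to [0, 1], no missing values).
    y:
        Binary labels in {0, 1}; both classes must be present.
    rounds:
        Maximum number of boosting rounds T.
    seed:
        Accepted for interface symmetry; training is deterministic and
        draws no random numbers.

    Boosting stops early when the best stump's weighted error reaches 0
    (after recording that stump) or is no better than chance (>= 1/2,
    without recording it).
    """
    del seed  # deterministic
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y).astype(int)
    classes = set(np.unique(y01))
    if not classes == {0, 1}:
        raise ValueError("training labels must contain both classes (0 and 1)")
    ysgn = np.where(y01 == 1, 1, -1)
    n, F = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    valid = Xs[1:] > Xs[:-1]  # cut only between distinct adjacent values
    if not valid.any():
        return BoostedModel(n_features=F, stumps=[])

    w = np.full(n, 1.0 / n)
    stumps: list[Stump] = []
    for _ in range(rounds):
        f, thr, pol, err = _best_stump(Xs, order, ysgn, w, valid)
        if err >= 0.5 - _EPS:
            break
        alpha = 0.5 * math.log((1.0 - err + _EPS) / (err + _EPS))
        stump = Stump(feature=f, threshold=thr, polarity=pol, alpha=alpha)
        stumps.append(stump)
        if err <= _EPS:
            break
        h = stump.predict(X)
        w = w * np.exp(-alpha * ysgn * h)
        w /= w.sum()
    return BoostedModel(n_features=F, stumps=stumps)


def predict_score(model: BoostedModel, X: np.ndarray) -> np.ndarray:
    """Signed ensemble margin sum_t alpha_t * h_t(x); monotone in P(FH+)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.n_features}"
        )
    scores = np.zeros(len(X))
    for s in model.stumps:
        scores += s.alpha * s.predict(X)
    return scores


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC in its Mann-Whitney form: P(random positive outscores a
    random negative), with tied scores counted 1/2.

    Returns NaN when only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        return math.nan
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
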