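"""Top-line thresholds, binarization, and decision-cutoff tuning.

Boundary semantics follow the two different rules used to define observed and
predicted classes: observed labels use ``y >= Y_tau`` (inclusive), predicted
labels use ``score > cutoff`` (strict).  Both operators are configurable.

The tuned cutoff minimizes the squared difference between sensitivity and
specificity over the exact candidate set of a step function: midpoints of
consecutive distinct scores, plus one candidate below the minimum and one
above the maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class ThresholdError(ValueError):
    pass


@dataclass
class ThresholdSpec:
    """How the top-line threshold Y_tau is defined, and its resolved value."""

    kind: str = "quantile"  # quantile | check_mean | check_max | fixed
    tau: float = 0.8
    value: float = None

    KINDS = ("quantile", "check_mean", "check_max", "fixed")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ThresholdError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "quantile":
            if self.tau is None or not 0.0 < self.tau < 1.0:
                raise ThresholdError("quantile tau must be in (0, 1)")
        if self.kind == "fixed" and self.value is None:
            raise ThresholdError("fixed threshold requires a value")

    def as_dict(self) -> dict:
        return {"kind": self.kind, "tau": self.tau, "value": self.value}


@dataclass
class OptimalCutoff:
    """A tuned decision cutoff and the objective it achieved.

    ``level`` is the fraction of tuning scores at or below ``value`` — for
    probability cutoffs it is reported for bookkeeping, for continuous
    cutoffs it is the quantile level re-resolved on refit predictions.
    """

    level: float
    value: float
    objective: float
    per_fold: list = field(default_factory=list)
    n_folds_used: int = None
    n_folds_skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "value": self.value,
            "objective": self.objective,
            "n_folds_used": self.n_folds_used,
            "n_folds_skipped": self.n_folds_skipped,
            "per_fold": [
                {"level": f.level, "value": f.value, "objective": f.objective}
                for f in self.per_fold
            ],
        }


@dataclass
class BinaryLabels:
    line_ids: list
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.line_ids):
            raise ThresholdError("labels inconsistent with line ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ThresholdError("labels must be 0/1")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def both_classes(self) -> bool:
        return 0 < self.n_positive < self.labels.shape[0]


# ---------------------------------------------------------------------------


def resolve_threshold(
    y: np.ndarray, spec: ThresholdSpec, checks: np.ndarray = None
) -> ThresholdSpec:
    """Resolve Y_tau on training trait values (type-7 empirical quantile for
    the quantile kind; mean/max of check values for check kinds)."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "quantile":
        if y.size == 0:
            raise ThresholdError("empty training values")
        value = float(np.quantile(y, spec.tau, method="linear"))
    elif spec.kind in ("check_mean", "check_max"):
        if checks is None or np.asarray(checks).size == 0:
            raise ThresholdError(f"{spec.kind} threshold requires check values")
        checks = np.asarray(checks, dtype=float)
        value = float(checks.mean() if spec.kind == "check_mean" else checks.max())
    else:  # fixed
        value = float(spec.value)
    return ThresholdSpec(kind=spec.kind, tau=spec.tau, value=value)


def binarize(y: np.ndarray, threshold: ThresholdSpec, line_ids=None,
             inclusive: bool = True) -> BinaryLabels:
    """Observed class labels: 1 where ``y >= Y_tau`` (default inclusive)."""
    if threshold.value is None:
        raise ThresholdError("threshold not resolved")
    y = np.asarray(y, dtype=float)
    labels = (y >= threshold.value) if inclusive else (y > threshold.value)
    out = BinaryLabels(
        line_ids if line_ids is not None else list(range(y.shape[0])),
        labels.astype(int),
    )
    logger.debug("binarize: %d/%d positive at %.6g",
                 out.n_positive, y.shape[0], threshold.value)
    return out


def classify(scores: np.ndarray, cutoff: float, line_ids=None,
             strict: bool = True) -> BinaryLabels:
    """Predicted class labels: 1 where ``score > cutoff`` (default strict)."""
    if not np.isfinite(cutoff):
        raise ThresholdError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = (scores > cutoff) if strict else (scores >= cutoff)
    return BinaryLabels(
        line_ids if line_ids is not None else list(range(scores.shape[0])),
        labels.astype(int),
    )


def _sens_spec(scores: np.ndarray, labels: np.ndarray, cutoff: float):
    pred = scores > cutoff
    pos = labels == 1
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens, spec


def candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive sorted distinct scores, plus one candidate
    below the minimum and one above the maximum."""
    s = np.unique(np.asarray(scores, dtype=float))
    span = s[-1] - s[0] if s.shape[0] > 1 else max(abs(s[0]), 1.0)
    below = s[0] - 0.5 * span - 1e-9
    above = s[-1] + 1e-9
    if s.shape[0] == 1:
        return np.array([below, above])
    mids = 0.5 * (s[:-1] + s[1:])
    return np.concatenate(([below], mids, [above]))


def optimal_cutoff(scores: np.ndarray, labels: BinaryLabels) -> OptimalCutoff:
    """Single-fold cutoff minimizing (sensitivity - specificity)^2.

    Ties are broken toward the smallest candidate cutoff, which favors
    sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    lab = labels.labels if isinstance(labels, BinaryLabels) else np.asarray(labels)
    if lab.shape[0] != scores.shape[0]:
        raise ThresholdError("scores and labels differ in length")
    if lab.min() == lab.max():
        raise ThresholdError("single-class validation labels; skip this fold")
    cands = candidate_cutoffs(scores)
    best_c, best_obj = None, np.inf
    for c in cands:
        sens, spec = _sens_spec(scores, lab, c)
        obj = (sens - spec) ** 2
        if obj < best_obj - 1e-15:
            best_c, best_obj = c, obj
    level = float(np.mean(scores <= best_c))
    return OptimalCutoff(level=level, value=float(best_c), objective=float(best_obj))


def aggregate_cutoffs(per_fold, strategy: str = "mean_of_cutoffs") -> OptimalCutoff:
    """Combine inner-fold optima into one tuned cutoff.

    ``mean_of_cutoffs`` averages cutoff values directly (probability scale,
    model B); ``mean_of_levels`` averages the quantile levels, to be
    re-resolved on refit predictions (continuous scale, model RO).
    """
    usable = [f for f in per_fold if f is not None]
    n_skipped = len(per_fold) - len(usable)
    if not usable:
        raise ThresholdError("no usable inner folds")
    if strategy == "mean_of_cutoffs":
        value = float(np.mean([f.value for f in usable]))
        level = float(np.mean([f.level for f in usable]))
    elif strategy == "mean_of_levels":
        level = float(np.mean([f.level for f in usable]))
        value = None  # resolved later on refit predictions
    else:
        raise ThresholdError(f"unknown aggregation strategy {strategy!r}")
    return OptimalCutoff(
        level=level,
        value=value,
        objective=float(np.mean([f.objective for f in usable])),
        per_fold=list(usable),
        n_folds_used=len(usable),
        n_folds_skipped=n_skipped,
    )


def pooled_optimal_cutoff(fold_scores, fold_labels) -> OptimalCutoff:
    """Alternative reading: average the per-candidate objective across folds,
    then take the argmin over a merged candidate grid."""
    pairs = [
        (np.asarray(s, dtype=float),
         l.labels if isinstance(l, BinaryLabels) else np.asarray(l))
        for s, l in zip(fold_scores, fold_labels)
    ]
    pairs = [(s, l) for s, l in pairs if l.min() != l.max()]
    if not pairs:
        raise ThresholdError("no usable inner folds")
    cands = candidate_cutoffs(np.concatenate([s for s, _ in pairs]))
    best_c, best_obj = None, np.inf
    for c in cands:
        obj = float(np.mean(
            [(lambda ss: (ss[0] - ss[1]) ** 2)(_sens_spec(s, l, c))
             for s, l in pairs]
        ))
        if obj < best_obj - 1e-15:
            best_c, best_obj = c, obj
    allsc = np.concatenate([s for s, _ in pairs])
    return OptimalCutoff(
        level=float(np.mean(allsc <= best_c)),
        value=float(best_c),
        objective=best_obj,
        n_folds_used=len(pairs),
        n_folds_skipped=len(fold_scores) - len(pairs),
    )


def resolve_continuous_cutoff(level: float, refit_predictions: np.ndarray) -> float:
    """Y_tau0: type-7 quantile of the refit model's fitted values at the
    tuned level.  Resolved on training fitted values only."""
    if not 0.0 < level < 1.0:
        raise ThresholdError("level must be in (0, 1)")
    preds = np.asarray(refit_predictions, dtype=float)
    if preds.size == 0:
        raise ThresholdError("empty refit predictions")
    return float(np.quantile(preds, level, method="linear"))


def adjust_predictions(y_hat: np.ndarray, Y_tau: float, Y_tau0: float) -> np.ndarray:
    """Rescale predictions so the nominal threshold can be reused:
    ``Y*_i = Y_i * (Y_tau / Y_tau0)``.

    When both thresholds are positive, ``classify(Y*, Y_tau)`` equals
    ``classify(Y_hat, Y_tau0)`` exactly; a sign-mixed pair breaks that
    equivalence and triggers a warning.
    """
    if Y_tau0 == 0.0:
        raise ThresholdError("Y_tau0 is zero; cannot rescale")
    if (Y_tau > 0) != (Y_tau0 > 0):
        warnings.warn(
            f"Y_tau ({Y_tau:.6g}) and Y_tau0 ({Y_tau0:.6g}) differ in sign; "
            "the rescaled-rule equivalence does not hold"
        )
    return np.asarray(y_hat, dtype=float) * (Y_tau / Y_tau0)
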