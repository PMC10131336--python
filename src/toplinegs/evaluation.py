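"""Binary-classifier evaluation: confusion counts, kappa/sensitivity/
specificity/precision/F1, relative efficiency, and fold summaries.

Undefined metrics (zero denominators) propagate as NaN and are excluded from
fold means, with the exclusion count reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .thresholding import BinaryLabels

logger = logging.getLogger(__name__)

METRIC_NAMES = ("f1", "kappa", "sensitivity", "specificity", "precision")


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for v in (self.TP, self.TN, self.FP, self.FN):
            if v < 0:
                raise EvaluationError("negative confusion count")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float
    p0: float
    pe: float

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "kappa": self.kappa,
            "p0": self.p0,
            "pe": self.pe,
        }


@dataclass
class ComparisonRow:
    metric: str
    model: str
    mean: float
    se: float
    ll: float
    ul: float
    n_folds: int
    n_na: int
    re_vs: dict = field(default_factory=dict)  # other model -> RE
    pct_adv_vs: dict = field(default_factory=dict)


def confusion(observed: BinaryLabels, predicted: BinaryLabels) -> ConfusionMatrix:
    """Exact counts with 1 (top line) as the positive class."""
    if list(observed.line_ids) != list(predicted.line_ids):
        raise EvaluationError("observed/predicted ids differ or are misordered")
    o, p = observed.labels, predicted.labels
    return ConfusionMatrix(
        TP=int(np.sum((o == 1) & (p == 1))),
        TN=int(np.sum((o == 0) & (p == 0))),
        FP=int(np.sum((o == 0) & (p == 1))),
        FN=int(np.sum((o == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Derive the metric suite from counts.

    Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); precision =
    TP/(TP+FP); F1 = harmonic mean of precision and sensitivity; kappa =
    (P0 - Pe)/(1 - Pe) with Pe the chance-agreement probability.  Any metric
    whose denominator is zero is NaN.
    """
    N = cm.N
    if N == 0:
        raise EvaluationError("empty confusion matrix")
    sens = _ratio(cm.TP, cm.TP + cm.FN)
    spec = _ratio(cm.TN, cm.TN + cm.FP)
    prec = _ratio(cm.TP, cm.TP + cm.FP)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    p0 = (cm.TP + cm.TN) / N
    pe = ((cm.TP + cm.FN) / N) * ((cm.TP + cm.FP) / N) + (
        (cm.FP + cm.TN) / N
    ) * ((cm.FN + cm.TN) / N)
    kappa = (p0 - pe) / (1.0 - pe) if pe != 1.0 else math.nan
    return MetricSet(
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        kappa=kappa, p0=p0, pe=pe,
    )


def evaluate_labels(observed: BinaryLabels, predicted: BinaryLabels) -> MetricSet:
    return metrics(confusion(observed, predicted))


def relative_efficiency(metric_y: float, metric_z: float) -> float:
    """RE = metric_y / metric_z; RE > 1 favors model y.  NaN inputs or a
    zero denominator give NaN."""
    if metric_y is None or metric_z is None:
        return math.nan
    if math.isnan(metric_y) or math.isnan(metric_z):
        logger.info("relative_efficiency: NaN input, RE undefined")
        return math.nan
    if metric_z == 0.0:
        logger.info("relative_efficiency: zero denominator, RE undefined")
        return math.nan
    return metric_y / metric_z


def percent_advantage(better: float, worse: float) -> float:
    """Percent by which the better model leads: 100 * (1 - worse/better)."""
    if better is None or math.isnan(better) or better <= 0.0:
        raise EvaluationError("percent_advantage requires better > 0")
    if worse is None or math.isnan(worse):
        return math.nan
    return 100.0 * (1.0 - worse / better)


def summarize_folds(per_model_folds: dict, confidence: float = 0.95) -> list:
    """Fold means, SEs and t-based interval bounds per metric and model,
    plus pairwise RE / percent advantage on the fold-mean metrics.

    Parameters
    ----------
    per_model_folds : mapping model label -> list of MetricSet (one per fold).
    """
    models = list(per_model_folds)
    if not models:
        raise EvaluationError("no models to summarize")
    for m, folds in per_model_folds.items():
        if len(folds) < 2:
            raise EvaluationError(f"model {m!r} has fewer than 2 folds")
    rows = []
    means = {}
    for metric in METRIC_NAMES:
        for model in models:
            vals = np.array([f[metric] for f in per_model_folds[model]], float)
            ok = vals[~np.isnan(vals)]
            n_na = int(np.isnan(vals).sum())
            if ok.size == 0:
                mean = se = ll = ul = math.nan
            else:
                mean = float(ok.mean())
                if ok.size > 1:
                    se = float(ok.std(ddof=1) / math.sqrt(ok.size))
                    tq = float(stats.t.ppf(0.5 + confidence / 2, ok.size - 1))
                    ll, ul = mean - tq * se, mean + tq * se
                else:
                    se, ll, ul = math.nan, math.nan, math.nan
            means[(metric, model)] = mean
            rows.append(ComparisonRow(
                metric=metric, model=model, mean=mean, se=se, ll=ll, ul=ul,
                n_folds=len(per_model_folds[model]), n_na=n_na,
            ))
    for row in rows:
        for other in models:
            if other == row.model:
                continue
            a, b = means[(row.metric, row.model)], means[(row.metric, other)]
            row.re_vs[other] = relative_efficiency(a, b)
            if not (math.isnan(a) or math.isnan(b)) and a > 0:
                row.pct_adv_vs[other] = percent_advantage(a, b)
            else:
                row.pct_adv_vs[other] = math.nan
    return rows


def comparison_table(rows: list) -> pd.DataFrame:
    """Render ComparisonRows as a flat table (metric, model, mean, SE, LL,
    UL, RE_vs_<other>...).  LL/UL are t-interval bounds over folds."""
    recs = []
    for r in rows:
        rec = {
            "metric": r.metric, "model": r.model, "mean": r.mean, "se": r.se,
            "ll": r.ll, "ul": r.ul, "n_folds": r.n_folds, "n_na": r.n_na,
        }
        for other, re in sorted(r.re_vs.items()):
            rec[f"re_vs_{other}"] = re
        for other, pa in sorted(r.pct_adv_vs.items()):
            rec[f"pct_adv_vs_{other}"] = pa
        recs.append(rec)
    return pd.DataFrame(recs)
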