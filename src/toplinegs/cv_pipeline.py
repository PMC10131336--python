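"""Nested cross-validation harness running models R, B and RO end to end.

Model R: fit the GBLUP regression on the outer-training lines, predict the
test lines, classify at the nominal threshold Y_tau.

Model B: binarize the outer-training responses at Y_tau, tune a probability
cutoff tau0 on inner folds of a probit threshold model, refit on the full
outer-training set, classify test probabilities at tau0.

Model RO: tune a continuous cutoff on inner folds of the regression model
(aggregating quantile levels), resolve Y_tau0 on the refit model's fitted
training values, classify test predictions at Y_tau0.

Test phenotypes and labels are never used for fitting, threshold resolution
or cutoff tuning; every fold's provenance records the id sets so this can be
asserted structurally.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import __version__
from .evaluation import (
    ConfusionMatrix,
    MetricSet,
    comparison_table,
    confusion,
    metrics,
    summarize_folds,
)
from .io_kinship import KinshipMatrix, MarkerMatrix, PhenotypeTable
from .models import (
    McmcConfig,
    fit_gblup,
    fit_tgblup,
    predict_gblup,
    predict_tgblup_proba,
)
from .thresholding import (
    BinaryLabels,
    OptimalCutoff,
    ThresholdError,
    ThresholdSpec,
    aggregate_cutoffs,
    binarize,
    classify,
    optimal_cutoff,
    resolve_continuous_cutoff,
    resolve_threshold,
)

logger = logging.getLogger(__name__)

MODELS = ("R", "B", "RO")


class PipelineError(RuntimeError):
    pass


@dataclass
class FoldPlan:
    """Outer/inner fold assignments, reproducible from the seed."""

    n_lines: int
    outer_k: int
    inner_k: int
    seed: int
    outer_assignment: np.ndarray  # fold index per line
    inner_assignments: dict = field(default_factory=dict)
    # outer fold -> (assignment over outer-training positions, stratified flag)

    def outer_fold_indices(self, fold: int):
        te = np.where(self.outer_assignment == fold)[0]
        tr = np.where(self.outer_assignment != fold)[0]
        return tr, te

    def inner_fold_for(self, fold: int, labels: np.ndarray):
        """Inner partition of the outer-training set, stratified on the
        binarized label when every stratum can fill the folds."""
        if fold in self.inner_assignments:
            return self.inner_assignments[fold]
        tr, _ = self.outer_fold_indices(fold)
        labels = np.asarray(labels)
        if labels.shape[0] != tr.shape[0]:
            raise PipelineError("labels must align with the outer-training set")
        rs = self.seed * 100003 + 7919 * (fold + 1)
        counts = np.bincount(labels, minlength=2)
        stratified = counts.min() >= self.inner_k
        assign = np.empty(tr.shape[0], dtype=int)
        if stratified:
            splitter = StratifiedKFold(
                n_splits=self.inner_k, shuffle=True, random_state=rs % (2**32)
            )
            splits = splitter.split(np.zeros(tr.shape[0]), labels)
        else:
            logger.warning(
                "outer fold %d: stratum smaller than inner_k=%d, "
                "falling back to unstratified inner folds", fold, self.inner_k
            )
            splitter = KFold(
                n_splits=self.inner_k, shuffle=True, random_state=rs % (2**32)
            )
            splits = splitter.split(np.zeros(tr.shape[0]))
        for j, (_, val) in enumerate(splits):
            assign[val] = j
        self.inner_assignments[fold] = (assign, stratified)
        return self.inner_assignments[fold]


def make_folds(n: int, outer_k: int = 5, inner_k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded random outer partition with fold sizes differing by at most 1."""
    if n < outer_k * 2:
        raise PipelineError(f"n = {n} too small for {outer_k} outer folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, outer_k)):
        assignment[chunk] = f
    return FoldPlan(
        n_lines=n, outer_k=outer_k, inner_k=inner_k, seed=seed,
        outer_assignment=assignment,
    )


@dataclass
class RunConfig:
    trait: str = "trait"
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    models: tuple = ("R", "B", "RO")
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    outer_k: int = 5
    inner_k: int = 10
    seed: int = 0
    gblup_mode: str = "blup_deterministic"  # or "gibbs"
    aggregation_b: str = "mean_of_cutoffs"
    aggregation_ro: str = "mean_of_levels"
    proba_mode: str = "posterior_mean_of_phi"
    global_threshold: bool = False  # resolve Y_tau once (check-based specs)

    def __post_init__(self):
        if not self.models:
            raise PipelineError("at least one model required")
        for m in self.models:
            if m not in MODELS:
                raise PipelineError(f"unknown model {m!r}")

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "threshold": self.threshold.as_dict(),
            "models": list(self.models),
            "mcmc": dict(self.mcmc.__dict__),
            "outer_k": self.outer_k,
            "inner_k": self.inner_k,
            "seed": self.seed,
            "gblup_mode": self.gblup_mode,
            "aggregation_b": self.aggregation_b,
            "aggregation_ro": self.aggregation_ro,
            "proba_mode": self.proba_mode,
            "global_threshold": self.global_threshold,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FoldModelResult:
    fold: int
    model: str
    test_ids: list
    scores: np.ndarray
    predicted: BinaryLabels
    observed: BinaryLabels
    cm: ConfusionMatrix
    metric_set: MetricSet
    threshold: ThresholdSpec = None
    cutoff: OptimalCutoff = None
    cutoff_value: float = None


@dataclass
class RunResult:
    config: RunConfig
    plan: FoldPlan
    fold_results: dict  # model -> list of FoldModelResult
    summary_rows: list
    provenance: dict

    def metrics_frame(self) -> pd.DataFrame:
        recs = []
        for model, frs in sorted(self.fold_results.items()):
            for fr in frs:
                rec = {"model": model, "fold": fr.fold,
                       **fr.metric_set.as_dict(), **fr.cm.as_dict()}
                rec["cutoff"] = fr.cutoff_value
                recs.append(rec)
        return pd.DataFrame(recs)

    def predictions_frame(self) -> pd.DataFrame:
        recs = []
        for model, frs in sorted(self.fold_results.items()):
            for fr in frs:
                for lid, s, pl, ol in zip(
                    fr.test_ids, fr.scores, fr.predicted.labels,
                    fr.observed.labels,
                ):
                    recs.append({
                        "line_id": lid, "fold": fr.fold, "model": model,
                        "score": s, "label": int(pl), "observed": int(ol),
                    })
        return pd.DataFrame(recs)

    def summary_frame(self) -> pd.DataFrame:
        return comparison_table(self.summary_rows)


def _mcmc_for(cfg: RunConfig, outer: int, inner: int = -1) -> McmcConfig:
    base = cfg.mcmc
    return McmcConfig(
        n_iter=base.n_iter, burn_in=base.burn_in, thin=base.thin,
        seed=base.seed * 1000003 + 997 * (outer + 1) + (inner + 2),
        df_e=base.df_e, df_g=base.df_g,
        scale_e=base.scale_e, scale_g=base.scale_g,
    )


def run_pipeline(
    K: KinshipMatrix, pheno: PhenotypeTable, cfg: RunConfig,
    plan: FoldPlan = None,
) -> RunResult:
    """Run the requested models through outer-k/inner-k nested CV."""
    if list(K.line_ids) != list(pheno.line_ids):
        raise PipelineError("kinship and phenotype ids misaligned; align first")
    y = pheno.values
    if np.isnan(y).any():
        raise PipelineError("phenotypes contain missing values")
    n = len(K.line_ids)
    plan = plan or make_folds(n, cfg.outer_k, cfg.inner_k, cfg.seed)
    checks = pheno.check_values if pheno.check_ids else None

    global_thr = None
    if cfg.global_threshold or cfg.threshold.kind in ("check_mean", "check_max", "fixed"):
        global_thr = resolve_threshold(y, cfg.threshold, checks)

    fold_results = {m: [] for m in cfg.models}
    fold_provenance = []
    ids = list(K.line_ids)

    for f in range(plan.outer_k):
        tr, te = plan.outer_fold_indices(f)
        tr_ids = [ids[i] for i in tr]
        te_ids = [ids[i] for i in te]
        thr = global_thr or resolve_threshold(y[tr], cfg.threshold, checks)
        obs_labels = binarize(y[te], thr, line_ids=te_ids)
        yb_tr = binarize(y[tr], thr, line_ids=tr_ids)
        if not yb_tr.both_classes():
            raise PipelineError(
                f"outer fold {f}: single-class training labels at "
                f"Y_tau = {thr.value:.6g}"
            )
        prov = {"fold": f, "train_ids": tr_ids, "test_ids": te_ids,
                "Y_tau": thr.value, "models": {}}

        shared_gblup = None
        if "R" in cfg.models or "RO" in cfg.models:
            y_masked = y.copy()
            y_masked[te] = np.nan
            shared_gblup = fit_gblup(
                y_masked, K, cfg=_mcmc_for(cfg, f), mode=cfg.gblup_mode,
            )
            y_hat_test = predict_gblup(shared_gblup, te_ids)

        if "R" in cfg.models:
            pred = classify(y_hat_test, thr.value, line_ids=te_ids)
            cm = confusion(obs_labels, pred)
            fold_results["R"].append(FoldModelResult(
                fold=f, model="R", test_ids=te_ids, scores=y_hat_test,
                predicted=pred, observed=obs_labels, cm=cm,
                metric_set=metrics(cm), threshold=thr, cutoff_value=thr.value,
            ))
            prov["models"]["R"] = {"cutoff": thr.value}

        needs_inner = [m for m in ("B", "RO") if m in cfg.models]
        inner_assign = None
        if needs_inner:
            inner_assign, stratified = plan.inner_fold_for(f, yb_tr.labels)
            K_tr = K.subset(tr_ids)

        if "RO" in cfg.models:
            per_fold = _tune_inner_ro(
                K_tr, y[tr], yb_tr.labels, inner_assign, plan.inner_k,
                cfg, f,
            )
            agg = aggregate_cutoffs(per_fold, strategy=cfg.aggregation_ro)
            fitted_tr = predict_gblup(shared_gblup, tr_ids)
            if cfg.aggregation_ro == "mean_of_levels":
                y_tau0 = resolve_continuous_cutoff(agg.level, fitted_tr)
            else:
                y_tau0 = agg.value
            agg.value = y_tau0
            pred = classify(y_hat_test, y_tau0, line_ids=te_ids)
            cm = confusion(obs_labels, pred)
            fold_results["RO"].append(FoldModelResult(
                fold=f, model="RO", test_ids=te_ids, scores=y_hat_test,
                predicted=pred, observed=obs_labels, cm=cm,
                metric_set=metrics(cm), threshold=thr, cutoff=agg,
                cutoff_value=y_tau0,
            ))
            prov["models"]["RO"] = {
                "tau0_level": agg.level, "Y_tau0": y_tau0,
                "inner_folds_used": agg.n_folds_used,
                "inner_folds_skipped": agg.n_folds_skipped,
            }

        if "B" in cfg.models:
            per_fold = _tune_inner_b(
                K_tr, yb_tr.labels, inner_assign, plan.inner_k, cfg, f,
            )
            agg = aggregate_cutoffs(per_fold, strategy=cfg.aggregation_b)
            yb_all = np.full(n, np.nan)
            yb_all[tr] = yb_tr.labels
            refit = fit_tgblup(yb_all, K, cfg=_mcmc_for(cfg, f))
            p_test = predict_tgblup_proba(refit, te_ids, cfg.proba_mode)
            pred = classify(p_test, agg.value, line_ids=te_ids)
            cm = confusion(obs_labels, pred)
            fold_results["B"].append(FoldModelResult(
                fold=f, model="B", test_ids=te_ids, scores=p_test,
                predicted=pred, observed=obs_labels, cm=cm,
                metric_set=metrics(cm), threshold=thr, cutoff=agg,
                cutoff_value=agg.value,
            ))
            prov["models"]["B"] = {
                "tau0": agg.value,
                "inner_folds_used": agg.n_folds_used,
                "inner_folds_skipped": agg.n_folds_skipped,
            }
        fold_provenance.append(prov)
        logger.info("outer fold %d/%d done", f + 1, plan.outer_k)

    summary = summarize_folds(
        {m: [fr.metric_set for fr in frs] for m, frs in fold_results.items()}
    )
    provenance = {
        "version": __version__,
        "config": cfg.as_dict(),
        "config_hash": cfg.config_hash(),
        "n_lines": n,
        "folds": fold_provenance,
    }
    return RunResult(cfg, plan, fold_results, summary, provenance)


def _tune_inner_ro(K_tr, y_tr, yb_tr, inner_assign, inner_k, cfg, outer):
    """Inner-fold cutoff optimization on continuous GBLUP predictions."""
    per_fold = []
    for j in range(inner_k):
        val = inner_assign == j
        val_labels = yb_tr[val]
        if val_labels.min() == val_labels.max():
            logger.info("fold %d inner %d skipped: single-class validation",
                        outer, j)
            per_fold.append(None)
            continue
        y_inner = y_tr.astype(float).copy()
        y_inner[val] = np.nan
        try:
            fit = fit_gblup(
                y_inner, K_tr, cfg=_mcmc_for(cfg, outer, j),
                mode=cfg.gblup_mode,
            )
        except Exception as exc:
            raise PipelineError(
                f"outer fold {outer}, inner fold {j} (RO): {exc}"
            ) from exc
        val_ids = [K_tr.line_ids[i] for i in np.where(val)[0]]
        scores = predict_gblup(fit, val_ids)
        try:
            per_fold.append(
                optimal_cutoff(scores, BinaryLabels(val_ids, val_labels))
            )
        except ThresholdError:
            per_fold.append(None)
    return per_fold


def _tune_inner_b(K_tr, yb_tr, inner_assign, inner_k, cfg, outer):
    """Inner-fold probability-cutoff optimization on probit predictions."""
    per_fold = []
    for j in range(inner_k):
        val = inner_assign == j
        val_labels = yb_tr[val]
        train_labels = yb_tr[~val]
        if (val_labels.min() == val_labels.max()
                or train_labels.min() == train_labels.max()):
            logger.info("fold %d inner %d skipped: single-class split",
                        outer, j)
            per_fold.append(None)
            continue
        yb_inner = yb_tr.astype(float).copy()
        yb_inner[val] = np.nan
        try:
            fit = fit_tgblup(yb_inner, K_tr, cfg=_mcmc_for(cfg, outer, j))
        except Exception as exc:
            raise PipelineError(
                f"outer fold {outer}, inner fold {j} (B): {exc}"
            ) from exc
        val_ids = [K_tr.line_ids[i] for i in np.where(val)[0]]
        scores = predict_tgblup_proba(fit, val_ids, cfg.proba_mode)
        try:
            per_fold.append(
                optimal_cutoff(scores, BinaryLabels(val_ids, val_labels))
            )
        except ThresholdError:
            per_fold.append(None)
    return per_fold


def run_model_R(K, pheno, cfg, plan=None):
    return run_pipeline(K, pheno, _with_models(cfg, ("R",)), plan)


def run_model_B(K, pheno, cfg, plan=None):
    return run_pipeline(K, pheno, _with_models(cfg, ("B",)), plan)


def run_model_RO(K, pheno, cfg, plan=None):
    return run_pipeline(K, pheno, _with_models(cfg, ("RO",)), plan)


def _with_models(cfg: RunConfig, models: tuple) -> RunConfig:
    d = cfg.as_dict()
    return RunConfig(
        trait=d["trait"],
        threshold=ThresholdSpec(**d["threshold"]),
        models=models,
        mcmc=McmcConfig(**d["mcmc"]),
        outer_k=d["outer_k"], inner_k=d["inner_k"], seed=d["seed"],
        gblup_mode=d["gblup_mode"],
        aggregation_b=d["aggregation_b"], aggregation_ro=d["aggregation_ro"],
        proba_mode=d["proba_mode"], global_threshold=d["global_threshold"],
    )


def compare_models(results: dict) -> list:
    """Cross-model summary from per-model RunResults sharing one FoldPlan."""
    plans = {
        m: r.plan.outer_assignment.tobytes() for m, r in results.items()
    }
    if len(set(plans.values())) != 1:
        raise PipelineError("results use different fold plans")
    per_model = {}
    for m, r in results.items():
        for model, frs in r.fold_results.items():
            per_model[model] = [fr.metric_set for fr in frs]
    return summarize_folds(per_model)


def write_results(result: RunResult, out_dir) -> dict:
    """Write predictions, per-fold metrics, the comparison summary and the
    provenance record.  Output is deterministic for a fixed config + seed."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "predictions": out / "predictions.csv",
        "metrics": out / "metrics.csv",
        "summary": out / "summary.csv",
        "provenance": out / "provenance.json",
    }
    result.predictions_frame().to_csv(paths["predictions"], index=False,
                                      float_format="%.10g")
    result.metrics_frame().to_csv(paths["metrics"], index=False,
                                  float_format="%.10g")
    result.summary_frame().to_csv(paths["summary"], index=False,
                                  float_format="%.10g")
    with open(paths["provenance"], "w") as fh:
        json.dump(result.provenance, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
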