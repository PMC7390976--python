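"""Classification performance under leave-one-out, Monte-Carlo and hold-out
evaluation.

The confusion matrix takes *insufficient* (CM content below threshold) as
the positive class.  Metrics:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Conventions: an MCC denominator factor of zero yields MCC = 0 (an
uninformative classifier, e.g. all-positive, has zero correlation with the
truth); undefined precision/recall (empty predicted-positive or
actual-positive set) is reported as NaN with a warning, never silently 0.

All per-fold preprocessing (imputation, standardisation, optional feature
selection or PCA) is refit inside each training fold to avoid leakage; a
flag reproduces the select-once-outside-CV protocol for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable
from .models import ClassLabel, DEFAULT_THRESHOLD, PredictiveModel, predict_class, train
from . import selection as sel

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "ModelSpec",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "mcc",
    "metrics_report",
    "loo_cv",
    "mc_cv",
    "holdout_evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_bool(labels: Sequence) -> np.ndarray:
    out = []
    for item in labels:
        if isinstance(item, ClassLabel):
            out.append(item.is_positive)
        elif isinstance(item, (bool, np.bool_)):
            out.append(bool(item))
        else:
            raise TypeError(f"cannot interpret label {item!r}")
    return np.asarray(out, dtype=bool)


def confusion(actual: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """Exact counts with *insufficient* as the positive class."""
    a = _as_bool(actual)
    p = _as_bool(predicted)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if a.size == 0:
        raise ValueError("need at least one label")
    return ConfusionMatrix(
        tp=int(np.sum(a & p)),
        fp=int(np.sum(~a & p)),
        tn=int(np.sum(~a & ~p)),
        fn=int(np.sum(a & ~p)),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.tp + cm.fp == 0:
        warnings.warn("no predicted positives; precision undefined", stacklevel=2)
        return float("nan")
    return cm.tp / (cm.tp + cm.fp)


def recall(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        warnings.warn("no actual positives; recall undefined", stacklevel=2)
        return float("nan")
    return cm.tp / (cm.tp + cm.fn)


def mcc(cm: ConfusionMatrix) -> float:
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    mcc: float
    counts: ConfusionMatrix


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MetricsReport(accuracy(cm), precision(cm), recall(cm), mcc(cm), cm)


# ---------------------------------------------------------------------------
# model specification for CV
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """How to build a classifier inside each training fold.

    ``features`` fixes the feature subset (the select-outside-CV protocol);
    ``selection`` instead names a selection method refit inside every fold
    (``{"method": "rf", ...settings}``).  ``use_pca`` replaces features by
    the principal components retained at ``pca_variance``.
    """

    backend: str = "rf_regressor"
    features: Optional[Sequence[str]] = None
    selection: Optional[dict] = None
    use_pca: bool = False
    pca_variance: float = 0.94
    threshold: float = DEFAULT_THRESHOLD
    settings: dict = field(default_factory=dict)
    trainer: Optional[Callable] = None  # test hook: (table, seed) -> PredictiveModel

    def __post_init__(self) -> None:
        active = sum(bool(x) for x in (self.features, self.selection, self.use_pca))
        if active > 1:
            raise ValueError("choose at most one of features / selection / use_pca")


_SELECTORS = {
    "pearson": lambda table, seed, kw: sel.correlation_select(table, "pearson", **kw),
    "spearman": lambda table, seed, kw: sel.correlation_select(table, "spearman", **kw),
    "rf": lambda table, seed, kw: sel.rf_select(table, seed=seed, **kw),
    "gpr_ard": lambda table, seed, kw: sel.gpr_ard_select(table, seed=seed, **kw),
    "mars": lambda table, seed, kw: sel.mars_select(table, seed=seed, **kw),
}


def _fit_fold(
    spec: ModelSpec, train_table: FeatureTable, seed: int
) -> tuple[PredictiveModel, Optional[sel.SelectionResult]]:
    pca_result = None
    if spec.features is not None:
        train_table = train_table.subset_features(list(spec.features))
    elif spec.selection is not None:
        options = dict(spec.selection)
        method = options.pop("method")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = _SELECTORS[method](train_table, seed, options)
        chosen = result.selected or list(result.scores)[:1]
        train_table = train_table.subset_features(chosen)
    elif spec.use_pca:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca_result = sel.pca_reduce(train_table, spec.pca_variance)
        scores = sel.pca_scores(pca_result, train_table)
        train_table = FeatureTable(scores, train_table.outcome)
    if spec.trainer is not None:
        return spec.trainer(train_table, seed), pca_result
    model = train(
        spec.backend, train_table, seed=seed, threshold=spec.threshold,
        settings=spec.settings,
    )
    return model, pca_result


def _predict_fold(
    spec: ModelSpec,
    model: PredictiveModel,
    pca_result: Optional[sel.SelectionResult],
    test_table: FeatureTable,
) -> list[ClassLabel]:
    if pca_result is not None:
        frame = sel.pca_scores(pca_result, test_table)
    else:
        frame = test_table.data
    return predict_class(model, frame)


def _actual_labels(table: FeatureTable, threshold: float) -> list[ClassLabel]:
    out = []
    for value in table.outcome.to_numpy(float):
        out.append(ClassLabel.SUFFICIENT if value >= threshold else ClassLabel.INSUFFICIENT)
    return out


@dataclass
class CVResult:
    scheme: str
    actual: list[ClassLabel]
    predicted: list[ClassLabel]
    aggregate: MetricsReport
    seed: Optional[int] = None
    run_ids: Optional[list[str]] = None
    per_trial: Optional[list[MetricsReport]] = None
    pooled: Optional[MetricsReport] = None

    @property
    def n_folds(self) -> int:
        if self.scheme == "loo":
            return len(self.actual)
        if self.per_trial is not None:
            return len(self.per_trial)
        return 1


# ---------------------------------------------------------------------------
# schemes
# ---------------------------------------------------------------------------

def _require_outcomes(table: FeatureTable) -> FeatureTable:
    if table.outcome is None:
        raise ValueError("evaluation requires an outcome column")
    keep = table.outcome.notna()
    if not keep.all():
        table = table.subset_runs(list(table.data.index[keep]))
    return table


def loo_cv(spec: ModelSpec, table: FeatureTable, seed: int = 0) -> CVResult:
    """Leave-one-out CV: one model per held-out run, preprocessing refit
    per fold; aggregate metrics over the n out-of-fold predictions."""
    table = _require_outcomes(table)
    n = table.n_runs
    if n < 5:
        raise ValueError("LOO CV needs at least 5 runs")
    run_ids = table.run_ids
    predicted: list[ClassLabel] = []
    for i, rid in enumerate(run_ids):
        train_ids = [r for r in run_ids if r != rid]
        try:
            model, pca_result = _fit_fold(spec, table.subset_runs(train_ids), seed)
        except Exception as err:
            raise RuntimeError(f"LOO fold for run {rid!r} failed: {err}") from err
        predicted.extend(
            _predict_fold(spec, model, pca_result, table.subset_runs([rid]))
        )
    actual = _actual_labels(table, spec.threshold)
    return CVResult(
        scheme="loo",
        actual=actual,
        predicted=predicted,
        aggregate=metrics_report(confusion(actual, predicted)),
        seed=seed,
        run_ids=run_ids,
    )


def _mean_metrics(reports: list[MetricsReport], pooled: ConfusionMatrix) -> MetricsReport:
    def nanmean(values):
        arr = np.asarray(values, dtype=float)
        return float(np.nanmean(arr)) if np.any(np.isfinite(arr)) else float("nan")

    return MetricsReport(
        accuracy=nanmean([r.accuracy for r in reports]),
        precision=nanmean([r.precision for r in reports]),
        recall=nanmean([r.recall for r in reports]),
        mcc=nanmean([r.mcc for r in reports]),
        counts=pooled,
    )


def mc_cv(
    spec: ModelSpec,
    table: FeatureTable,
    test_size: int = 5,
    trials: int = 40,
    seed: int = 0,
) -> CVResult:
    """Monte-Carlo CV: per trial a random ``test_size`` validation set is
    held out (without replacement within the trial); the aggregate is the
    unweighted mean of per-trial metrics (pooled counts are also kept)."""
    table = _require_outcomes(table)
    n = table.n_runs
    if not (1 <= test_size < n):
        raise ValueError(f"test_size must be in [1, n); got {test_size} with n={n}")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    run_ids = np.asarray(table.run_ids)
    per_trial: list[MetricsReport] = []
    all_actual: list[ClassLabel] = []
    all_pred: list[ClassLabel] = []
    for trial in range(trials):
        test_ids = list(rng.choice(run_ids, size=test_size, replace=False))
        train_ids = [r for r in run_ids if r not in test_ids]
        model, pca_result = _fit_fold(spec, table.subset_runs(train_ids), seed)
        test_table = table.subset_runs(test_ids)
        pred = _predict_fold(spec, model, pca_result, test_table)
        actual = _actual_labels(test_table, spec.threshold)
        per_trial.append(metrics_report(confusion(actual, pred)))
        all_actual.extend(actual)
        all_pred.extend(pred)
    pooled_cm = confusion(all_actual, all_pred)
    return CVResult(
        scheme="monte_carlo",
        actual=all_actual,
        predicted=all_pred,
        aggregate=_mean_metrics(per_trial, pooled_cm),
        seed=seed,
        per_trial=per_trial,
        pooled=metrics_report(pooled_cm),
    )


def holdout_evaluate(
    spec: ModelSpec,
    train_table: FeatureTable,
    test_table: FeatureTable,
    seed: int = 0,
) -> CVResult:
    """Fit once on the training cohort, report metrics on the reserved
    test cohort (the 42/16 protocol)."""
    overlap = set(train_table.run_ids) & set(test_table.run_ids)
    if overlap:
        raise ValueError(f"train/test run_ids overlap: {sorted(overlap)[:3]}")
    train_table = _require_outcomes(train_table)
    test_table = _require_outcomes(test_table)
    model, pca_result = _fit_fold(spec, train_table, seed)
    predicted = _predict_fold(spec, model, pca_result, test_table)
    actual = _actual_labels(test_table, spec.threshold)
    cm = confusion(actual, predicted)
    if cm.tp + cm.fn == 0:
        warnings.warn("test set has no positive (insufficient) runs", stacklevel=2)
    return CVResult(
        scheme="holdout",
        actual=actual,
        predicted=predicted,
        aggregate=metrics_report(cm),
        seed=seed,
        run_ids=test_table.run_ids,
    )
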