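"""Predictive models for endpoint CM content and the 90% classification rule.

MARS, random-forest and Gaussian-process regressors predict the day-10
cardiomyocyte content (%); predictions are thresholded at 90% to yield the
binary classes.  A run with CM content at or above the threshold is
*sufficient*; below it is *insufficient*, which is the positive class
throughout (the event worth flagging is a failing process).  Random forests
additionally support direct classification on binarised labels.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .features import FeatureTable
from .mars import MarsModel

__all__ = [
    "BACKENDS",
    "ClassLabel",
    "PredictiveModel",
    "classify",
    "train",
    "predict_cm",
    "predict_class",
]

BACKENDS = ("mars", "rf_regressor", "rf_classifier", "gpr", "mean")

DEFAULT_THRESHOLD = 90.0  # % CM content separating sufficient from insufficient
RF_N_TREES = 5  # study protocol: forests with 5 trees


class ClassLabel(enum.Enum):
    """Binary process outcome; *insufficient* is the positive class."""

    INSUFFICIENT = "insufficient"
    SUFFICIENT = "sufficient"

    @property
    def is_positive(self) -> bool:
        return self is ClassLabel.INSUFFICIENT


def classify(cm_percent: float, threshold: float = DEFAULT_THRESHOLD) -> ClassLabel:
    """Label a CM content: sufficient iff ``cm_percent >= threshold``."""
    if not (0.0 < threshold < 100.0):
        raise ValueError(f"threshold must be in (0, 100), got {threshold}")
    if not (0.0 <= cm_percent <= 100.0) or not np.isfinite(cm_percent):
        raise ValueError(f"CM content {cm_percent} outside [0, 100]")
    return ClassLabel.SUFFICIENT if cm_percent >= threshold else ClassLabel.INSUFFICIENT


@dataclass
class PredictiveModel:
    """A fitted backend plus everything needed to reproduce predictions:
    the exact training feature list, per-feature imputation medians,
    optional standardisation constants and the decision threshold."""

    backend: str
    estimator: object
    feature_names: list[str]
    threshold: float = DEFAULT_THRESHOLD
    seed: Optional[int] = None
    medians: Optional[pd.Series] = None
    x_mean: Optional[pd.Series] = None
    x_sd: Optional[pd.Series] = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")
        if not (0.0 < self.threshold < 100.0):
            raise ValueError("threshold must be in (0, 100)")


class _MeanRegressor:
    """Baseline that memorises the training mean (leakage probe / floor)."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


def _gpr_kernel():
    # isotropic RBF for prediction models (ARD lives in selection)
    return ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3)) + WhiteKernel(
        0.1, (1e-8, 1e1)
    )


def train(
    backend: str,
    table: FeatureTable,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    settings: Optional[dict] = None,
) -> PredictiveModel:
    """Fit a predictor of endpoint CM content on a feature table.

    Missing feature values are imputed with per-feature training medians
    (learned here, applied to any future input).  GPR standardises features
    and outcome; hyperparameters are optimised by marginal likelihood with
    5 fixed-seed restarts.  Deterministic given ``seed``.
    """
    settings = dict(settings or {})
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    if table.outcome is None:
        raise ValueError("training table has no outcome column")
    y = table.outcome
    keep = y.notna()
    if keep.sum() < 5:
        raise ValueError(f"need at least 5 training runs with outcomes, got {int(keep.sum())}")
    X = table.data.loc[keep]
    y = y.loc[keep].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to learn")

    medians = X.median(skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()][0]
        raise ValueError(f"feature {bad!r} has no observed training values")
    Xi = X.fillna(medians)

    model = PredictiveModel(
        backend=backend,
        estimator=None,
        feature_names=list(table.feature_names),
        threshold=threshold,
        seed=seed,
        medians=medians,
        settings=settings,
    )

    rf_kwargs = {
        k: v for k, v in settings.items() if k not in ("n_trees", "n_restarts")
    }
    if backend == "rf_regressor":
        est = RandomForestRegressor(
            n_estimators=settings.get("n_trees", RF_N_TREES), random_state=seed,
            n_jobs=1, **rf_kwargs,
        ).fit(Xi.to_numpy(float), y)
    elif backend == "rf_classifier":
        labels = (y < threshold).astype(int)  # 1 = insufficient (positive)
        if labels.min() == labels.max():
            raise ValueError("training outcomes fall in a single class")
        est = RandomForestClassifier(
            n_estimators=settings.get("n_trees", RF_N_TREES), random_state=seed,
            n_jobs=1, **rf_kwargs,
        ).fit(Xi.to_numpy(float), labels)
    elif backend == "mars":
        est = MarsModel(
            max_terms=settings.get("max_terms", 21),
            max_knots=settings.get("max_knots", 12),
        ).fit(Xi.to_numpy(float), y)
    elif backend == "gpr":
        x_mean = Xi.mean()
        x_sd = Xi.std(ddof=1).replace(0.0, 1.0)
        y_sd = float(np.std(y)) or 1.0
        model.x_mean, model.x_sd = x_mean, x_sd
        model.y_mean, model.y_sd = float(np.mean(y)), y_sd
        Z = ((Xi - x_mean) / x_sd).to_numpy(float)
        est = GaussianProcessRegressor(
            kernel=_gpr_kernel(),
            n_restarts_optimizer=settings.get("n_restarts", 5),
            random_state=seed,
            normalize_y=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            est.fit(Z, (y - model.y_mean) / y_sd)
    elif backend == "mean":
        est = _MeanRegressor().fit(Xi.to_numpy(float), y)
    model.estimator = est
    return model


def _coerce_features(model: PredictiveModel, features) -> pd.DataFrame:
    """Validate and align an input against the training feature list."""
    if isinstance(features, FeatureTable):
        frame = features.data
    elif isinstance(features, pd.DataFrame):
        frame = features
    elif isinstance(features, pd.Series):
        frame = features.to_frame().T
    elif isinstance(features, dict):
        frame = pd.DataFrame([features])
    else:
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        if arr.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {arr.shape[1]}"
            )
        frame = pd.DataFrame(arr, columns=model.feature_names)
    missing = [c for c in model.feature_names if c not in frame.columns]
    if missing:
        raise ValueError(f"missing feature(s): {missing[:3]}")
    return frame[model.feature_names]


def predict_cm(model: PredictiveModel, features) -> np.ndarray:
    """Predicted CM content (%), clipped to [0, 100]; one value per row."""
    if model.backend == "rf_classifier":
        raise ValueError("rf_classifier predicts classes directly, not CM content")
    frame = _coerce_features(model, features).fillna(model.medians)
    X = frame.to_numpy(float)
    if model.backend == "gpr":
        Z = ((frame - model.x_mean) / model.x_sd).to_numpy(float)
        raw = model.estimator.predict(Z) * model.y_sd + model.y_mean
    else:
        raw = model.estimator.predict(X)
    return np.clip(np.asarray(raw, dtype=float), 0.0, 100.0)


def predict_class(model: PredictiveModel, features) -> list[ClassLabel]:
    """Predicted outcome classes.

    Regression backends threshold their CM prediction; the direct RF
    classifier votes over trees, with 0.5 probability ties broken toward
    the positive (insufficient) class.
    """
    if model.backend == "rf_classifier":
        frame = _coerce_features(model, features).fillna(model.medians)
        proba = model.estimator.predict_proba(frame.to_numpy(float))
        positive_idx = list(model.estimator.classes_).index(1)
        p_pos = proba[:, positive_idx]
        return [
            ClassLabel.INSUFFICIENT if p >= 0.5 else ClassLabel.SUFFICIENT
            for p in p_pos
        ]
    cm = predict_cm(model, features)
    return [classify(float(v), model.threshold) for v in cm]
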