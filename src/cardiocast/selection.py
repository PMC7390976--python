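"""Feature ranking and selection.

Five routes mirroring the study design: Pearson/Spearman correlation
screening, principal component retention, random-forest impurity
importance, Gaussian-process automatic relevance determination (ARD) with
a posterior-mean sensitivity analysis, and MARS basis membership.

All selectors consume a :class:`~cardiocast.features.FeatureTable` whose
outcome column is the endpoint CM content.  Features are z-scored before
PCA and GP fitting; tree- and spline-based selectors see raw features.
Zero-variance features are dropped with a warning before any selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .features import FeatureTable
from .mars import MarsModel

__all__ = [
    "SelectionResult",
    "pearson_correlation",
    "spearman_correlation",
    "correlation_select",
    "pca_reduce",
    "pca_scores",
    "rf_select",
    "gpr_ard_select",
    "mars_select",
]


@dataclass
class SelectionResult:
    """Ranked scores plus the selected subset for one method."""

    method: str
    scores: dict[str, float]
    selected: list[str]
    settings: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.selected) - set(self.scores)
        if unknown and self.method != "pca":
            raise ValueError(f"selected features without scores: {sorted(unknown)[:3]}")


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _check_pair(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return x, y


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x, y = _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation (Pearson on average ranks) in [-1, 1]."""
    x, y = _check_pair(x, y)
    return float(stats.spearmanr(x, y).statistic)


def _corr_scores(table: FeatureTable, method: str) -> dict[str, float]:
    y = _outcome(table)
    scores: dict[str, float] = {}
    fn = pearson_correlation if method == "pearson" else spearman_correlation
    for name in table.feature_names:
        x = table.data[name]
        mask = x.notna() & y.notna()
        try:
            scores[name] = fn(x[mask].to_numpy(), y[mask].to_numpy())
        except ValueError:
            scores[name] = float("nan")
    return scores


def correlation_select(
    table: FeatureTable,
    method: str = "pearson",
    threshold: float = 0.3,
) -> SelectionResult:
    """Select features whose |correlation| with the outcome is at least
    ``threshold``, strongest first."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    table = _drop_zero_variance(table)
    scores = _corr_scores(table, method)
    ranked = sorted(
        (n for n, s in scores.items() if np.isfinite(s)),
        key=lambda n: -abs(scores[n]),
    )
    selected = [n for n in ranked if abs(scores[n]) >= threshold]
    return SelectionResult(method, scores, selected, {"threshold": threshold})


# ---------------------------------------------------------------------------
# shared preparation
# ---------------------------------------------------------------------------

def _outcome(table: FeatureTable) -> pd.Series:
    if table.outcome is None:
        raise ValueError("feature table has no outcome column")
    return table.outcome


def _drop_zero_variance(table: FeatureTable) -> FeatureTable:
    distinct = table.data.nunique(dropna=True)
    dead = [c for c in table.feature_names if distinct[c] <= 1]
    if dead:
        warnings.warn(
            f"dropping {len(dead)} zero-variance feature(s) (first: {dead[0]!r})",
            stacklevel=3,
        )
        keep = [c for c in table.feature_names if c not in dead]
        return table.subset_features(keep)
    return table


def _impute_median(frame: pd.DataFrame) -> pd.DataFrame:
    med = frame.median(skipna=True)
    if med.isna().any():
        bad = med.index[med.isna()][0]
        raise ValueError(f"feature {bad!r} has no observed values")
    return frame.fillna(med)


def _complete_xy(table: FeatureTable) -> tuple[pd.DataFrame, np.ndarray]:
    y = _outcome(table)
    if y.isna().any():
        keep = y.notna()
        table = table.subset_runs(list(table.data.index[keep]))
        y = _outcome(table)
    if np.ptp(y.to_numpy()) == 0:
        raise ValueError("outcome is constant; selection is undefined")
    X = _impute_median(table.data)
    return X, y.to_numpy(float)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_reduce(table: FeatureTable, variance_target: float = 0.94) -> SelectionResult:
    """Retain the smallest number of principal components of the z-scored
    feature matrix whose cumulative explained variance reaches
    ``variance_target``."""
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must be in (0, 1]")
    if table.n_runs < 2:
        raise ValueError("PCA needs at least 2 runs")
    table = _drop_zero_variance(table)
    X = _impute_median(table.data)
    mean = X.mean()
    sd = X.std(ddof=1)
    Z = ((X - mean) / sd).to_numpy(float)
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    n_components = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    n_components = min(n_components, len(evr))
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(
        pca.components_[:n_components],
        index=pc_names,
        columns=table.feature_names,
    )
    return SelectionResult(
        method="pca",
        scores={f"PC{i + 1}": float(v) for i, v in enumerate(evr)},
        selected=pc_names,
        settings={"variance_target": variance_target},
        extras={
            "loadings": loadings,
            "explained_variance_ratio": evr,
            "n_components": n_components,
            "feature_mean": mean,
            "feature_sd": sd,
        },
    )


def pca_scores(result: SelectionResult, table: FeatureTable) -> pd.DataFrame:
    """Project a feature table onto retained principal components."""
    if result.method != "pca":
        raise ValueError("not a PCA selection result")
    mean = result.extras["feature_mean"]
    sd = result.extras["feature_sd"]
    loadings: pd.DataFrame = result.extras["loadings"]
    X = table.data[list(loadings.columns)]
    X = X.fillna(mean)
    Z = (X - mean) / sd
    scores = Z.to_numpy(float) @ loadings.to_numpy(float).T
    return pd.DataFrame(scores, index=table.data.index, columns=list(loadings.index))


# ---------------------------------------------------------------------------
# random forest importance
# ---------------------------------------------------------------------------

def rf_select(
    table: FeatureTable,
    seed: int = 0,
    n_trees: int = 500,
    importance_threshold: str | float = "mean",
) -> SelectionResult:
    """Impurity-decrease importances from a seeded regression forest;
    by default a feature is selected when its importance reaches the mean
    importance."""
    table = _drop_zero_variance(table)
    X, y = _complete_xy(table)
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X.to_numpy(float), y)
    imp = forest.feature_importances_
    scores = dict(zip(table.feature_names, map(float, imp)))
    cut = float(np.mean(imp)) if importance_threshold == "mean" else float(importance_threshold)
    ranked = sorted(scores, key=lambda n: -scores[n])
    selected = [n for n in ranked if scores[n] >= cut]
    return SelectionResult(
        "rf",
        scores,
        selected,
        {"n_trees": n_trees, "importance_threshold": importance_threshold, "seed": seed},
    )


# ---------------------------------------------------------------------------
# GPR with automatic relevance determination
# ---------------------------------------------------------------------------

def _capped_lbfgs(obj_func, initial_theta, bounds):
    """Marginal-likelihood optimiser: L-BFGS-B with a bounded iteration
    budget (ARD length-scale refinement past ~60 iterations does not change
    the relevance ordering but dominates runtime)."""
    from scipy.optimize import minimize

    res = minimize(
        obj_func,
        initial_theta,
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": 60},
    )
    return res.x, res.fun


def _ard_kernel(d: int):
    # init at sqrt(d): unit length-scales make the kernel vanish between
    # z-scored points in ~100 dimensions and strand the optimiser
    return ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=np.full(d, np.sqrt(d)), length_scale_bounds=(1e-2, 1e4)
    ) + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-6, 1e1))


def gpr_ard_select(
    table: FeatureTable,
    seed: int = 0,
    n_restarts: int = 1,
    sensitivity_fraction: float = 0.1,
    fd_step: float = 0.1,
) -> SelectionResult:
    """ARD relevance plus sensitivity selection.

    A GP regression with an anisotropic RBF kernel (one length-scale per
    feature) is fitted by marginal likelihood; the per-feature relevance is
    the inverse optimised length-scale.  The sensitivity of feature j is
    the mean over training points of the squared central-finite-difference
    partial derivative of the posterior mean.  Features with sensitivity of
    at least ``sensitivity_fraction`` of the maximum are selected.
    """
    table = _drop_zero_variance(table)
    X, y = _complete_xy(table)
    Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy(float)
    y_mean, y_sd = float(np.mean(y)), float(np.std(y))
    ys = (y - y_mean) / (y_sd if y_sd > 0 else 1.0)
    n, d = Z.shape
    gp = GaussianProcessRegressor(
        kernel=_ard_kernel(d),
        optimizer=_capped_lbfgs,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
        normalize_y=False,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(Z, ys)
    except Exception as err:  # pragma: no cover - optimiser failure path
        raise RuntimeError(
            f"GPR hyperparameter optimisation failed after {n_restarts} restart(s): {err}"
        ) from err

    length_scales = np.asarray(gp.kernel_.k1.k2.length_scale, dtype=float)
    if length_scales.ndim == 0:
        length_scales = np.full(d, float(length_scales))

    sens = _posterior_mean_sensitivity(gp, Z, fd_step)
    scores = dict(zip(table.feature_names, map(float, sens)))
    cut = sensitivity_fraction * max(sens.max(), 1e-300)
    ranked = sorted(scores, key=lambda name: -scores[name])
    selected = [name for name in ranked if scores[name] >= cut]
    return SelectionResult(
        "gpr_ard",
        scores,
        selected,
        {
            "n_restarts": n_restarts,
            "sensitivity_fraction": sensitivity_fraction,
            "fd_step": fd_step,
            "seed": seed,
        },
        extras={
            "length_scales": dict(zip(table.feature_names, map(float, length_scales))),
            "relevance": dict(
                zip(table.feature_names, map(float, 1.0 / length_scales))
            ),
            "log_marginal_likelihood": float(gp.log_marginal_likelihood_value_),
        },
    )


def _posterior_mean_sensitivity(gp, Z: np.ndarray, h: float) -> np.ndarray:
    """Mean squared central-difference gradient of the posterior mean,
    evaluated at the training points, one value per feature."""
    n, d = Z.shape
    sens = np.empty(d)
    for j in range(d):
        plus = Z.copy()
        minus = Z.copy()
        plus[:, j] += h
        minus[:, j] -= h
        grad = (gp.predict(plus) - gp.predict(minus)) / (2.0 * h)
        sens[j] = float(np.mean(grad**2))
    return sens


# ---------------------------------------------------------------------------
# MARS basis membership
# ---------------------------------------------------------------------------

def mars_select(
    table: FeatureTable,
    seed: int = 0,
    max_terms: int = 21,
    max_knots: int = 12,
) -> SelectionResult:
    """Features appearing in at least one retained (non-constant) MARS
    basis function.  Scores are retained-basis counts per feature."""
    table = _drop_zero_variance(table)
    X, y = _complete_xy(table)
    model = MarsModel(max_terms=max_terms, max_knots=max_knots)
    model.fit(X.to_numpy(float), y)
    counts = model.basis_count_per_variable()
    names = table.feature_names
    scores = {name: float(counts.get(i, 0)) for i, name in enumerate(names)}
    selected = [names[i] for i in model.selected_variables]
    return SelectionResult(
        "mars",
        scores,
        selected,
        {"max_terms": max_terms, "max_knots": max_knots, "seed": seed},
        extras={"n_basis": len(model.basis_), "gcv": model.gcv_},
    )
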