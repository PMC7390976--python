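"""Config-driven orchestration: simulate/load -> featurize -> select ->
train -> evaluate, with deterministic, text-only report bundles.

A pipeline config (YAML or JSON) mirrors the CLI flags::

    seed: 7
    data:
      synthetic: {n_runs: 58}          # or  runs_dir: path/to/manifests
    feature_set: fs1                   # fs1 | fs2 | full
    feature_whitelist: null            # optional canonical-name list
    split: {train: 42, test: 16}       # optional hold-out split
    selection: [rf, pca]               # pearson|spearman|pca|rf|gpr_ard|mars
    model: [rf]                        # mars | rf | gpr (rf expands to both
                                       # regressor-threshold and direct paths)
    cv: [loo, mc, holdout]
    mc: {test_size: 5, trials: 40}
    threshold: 90
    selection_within_cv: false         # true refits selection in every fold

Identical config + seed produces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .evaluation import CVResult, ModelSpec, holdout_evaluate, loo_cv, mc_cv
from .features import (
    FeatureTable,
    build_feature_table,
    default_schema,
    feature_window_end,
    CUTOFF_HOURS,
    resolve_alias,
)
from .io import read_runs_dir, write_feature_table
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["ConfigError", "run_pipeline", "load_config"]

_FEATURE_SETS = {"fs1": "dd7", "fs2": "dd5", "full": None}
_MODEL_GROUPS = {
    "mars": ["mars"],
    "rf": ["rf_regressor", "rf_classifier"],
    "gpr": ["gpr"],
    "rf_regressor": ["rf_regressor"],
    "rf_classifier": ["rf_classifier"],
    "mean": ["mean"],
}
_SELECTION_METHODS = ("pearson", "spearman", "pca", "rf", "gpr_ard", "mars")


class ConfigError(ValueError):
    """The pipeline config is internally inconsistent."""


def load_config(source: Union[str, Path, dict]) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _report_dict(result: CVResult) -> dict:
    def metrics(report):
        return {
            "accuracy": report.accuracy,
            "precision": report.precision,
            "recall": report.recall,
            "mcc": report.mcc,
            "counts": {
                "tp": report.counts.tp,
                "fp": report.counts.fp,
                "tn": report.counts.tn,
                "fn": report.counts.fn,
            },
        }

    out = {
        "scheme": result.scheme,
        "seed": result.seed,
        "n_evaluated": len(result.actual),
        "metrics": metrics(result.aggregate),
        "actual": [lbl.value for lbl in result.actual],
        "predicted": [lbl.value for lbl in result.predicted],
    }
    if result.run_ids is not None:
        out["run_ids"] = list(result.run_ids)
    if result.per_trial is not None:
        out["per_trial"] = [metrics(r) for r in result.per_trial]
    if result.pooled is not None:
        out["pooled"] = metrics(result.pooled)
    return _jsonify(out)


def _validate_whitelist(whitelist, cutoff: Optional[str]) -> list[str]:
    names = [resolve_alias(n) for n in whitelist]
    if cutoff is not None:
        limit = CUTOFF_HOURS[cutoff]
        bad = [n for n in names if feature_window_end(n) > limit]
        if bad:
            raise ConfigError(
                f"feature whitelist entries past the {cutoff} cutoff: {bad[:3]}"
            )
    return names


def _get_runs(config: dict, seed: int):
    data = config.get("data") or {}
    if ("synthetic" in data) == ("runs_dir" in data):
        raise ConfigError("data must specify exactly one of 'synthetic' or 'runs_dir'")
    if "synthetic" in data:
        params = dict(data["synthetic"] or {})
        params.setdefault("seed", seed)
        syn = SyntheticConfig(**params)
        runs, gt = generate_cohort(syn)
        return runs, gt
    return read_runs_dir(data["runs_dir"]), None


def _spec_for(selection_name: Optional[str], backend: str, config: dict,
              selected: Optional[list[str]]) -> ModelSpec:
    threshold = float(config.get("threshold", 90))
    settings = dict(config.get("model_settings") or {})
    if selection_name == "pca":
        return ModelSpec(backend=backend, use_pca=True,
                         pca_variance=float(config.get("pca_variance", 0.94)),
                         threshold=threshold, settings=settings)
    if selection_name is None:
        return ModelSpec(backend=backend, threshold=threshold, settings=settings)
    if config.get("selection_within_cv", False):
        return ModelSpec(backend=backend, selection={"method": selection_name},
                         threshold=threshold, settings=settings)
    return ModelSpec(backend=backend, features=selected, threshold=threshold,
                     settings=settings)


def run_pipeline(config_source: Union[str, Path, dict], out_dir: Union[str, Path]) -> dict:
    """Execute the full pipeline described by a config; returns a bundle
    manifest of everything written under ``out_dir``."""
    from . import selection as sel  # local import avoids cycle at module load

    config = load_config(config_source)
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cardiocast")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        import sklearn

        log.info("cardiocast %s (numpy %s, scikit-learn %s)",
                 __version__, np.__version__, sklearn.__version__)
        log.info("seed=%d config_hash=%s", seed, _config_hash(config))

        feature_set = str(config.get("feature_set", "fs1")).lower()
        if feature_set not in _FEATURE_SETS:
            raise ConfigError(f"unknown feature_set {feature_set!r}")
        cutoff = _FEATURE_SETS[feature_set]

        whitelist = config.get("feature_whitelist")
        schema = default_schema()
        if whitelist:
            schema = _validate_whitelist(whitelist, cutoff)

        runs, _gt = _get_runs(config, seed)
        log.info("cohort: %d runs", len(runs))

        split = config.get("split")
        rng = np.random.default_rng(seed)
        if split:
            n_train = int(split.get("train", 42))
            n_test = int(split.get("test", len(runs) - n_train))
            if n_train + n_test > len(runs):
                raise ConfigError(
                    f"split {n_train}/{n_test} exceeds cohort size {len(runs)}"
                )
            order = rng.permutation(len(runs))
            train_runs = [runs[i] for i in sorted(order[:n_train])]
            test_runs = [runs[i] for i in sorted(order[n_train : n_train + n_test])]
        else:
            train_runs, test_runs = runs, []

        train_table = build_feature_table(train_runs, cutoff=cutoff, schema=schema)
        test_table = (
            build_feature_table(test_runs, cutoff=cutoff, schema=schema)
            if test_runs
            else None
        )
        log.info("feature table: %d features (%s)", len(train_table.feature_names),
                 feature_set)

        table_path = out_dir / f"features_{feature_set}.csv"
        write_feature_table(train_table, table_path)
        bundle: dict = {"feature_table": str(table_path), "selections": {},
                        "reports": {}, "log": str(log_path)}
        if test_table is not None:
            test_path = out_dir / f"features_{feature_set}_test.csv"
            write_feature_table(test_table, test_path)
            bundle["feature_table_test"] = str(test_path)

        selectors = {
            "pearson": lambda t: sel.correlation_select(t, "pearson"),
            "spearman": lambda t: sel.correlation_select(t, "spearman"),
            "pca": lambda t: sel.pca_reduce(t, float(config.get("pca_variance", 0.94))),
            "rf": lambda t: sel.rf_select(t, seed=seed),
            "gpr_ard": lambda t: sel.gpr_ard_select(t, seed=seed),
            "mars": lambda t: sel.mars_select(t, seed=seed),
        }

        selection_names = list(config.get("selection") or [None])
        selected_map: dict = {}
        for name in selection_names:
            if name is None:
                continue
            if name not in _SELECTION_METHODS:
                raise ConfigError(f"unknown selection method {name!r}")
            result = selectors[name](train_table)
            selected_map[name] = result
            payload = _jsonify(
                {
                    "method": result.method,
                    "settings": result.settings,
                    "scores": result.scores,
                    "selected": result.selected,
                }
            )
            spath = out_dir / f"selection_{name}.json"
            spath.write_text(json.dumps(payload, indent=2, sort_keys=True))
            bundle["selections"][name] = str(spath)
            log.info("selection %s: %d selected", name, len(result.selected))

        cv_schemes = list(config.get("cv") or ["loo"])
        mc_params = config.get("mc") or {}
        for model_name in config.get("model") or ["rf"]:
            if model_name not in _MODEL_GROUPS:
                raise ConfigError(f"unknown model {model_name!r}")
            for backend in _MODEL_GROUPS[model_name]:
                for sel_name in selection_names:
                    result_sel = selected_map.get(sel_name)
                    selected = result_sel.selected if result_sel else None
                    if sel_name == "pca":
                        selected = None
                    spec = _spec_for(sel_name, backend, config, selected)
                    for scheme in cv_schemes:
                        tag = "-".join(
                            filter(None, [feature_set, sel_name or "all", backend, scheme])
                        )
                        if scheme == "loo":
                            res = loo_cv(spec, train_table, seed=seed)
                        elif scheme == "mc":
                            res = mc_cv(
                                spec,
                                train_table,
                                test_size=int(mc_params.get("test_size", 5)),
                                trials=int(mc_params.get("trials", 40)),
                                seed=seed,
                            )
                        elif scheme == "holdout":
                            if test_table is None:
                                raise ConfigError("cv 'holdout' requires a split")
                            res = holdout_evaluate(spec, train_table, test_table, seed=seed)
                        else:
                            raise ConfigError(f"unknown cv scheme {scheme!r}")
                        rpath = out_dir / f"report_{tag}.json"
                        rpath.write_text(
                            json.dumps(_report_dict(res), indent=2, sort_keys=True)
                        )
                        bundle["reports"][tag] = str(rpath)
                        log.info(
                            "%s: accuracy=%.3f mcc=%.3f",
                            tag,
                            res.aggregate.accuracy,
                            res.aggregate.mcc,
                        )
        manifest_path = out_dir / "bundle.json"
        manifest_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
        bundle["manifest"] = str(manifest_path)
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()
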