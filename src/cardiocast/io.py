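"""Reading and writing run manifests, time-series files and feature tables.

A run is stored as one YAML manifest plus plain CSV files: one
``<run_id>_<variable>.csv`` per online series (columns ``time_h,value``)
and one ``<run_id>_offline.csv`` offline table.  Missing offline
measurements are explicit ``NA`` sentinels; nothing is imputed at the I/O
level.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .features import FeatureTable, OUTCOME_COLUMN, is_canonical
from .runs import (
    BioreactorRun,
    OfflineSample,
    OnlineSeries,
    RunMetadata,
    ValidationError,
)

__all__ = [
    "ManifestError",
    "read_run",
    "write_run",
    "read_runs_dir",
    "read_feature_table",
    "write_feature_table",
]

_OFFLINE_COLUMNS = [
    "day_label",
    "sample_time_h",
    "cell_density",
    "aggregate_diameter",
    "glucose",
    "lactate",
]

PathLike = Union[str, Path]


class ManifestError(ValueError):
    """A manifest file is malformed; the message names the offending field."""


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ManifestError(f"{context}: missing field {key!r}")
    return mapping[key]


def write_run(run: BioreactorRun, out_dir: PathLike) -> Path:
    """Write a run to ``out_dir``; returns the manifest path.

    ``read_run`` inverts this (exactly for strings/integers, to float
    round-trip precision for reals).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    md = run.metadata
    manifest: dict = {
        "run_id": md.run_id,
        "metadata": {
            "preculture_time": float(md.preculture_time),
            "iwp2_treatment_time": float(md.iwp2_treatment_time),
            "chir_concentration": float(md.chir_concentration),
            "rotation_speed": float(md.rotation_speed),
            "media_change_events": [[float(s), float(e)] for s, e in md.media_change_events],
        },
        "online": {},
    }
    for series in run.online:
        fname = f"{md.run_id}_{series.variable}.csv"
        pd.DataFrame({"time_h": series.times, "value": series.values}).to_csv(
            out_dir / fname, index=False, float_format="%.10g"
        )
        manifest["online"][series.variable] = fname
    if run.offline:
        fname = f"{md.run_id}_offline.csv"
        rows = []
        for s in run.offline:
            rows.append(
                {
                    "day_label": s.day_label,
                    "sample_time_h": s.sample_time,
                    "cell_density": s.cell_density,
                    "aggregate_diameter": s.aggregate_diameter,
                    "glucose": s.glucose,
                    "lactate": s.lactate,
                }
            )
        pd.DataFrame(rows, columns=_OFFLINE_COLUMNS).to_csv(
            out_dir / fname, index=False, float_format="%.10g", na_rep="NA"
        )
        manifest["offline"] = fname
    if run.endpoint_cm_content is not None:
        manifest["endpoint_cm_content"] = float(run.endpoint_cm_content)
    manifest_path = out_dir / f"{md.run_id}.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_run(manifest_path: PathLike) -> BioreactorRun:
    """Read and validate a run from its manifest.

    Raises :class:`ManifestError` for malformed manifests (naming the
    field) and :class:`~cardiocast.runs.ValidationError` when an invariant
    fails (naming the series).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ManifestError(f"{manifest_path}: manifest is not a mapping")
    ctx = str(manifest_path)
    run_id = _require(manifest, "run_id", ctx)
    md_raw = _require(manifest, "metadata", ctx)
    if not isinstance(md_raw, dict):
        raise ManifestError(f"{ctx}: field 'metadata' is not a mapping")
    try:
        metadata = RunMetadata(
            run_id=str(run_id),
            preculture_time=float(_require(md_raw, "preculture_time", f"{ctx}: metadata")),
            iwp2_treatment_time=float(
                _require(md_raw, "iwp2_treatment_time", f"{ctx}: metadata")
            ),
            chir_concentration=float(
                _require(md_raw, "chir_concentration", f"{ctx}: metadata")
            ),
            rotation_speed=float(_require(md_raw, "rotation_speed", f"{ctx}: metadata")),
            media_change_events=[
                (float(s), float(e)) for s, e in md_raw.get("media_change_events", [])
            ],
        )
    except (TypeError, ValueError) as err:
        if isinstance(err, ValidationError):
            raise
        raise ManifestError(f"{ctx}: malformed metadata ({err})") from err

    online = []
    base = manifest_path.parent
    for variable, fname in (manifest.get("online") or {}).items():
        frame = pd.read_csv(base / fname)
        for col in ("time_h", "value"):
            if col not in frame.columns:
                raise ManifestError(f"{fname}: missing column {col!r}")
        online.append(
            OnlineSeries(
                variable=str(variable),
                times=frame["time_h"].to_numpy(float),
                values=frame["value"].to_numpy(float),
            )
        )

    offline = []
    if manifest.get("offline"):
        frame = pd.read_csv(base / manifest["offline"], na_values=["NA"])
        for col in _OFFLINE_COLUMNS:
            if col not in frame.columns:
                raise ManifestError(f"{manifest['offline']}: missing column {col!r}")
        for _, row in frame.iterrows():
            offline.append(
                OfflineSample(
                    day_label=str(row["day_label"]),
                    sample_time=float(row["sample_time_h"]),
                    cell_density=_opt(row["cell_density"]),
                    aggregate_diameter=_opt(row["aggregate_diameter"]),
                    glucose=_opt(row["glucose"]),
                    lactate=_opt(row["lactate"]),
                )
            )

    endpoint = manifest.get("endpoint_cm_content")
    return BioreactorRun(
        metadata=metadata,
        online=online,
        offline=offline,
        endpoint_cm_content=None if endpoint is None else float(endpoint),
    )


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_runs_dir(runs_dir: PathLike) -> list[BioreactorRun]:
    """Read every ``*.yaml`` manifest in a directory, sorted by run_id."""
    runs = [read_run(p) for p in sorted(Path(runs_dir).glob("*.yaml"))]
    if not runs:
        raise FileNotFoundError(f"no run manifests in {runs_dir}")
    return runs


def write_feature_table(table: FeatureTable, path: PathLike) -> None:
    """Serialise a FeatureTable as delimited text (``NA`` for missing)."""
    frame = table.to_frame()
    frame.index.name = "run_id"
    frame.to_csv(path, na_rep="NA", float_format="%.10g")


def read_feature_table(path: PathLike) -> FeatureTable:
    """Read a FeatureTable written by :func:`write_feature_table`.

    Unknown (non-canonical) feature columns are retained verbatim with a
    warning; duplicate run_id rows are an error.
    """
    frame = pd.read_csv(path, index_col="run_id", na_values=["NA"])
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate run_id rows")
    outcome = None
    if OUTCOME_COLUMN in frame.columns:
        outcome = frame.pop(OUTCOME_COLUMN)
    unknown = [c for c in frame.columns if not is_canonical(c)]
    if unknown:
        warnings.warn(
            f"{path}: {len(unknown)} unknown feature column(s) retained verbatim "
            f"(first: {unknown[0]!r})",
            stacklevel=2,
        )
    return FeatureTable(frame.astype(float), outcome)
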