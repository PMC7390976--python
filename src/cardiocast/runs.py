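"""Domain containers for single bioreactor differentiation runs.

A run covers a ~48 h stirred-tank preculture followed by 10 days of directed
cardiac differentiation.  Time is measured in hours with t = 0 at
differentiation induction (CHIR addition), so preculture spans negative
times.  Day labels follow the study convention: ``d0``/``d1`` are the two
preculture days, ``dd0`` .. ``dd10`` are differentiation days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DAY_LABELS",
    "ValidationError",
    "RunMetadata",
    "OnlineSeries",
    "OfflineSample",
    "BioreactorRun",
    "day_window",
    "day_index",
]

#: All recognised day labels, in chronological order.
DAY_LABELS: tuple[str, ...] = ("d0", "d1") + tuple(f"dd{k}" for k in range(11))

_OFFLINE_FIELDS = ("cell_density", "aggregate_diameter", "glucose", "lactate")


class ValidationError(ValueError):
    """A run (or one of its components) violates a structural invariant."""


def day_index(label: str) -> int:
    """Map a day label to its integer day offset from induction.

    ``d0`` -> -2, ``d1`` -> -1, ``dd{k}`` -> k.
    """
    if label not in DAY_LABELS:
        raise ValidationError(f"unknown day label {label!r}")
    if label == "d0":
        return -2
    if label == "d1":
        return -1
    return int(label[2:])


def day_window(label: str) -> tuple[float, float]:
    """Half-open [start, end) window of a day label, in hours."""
    k = day_index(label)
    return 24.0 * k, 24.0 * k + 24.0


@dataclass
class RunMetadata:
    """Process metadata for one differentiation run.

    Parameters
    ----------
    run_id
        Unique identifier of the run.
    preculture_time
        Duration of the pre-differentiation expansion phase, hours (> 0).
    iwp2_treatment_time
        Residence time of the WNT inhibitor IWP2, hours (>= 0).
    chir_concentration
        CHIR99021 concentration at induction, micromolar.
    rotation_speed
        Impeller speed, rpm.
    media_change_events
        ``(start, end)`` intervals (hours, relative to induction) during
        which medium was exchanged; online samples inside them are
        artefactual and excluded from day averaging.
    """

    run_id: str
    preculture_time: float
    iwp2_treatment_time: float
    chir_concentration: float
    rotation_speed: float
    media_change_events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValidationError("run_id must be non-empty")
        if not self.preculture_time > 0:
            raise ValidationError(
                f"run {self.run_id}: preculture_time must be > 0, got {self.preculture_time}"
            )
        if self.iwp2_treatment_time < 0:
            raise ValidationError(
                f"run {self.run_id}: iwp2_treatment_time must be >= 0"
            )
        events = [(float(s), float(e)) for s, e in self.media_change_events]
        events.sort()
        for s, e in events:
            if not s < e:
                raise ValidationError(
                    f"run {self.run_id}: media-change interval ({s}, {e}) has start >= end"
                )
        for (s1, e1), (s2, e2) in zip(events, events[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"run {self.run_id}: media-change intervals overlap near t={s2} h"
                )
        self.media_change_events = events


_ONLINE_BOUNDS = {"DO_percent": (0.0, 200.0), "pH": (4.0, 10.0)}


@dataclass
class OnlineSeries:
    """One continuously logged variable (``DO_percent`` or ``pH``)."""

    variable: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.variable not in _ONLINE_BOUNDS:
            raise ValidationError(f"unknown online variable {self.variable!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError(
                f"series {self.variable}: times and values must be equal-length 1-D arrays"
            )
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"series {self.variable}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"series {self.variable}: values must be finite")
        lo, hi = _ONLINE_BOUNDS[self.variable]
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise ValidationError(
                f"series {self.variable}: values outside [{lo}, {hi}]"
            )


@dataclass
class OfflineSample:
    """Daily offline measurements; any individual value may be missing (None)."""

    day_label: str
    sample_time: float
    cell_density: Optional[float] = None  # 10^6 cells/mL
    aggregate_diameter: Optional[float] = None  # um
    glucose: Optional[float] = None  # mmol/L
    lactate: Optional[float] = None  # mmol/L

    def __post_init__(self) -> None:
        start, end = day_window(self.day_label)
        if not (start <= self.sample_time < end):
            raise ValidationError(
                f"offline sample {self.day_label}: sample_time {self.sample_time} h "
                f"outside window [{start}, {end})"
            )
        for name in ("cell_density", "aggregate_diameter"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"offline sample {self.day_label}: {name} must be >= 0"
                )

    def get(self, field_name: str) -> Optional[float]:
        if field_name not in _OFFLINE_FIELDS:
            raise KeyError(field_name)
        return getattr(self, field_name)


@dataclass
class BioreactorRun:
    """One complete experiment: metadata, online series, offline samples and
    (optionally) the flow-cytometry endpoint CM content on dd10."""

    metadata: RunMetadata
    online: list[OnlineSeries] = field(default_factory=list)
    offline: list[OfflineSample] = field(default_factory=list)
    endpoint_cm_content: Optional[float] = None

    def __post_init__(self) -> None:
        variables = [s.variable for s in self.online]
        if len(variables) != len(set(variables)):
            raise ValidationError(
                f"run {self.metadata.run_id}: at most one series per online variable"
            )
        labels = [s.day_label for s in self.offline]
        if len(labels) != len(set(labels)):
            raise ValidationError(
                f"run {self.metadata.run_id}: duplicate offline day labels"
            )
        self.offline = sorted(self.offline, key=lambda s: s.sample_time)
        if self.endpoint_cm_content is not None:
            cm = float(self.endpoint_cm_content)
            if not (0.0 <= cm <= 100.0):
                raise ValidationError(
                    f"run {self.metadata.run_id}: endpoint CM content {cm} outside [0, 100]"
                )
            self.endpoint_cm_content = cm

    @property
    def run_id(self) -> str:
        return self.metadata.run_id

    @property
    def prediction_only(self) -> bool:
        """True when the run has no endpoint and can only be scored, not used
        for training."""
        return self.endpoint_cm_content is None

    def get_series(self, variable: str) -> Optional[OnlineSeries]:
        for s in self.online:
            if s.variable == variable:
                return s
        return None

    def offline_value(self, day_label: str, field_name: str) -> Optional[float]:
        for s in self.offline:
            if s.day_label == day_label:
                return s.get(field_name)
        return None

    def offline_sample(self, day_label: str) -> Optional[OfflineSample]:
        for s in self.offline:
            if s.day_label == day_label:
                return s
        return None


def check_runs_unique(runs: Sequence[BioreactorRun]) -> None:
    ids = [r.run_id for r in runs]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate run_id in cohort")
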