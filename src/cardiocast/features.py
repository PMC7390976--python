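"""Engineered bioprocess features.

Each run is reduced to a vector of named features: per-day means, mean
gradients and mean second derivatives of the online signals (DO, pH and
cell-density-normalised DO), per-day offline values and day-to-day
gradients for cell density, aggregate size and nutrients, plus scalar
process metadata.

Gradients are first-order difference quotients,

    g_i = (y_i - y_{i-1}) / (t_i - t_{i-1}),

and second derivatives are difference quotients of the gradients,

    h_i = (g_i - g_{i-1}) / (t_i - t_{i-1}).

"Average X gradient ddk" is the mean of the instantaneous gradient series
inside the ddk window (not a difference of day means).  Offline day-to-day
gradients use day midpoints, in days, as timestamps, so "dd0-dd1 cell
density gradient" has units 10^6 cells mL^-1 day^-1.

Canonical feature names form a small grammar, e.g.::

    do_mean_dd0            mean DO over differentiation day 0
    ph_grad_d0             mean pH gradient over preculture day 0
    dopd_accel_dd3         mean second derivative of DO/cell-density, dd3
    cell_density_dd1       offline cell density measured on dd1
    cell_density_grad_dd0_dd1   day-to-day cell density gradient
    aggregate_size_grad_overall (last - first) / elapsed days, cutoff-aware
    iwp2_time_h            scalar metadata

Every feature name printed in the study's selection tables is a registered
alias of exactly one canonical name (see :func:`resolve_alias`).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .runs import BioreactorRun, DAY_LABELS, day_index, day_window

log = logging.getLogger(__name__)

__all__ = [
    "gradient_series",
    "second_derivative_series",
    "day_average",
    "density_normalized_do",
    "extract_features",
    "build_feature_table",
    "default_schema",
    "resolve_alias",
    "parse_feature_name",
    "feature_window_end",
    "FeatureName",
    "FeatureTable",
    "OUTCOME_COLUMN",
    "CUTOFF_HOURS",
]

OUTCOME_COLUMN = "cm_content"

#: Feature-set cutoffs: a feature survives when every constituent
#: measurement falls at or before the end of the cutoff day's window.
CUTOFF_HOURS = {"dd7": day_window("dd7")[1], "dd5": day_window("dd5")[1]}

_ONLINE_VARS = ("do", "ph", "dopd")
_OFFLINE_VARS = ("cell_density", "aggregate_size", "glucose", "lactate")
_OFFLINE_FIELD = {
    "cell_density": "cell_density",
    "aggregate_size": "aggregate_diameter",
    "glucose": "glucose",
    "lactate": "lactate",
}
_SCALARS = {
    "preculture_time_h": "preculture_time",
    "iwp2_time_h": "iwp2_treatment_time",
    "chir_concentration_um": "chir_concentration",
    "rotation_speed_rpm": "rotation_speed",
}

_DAY_RE = "|".join(DAY_LABELS)


# ---------------------------------------------------------------------------
# difference-quotient operators
# ---------------------------------------------------------------------------

def _check_times(times: np.ndarray, minimum: int) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size < minimum:
        raise ValueError(f"need at least {minimum} points, got {times.size}")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing (duplicate timestamp?)")
    return times


def gradient_series(values: Sequence[float], times: Sequence[float]) -> np.ndarray:
    """First-order difference-quotient gradients, reported at ``times[1:]``."""
    times = _check_times(np.asarray(times), 2)
    values = np.asarray(values, dtype=float)
    return np.diff(values) / np.diff(times)


def second_derivative_series(values: Sequence[float], times: Sequence[float]) -> np.ndarray:
    """Second derivatives (difference quotients of gradients) at ``times[2:]``."""
    times = _check_times(np.asarray(times), 3)
    g = gradient_series(values, times)
    return np.diff(g) / np.diff(times[1:])


def day_average(
    times: Sequence[float],
    values: Sequence[float],
    window: tuple[float, float],
    exclusions: Iterable[tuple[float, float]] = (),
) -> float:
    """Arithmetic mean of the samples inside a half-open day window,
    skipping samples inside any exclusion (media-change) interval.

    Returns NaN when no sample survives; missing is a value, not an error.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times >= window[0]) & (times < window[1])
    for s, e in exclusions:
        mask &= ~((times >= s) & (times <= e))
    if not mask.any():
        return float("nan")
    return float(values[mask].mean())


# ---------------------------------------------------------------------------
# feature-name grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureName:
    """Structured form of a canonical feature name."""

    variable: str
    statistic: str  # mean | mean_gradient | mean_acceleration | value | span_gradient | overall_gradient | scalar
    window: Optional[str] = None          # day label for per-day statistics
    span: Optional[tuple[str, str]] = None  # (day_i, day_j) for span gradients

    def canonical(self) -> str:
        if self.statistic == "scalar":
            return self.variable
        if self.statistic == "overall_gradient":
            return f"{self.variable}_grad_overall"
        if self.statistic == "span_gradient":
            return f"{self.variable}_grad_{self.span[0]}_{self.span[1]}"
        if self.statistic == "value":
            return f"{self.variable}_{self.window}"
        stat = {"mean": "mean", "mean_gradient": "grad", "mean_acceleration": "accel"}[self.statistic]
        return f"{self.variable}_{stat}_{self.window}"


_ONLINE_NAME_RE = re.compile(rf"^(do|ph|dopd)_(mean|grad|accel)_({_DAY_RE})$")
_SPAN_NAME_RE = re.compile(
    rf"^(cell_density|aggregate_size|glucose|lactate)_grad_({_DAY_RE})_({_DAY_RE})$"
)
_OVERALL_NAME_RE = re.compile(
    r"^(cell_density|aggregate_size|glucose|lactate)_grad_overall$"
)
_VALUE_NAME_RE = re.compile(
    rf"^(cell_density|aggregate_size|glucose|lactate)_({_DAY_RE})$"
)


def parse_feature_name(name: str) -> FeatureName:
    """Parse a canonical name; raises ``ValueError`` for unknown names."""
    if name in _SCALARS:
        return FeatureName(variable=name, statistic="scalar")
    m = _ONLINE_NAME_RE.match(name)
    if m:
        stat = {"mean": "mean", "grad": "mean_gradient", "accel": "mean_acceleration"}[m.group(2)]
        return FeatureName(variable=m.group(1), statistic=stat, window=m.group(3))
    m = _OVERALL_NAME_RE.match(name)
    if m:
        return FeatureName(variable=m.group(1), statistic="overall_gradient")
    m = _SPAN_NAME_RE.match(name)
    if m:
        di, dj = m.group(2), m.group(3)
        if day_index(di) >= day_index(dj):
            raise ValueError(f"span gradient {name!r}: days out of order")
        return FeatureName(variable=m.group(1), statistic="span_gradient", span=(di, dj))
    m = _VALUE_NAME_RE.match(name)
    if m:
        return FeatureName(variable=m.group(1), statistic="value", window=m.group(2))
    raise ValueError(f"unknown feature name {name!r}")


def is_canonical(name: str) -> bool:
    try:
        parse_feature_name(name)
        return True
    except ValueError:
        return False


def feature_window_end(name: str) -> float:
    """Latest measurement time (hours) a feature can depend on.

    Scalars and cutoff-aware overall gradients return ``-inf`` (they never
    reach past any cutoff).
    """
    fn = parse_feature_name(name)
    if fn.statistic in ("scalar", "overall_gradient"):
        return float("-inf")
    if fn.statistic == "span_gradient":
        return day_window(fn.span[1])[1]
    return day_window(fn.window)[1]


# ---------------------------------------------------------------------------
# printed-name aliases (selection-table vocabulary)
# ---------------------------------------------------------------------------

_ALIAS_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(rf"^Average DO concentration gradient ({_DAY_RE})$"), "do_grad_{0}"),
    (re.compile(rf"^Average DO concentration ({_DAY_RE})$"), "do_mean_{0}"),
    (re.compile(rf"^({_DAY_RE}) average acceleration of DO gradient$"), "do_accel_{0}"),
    (re.compile(rf"^({_DAY_RE}) average pH gradient$"), "ph_grad_{0}"),
    (re.compile(rf"^({_DAY_RE}) average pH$"), "ph_mean_{0}"),
    (
        re.compile(rf"^Average cell density normalized DO concentration gradient ({_DAY_RE})$"),
        "dopd_grad_{0}",
    ),
    (
        re.compile(rf"^Cell density normalized DO concentration ({_DAY_RE})$"),
        "dopd_mean_{0}",
    ),
    (
        re.compile(rf"^({_DAY_RE}) average acceleration of cell density normalized DO gradient$"),
        "dopd_accel_{0}",
    ),
    (
        re.compile(rf"^({_DAY_RE})[–—-]({_DAY_RE}) cell density gradient$"),
        "cell_density_grad_{0}_{1}",
    ),
    (
        re.compile(rf"^({_DAY_RE})[–—-]({_DAY_RE}) aggregate size gradient$"),
        "aggregate_size_grad_{0}_{1}",
    ),
    (re.compile(rf"^({_DAY_RE}) cell density$"), "cell_density_{0}"),
    (re.compile(rf"^({_DAY_RE}) aggregate size$"), "aggregate_size_{0}"),
    (re.compile(rf"^({_DAY_RE}) glucose$"), "glucose_{0}"),
    (re.compile(rf"^({_DAY_RE}) lactate$"), "lactate_{0}"),
]

_ALIAS_FIXED = {
    "IWP2 treatment time [h]": "iwp2_time_h",
    "Preculture time [h]": "preculture_time_h",
    "Rotation speed [rpm]": "rotation_speed_rpm",
    "Overall density gradient": "cell_density_grad_overall",
    "Overall cell density gradient": "cell_density_grad_overall",
    "Overall aggregate size gradient": "aggregate_size_grad_overall",
    "Overall glucose gradient": "glucose_grad_overall",
    "Overall lactate gradient": "lactate_grad_overall",
}


def resolve_alias(printed_name: str) -> str:
    """Map a printed selection-table feature name to its canonical name.

    Canonical names pass through unchanged.
    """
    name = printed_name.strip()
    if is_canonical(name):
        return name
    if name in _ALIAS_FIXED:
        return _ALIAS_FIXED[name]
    for pattern, template in _ALIAS_PATTERNS:
        m = pattern.match(name)
        if m:
            out = template
            for i, grp in enumerate(m.groups()):
                out = out.replace("{" + str(i) + "}", grp)
            return out
    raise ValueError(f"cannot resolve feature name {printed_name!r}")


# ---------------------------------------------------------------------------
# default schema
# ---------------------------------------------------------------------------

#: Offline sampling grid: daily through dd3, then at medium exchanges.
DEFAULT_SAMPLING_DAYS = ("dd0", "dd1", "dd2", "dd3", "dd5", "dd7")
#: Days on which nutrient (glucose/lactate) samples are assayed.
DEFAULT_NUTRIENT_DAYS = ("dd3", "dd5", "dd7")

_FULL_DAYS = ("d0", "d1") + tuple(f"dd{k}" for k in range(8))
_DIFF_DAYS = tuple(f"dd{k}" for k in range(8))
_ACCEL_DAYS = tuple(f"dd{k}" for k in range(6))


def default_schema() -> list[str]:
    """The default engineered-feature schema (101 columns).

    Layout: DO and pH day means/mean-gradients over preculture + dd0..dd7,
    second derivatives for the oxygen signals over dd0..dd5,
    density-normalised DO over dd0..dd7, offline values and
    consecutive-sampling-day gradients for cell density and aggregate size,
    nutrient values at exchange days, overall gradients and scalar metadata.
    """
    names: list[str] = []
    for day in _FULL_DAYS:
        names.append(f"do_mean_{day}")
    for day in _FULL_DAYS:
        names.append(f"do_grad_{day}")
    for day in _ACCEL_DAYS:
        names.append(f"do_accel_{day}")
    for day in _FULL_DAYS:
        names.append(f"ph_mean_{day}")
    for day in _FULL_DAYS:
        names.append(f"ph_grad_{day}")
    for day in _DIFF_DAYS:
        names.append(f"dopd_mean_{day}")
    for day in _DIFF_DAYS:
        names.append(f"dopd_grad_{day}")
    for day in _ACCEL_DAYS:
        names.append(f"dopd_accel_{day}")
    for var in ("cell_density", "aggregate_size"):
        for day in DEFAULT_SAMPLING_DAYS:
            names.append(f"{var}_{day}")
        for di, dj in zip(DEFAULT_SAMPLING_DAYS, DEFAULT_SAMPLING_DAYS[1:]):
            names.append(f"{var}_grad_{di}_{dj}")
        names.append(f"{var}_grad_overall")
    for var in ("glucose", "lactate"):
        for day in DEFAULT_NUTRIENT_DAYS:
            names.append(f"{var}_{day}")
    names.extend(["preculture_time_h", "iwp2_time_h", "rotation_speed_rpm"])
    if len(names) != 101:  # soft reconstruction check, not a hard contract
        warnings.warn(
            f"default schema has {len(names)} columns (expected 101)", stacklevel=2
        )
    return names


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

@dataclass
class DerivedSeries:
    """A derived online signal (e.g. DO per unit cell density)."""

    variable: str
    times: np.ndarray
    values: np.ndarray


def density_normalized_do(run: BioreactorRun) -> DerivedSeries:
    """DO divided by offline cell density linearly interpolated in time.

    Timestamps outside the offline density span use nearest-sample
    extrapolation (flagged in the log).  Units: % air saturation per
    10^6 cells/mL.
    """
    do = run.get_series("DO_percent")
    if do is None:
        raise ValueError(f"run {run.run_id}: no DO series")
    pts = [
        (s.sample_time, s.cell_density)
        for s in run.offline
        if s.cell_density is not None
    ]
    if len(pts) < 2:
        raise ValueError(f"run {run.run_id}: need >=2 offline cell-density values")
    ts = np.array([p[0] for p in pts])
    vs = np.array([p[1] for p in pts])
    dens = np.interp(do.times, ts, vs)
    if np.any(dens <= 0):
        raise ValueError(f"run {run.run_id}: interpolated cell density <= 0")
    n_out = int(((do.times < ts[0]) | (do.times > ts[-1])).sum())
    if n_out:
        log.info(
            "run %s: %d DO samples outside offline density span; "
            "nearest-sample extrapolation used",
            run.run_id,
            n_out,
        )
    return DerivedSeries("DO_per_density", do.times.copy(), do.values / dens)


def _filtered(times: np.ndarray, values: np.ndarray,
              exclusions: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    mask = np.ones(times.shape, dtype=bool)
    for s, e in exclusions:
        mask &= ~((times >= s) & (times <= e))
    return times[mask], values[mask]


class _OnlineStats:
    """Day statistics of one online signal, media-change samples excluded."""

    def __init__(self, times: np.ndarray, values: np.ndarray,
                 exclusions: Sequence[tuple[float, float]]):
        self.t, self.v = _filtered(np.asarray(times, float), np.asarray(values, float),
                                   exclusions)
        if self.t.size >= 2:
            self.gt = self.t[1:]
            self.g = gradient_series(self.v, self.t)
        else:
            self.gt = np.empty(0)
            self.g = np.empty(0)
        if self.t.size >= 3:
            self.ht = self.t[2:]
            self.h = np.diff(self.g) / np.diff(self.t[1:])
        else:
            self.ht = np.empty(0)
            self.h = np.empty(0)

    def stat(self, statistic: str, window: tuple[float, float]) -> float:
        if statistic == "mean":
            return day_average(self.t, self.v, window)
        if statistic == "mean_gradient":
            return day_average(self.gt, self.g, window)
        if statistic == "mean_acceleration":
            return day_average(self.ht, self.h, window)
        raise ValueError(statistic)


def extract_features(
    run: BioreactorRun,
    schema: Optional[Sequence[str]] = None,
    cutoff: Optional[str] = None,
) -> dict[str, float]:
    """Compute the engineered feature vector of one run.

    Features that cannot be computed from the available data come back as
    NaN with a warning.  ``cutoff`` (``"dd7"``/``"dd5"``) limits the data
    used by cutoff-aware features (overall gradients); per-window features
    past the cutoff should be removed from the schema beforehand (see
    :func:`build_feature_table`).
    """
    if schema is None:
        schema = default_schema()
    cutoff_hours = CUTOFF_HOURS[cutoff] if cutoff is not None else float("inf")
    exclusions = run.metadata.media_change_events

    stats: dict[str, _OnlineStats] = {}
    do = run.get_series("DO_percent")
    ph = run.get_series("pH")
    if do is not None:
        stats["do"] = _OnlineStats(do.times, do.values, exclusions)
    if ph is not None:
        stats["ph"] = _OnlineStats(ph.times, ph.values, exclusions)
    try:
        dopd = density_normalized_do(run)
        stats["dopd"] = _OnlineStats(dopd.times, dopd.values, exclusions)
    except ValueError:
        pass

    out: dict[str, float] = {}
    missing: list[str] = []
    for name in schema:
        fn = parse_feature_name(name)
        value = float("nan")
        if fn.statistic == "scalar":
            value = float(getattr(run.metadata, _SCALARS[fn.variable]))
        elif fn.variable in _ONLINE_VARS:
            s = stats.get(fn.variable)
            if s is not None:
                value = s.stat(fn.statistic, day_window(fn.window))
        elif fn.statistic == "value":
            v = run.offline_value(fn.window, _OFFLINE_FIELD[fn.variable])
            value = float("nan") if v is None else float(v)
        elif fn.statistic == "span_gradient":
            vi = run.offline_value(fn.span[0], _OFFLINE_FIELD[fn.variable])
            vj = run.offline_value(fn.span[1], _OFFLINE_FIELD[fn.variable])
            if vi is not None and vj is not None:
                value = (vj - vi) / (day_index(fn.span[1]) - day_index(fn.span[0]))
        elif fn.statistic == "overall_gradient":
            pts = [
                (day_index(s.day_label), s.get(_OFFLINE_FIELD[fn.variable]))
                for s in run.offline
                if s.get(_OFFLINE_FIELD[fn.variable]) is not None
                and day_window(s.day_label)[1] <= cutoff_hours
            ]
            if len(pts) >= 2:
                pts.sort()
                (d0, v0), (d1, v1) = pts[0], pts[-1]
                if d1 > d0:
                    value = (v1 - v0) / (d1 - d0)
        if np.isnan(value):
            missing.append(name)
        out[name] = value
    if missing:
        warnings.warn(
            f"run {run.run_id}: {len(missing)} feature(s) uncomputable "
            f"(first: {missing[0]})",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Runs x engineered features, with an optional outcome column.

    ``data`` is a DataFrame indexed by run_id whose columns are canonical
    feature names; ``outcome`` (endpoint CM content, %) is kept separately.
    """

    data: pd.DataFrame
    outcome: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate run_id rows")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValueError("duplicate feature names")
        if self.outcome is not None:
            self.outcome = self.outcome.reindex(self.data.index).astype(float)
            self.outcome.name = OUTCOME_COLUMN

    @property
    def run_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_runs(self) -> int:
        return len(self.data)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        unknown = [n for n in names if n not in self.data.columns]
        if unknown:
            raise KeyError(f"features not in table: {unknown[:3]}")
        return FeatureTable(self.data[list(names)].copy(), self.outcome)

    def subset_runs(self, run_ids: Sequence[str]) -> "FeatureTable":
        sub = self.data.loc[list(run_ids)]
        out = self.outcome.loc[list(run_ids)] if self.outcome is not None else None
        return FeatureTable(sub.copy(), out)

    def to_frame(self) -> pd.DataFrame:
        """Features plus outcome column, for serialisation."""
        frame = self.data.copy()
        if self.outcome is not None:
            frame[OUTCOME_COLUMN] = self.outcome
        return frame


def build_feature_table(
    runs: Sequence[BioreactorRun],
    cutoff: Optional[str] = "dd7",
    schema: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """Assemble a cohort FeatureTable.

    ``cutoff`` restricts the table to features whose window (and every
    constituent measurement) ends at or before the cutoff day's window end:
    ``"dd7"`` for Feature Set 1, ``"dd5"`` for Feature Set 2, ``None`` for
    the unrestricted schema.
    """
    if not runs:
        raise ValueError("need at least one run")
    if schema is None:
        schema = default_schema()
    if cutoff is not None:
        if cutoff not in CUTOFF_HOURS:
            raise ValueError(f"unknown cutoff {cutoff!r}")
        limit = CUTOFF_HOURS[cutoff]
        schema = [n for n in schema if feature_window_end(n) <= limit]
    rows = {}
    outcomes = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for run in runs:
            rows[run.run_id] = extract_features(run, schema, cutoff=cutoff)
            if run.endpoint_cm_content is not None:
                outcomes[run.run_id] = run.endpoint_cm_content
    data = pd.DataFrame.from_dict(rows, orient="index", columns=list(schema))
    outcome = None
    if outcomes:
        outcome = pd.Series(outcomes, name=OUTCOME_COLUMN).reindex(data.index)
    return FeatureTable(data, outcome)
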