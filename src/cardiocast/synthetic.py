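"""Synthetic bioreactor differentiation cohorts with planted feature effects.

The generator emulates the qualitative trajectory phenomenology of stirred
tank hiPSC cardiac differentiation runs: near-linear early cell growth that
saturates mid-process, dissolved oxygen declining in proportion to cell
density and per-cell metabolic demand (with rectangular media-change
artefacts and missing-data gaps), pH drifting down with accumulated lactate
and partially resetting at medium exchanges, glucose depletion with
restoration at each exchange, and cube-root-like aggregate growth.

Outcome model: each run carries standard-normal (or standardised) latent
draws z_j, one per *plantable* engineered feature; the endpoint
cardiomyocyte content is

    CM = clip(100 * logistic(beta0 + sum_j beta_j z_j) + eps, 0, 100)

with Gaussian noise eps.  Each latent is rendered into the raw trajectories
so that the corresponding engineered feature is a faithful proxy of z_j,
making end-to-end recovery experiments well-posed.  The intercept beta0 is
calibrated numerically so that P(CM < 90%) matches the configured class
balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .features import parse_feature_name
from .runs import BioreactorRun, OfflineSample, OnlineSeries, RunMetadata, day_index

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PLANTABLE_FEATURES",
    "DEFAULT_PLANTED_EFFECTS",
    "generate_run",
    "generate_cohort",
    "describe_ground_truth",
]

#: Engineered features the generator knows how to render from a latent.
PLANTABLE_FEATURES = {
    "cell_density_grad_dd0_dd1": "z_early_growth",
    "cell_density_dd1": "z_inoculum",
    "iwp2_time_h": "z_iwp2",
    "dopd_grad_dd2": "z_do_tilt",
    "cell_density_grad_dd5_dd7": "z_late_growth",
    "preculture_time_h": "z_preculture",
}

#: Default planted feature->outcome effects (coefficients on the latent
#: z-scale of the logistic outcome model).
DEFAULT_PLANTED_EFFECTS: tuple[tuple[str, float], ...] = (
    ("cell_density_grad_dd0_dd1", 1.0),
    ("cell_density_dd1", 0.8),
    ("iwp2_time_h", -1.0),
    ("dopd_grad_dd2", 0.9),
    ("cell_density_grad_dd5_dd7", 0.7),
    ("preculture_time_h", -0.6),
)


@dataclass
class TrajectoryParams:
    """Deterministic skeleton of the simulated process and its run-to-run
    latent amplitudes.  Units noted per field."""

    do_setpoint: float = 100.0        # % air saturation with no consumption
    oxygen_coefficient: float = 9.0   # % per (10^6 cells/mL) at unit demand
    demand_base: float = 1.0          # per-cell demand, early differentiation
    demand_rise: float = 0.6          # additional demand after metabolic switch
    demand_switch_time: float = 96.0  # h, centre of the metabolic switch
    demand_switch_width: float = 18.0  # h
    day1_density: float = 1.0         # 10^6 cells/mL at dd1 (z_inoculum anchor)
    day1_sd_log: float = 0.35         # run-to-run lognormal spread (z_inoculum)
    early_gain: float = 0.35          # 10^6 cells/mL/day gained on dd0
    early_sd_log: float = 0.45        # spread of the dd0 gain (z_early_growth)
    saturation_density: float = 3.5   # 10^6 cells/mL logistic ceiling
    mid_rate: float = 0.018           # 1/h relaxation toward the ceiling
    late_gain: float = 0.25           # 10^6 cells/mL/day over dd5-dd7
    late_sd_log: float = 0.5          # spread of the late gain (z_late_growth)
    do_tilt_amplitude: float = 6.0    # DO/density slope per day on dd2 (z_do_tilt)
    preculture_rate: float = 0.02     # 1/h preculture growth
    aggregate_base: float = 130.0     # um at induction
    aggregate_exponent: float = 1 / 3  # diameter ~ density ** exponent
    aggregate_exponent_sd: float = 0.04  # per-run aggregation-morphology spread
    lactate_rate: float = 0.055       # mM per h per (10^6 cells/mL)
    glucose_rate: float = 0.11        # mM per h per (10^6 cells/mL)
    glucose_fresh: float = 18.0       # mM in fresh medium
    exchange_fraction: float = 2 / 3  # medium volume replaced per exchange
    ph_base: float = 7.35
    ph_lactate_coupling: float = 0.025  # pH drop per mM lactate
    ph_drift: float = 0.0003          # slow probe drift, pH per h
    # run-to-run nuisance spreads (probe calibration, metabolic variability)
    do_setpoint_sd: float = 2.0       # % air saturation, run-level offset
    oxygen_coefficient_sd_log: float = 0.15
    demand_rise_sd_log: float = 0.3   # run-to-run metabolic-switch magnitude
    saturation_density_sd: float = 0.3  # 10^6 cells/mL, run-level ceiling spread
    lactate_rate_sd_log: float = 0.25
    ph_base_sd: float = 0.04          # probe calibration offset
    demand_switch_time_sd: float = 6.0  # h
    aggregate_base_sd_log: float = 0.15
    do_noise_sd: float = 0.8          # % air saturation observation noise
    ph_noise_sd: float = 0.008
    offline_noise_cv: float = 0.02    # lognormal CV of density measurements
    aggregate_noise_cv: float = 0.01
    nutrient_noise_cv: float = 0.02
    media_artifact_do: float = 12.0   # rectangular DO excursion during exchange
    media_artifact_ph: float = 0.08


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort."""

    n_runs: int = 58
    seed: int = 0
    class_balance_target: float = 0.67  # fraction of insufficient (<90%) runs
    planted_effects: Sequence[tuple[str, float]] = DEFAULT_PLANTED_EFFECTS
    noise_sd_cm: float = 2.5            # % CM content noise on the endpoint
    effect_sharpness: float = 0.0       # tanh gain per latent; 0 = all-linear effects
    effect_center: float = -0.8         # tolerance edge for process-window factors
    effect_shapes: Optional[dict] = None  # feature -> "window" | "graded" | "linear"
    sampling_interval: float = 0.25     # h between online samples
    media_change_days: Sequence[str] = ("dd1", "dd3", "dd5", "dd7")
    sampling_days: Sequence[str] = ("dd0", "dd1", "dd2", "dd3", "dd5", "dd7")
    nutrient_days: Sequence[str] = ("dd3", "dd5", "dd7")
    preculture_range: tuple[float, float] = (45.0, 56.0)
    iwp2_default: float = 48.0
    iwp2_varied_fraction: float = 0.4
    iwp2_spread: float = 24.0           # varied runs: 48 +/- uniform spread, h
    chir_concentration: float = 5.0     # uM, protocol constant
    rotation_range: tuple[float, float] = (60.0, 80.0)  # rpm
    observation_noise: float = 1.0      # global scale on measurement noise
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    end_time: float = 240.0             # h, end of online logging (dd10)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.noise_sd_cm < 0:
            raise ValueError("noise_sd_cm must be >= 0")
        if not (0.0 <= self.class_balance_target <= 1.0):
            raise ValueError("class_balance_target must be in [0, 1]")
        if not (0.0 <= self.iwp2_varied_fraction <= 1.0):
            raise ValueError("iwp2_varied_fraction must be in [0, 1]")
        lo, hi = self.preculture_range
        if not (0 < lo <= hi <= 96):
            raise ValueError("preculture_range outside physical bounds")
        self.planted_effects = [(str(n), float(c)) for n, c in self.planted_effects]
        for name, _ in self.planted_effects:
            parse_feature_name(name)  # must be valid in the feature grammar
            if name not in PLANTABLE_FEATURES:
                raise ValueError(
                    f"planted feature {name!r} is valid but not plantable; "
                    f"choose from {sorted(PLANTABLE_FEATURES)}"
                )
        if len({n for n, _ in self.planted_effects}) != len(self.planted_effects):
            raise ValueError("duplicate planted feature")


@dataclass
class GroundTruth:
    """What the generator actually did: echoed effects, per-run latents and
    noise-free endpoints.  Enables recovery tests."""

    planted_effects: list[tuple[str, float]]
    beta0: float
    latents: pd.DataFrame            # one row per run, latent z columns + metadata
    noise_free_cm: pd.Series         # 100 * logistic(u), per run

    @property
    def planted_features(self) -> list[str]:
        return [name for name, _ in self.planted_effects]


# ---------------------------------------------------------------------------
# latent draws and outcome calibration
# ---------------------------------------------------------------------------

def _iwp2_z_sd(config: SyntheticConfig) -> float:
    # mixture: point mass at 48 h w.p. (1 - f), uniform(+-spread) w.p. f
    f = config.iwp2_varied_fraction
    return config.iwp2_spread * np.sqrt(f / 3.0) if f > 0 else 1.0


def _draw_latents(rng: np.random.Generator, n: int, config: SyntheticConfig) -> pd.DataFrame:
    lo, hi = config.preculture_range
    preculture = rng.uniform(lo, hi, size=n)
    pre_sd = (hi - lo) / np.sqrt(12.0)
    varied = rng.random(n) < config.iwp2_varied_fraction
    iwp2 = np.full(n, config.iwp2_default)
    iwp2[varied] += rng.uniform(-config.iwp2_spread, config.iwp2_spread, size=varied.sum())
    frame = pd.DataFrame(
        {
            "z_early_growth": rng.standard_normal(n),
            "z_inoculum": rng.standard_normal(n),
            "z_do_tilt": rng.standard_normal(n),
            "z_late_growth": rng.standard_normal(n),
            "z_preculture": (preculture - (lo + hi) / 2.0) / pre_sd if hi > lo else np.zeros(n),
            "z_iwp2": (iwp2 - config.iwp2_default) / _iwp2_z_sd(config),
            "preculture_time": preculture,
            "iwp2_time": iwp2,
        }
    )
    return frame


#: Default response shape per plantable factor: timing/process-window
#: factors have sharp tolerance edges; trajectory factors are graded.
DEFAULT_EFFECT_SHAPES = {
    "iwp2_time_h": "window",
    "preculture_time_h": "window",
}


def _effect_term(config: SyntheticConfig, name: str, coef: float,
                 z: np.ndarray) -> np.ndarray:
    """Contribution of one planted factor to the linear predictor.

    ``graded`` (default): saturating dose response |coef| * tanh(k v) on
    the favourable scale v = sign(coef) * z.  ``window``: tolerance
    response |coef| * tanh(k (v - center)) — the factor is neutral inside
    its process window and swings hard against the outcome outside it
    (conjunctive failure, typical of exposure-timing variables).
    ``linear``, or ``effect_sharpness = 0``: plain coef * z.
    """
    k = config.effect_sharpness
    shapes = config.effect_shapes if config.effect_shapes is not None else DEFAULT_EFFECT_SHAPES
    shape = shapes.get(name, "graded")
    if k <= 0 or shape == "linear":
        return coef * z
    v = np.sign(coef) * z if coef != 0 else z
    if shape == "window":
        return abs(coef) * np.tanh(k * (v - config.effect_center))
    return abs(coef) * np.tanh(k * v)


def _linear_predictor(config: SyntheticConfig, latents: pd.DataFrame) -> np.ndarray:
    u = np.zeros(len(latents))
    for name, coef in config.planted_effects:
        u += _effect_term(config, name, coef, latents[PLANTABLE_FEATURES[name]].to_numpy())
    return u


_BETA0_CACHE: dict[tuple, float] = {}


def calibrate_beta0(config: SyntheticConfig) -> float:
    """Intercept of the outcome model such that P(CM < 90) equals the
    configured class balance (quasi-Monte-Carlo + bisection)."""
    key = (
        tuple(config.planted_effects),
        config.class_balance_target,
        config.noise_sd_cm,
        config.effect_sharpness,
        config.effect_center,
        tuple(sorted((config.effect_shapes or DEFAULT_EFFECT_SHAPES).items())),
        config.iwp2_varied_fraction,
        config.iwp2_spread,
        config.preculture_range,
    )
    if key in _BETA0_CACHE:
        return _BETA0_CACHE[key]
    target = config.class_balance_target
    rng = np.random.default_rng(20240917)  # internal, independent of cohort seed
    u_off = _linear_predictor(config, _draw_latents(rng, 8192, config))

    def p_insufficient(beta0: float) -> float:
        mean_cm = 100.0 * expit(beta0 + u_off)
        if config.noise_sd_cm > 0:
            return float(norm.cdf((90.0 - mean_cm) / config.noise_sd_cm).mean())
        return float((mean_cm < 90.0).mean())

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        # p_insufficient decreases in beta0
        if p_insufficient(mid) > target:
            lo = mid
        else:
            hi = mid
    beta0 = 0.5 * (lo + hi)
    _BETA0_CACHE[key] = beta0
    return beta0


# ---------------------------------------------------------------------------
# trajectory rendering
# ---------------------------------------------------------------------------

def _density_profile(t: np.ndarray, tp: TrajectoryParams, lat: dict) -> np.ndarray:
    """Cell density (10^6 cells/mL) on an arbitrary time grid (hours)."""
    n24 = tp.day1_density * np.exp(
        tp.day1_sd_log * lat["z_inoculum"] - tp.day1_sd_log**2 / 2
    )
    early = tp.early_gain * np.exp(
        tp.early_sd_log * lat["z_early_growth"] - tp.early_sd_log**2 / 2
    )
    late = tp.late_gain * np.exp(
        tp.late_sd_log * lat["z_late_growth"] - tp.late_sd_log**2 / 2
    )
    # dd1 level carries the inoculum latent; the dd0 gain carries the
    # early-growth latent; induction density is their difference
    n0 = np.maximum(n24 - early, 0.05)
    early = n24 - n0
    n120 = tp.saturation_density - (tp.saturation_density - n24) * np.exp(
        -tp.mid_rate * 96.0
    )
    n192 = n120 + late * 3.0
    out = np.empty_like(t)
    pre = t < 0
    out[pre] = n0 * np.exp(tp.preculture_rate * t[pre])
    seg = (t >= 0) & (t < 24)
    out[seg] = n0 + early * (t[seg] / 24.0)
    seg = (t >= 24) & (t < 120)
    out[seg] = tp.saturation_density - (tp.saturation_density - n24) * np.exp(
        -tp.mid_rate * (t[seg] - 24.0)
    )
    seg = (t >= 120) & (t < 192)
    out[seg] = n120 + late * (t[seg] - 120.0) / 24.0
    out[t >= 192] = n192
    return out


def _demand(t: np.ndarray, tp: TrajectoryParams) -> np.ndarray:
    m = tp.demand_base + tp.demand_rise * expit(
        (t - tp.demand_switch_time) / tp.demand_switch_width
    )
    m = np.where(t < 0, 0.7 * tp.demand_base, m)
    return m


def _media_events(config: SyntheticConfig) -> list[tuple[float, float]]:
    events = []
    for day in config.media_change_days:
        k = day_index(day)
        events.append((24.0 * k + 1.0, 24.0 * k + 2.0))
    return sorted(events)


def _metabolites(
    t: np.ndarray, density: np.ndarray, events: Sequence[tuple[float, float]],
    tp: TrajectoryParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Lactate and glucose (mM) on the grid; production/consumption scale
    with cell density, partial reset at each medium exchange."""
    dt = np.diff(t, prepend=t[0])
    rate = np.where(t > 0, density, 0.0) * dt  # perfused preculture: quasi-steady
    cum = np.cumsum(rate)
    lac = np.zeros_like(t)
    glc = np.full_like(t, tp.glucose_fresh)
    resets = sorted(s for s, _ in events if s > 0)
    bounds = [t[0]] + resets + [t[-1] + 1.0]
    lac0, glc0 = 0.0, tp.glucose_fresh
    for left, right in zip(bounds, bounds[1:]):
        seg = (t >= left) & (t < right)
        if not seg.any():
            continue
        base = cum[seg][0] - rate[seg][0]
        produced = cum[seg] - base
        lac[seg] = lac0 + tp.lactate_rate * produced
        glc[seg] = np.maximum(glc0 - tp.glucose_rate * produced, 0.2)
        lac_end, glc_end = lac[seg][-1], glc[seg][-1]
        lac0 = lac_end * (1.0 - tp.exchange_fraction)
        glc0 = glc_end + tp.exchange_fraction * (tp.glucose_fresh - glc_end)
    return lac, glc


def generate_run(
    config: SyntheticConfig,
    run_seed: int | np.random.SeedSequence,
    latents: dict,
    run_id: Optional[str] = None,
) -> tuple[BioreactorRun, float]:
    """Render one run from its latent draw.

    Returns the run and its noise-free endpoint (100 * logistic(u)).
    """
    rng = np.random.default_rng(run_seed)
    base = config.trajectory
    # per-run nuisance draws: calibration offsets and metabolic variability
    tp = replace(
        base,
        do_setpoint=base.do_setpoint + base.do_setpoint_sd * rng.standard_normal(),
        oxygen_coefficient=base.oxygen_coefficient
        * np.exp(base.oxygen_coefficient_sd_log * rng.standard_normal()
                 - base.oxygen_coefficient_sd_log**2 / 2),
        demand_rise=base.demand_rise
        * np.exp(base.demand_rise_sd_log * rng.standard_normal()
                 - base.demand_rise_sd_log**2 / 2),
        lactate_rate=base.lactate_rate
        * np.exp(base.lactate_rate_sd_log * rng.standard_normal()
                 - base.lactate_rate_sd_log**2 / 2),
        ph_base=base.ph_base + base.ph_base_sd * rng.standard_normal(),
        saturation_density=base.saturation_density
        + base.saturation_density_sd * rng.standard_normal(),
        demand_switch_time=base.demand_switch_time
        + base.demand_switch_time_sd * rng.standard_normal(),
        aggregate_base=base.aggregate_base
        * np.exp(base.aggregate_base_sd_log * rng.standard_normal()),
        aggregate_exponent=base.aggregate_exponent
        + base.aggregate_exponent_sd * rng.standard_normal(),
    )
    noise = config.observation_noise
    events = _media_events(config)

    preculture_time = float(latents["preculture_time"])
    metadata = RunMetadata(
        run_id=run_id or f"run{rng.integers(1e9):09d}",
        preculture_time=preculture_time,
        iwp2_treatment_time=float(latents["iwp2_time"]),
        chir_concentration=config.chir_concentration,
        rotation_speed=float(rng.uniform(*config.rotation_range)),
        media_change_events=[(s, e) for s, e in events],
    )

    t = np.arange(-preculture_time, config.end_time + 1e-9, config.sampling_interval)
    density = _density_profile(t, tp, latents)

    do = tp.do_setpoint - tp.oxygen_coefficient * density * _demand(t, tp)
    dd2 = (t >= 48.0) & (t < 72.0)
    do[dd2] += (
        latents["z_do_tilt"] * tp.do_tilt_amplitude * density[dd2] * (t[dd2] - 48.0) / 24.0
    )
    lac, glc = _metabolites(t, density, events, tp)
    ph = tp.ph_base - tp.ph_lactate_coupling * lac - tp.ph_drift * np.maximum(t, 0.0)

    do = do + noise * tp.do_noise_sd * rng.standard_normal(t.size)
    ph = ph + noise * tp.ph_noise_sd * rng.standard_normal(t.size)

    # media-change artefact: rectangular excursion + missing-data gap
    keep = np.ones(t.size, dtype=bool)
    for s, e in events:
        inside = (t >= s) & (t <= e)
        do[inside] += tp.media_artifact_do
        ph[inside] += tp.media_artifact_ph
        gap = (t >= s + 0.25 * (e - s)) & (t <= s + 0.75 * (e - s))
        keep &= ~gap
    do = np.clip(do, 0.0, 200.0)
    ph = np.clip(ph, 4.0, 10.0)

    online = [
        OnlineSeries("DO_percent", t[keep], do[keep]),
        OnlineSeries("pH", t[keep], ph[keep]),
    ]

    offline = []
    prev_diam = 0.0
    n0_run = density[np.searchsorted(t, 0.0)]
    for day in config.sampling_days:
        ts = 24.0 * day_index(day) + 0.5
        idx = np.searchsorted(t, ts)
        dens = density[idx] * np.exp(noise * tp.offline_noise_cv * rng.standard_normal())
        diam = (
            tp.aggregate_base
            * (density[idx] / n0_run) ** tp.aggregate_exponent
            * np.exp(noise * tp.aggregate_noise_cv * rng.standard_normal())
        )
        prev_diam = diam = max(diam, prev_diam * 1.0005)  # aggregates never shrink
        sample = OfflineSample(
            day_label=day,
            sample_time=ts,
            cell_density=float(dens),
            aggregate_diameter=float(diam),
        )
        if day in config.nutrient_days:
            sample.glucose = float(
                glc[idx] * np.exp(noise * tp.nutrient_noise_cv * rng.standard_normal())
            )
            sample.lactate = float(
                lac[idx] * np.exp(noise * tp.nutrient_noise_cv * rng.standard_normal())
            )
        offline.append(sample)

    beta0 = calibrate_beta0(config)
    u = beta0 + sum(
        float(_effect_term(config, name, coef, np.asarray(latents[PLANTABLE_FEATURES[name]])))
        for name, coef in config.planted_effects
    )
    clean_cm = 100.0 * float(expit(u))
    cm = float(np.clip(clean_cm + config.noise_sd_cm * rng.standard_normal(), 0.0, 100.0))

    run = BioreactorRun(
        metadata=metadata,
        online=online,
        offline=offline,
        endpoint_cm_content=cm,
    )
    return run, clean_cm


def generate_cohort(config: SyntheticConfig) -> tuple[list[BioreactorRun], GroundTruth]:
    """Generate ``config.n_runs`` runs, reproducibly from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    latent_rng = np.random.default_rng(ss.spawn(1)[0])
    latents = _draw_latents(latent_rng, config.n_runs, config)
    run_seeds = ss.spawn(config.n_runs)

    runs: list[BioreactorRun] = []
    clean = []
    for i in range(config.n_runs):
        run, clean_cm = generate_run(
            config, run_seeds[i], latents.iloc[i].to_dict(), run_id=f"run{i + 1:03d}"
        )
        runs.append(run)
        clean.append(clean_cm)

    latents = latents.copy()
    latents.index = [r.run_id for r in runs]
    gt = GroundTruth(
        planted_effects=list(config.planted_effects),
        beta0=calibrate_beta0(config),
        latents=latents,
        noise_free_cm=pd.Series(clean, index=latents.index, name="noise_free_cm"),
    )
    return runs, gt


def describe_ground_truth(gt: GroundTruth) -> pd.DataFrame:
    """Tabulate planted effects with realised latent summaries."""
    rows = []
    for name, coef in gt.planted_effects:
        z = gt.latents[PLANTABLE_FEATURES[name]]
        rows.append(
            {
                "feature": name,
                "coefficient": coef,
                "latent_mean": float(z.mean()),
                "latent_sd": float(z.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "coefficient", "latent_mean", "latent_sd"])
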