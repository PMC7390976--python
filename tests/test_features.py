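import warnings

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from cardiocast.features import (
    CUTOFF_HOURS,
    build_feature_table,
    day_average,
    default_schema,
    density_normalized_do,
    extract_features,
    feature_window_end,
    gradient_series,
    parse_feature_name,
    resolve_alias,
    second_derivative_series,
)
from cardiocast.runs import (
    BioreactorRun,
    OfflineSample,
    OnlineSeries,
    RunMetadata,
    day_window,
)

# every feature name printed in the study's two selection tables
TABLE1_NAMES = [
    "Average DO concentration dd0",
    "Average DO concentration gradient d0",
    "Average DO concentration gradient dd2",
    "Average DO concentration gradient dd6",
    "Average DO concentration gradient dd7",
    "d0 average pH gradient",
    "dd0 average pH gradient",
    "dd0 average acceleration of cell density normalized DO gradient",
    "dd0–dd1 cell density gradient",
    "dd1 aggregate size",
    "dd1 cell density",
    "dd2 average pH",
    "dd7 average pH",
    "dd3 aggregate size",
    "dd3 average acceleration of DO gradient",
    "dd3 average pH gradient",
    "dd3 average acceleration of cell density normalized DO gradient",
    "dd5 average pH gradient",
    "dd5–dd7 aggregate size gradient",
    "dd5–dd7 cell density gradient",
    "dd7 cell density",
    "Cell density normalized DO concentration dd2",
    "Cell density normalized DO concentration dd3",
    "Cell density normalized DO concentration dd7",
    "Average cell density normalized DO concentration gradient dd2",
    "Average cell density normalized DO concentration gradient dd5",
    "Average cell density normalized DO concentration gradient dd7",
    "IWP2 treatment time [h]",
    "Preculture time [h]",
]
TABLE2_NAMES = [
    "Average DO concentration d0",
    "Average DO concentration dd0",
    "Average DO concentration dd2",
    "Average DO concentration dd4",
    "Average DO concentration gradient d0",
    "Average DO concentration gradient dd2",
    "Average DO concentration gradient dd4",
    "Average DO concentration gradient dd5",
    "d1 average pH gradient",
    "dd0 aggregate size",
    "dd0 cell density",
    "dd0–dd1 cell density gradient",
    "dd1 average pH",
    "dd1 average acceleration of cell density normalized DO gradient",
    "dd2 aggregate size",
    "dd2 average acceleration of DO gradient",
    "dd2 average pH",
    "dd2 average pH gradient",
    "dd2 average acceleration of cell density normalized DO gradient",
    "dd2–dd3 aggregate size gradient",
    "dd3–dd5 cell density gradient",
    "dd4 average pH gradient",
    "dd5 average acceleration of cell density normalized DO gradient",
    "Cell density normalized DO concentration dd1",
    "Average cell density normalized DO concentration gradient dd5",
    "IWP2 treatment time [h]",
    "Overall aggregate size gradient",
    "Overall density gradient",
]


class TestDifferenceQuotients:
    @pytest.mark.parametrize(
        "values,times,expected",
        [
            ((2, 4), (0, 1), (2.0,)),
            ((5, 5, 5, 5), (0, 1, 4, 9), (0.0, 0.0, 0.0)),
            ((0, 1, 4), (0, 1, 2), (1.0, 3.0)),  # y = t^2
        ],
    )
    def test_gradient_examples(self, values, times, expected):
        npt.assert_array_equal(gradient_series(values, times), expected)

    @pytest.mark.parametrize(
        "values,times,expected",
        [
            ((0, 1, 4), (0, 1, 2), (2.0,)),  # quadratic -> constant 2
            ((1, 3, 5, 7), (0, 1, 2, 3), (0.0, 0.0)),  # linear -> zero
            ((0, 0, 6), (0, 1, 2), (6.0,)),  # hand evaluation
        ],
    )
    def test_second_derivative_examples(self, values, times, expected):
        npt.assert_array_equal(second_derivative_series(values, times), expected)

    def test_duplicate_timestamps_error(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            gradient_series([0, 2, 1], [0, 2, 1])
        with pytest.raises(ValueError):
            second_derivative_series([1, 2, 3], [0, 1, 1])

    @given(
        slope=st.floats(-50, 50),
        intercept=st.floats(-50, 50),
        times=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=3, max_size=12, unique=True
        ),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_linear_series_exactness(self, slope, intercept, times):
        """First differences of a linear series equal the slope; second
        differences vanish (up to float cancellation)."""
        t = np.sort(np.asarray(times))
        if np.min(np.diff(t)) < 1e-3:
            return
        y = slope * t + intercept
        g = gradient_series(y, t)
        npt.assert_allclose(g, slope, rtol=1e-7, atol=1e-7)
        h = second_derivative_series(y, t)
        npt.assert_allclose(h, 0.0, atol=1e-5 * (1 + abs(slope) + abs(intercept)))


class TestDayAverage:
    def test_exclusion_removes_artifact(self):
        t = [1.0, 2.0, 3.0, 4.0]
        v = [10.0, 10.0, 50.0, 10.0]
        assert day_average(t, v, (0, 24), exclusions=[(2.5, 3.5)]) == 10.0

    def test_plain_mean(self):
        assert day_average([1, 2, 3], [1.0, 2.0, 3.0], (0, 24)) == 2.0

    def test_all_excluded_is_missing(self):
        assert np.isnan(day_average([1, 2], [1.0, 2.0], (0, 24), exclusions=[(0, 24)]))

    def test_enlarging_disjoint_exclusion_is_noop(self):
        t = np.linspace(0.5, 23.5, 30)
        v = np.sin(t)
        base = day_average(t, v, (0, 24), exclusions=[(30.0, 31.0)])
        widened = day_average(t, v, (0, 24), exclusions=[(24.5, 40.0)])
        assert base == widened == day_average(t, v, (0, 24))


def test_day_windows_tile_differentiation_span():
    edges = [day_window(f"dd{k}") for k in range(10)]
    assert edges[0][0] == 0.0 and edges[-1][1] == 240.0
    for (s1, e1), (s2, e2) in zip(edges, edges[1:]):
        assert e1 == s2 and e1 - s1 == 24.0


class TestFeatureGrammar:
    @pytest.mark.parametrize("printed", sorted(set(TABLE1_NAMES + TABLE2_NAMES)))
    def test_printed_names_resolve(self, printed):
        canonical = resolve_alias(printed)
        parse_feature_name(canonical)  # must be a canonical feature

    def test_printed_vocabulary_size(self):
        assert len(TABLE1_NAMES) == 29 and len(TABLE2_NAMES) == 28

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            resolve_alias("dd3 average moon phase")

    def test_default_schema_covers_vocabulary(self):
        schema = set(default_schema())
        for printed in TABLE1_NAMES + TABLE2_NAMES:
            assert resolve_alias(printed) in schema, printed

    def test_default_schema_has_101_columns(self):
        assert len(default_schema()) == 101

    def test_window_end_ordering(self):
        assert feature_window_end("do_mean_dd7") == 192.0
        assert feature_window_end("cell_density_grad_dd5_dd7") == 192.0
        assert feature_window_end("preculture_time_h") == float("-inf")


class TestExtraction:
    def test_complete_run_has_no_missing_features(self, complete_run):
        features = extract_features(complete_run)
        assert len(features) == 101
        assert not any(np.isnan(v) for v in features.values())

    def test_table_alias_features_computable(self, complete_run):
        schema = sorted({resolve_alias(n) for n in TABLE1_NAMES + TABLE2_NAMES})
        features = extract_features(complete_run, schema=schema)
        assert all(np.isfinite(v) for v in features.values())

    def test_density_normalized_do_definition(self):
        run = _run_with_do(do_value=40.0, densities=[(0.5, 2.0), (100.0, 2.0)])
        series = density_normalized_do(run)
        npt.assert_allclose(series.values, 20.0)

    def test_density_normalized_do_proportionality(self):
        run1 = _run_with_do(40.0, [(0.5, 1.0), (100.0, 1.0)])
        run2 = _run_with_do(40.0, [(0.5, 2.0), (100.0, 2.0)])
        npt.assert_allclose(
            density_normalized_do(run1).values, 2 * density_normalized_do(run2).values
        )

    def test_extrapolation_matches_drop_oracle_on_common_support(self):
        run = _run_with_do(40.0, [(10.0, 2.0), (50.0, 4.0)], t_end=80.0)
        series = density_normalized_do(run)
        inside = (series.times >= 10.0) & (series.times <= 50.0)
        oracle = 40.0 / np.interp(series.times[inside], [10.0, 50.0], [2.0, 4.0])
        npt.assert_allclose(series.values[inside], oracle)
        # outside the span: nearest-sample extrapolation
        npt.assert_allclose(series.values[series.times < 10.0], 40.0 / 2.0)
        npt.assert_allclose(series.values[series.times > 50.0], 40.0 / 4.0)

    def test_missingness_is_local(self, complete_run):
        schema = [
            "cell_density_dd3",
            "cell_density_dd5",
            "cell_density_grad_dd3_dd5",
            "cell_density_grad_dd5_dd7",
            "cell_density_grad_dd0_dd1",
        ]
        run = BioreactorRun(
            metadata=complete_run.metadata,
            online=list(complete_run.online),
            offline=[s for s in complete_run.offline if s.day_label != "dd5"],
            endpoint_cm_content=complete_run.endpoint_cm_content,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = extract_features(run, schema=schema)
        assert np.isnan(feats["cell_density_dd5"])
        assert np.isnan(feats["cell_density_grad_dd3_dd5"])
        assert np.isnan(feats["cell_density_grad_dd5_dd7"])
        assert np.isfinite(feats["cell_density_dd3"])
        assert np.isfinite(feats["cell_density_grad_dd0_dd1"])

    def test_overall_gradient_uses_day_timestamps(self):
        run = _offline_only_run([("dd0", 0.5), ("dd7", 2.5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = extract_features(run, schema=["cell_density_grad_overall"])
        npt.assert_allclose(feats["cell_density_grad_overall"], (2.5 - 0.5) / 7)

    def test_overall_gradient_respects_cutoff(self):
        run = _offline_only_run([("dd0", 0.5), ("dd5", 2.0), ("dd7", 2.5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = extract_features(run, schema=["cell_density_grad_overall"])
            fs2 = extract_features(
                run, schema=["cell_density_grad_overall"], cutoff="dd5"
            )
        npt.assert_allclose(full["cell_density_grad_overall"], 2.0 / 7)
        npt.assert_allclose(fs2["cell_density_grad_overall"], 1.5 / 5)


class TestFeatureSets:
    def test_fs2_has_no_feature_past_dd5(self, small_cohort):
        _, runs, _ = small_cohort
        table = build_feature_table(runs, cutoff="dd5")
        for name in table.feature_names:
            assert feature_window_end(name) <= CUTOFF_HOURS["dd5"], name
        assert "cell_density_grad_dd5_dd7" not in table.feature_names
        assert not any("dd6" in n or "dd7" in n for n in table.feature_names)

    def test_fs1_includes_dd7_gradient(self, cohort_table):
        assert "do_grad_dd7" in cohort_table.feature_names
        assert resolve_alias("Average DO concentration gradient dd7") == "do_grad_dd7"

    def test_full_table_has_101_columns(self, small_cohort):
        _, runs, _ = small_cohort
        table = build_feature_table(runs, cutoff=None)
        assert len(table.feature_names) == 101


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _run_with_do(do_value, densities, t_end=100.0):
    times = np.arange(0.5, t_end, 1.0)
    offline = [
        OfflineSample(
            day_label=f"dd{int(t // 24)}", sample_time=t, cell_density=v
        )
        for t, v in densities
    ]
    return BioreactorRun(
        metadata=RunMetadata("t1", 48.0, 48.0, 5.0, 70.0),
        online=[OnlineSeries("DO_percent", times, np.full(times.size, do_value))],
        offline=offline,
    )


def _offline_only_run(day_values):
    offline = [
        OfflineSample(day_label=d, sample_time=day_window(d)[0] + 0.5, cell_density=v)
        for d, v in day_values
    ]
    return BioreactorRun(
        metadata=RunMetadata("t2", 48.0, 48.0, 5.0, 70.0), online=[], offline=offline
    )
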