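import warnings

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from scipy import stats

from cardiocast.selection import (
    correlation_select,
    gpr_ard_select,
    mars_select,
    pca_reduce,
    pca_scores,
    pearson_correlation,
    rf_select,
    spearman_correlation,
)

from conftest import make_table


class TestCorrelations:
    def test_perfect_linear(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_convex_curve_below_one(self):
        r = pearson_correlation([1, 2, 3, 4], [1, 4, 9, 16])
        assert 0.96 < r < 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 2, 3], [5, 5, 5])

    def test_spearman_rank_invariance(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        assert spearman_correlation(x, x**3) == pytest.approx(1.0)
        assert spearman_correlation(x, -x + 7) == pytest.approx(-1.0)

    def test_spearman_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        oracle = pearson_correlation(stats.rankdata(x), stats.rankdata(y))
        assert spearman_correlation(x, y) == pytest.approx(oracle)

    def test_correlation_select_orders_by_strength(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = 80 + 10 * X[:, 0] + 2 * X[:, 1] + rng.normal(size=40)
        table = make_table(X, y)
        result = correlation_select(table, "pearson", threshold=0.3)
        assert result.selected[0] == "do_mean_dd0"


class TestPca:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10)) @ rng.normal(size=(10, 10))
        table = make_table(X, columns=[f"ph_mean_dd{j}" for j in range(10)])
        result = pca_reduce(table, variance_target=0.94)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        corr = Z.T @ Z / (len(X) - 1)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        evr_oracle = eigvals / eigvals.sum()
        evr = result.extras["explained_variance_ratio"]
        npt.assert_allclose(evr, evr_oracle, atol=1e-8)
        # retained count is minimal for the target
        n = result.extras["n_components"]
        cum = np.cumsum(evr_oracle)
        assert cum[n - 1] >= 0.94 and (n == 1 or cum[n - 2] < 0.94)
        # loadings are eigenvectors: projecting reproduces the variance
        scores = pca_scores(result, table)
        npt.assert_allclose(
            scores.var(ddof=1).to_numpy(), eigvals[:n], rtol=1e-8
        )

    def test_rank_one_structure_needs_single_component(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=30)
        X = np.column_stack([base, 2 * base, np.zeros(30)])
        table = make_table(X, columns=["do_mean_dd0", "do_mean_dd1", "do_mean_dd2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            result = pca_reduce(table, variance_target=1.0)
        assert result.extras["n_components"] == 1
        npt.assert_allclose(result.extras["explained_variance_ratio"][0], 1.0)

    def test_cumulative_variance_monotone(self, cohort_table):
        result = pca_reduce(cohort_table)
        evr = result.extras["explained_variance_ratio"]
        assert np.all(evr >= -1e-12)
        assert np.all(np.diff(np.cumsum(evr)) >= -1e-12)
        assert np.sum(evr) <= 1 + 1e-9

    def test_column_permutation_permutes_loadings(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        cols = ["do_mean_dd0", "do_mean_dd1", "do_mean_dd2", "do_mean_dd3"]
        t1 = make_table(X, columns=cols)
        perm = [2, 0, 3, 1]
        t2 = make_table(X[:, perm], columns=[cols[i] for i in perm])
        r1, r2 = pca_reduce(t1), pca_reduce(t2)
        l1 = r1.extras["loadings"][cols].to_numpy()
        l2 = r2.extras["loadings"][cols].to_numpy()
        sign = np.sign(np.sum(l1 * l2, axis=1, keepdims=True))
        npt.assert_allclose(l1, sign * l2, atol=1e-8)

    def test_variance_target_validated(self, cohort_table):
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                pca_reduce(cohort_table, variance_target=bad)


class TestRfSelect:
    def test_importances_normalised(self, cohort_table):
        result = rf_select(cohort_table, seed=0, n_trees=50)
        npt.assert_allclose(sum(result.scores.values()), 1.0, atol=1e-9)
        assert set(result.selected) <= set(result.scores)

    def test_strong_signal_ranks_first(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 6))
        y = np.clip(70 + 20 * X[:, 3] + rng.normal(size=80), 0, 100)
        result = rf_select(make_table(X, y), seed=1, n_trees=100)
        assert result.selected[0] == "do_mean_dd3"

    def test_null_cohort_selection_is_unremarkable(self):
        """Under a pure-noise outcome the mean-importance rule still selects
        a nontrivial fraction by chance, but no feature dominates."""
        rng = np.random.default_rng(7)
        frequencies = np.zeros(30)
        n_seeds = 12
        for seed in range(n_seeds):
            X = rng.normal(size=(40, 30))
            y = rng.normal(size=40) * 5 + 70
            result = rf_select(
                make_table(X, y, columns=[f"f{j}" for j in range(30)]),
                seed=seed, n_trees=100,
            )
            frac = len(result.selected) / 30
            assert 0.05 < frac < 0.8
            for name in result.selected:
                frequencies[int(name[1:])] += 1
        assert frequencies.max() / n_seeds < 0.95

    def test_constant_outcome_rejected(self):
        table = make_table(np.random.default_rng(8).normal(size=(10, 3)), [50.0] * 10)
        with pytest.raises(ValueError, match="constant"):
            rf_select(table, seed=0)


class TestGprArdSelect:
    def test_informative_feature_beats_noise(self):
        hits_ls, hits_sens = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(100, 2))
            y = np.clip(70 + 15 * X[:, 0] + 2 * rng.normal(size=100), 0, 100)
            table = make_table(X, y, columns=["do_mean_dd0", "do_mean_dd1"])
            result = gpr_ard_select(table, seed=seed)
            ls = result.extras["length_scales"]
            if ls["do_mean_dd0"] < ls["do_mean_dd1"]:
                hits_ls += 1
            if result.scores["do_mean_dd0"] > result.scores["do_mean_dd1"]:
                hits_sens += 1
        assert hits_ls >= 18 and hits_sens >= 18

    def test_signal_free_outcome_selects_near_empty_set(self):
        """With an outcome independent of every feature, ARD retains at
        most a stray feature or two (chance correlations), never a broad
        set."""
        sizes = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(80, 8))
            null_y = np.clip(70 + 5 * rng.normal(size=80), 0, 100)
            cols = [f"do_mean_dd{j}" for j in range(8)]
            result = gpr_ard_select(make_table(X, null_y, columns=cols), seed=seed)
            sizes.append(len(result.selected))
        assert np.mean(sizes) <= 3.0

    def test_duplicated_feature_union_covers_signal(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 3))
        y = np.clip(70 + 15 * X[:, 0] + 2 * rng.normal(size=100), 0, 100)
        X_dup = np.column_stack([X, X[:, 0]])
        cols = ["do_mean_dd0", "do_mean_dd1", "do_mean_dd2", "do_mean_dd3"]
        result = gpr_ard_select(make_table(X_dup, y, columns=cols), seed=0)
        assert {"do_mean_dd0", "do_mean_dd3"} & set(result.selected)


class TestMarsSelect:
    def test_single_hinge_outcome_identified_exactly(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, size=(100, 5))
        y = np.clip(60 + 30 * np.maximum(X[:, 2], 0.0), 0, 100)
        result = mars_select(make_table(X, y), seed=0)
        assert result.selected == ["do_mean_dd2"]

    def test_unused_features_score_zero(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(-1, 1, size=(80, 4))
        y = np.clip(60 + 25 * np.maximum(X[:, 0], 0.0), 0, 100)
        result = mars_select(make_table(X, y), seed=0)
        for name in set(result.scores) - set(result.selected):
            assert result.scores[name] == 0.0


def test_zero_variance_features_dropped_with_warning():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(30, 3))
    X[:, 1] = 4.2
    y = np.clip(70 + 10 * X[:, 0] + rng.normal(size=30), 0, 100)
    table = make_table(X, y)
    with pytest.warns(UserWarning, match="zero-variance"):
        result = rf_select(table, seed=0, n_trees=20)
    assert "do_mean_dd1" not in result.scores


def test_planted_recovery_improves_with_cohort_size():
    """RF-importance recall of planted features does not degrade as the
    cohort grows (checked at n in {40, 100, 400})."""
    import warnings as _w

    from cardiocast import SyntheticConfig, build_feature_table, generate_cohort
    from cardiocast.synthetic import DEFAULT_PLANTED_EFFECTS

    planted = [n for n, _ in DEFAULT_PLANTED_EFFECTS]
    means = []
    for n in (40, 100, 400):
        recalls = []
        for seed in range(5):
            runs, _ = generate_cohort(SyntheticConfig(n_runs=n, seed=900 + seed))
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                table = build_feature_table(runs, cutoff="dd7")
            selected = rf_select(table, seed=seed).selected
            recalls.append(np.mean([f in selected for f in planted]))
        means.append(np.mean(recalls))
    assert means[2] >= means[0]
    assert means[1] >= means[0] - 0.05 and means[2] >= means[1] - 0.05
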