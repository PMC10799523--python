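"""Filtering, imputation and log/Pareto scaling."""
import numpy as np
import pandas as pd
import pytest

from sepsismet.preprocess import (
    PreprocessConfig,
    filter_features_by_missingness,
    filter_patients_by_missingness,
    impute,
    log_pareto_scale,
    preprocess,
    remove_nonpositive_features,
    unscale,
)


def _with_missing(df, cells):
    out = df.copy()
    for i, j in cells:
        out.iloc[i, j] = np.nan
    return out


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        np.exp(rng.standard_normal((10, 4))), columns=list("ABCD")
    )


class TestFeatureFilter:
    def test_complete_matrix_untouched(self, small_matrix):
        kept, removed = filter_features_by_missingness(small_matrix, 0.10)
        assert removed == [] and kept.equals(small_matrix)

    def test_strict_inequality_at_10_percent(self, small_matrix):
        # n=10: A has 2 missing (20%) -> removed; B has 1 (10%) -> retained
        m = _with_missing(small_matrix, [(0, 0), (1, 0), (2, 1)])
        kept, removed = filter_features_by_missingness(m, 0.10)
        assert removed == ["A"]
        assert list(kept.columns) == ["B", "C", "D"]

    def test_boundary_at_n52(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(np.exp(rng.standard_normal((52, 2))), columns=["x", "y"])
        m.iloc[:6, 0] = np.nan  # 11.5% -> removed
        m.iloc[:5, 1] = np.nan  # 9.6% -> retained
        kept, removed = filter_features_by_missingness(m, 0.10)
        assert removed == ["x"] and list(kept.columns) == ["y"]

    def test_idempotent(self, small_matrix):
        m = _with_missing(small_matrix, [(0, 0), (1, 0)])
        kept, _ = filter_features_by_missingness(m, 0.10)
        again, removed = filter_features_by_missingness(kept, 0.10)
        assert removed == [] and again.equals(kept)

    def test_all_removed_raises(self):
        m = pd.DataFrame({"A": [np.nan] * 9 + [1.0]})
        with pytest.raises(ValueError):
            filter_features_by_missingness(m, 0.10)


class TestPatientFilter:
    def test_complete_matrix_untouched(self, small_matrix):
        kept, removed = filter_patients_by_missingness(small_matrix, 0.10)
        assert removed == [] and kept.equals(small_matrix)

    def test_patient_above_threshold_removed(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(np.exp(rng.standard_normal((5, 20))))
        m.iloc[0, :3] = np.nan  # 15% of features
        kept, removed = filter_patients_by_missingness(m, 0.10)
        assert removed == [0] and 0 not in kept.index

    def test_exactly_10_percent_retained(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(np.exp(rng.standard_normal((5, 20))))
        m.iloc[0, :2] = np.nan  # exactly 10%
        kept, removed = filter_patients_by_missingness(m, 0.10)
        assert removed == [] and 0 in kept.index


class TestNonpositiveFilter:
    def test_all_positive_unchanged(self, small_matrix):
        kept, removed = remove_nonpositive_features(small_matrix)
        assert removed == [] and kept.equals(small_matrix)

    @pytest.mark.parametrize("bad_value", [-0.3, 0.0])
    def test_feature_with_nonpositive_value_removed(self, small_matrix, bad_value):
        m = small_matrix.copy()
        m.iloc[3, 1] = bad_value
        kept, removed = remove_nonpositive_features(m)
        assert removed == ["B"] and "B" not in kept.columns


class TestImpute:
    def test_complete_matrix_returned_unchanged(self, small_matrix):
        out = impute(small_matrix, PreprocessConfig())
        assert out.equals(small_matrix)

    @pytest.mark.parametrize("method", ["median", "knn", "chained_forest"])
    def test_observed_cells_bit_identical(self, small_matrix, method):
        m = _with_missing(small_matrix, [(0, 0), (5, 2)])
        out = impute(m, PreprocessConfig(imputation_method=method))
        obs = m.notna().to_numpy()
        assert np.array_equal(out.to_numpy()[obs], m.to_numpy()[obs])
        assert not out.isna().any().any()

    def test_chained_forest_beats_median_on_correlated_data(self, correlated_matrix):
        rng = np.random.default_rng(7)
        mask = rng.random(correlated_matrix.shape) < 0.10
        masked = correlated_matrix.mask(
            pd.DataFrame(mask, columns=correlated_matrix.columns)
        )
        truth = correlated_matrix.to_numpy()[mask]
        cf = impute(masked, PreprocessConfig(imputation_method="chained_forest",
                                             imputation_seed=1))
        md = impute(masked, PreprocessConfig(imputation_method="median"))
        rmse_cf = np.sqrt(np.mean((cf.to_numpy()[mask] - truth) ** 2))
        rmse_md = np.sqrt(np.mean((md.to_numpy()[mask] - truth) ** 2))
        assert rmse_cf <= rmse_md

    def test_chained_forest_deterministic_under_seed(self, correlated_matrix):
        rng = np.random.default_rng(8)
        mask = rng.random(correlated_matrix.shape) < 0.08
        masked = correlated_matrix.mask(
            pd.DataFrame(mask, columns=correlated_matrix.columns)
        )
        cfg = PreprocessConfig(imputation_method="chained_forest", imputation_seed=3)
        assert impute(masked, cfg).equals(impute(masked, cfg))

    def test_empty_feature_raises(self, small_matrix):
        m = small_matrix.copy()
        m["A"] = np.nan
        with pytest.raises(ValueError, match="A"):
            impute(m, PreprocessConfig(imputation_method="median"))


class TestLogParetoScale:
    def test_hand_evaluated_example(self):
        m = pd.DataFrame({"f": np.exp([1.0, 2.0, 3.0])})
        scaled, params = log_pareto_scale(m)
        np.testing.assert_allclose(scaled["f"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert params.loc["f", "log_mean"] == pytest.approx(2.0)
        assert params.loc["f", "log_sd"] == pytest.approx(1.0)

    def test_scaled_features_centred(self, small_matrix):
        scaled, _ = log_pareto_scale(small_matrix)
        assert np.all(np.abs(scaled.mean(axis=0)) < 1e-12)

    def test_pareto_variance_equals_log_sd(self, small_matrix):
        scaled, params = log_pareto_scale(small_matrix)
        np.testing.assert_allclose(
            scaled.var(axis=0, ddof=1), params["log_sd"], atol=1e-10
        )

    def test_invertible(self, small_matrix):
        scaled, params = log_pareto_scale(small_matrix)
        back = unscale(scaled, params)
        np.testing.assert_allclose(back.to_numpy(), small_matrix.to_numpy(), atol=1e-10)

    def test_constant_feature_error_names_it(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            log_pareto_scale(m)


class TestFullChain:
    def test_chain_accounting_and_order(self, default_cohort):
        cfg = PreprocessConfig(imputation_method="knn", imputation_seed=0)
        scaled, report = preprocess(default_cohort.metabolites, cfg)
        removed = {f for f, _ in report.removed_features}
        assert removed | set(scaled.columns) == set(default_cohort.metabolites.columns)
        assert len(removed & set(scaled.columns)) == 0
        # the forced high-missing features must all be gone
        frac = default_cohort.metabolites.isna().mean()
        assert set(frac.index[frac > 0.10]) <= removed
        assert report.scaling_params is not None
        assert set(report.scaling_params.index) == set(scaled.columns)
        assert report.n_imputed_cells > 0

    def test_report_serialises(self, tmp_path, default_cohort):
        cfg = PreprocessConfig(imputation_method="median")
        _, report = preprocess(default_cohort.metabolites, cfg)
        report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").stat().st_size > 0
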