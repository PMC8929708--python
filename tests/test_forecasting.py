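"""Lagged-dataset construction, metrics, and regression evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ophs


def _bundle(n=40, seed=0, start="2020-01-31"):
    rng = np.random.default_rng(seed)
    index = pd.date_range(start, periods=n, freq="D", name="date")
    frame = pd.DataFrame(
        rng.normal(size=(n, 3)), index=index, columns=["a", "b", "c"]
    )
    return ophs.FeatureBundle(blocks={"covid": frame})


class TestBuildLaggedDataset:
    def test_index_arithmetic(self):
        bundle = _bundle(n=5)
        target = pd.Series(
            np.arange(5.0), index=bundle.calendar, name="count"
        )
        ds = ophs.build_lagged_dataset(bundle, target, horizon=3)
        assert ds.n_rows == 2
        # the row for day 1 targets day 4
        assert ds.y.iloc[1] == target.iloc[4]
        assert ds.X.index[1] == bundle.calendar[1]
        assert ds.target_dates[1] == bundle.calendar[4]

    def test_column_conservation(self, bundle_small, demand_small):
        ds = ophs.build_lagged_dataset(
            bundle_small, demand_small.primary.astype(float), horizon=1
        )
        widths = sum(f.shape[1] for f in bundle_small.blocks.values())
        assert len(ds.feature_names) == widths

    def test_shifted_copy_aligns_perfectly(self):
        n, lag = 60, 7
        rng = np.random.default_rng(3)
        target_values = rng.normal(size=n)
        index = pd.date_range("2020-01-31", periods=n, freq="D", name="date")
        leak = pd.DataFrame(
            {"future": np.roll(target_values, -lag)}, index=index
        )
        bundle = ophs.FeatureBundle(blocks={"covid": leak})
        target = pd.Series(target_values, index=index)
        ds = ophs.build_lagged_dataset(bundle, target, horizon=lag)
        r = np.corrcoef(ds.X["covid__future"], ds.y)[0, 1]
        assert r == pytest.approx(1.0)

    def test_horizon_errors(self):
        bundle = _bundle(n=5)
        target = pd.Series(np.ones(5), index=bundle.calendar)
        with pytest.raises(ValueError):
            ophs.build_lagged_dataset(bundle, target, horizon=0)
        with pytest.raises(ValueError, match="empty"):
            ophs.build_lagged_dataset(bundle, target, horizon=5)

    def test_target_coverage_error(self):
        bundle = _bundle(n=10)
        target = pd.Series(np.ones(5), index=bundle.calendar[:5])
        with pytest.raises(ValueError, match="cover"):
            ophs.build_lagged_dataset(bundle, target, horizon=1)


class TestMetrics:
    def test_identical_vectors(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ophs.mae(y, y) == 0.0
        assert ophs.pearson(y, y) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert ophs.mae([1, 2], [2, 4]) == pytest.approx(1.5)

    def test_antisymmetry(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert ophs.pearson(y, -y) == pytest.approx(-1.0)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            ophs.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ophs.mae([1.0], [2.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=20),
        st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_mae_translation_equivariance(self, values, shift):
        y = np.asarray(values)
        pred = y + 1.0
        assert ophs.mae(y + shift, pred + shift) == pytest.approx(
            ophs.mae(y, pred), abs=1e-9
        )

    def test_ratio(self):
        assert ophs.mae_to_mean_ratio(6.0, 30.0) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            ophs.mae_to_mean_ratio(1.0, 0.0)


class TestFitAndEvaluate:
    def test_linear_realizable_function(self):
        bundle = _bundle(n=50, seed=1)
        target_future = 3.0 * bundle.blocks["covid"]["covid__a"]
        # construct a target whose day-(t+1) value is linear in day-t features
        target = pd.Series(
            np.concatenate([[0.0], target_future.to_numpy()[:-1]]),
            index=bundle.calendar,
        )
        ds = ophs.build_lagged_dataset(bundle, target, horizon=1)
        row, results = ophs.fit_and_evaluate(ds, "lr", seed=0)
        assert results.mae < 1e-8

    def test_constant_target_rf(self):
        bundle = _bundle(n=40, seed=2)
        target = pd.Series(np.full(40, 7.0), index=bundle.calendar)
        ds = ophs.build_lagged_dataset(bundle, target, horizon=1)
        with pytest.warns(UserWarning, match="Pearson"):
            row, results = ophs.fit_and_evaluate(
                ds, "rf", seed=0, config=ophs.ModelConfig(rf_n_estimators=20)
            )
        assert results.mae == 0.0
        assert np.isnan(results.pearson_r)

    def test_unknown_algorithm(self, bundle_small, demand_small):
        ds = ophs.build_lagged_dataset(
            bundle_small, demand_small.primary.astype(float), horizon=1
        )
        with pytest.raises(ValueError, match="unknown algorithm"):
            ophs.DemandModel(ds, algorithm="xgb")

    def test_rf_beats_mean_baseline(self, bundle_small, demand_small):
        ds = ophs.build_lagged_dataset(
            bundle_small, demand_small.primary.astype(float), horizon=3
        )
        _, results = ophs.fit_and_evaluate(
            ds, "rf", seed=0, config=ophs.ModelConfig(rf_n_estimators=100)
        )
        assert results.mae < ophs.mean_baseline_mae(ds)

    @pytest.mark.parametrize("algorithm", ["ridge", "lasso", "svr"])
    def test_linear_family_runs(self, algorithm, bundle_small, demand_small):
        ds = ophs.build_lagged_dataset(
            bundle_small, demand_small.primary.astype(float), horizon=1
        )
        row, results = ophs.fit_and_evaluate(ds, algorithm, seed=0)
        assert results.mae >= 0
        assert abs(results.pearson_r) <= 1

    def test_summary_mentions_scores(self, rf_results_p4):
        text = rf_results_p4.summary()
        assert "MAE" in text and "Pearson" in text and "rf" in text

    def test_blocked_split_and_causal_mode(self, bundle_small, demand_small):
        model = ophs.DemandModel.from_bundle(
            bundle_small,
            demand_small.primary.astype(float),
            horizon=3,
            algorithm="ridge",
            config=ophs.ModelConfig(temporal_mode="causal"),
        )
        results = model.fit(split="blocked", seed=0)
        assert np.isfinite(results.mae)


class TestCompareFeatureSets:
    def test_report_enumerates_all_combinations(self, bundle_small, demand_small):
        horizons = (1, 3)
        report = ophs.compare_feature_sets(
            bundle_small,
            demand_small.primary.astype(float),
            horizons=horizons,
            algorithm="ridge",
            seed=0,
        )
        # two blocks -> 3 non-empty combinations, plus one baseline row each
        assert len(report) == (3 + 1) * len(horizons)
        assert (report.groupby("horizon")["optimal"].sum() == 1).all()

    def test_optimal_not_worse_than_full_combination(self, bundle_small, demand_small):
        report = ophs.compare_feature_sets(
            bundle_small,
            demand_small.primary.astype(float),
            horizons=(3,),
            algorithm="ridge",
            seed=0,
        )
        fitted = report[report["algorithm"] == "ridge"]
        best = fitted.loc[fitted["optimal"], "mae"].iloc[0]
        full = fitted.loc[fitted["blocks"] == "temporal+covid", "mae"]
        if full.empty:
            full = fitted.loc[fitted["blocks"] == "covid+temporal", "mae"]
        assert best <= full.iloc[0] + 1e-12

    def test_informative_block_dominates_noise(self):
        rng = np.random.default_rng(5)
        n = 80
        index = pd.date_range("2020-01-31", periods=n, freq="D", name="date")
        signal = pd.DataFrame({"s": rng.normal(size=n)}, index=index)
        noise = pd.DataFrame(
            rng.normal(size=(n, 3)), index=index, columns=["n1", "n2", "n3"]
        )
        target = pd.Series(
            np.concatenate([[0.0], 5.0 * signal["s"].to_numpy()[:-1]]),
            index=index,
        )
        bundle = ophs.FeatureBundle(blocks={"temporal": signal, "covid": noise})
        report = ophs.compare_feature_sets(
            bundle, target, horizons=(1,), algorithm="ridge", seed=0,
            include_baseline=False,
        )
        by_blocks = report.set_index("blocks")["mae"]
        assert by_blocks["temporal"] < by_blocks["covid"]
        # adding the noise block cannot improve on the informative block much
        combo = [b for b in by_blocks.index if "+" in b][0]
        assert by_blocks[combo] < by_blocks["covid"]
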