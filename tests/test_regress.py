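"""OLS reporting, VIF screening and hierarchical partitioning."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from statsmodels.stats.outliers_influence import variance_inflation_factor

from lakesize import (
    HierarchicalPartitioner,
    RunConfig,
    build_predictor_table,
    hierarchical_partition,
    ols_fit,
    run_model_battery,
    vif,
)


def _r2(X, y, subset):
    design = np.column_stack([np.ones(len(y)), X[:, subset]]) if subset else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return 1.0 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()


def brute_force_partition(X, y):
    """Average R² gain of each predictor over all k! entry orders."""
    k = X.shape[1]
    gains = np.zeros(k)
    orders = list(permutations(range(k)))
    for order in orders:
        entered = []
        for j in order:
            before = _r2(X, y, tuple(entered))
            entered.append(j)
            gains[j] += _r2(X, y, tuple(entered)) - before
    return gains / len(orders)


class TestOls:
    def test_exact_line(self):
        fit = ols_fit(pd.DataFrame({"x": [0.0, 1.0, 2.0]}), [1.0, 3.0, 5.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_response(self):
        fit = ols_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [2.0, 2.0, 2.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_points(self):
        # Sxy = 3, Sxx = Syy = 5 -> slope .6, intercept 1, R² = .36
        fit = ols_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), [2.0, 1.0, 4.0, 3.0])
        assert fit.slope == pytest.approx(0.6)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(0.36)

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            fit = ols_fit(pd.DataFrame({"x": x}), y)
            sxx = ((x - x.mean()) ** 2).sum()
            slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        X["b"] = 2 * X["a"]
        X["c"] = [0.1, 0.9, 0.3, 0.7, 0.2]
        with pytest.raises(np.linalg.LinAlgError, match="'a'.*'b'|collinear"):
            ols_fit(X, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_adjusted_r2_can_be_negative(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        y = rng.normal(size=8)
        fit = ols_fit(X, y)
        assert fit.r2_adj == pytest.approx(
            1 - (1 - fit.r2) * (fit.n - 1) / (fit.n - 3 - 1)
        )


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, 1.0, -1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]})
        assert vif(X).tolist() == pytest.approx([1.0, 1.0])

    def test_duplicated_predictor_is_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        X["b"] = X["a"]
        X["c"] = [0.3, 0.1, 0.4, 0.1]
        report = vif(X)
        assert np.isinf(report["a"]) and np.isinf(report["b"])

    def test_auxiliary_regression_identity_and_statsmodels_agreement(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=40)
        X = pd.DataFrame(
            {
                "a": base + rng.normal(size=40),
                "b": base + rng.normal(size=40),
                "c": rng.normal(size=40),
            }
        )
        ours = vif(X)
        design = np.column_stack([np.ones(40), X.to_numpy()])
        for j, name in enumerate(X.columns):
            sm_vif = variance_inflation_factor(design, j + 1)
            assert ours[name] == pytest.approx(sm_vif, rel=1e-8)
            assert ours[name] >= 1.0


class TestHierarchicalPartition:
    def test_single_predictor_independent_equals_r2(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=15)})
        y = 0.5 * X["a"].to_numpy() + rng.normal(size=15)
        part = hierarchical_partition(X, y)
        assert part.independent["a"] == pytest.approx(part.r2_full, abs=1e-12)

    def test_orthogonal_predictors_have_zero_joint(self):
        X = pd.DataFrame(
            {"a": [1.0, 1.0, -1.0, -1.0, 0.0], "b": [1.0, -1.0, 1.0, -1.0, 0.0]}
        )
        y = np.array([2.0, 0.5, -0.5, -2.0, 0.3])
        part = hierarchical_partition(X, y)
        marg_a = _r2(X.to_numpy(), y, (0,))
        marg_b = _r2(X.to_numpy(), y, (1,))
        assert part.independent["a"] == pytest.approx(marg_a, abs=1e-10)
        assert part.independent["b"] == pytest.approx(marg_b, abs=1e-10)
        assert part.joint.abs().max() < 1e-10

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_equals_brute_force_over_orderings(self, k):
        rng = np.random.default_rng(k)
        X = rng.normal(size=(20, k))
        y = X @ rng.normal(size=k) + rng.normal(size=20)
        part = hierarchical_partition(pd.DataFrame(X, columns=[f"x{i}" for i in range(k)]), y)
        expected = brute_force_partition(X, y)
        np.testing.assert_allclose(part.independent.to_numpy(), expected, atol=1e-10)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_partition_identity_and_percentages(self, k):
        rng = np.random.default_rng(100 + k)
        X = rng.normal(size=(25, k))
        y = X @ rng.normal(size=k) + rng.normal(size=25)
        part = hierarchical_partition(pd.DataFrame(X), y)
        # independent effects alone partition the full model's R²
        assert part.independent.sum() == pytest.approx(part.r2_full, abs=1e-10)
        # per predictor, independent + joint reconstruct the marginal R²
        for j, name in enumerate(part.independent.index):
            marginal = _r2(X, y, (j,))
            assert part.independent[name] + part.joint[name] == pytest.approx(
                marginal, abs=1e-10
            )
        assert part.independent_pct.sum() == pytest.approx(100.0, abs=0.2)

    def test_estimator_api(self):
        est = HierarchicalPartitioner(max_predictors=8)
        assert clone(est).get_params()["max_predictors"] == 8
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        fitted = est.fit(X, rng.normal(size=15))
        assert fitted.n_features_in_ == 2
        assert list(fitted.feature_names_in_) == ["a", "b"]

    def test_too_many_predictors_guarded(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 13)))
        with pytest.raises(ValueError, match="2\\^k"):
            hierarchical_partition(X, rng.normal(size=40))


class TestBattery:
    def test_predictor_table_transforms(self, synthetic_dataset, synthetic_results):
        table = synthetic_results.predictors
        lakes = synthetic_dataset.lakes.set_index("lake_id")
        np.testing.assert_allclose(
            table["log10_area"], np.log10(lakes["area"].loc[table.index])
        )
        np.testing.assert_allclose(
            table["pct_endemism"], lakes["pct_endemism"].loc[table.index]
        )

    def test_battery_shape_and_blocks(self, synthetic_results):
        battery = synthetic_results.battery
        assert len(battery) == 4 * 7
        assert set(battery["size_measure"]) == {"s_range", "s_max", "s_min", "s_mean"}
        for _, block in battery.groupby("size_measure"):
            assert len(block) == 7
            assert block["i_pct"].sum() == pytest.approx(100.0, abs=0.2)
            assert block["model_r2"].nunique() == 1

    def test_planted_outlier_exclusion_raises_area_r2(self, synthetic_dataset):
        """A huge lake with an artificially tiny fauna (the Caspian pattern)
        depresses the area regression; removing it restores the fit."""
        from lakesize.pipeline import run_analysis

        species = synthetic_dataset.species.copy()
        lakes = synthetic_dataset.lakes.copy()
        big = lakes["area"].idxmax()
        big_id = lakes.loc[big, "lake_id"]
        rows = species["lake_id"] == big_id
        # shrink that fauna's shells tenfold: an outlier against the trend
        species.loc[rows, ["height", "width"]] /= 10.0

        cfg = RunConfig(seed=0, caspian_lake_id=big_id)
        with_outlier = run_analysis(species, lakes, cfg, with_resampling=False)
        cfg_x = RunConfig(seed=0, exclude_caspian=True, caspian_lake_id=big_id)
        without = run_analysis(species, lakes, cfg_x, with_resampling=False)

        def area_r2(res, measure="s_max"):
            b = res.battery
            row = b[(b["size_measure"] == measure) & (b["variable"] == "log10_area")]
            return float(row["lr_r2"].iloc[0])

        assert area_r2(without) > area_r2(with_outlier)
        # the sensitivity table re-fits the same regressions without the lake
        sens = with_outlier.caspian_sensitivity
        assert set(sens["size_measure"]) == {"s_range", "s_max"}
        smax = sens[sens["size_measure"] == "s_max"]["r2"].iloc[0]
        assert smax == pytest.approx(area_r2(without), abs=1e-10)
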