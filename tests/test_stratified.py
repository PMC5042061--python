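"""Family-stratified, longevity, lake-age and clade-rank analyses."""

import numpy as np
import pandas as pd
import pytest

from lakesize import (
    RunConfig,
    clade_rank_trend,
    family_level_battery,
    horizon_faunas,
    lake_age_regressions,
    longevity_records,
    species_longevity_regression,
)
from lakesize.simulate import generate_lineage
from lakesize.stratified import family_subsets


def _species(rows, **extra):
    df = pd.DataFrame(
        rows, columns=["species_id", "lake_id", "family", "height", "width"]
    )
    df["endemic"] = False
    df["size_missing"] = False
    for k, v in extra.items():
        df[k] = v
    return df


def _make_family(family, lakes, per_lake=2, size=4.0):
    rows = []
    for lake in lakes:
        for i in range(per_lake):
            rows.append((f"{family}-{lake}-{i}", lake, family, size + i, size + i))
    return rows


class TestFamilyFilters:
    def test_family_in_five_lakes_is_excluded(self):
        rows = _make_family("F5", [f"L{i}" for i in range(5)]) + _make_family(
            "F6", [f"L{i}" for i in range(6)]
        )
        subsets = family_subsets(_species(rows), min_lakes=6)
        assert set(subsets) == {"F6"}

    def test_single_species_cells_dropped_before_lake_count(self):
        # F occurs in 6 lakes but only 5 cells have >= 2 species
        rows = _make_family("F", [f"L{i}" for i in range(5)], per_lake=2)
        rows += _make_family("F", ["L5"], per_lake=1)
        subsets = family_subsets(_species(rows), min_lakes=6)
        assert subsets == {}

    def test_filters_commute(self):
        rng = np.random.default_rng(8)
        rows = []
        for f in range(6):
            for lake in rng.choice(10, size=rng.integers(3, 9), replace=False):
                for i in range(rng.integers(1, 4)):
                    s = float(rng.uniform(1, 20))
                    rows.append((f"F{f}-L{lake}-{i}", f"L{lake}", f"F{f}", s, s))
        sp = _species(rows)
        # lake-first: drop 1-species cells inside each family, then count lakes
        direct = family_subsets(sp, min_lakes=4)
        # family-first: pre-restrict to families in >= 4 lakes ignoring cells,
        # then apply the cell filter; surviving sets must agree
        counts = sp.groupby(["family", "lake_id"]).size()
        fam_lakes = counts[counts >= 2].groupby("family").size()
        prefiltered = sp[sp["family"].isin(fam_lakes[fam_lakes >= 4].index)]
        swapped = family_subsets(prefiltered, min_lakes=4)
        assert set(direct) == set(swapped)
        for fam in direct:
            pd.testing.assert_frame_equal(
                direct[fam].reset_index(drop=True),
                swapped[fam].reset_index(drop=True),
            )

    def test_flat_family_has_zero_slopes(self):
        # F has the same size spectrum everywhere; G varies the lakes'
        # overall richness but is too sparse to enter the battery itself
        rows = _make_family("F", [f"L{i}" for i in range(7)], per_lake=3)
        for i in range(7):
            for j in range(i):
                rows.append((f"G-L{i}-{j}", f"L{i}", "G", 2.0 + j, 2.0 + j))
        lakes = pd.DataFrame(
            {"lake_id": [f"L{i}" for i in range(7)], "area": np.logspace(1, 4, 7)}
        )
        battery = family_level_battery(_species(rows), lakes, RunConfig())
        assert set(battery["family"]) == {"F"}
        assert battery["slope"].abs().max() < 1e-10


class TestLongevity:
    def test_subtraction_and_pooling(self):
        sp = _species(
            [("s1", "A", "F", 4.0, 4.0), ("s1", "B", "F", 4.0, 4.0)],
            first_age=[15.0, 14.5],
            last_age=[13.8, 14.0],
            age_uncertainty=[1.0, 1.0],
        )
        rec = longevity_records(sp)
        assert len(rec) == 1
        assert rec["longevity"].iloc[0] == pytest.approx(15.0 - 13.8)

    def test_single_locality_species_retained_at_zero(self):
        sp = _species(
            [("s1", "A", "F", 4.0, 4.0)], first_age=12.0, last_age=12.0,
            age_uncertainty=0.5,
        )
        rec = longevity_records(sp)
        assert rec["longevity"].iloc[0] == 0.0

    def test_uncertain_occurrences_excluded(self):
        sp = _species(
            [("s1", "A", "F", 4.0, 4.0), ("s2", "A", "F", 4.0, 4.0)],
            first_age=[12.0, 12.0],
            last_age=[10.0, 10.0],
            age_uncertainty=[5.0, 1.0],
        )
        rec = longevity_records(sp, max_age_uncertainty=3.0)
        assert rec["species_id"].tolist() == ["s2"]

    def test_order_invariance(self):
        sp = _species(
            [("s1", "A", "F", 4.0, 4.0), ("s1", "B", "F", 4.0, 4.0)],
            first_age=[15.0, 14.5],
            last_age=[13.8, 14.0],
            age_uncertainty=1.0,
        )
        rec1 = longevity_records(sp)
        rec2 = longevity_records(sp.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_null_regression_recovers_no_effect(self):
        """Sizes independent of longevity: R²_adj stays near zero."""
        rng = np.random.default_rng(60)
        rec = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(500)],
                "longevity": rng.exponential(1.5, 500),
                "S": 10 ** rng.normal(0.6, 0.4, 500),
            }
        )
        fit = species_longevity_regression(rec)
        assert abs(fit.r2_adj) < 0.02

    def test_degenerate_inputs(self):
        rec = pd.DataFrame(
            {"species_id": list("ab"), "longevity": [0.0, 0.0], "S": [2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            species_longevity_regression(rec, min_records=2)
        with pytest.raises(ValueError, match="at least"):
            species_longevity_regression(rec.iloc[:1], min_records=10)


class TestLakeAge:
    def _horizons(self, slope, noise_sd, rng, n_lakes=4, horizons=3):
        rows = []
        for lake in range(n_lakes):
            base = rng.uniform(8, 15)
            for h in range(horizons):
                lake_age = rng.uniform(0.2, 5.0)
                rows.append(
                    {
                        "lake_id": f"L{lake}",
                        "horizon": f"H{h}",
                        "horizon_age": base - lake_age,
                        "lake_age": lake_age,
                        "s_range": 1.0 + slope * lake_age + rng.normal(0, noise_sd),
                        "s_max": 1.2 + slope * lake_age + rng.normal(0, noise_sd),
                        "s_min": 0.3 + slope * lake_age + rng.normal(0, noise_sd),
                        "s_mean": 0.8 + slope * lake_age + rng.normal(0, noise_sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_summaries_give_zero_slope(self):
        h = self._horizons(0.0, 0.0, np.random.default_rng(0))
        fits = lake_age_regressions(h)
        assert fits["slope"].abs().max() < 1e-10

    def test_planted_trend_recovered_within_ci(self):
        rng = np.random.default_rng(21)
        h = self._horizons(0.25, 0.05, rng, n_lakes=8)
        fits = lake_age_regressions(h).set_index("size_measure")
        for m in ("s_range", "s_mean"):
            slope, se = fits.loc[m, "slope"], fits.loc[m, "se"]
            assert abs(slope - 0.25) < 3 * se

    def test_zero_trend_ci_covers_zero_at_nominal_rate(self):
        from scipy import stats as ss

        rng = np.random.default_rng(5)
        covered = 0
        n_reps = 200
        for _ in range(n_reps):
            h = self._horizons(0.0, 0.1, rng)
            fits = lake_age_regressions(h).set_index("size_measure")
            slope, se = fits.loc["s_mean", "slope"], fits.loc["s_mean", "se"]
            tcrit = ss.t.ppf(0.975, len(h) - 2)
            covered += abs(slope) <= tcrit * se
        assert 0.90 <= covered / n_reps <= 0.99

    def test_single_lake_warns(self):
        h = self._horizons(0.1, 0.02, np.random.default_rng(3), n_lakes=1, horizons=5)
        with pytest.warns(UserWarning, match="single lake"):
            lake_age_regressions(h)

    def test_horizon_faunas_from_species_table(self, synthetic_dataset):
        h = horizon_faunas(synthetic_dataset.species, synthetic_dataset.lakes)
        assert not h.empty
        assert (h["lake_age"] >= 0).all()
        merged = h.merge(
            synthetic_dataset.lakes[["lake_id", "duration"]], on="lake_id"
        )
        assert (merged["lake_age"] <= merged["duration"] + 1e-9).all()
        fits = lake_age_regressions(h)
        assert len(fits) == 4


class TestCladeRank:
    def test_exact_log_linear_trend(self):
        lineage = pd.DataFrame(
            {"clade_rank": [1, 2, 3, 4, 5], "S": 10 ** (0.5 + 0.2 * np.arange(1, 6))}
        )
        fit = clade_rank_trend(lineage)
        assert fit.slope == pytest.approx(0.2)
        assert fit.r2 == pytest.approx(1.0)

    def test_final_stage_decrease_keeps_positive_overall_slope(self):
        s = 10 ** np.array([0.5, 0.8, 1.1, 1.4, 1.2])
        fit = clade_rank_trend(pd.DataFrame({"clade_rank": [1, 2, 3, 4, 5], "S": s}))
        assert fit.slope > 0
        assert fit.r2 < 1.0

    def test_shuffled_sizes_rarely_significant(self):
        rng = np.random.default_rng(14)
        lineage = generate_lineage(20, slope=0.1, noise_sd=0.05, rng=rng)
        sizes = lineage["S"].to_numpy().copy()
        n_sig = 0
        for _ in range(200):
            rng.shuffle(sizes)
            fit = clade_rank_trend(
                pd.DataFrame({"clade_rank": lineage["clade_rank"], "S": sizes})
            )
            n_sig += fit.pvalues["clade_rank"] < 0.05
        assert n_sig / 200 <= 0.10

    def test_degenerate_ranks_rejected(self):
        with pytest.raises(ValueError):
            clade_rank_trend(pd.DataFrame({"clade_rank": [2, 2, 2], "S": [1, 2, 3]}))
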