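"""CCC/RMSE scoring, downsampling, the experiment harness and model ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saeval import (
    ModelSpec,
    build_gold_standard,
    ccc,
    downsample,
    rank_models,
    rmse,
    run_experiment,
    score_direct_baseline,
    us_2000_standard,
)
from saeval.validate import ValidationResult, best_spec

from oracles import ccc_two_formula


class TestCCC:
    def test_perfect_agreement_is_one(self):
        x = np.array([0.1, 0.2, 0.3])
        assert ccc(x, x) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2, 4; population variances 2/3, 8/3; covariance 4/3
        assert ccc([1, 2, 3], [2, 4, 6]) == pytest.approx(8 / 22)

    def test_location_shift_penalised_below_pearson(self):
        x = np.array([0.1, 0.4, 0.2, 0.9])
        assert ccc(x, x + 0.3) < 1.0
        assert np.corrcoef(x, x + 0.3)[0, 1] == pytest.approx(1.0)

    def test_equal_constant_vectors_undefined(self):
        with pytest.raises(ZeroDivisionError):
            ccc([0.5, 0.5], [0.5, 0.5])

    @given(seed=st.integers(0, 10_000), n=st.integers(3, 50))
    @settings(max_examples=50, deadline=None)
    def test_equals_pearson_times_bias_correction(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        expected, c_b = ccc_two_formula(x, y)
        assert c_b <= 1.0 + 1e-12
        assert ccc(x, y) == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        perm = rng.permutation(20)
        assert ccc(x[perm], y[perm]) == pytest.approx(ccc(x, y), abs=1e-12)
        assert rmse(x[perm], y[perm]) == pytest.approx(rmse(x, y), abs=1e-12)


class TestRMSE:
    def test_identical_vectors_give_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_example(self):
        assert rmse([0.0, 0.0], [0.1, -0.1]) == pytest.approx(0.1)

    def test_homogeneous_in_scale(self):
        x = np.array([0.1, 0.5, 0.3])
        y = np.array([0.2, 0.4, 0.1])
        assert rmse(3 * x, 3 * y) == pytest.approx(3 * rmse(x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


def _records_for(areas, years, n_per, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for area in areas:
        for year in years:
            for _ in range(n_per):
                rows.append(
                    [area, "female", "50-54", "white_nh", year,
                     int(rng.integers(0, 2)), 1.0]
                )
    return pd.DataFrame(
        rows,
        columns=["area_id", "sex", "age_group", "race_group",
                 "survey_year", "outcome", "weight"],
    )


class TestDownsample:
    def test_level_times_years_records_per_area(self):
        rec = _records_for(["A", "B"], range(1996, 2005), 40)
        ds = downsample(rec, 10, seed=1)
        per_area = ds.groupby("area_id", observed=True).size()
        assert (per_area == 90).all()  # 10 per county-year x 9 years

    def test_level_above_cell_size_uses_replacement(self):
        rec = _records_for(["A"], [2004], 5)
        ds = downsample(rec, 50, seed=1)
        assert len(ds) == 50
        assert ds.duplicated(keep=False).any()

    def test_seed_determinism(self):
        rec = _records_for(["A", "B"], [2003, 2004], 30)
        d1 = downsample(rec, 10, seed=5)
        d2 = downsample(rec, 10, seed=5)
        d3 = downsample(rec, 10, seed=6)
        pd.testing.assert_frame_equal(d1, d2)
        assert not d1.equals(d3)


class TestExperimentHarness:
    def test_cardinality_one_spec_one_level(self, small_world):
        records, truth, _ = small_world
        gold = build_gold_standard(
            records, ((2000, 2002), (2002, 2004)), 120, us_2000_standard()
        )
        specs = [ModelSpec("naive", include_race=False, year_effect="fixed")]
        result = run_experiment(
            records, gold, specs, levels=(20,), replicates=3, target_year=2004,
            seed=0, counties=truth.county_covariates, std=us_2000_standard(),
            graph=truth.graph, sexes=("female",),
        )
        # 3 replicate rows + 1 'all' row
        assert len(result.table) == 4
        assert (result.table["n_areas"] == len(gold.areas("female"))).all()

    def test_baseline_rows_labelled_direct(self, small_world):
        records, truth, _ = small_world
        gold = build_gold_standard(
            records, ((2000, 2002), (2002, 2004)), 120, us_2000_standard()
        )
        base = score_direct_baseline(
            records, gold, levels=(20,), replicates=2, target_year=2004,
            seed=0, std=us_2000_standard(), sexes=("female",),
        )
        assert (base.table["spec"] == "direct").all()
        assert len(base.table) == 3


class TestRanking:
    def _result(self, rows):
        cols = ["sex", "family", "include_race", "year_effect", "spec", "level",
                "replicate", "ccc", "rmse", "n_areas", "converged"]
        return ValidationResult(pd.DataFrame(rows, columns=cols))

    def test_single_spec_wins(self):
        res = self._result(
            [["female", "naive", False, "fixed", "naive-norace-fixedyear",
              10, 1, 0.5, 0.02, 30, True]]
        )
        ranking = rank_models(res)
        assert best_spec(ranking, "female").family == "naive"

    def test_rmse_breaks_ccc_ties(self):
        rows = [
            ["female", "naive", False, "fixed", "naive-norace-fixedyear",
             10, 1, 0.5, 0.05, 30, True],
            ["female", "covariate", False, "fixed", "covariate-norace-fixedyear",
             10, 1, 0.5, 0.02, 30, True],
        ]
        ranking = rank_models(self._result(rows))
        assert best_spec(ranking, "female").family == "covariate"

    def test_nonconverged_rows_excluded_but_counted(self):
        rows = [
            ["female", "naive", False, "fixed", "naive-norace-fixedyear",
             10, 1, 0.9, 0.01, 30, True],
            ["female", "naive", False, "fixed", "naive-norace-fixedyear",
             10, 2, np.nan, np.nan, 30, False],
            ["female", "covariate", False, "fixed", "covariate-norace-fixedyear",
             10, 1, 0.5, 0.02, 30, True],
        ]
        ranking = rank_models(self._result(rows))
        assert best_spec(ranking, "female").family == "naive"
        naive_row = ranking[ranking["family"] == "naive"].iloc[0]
        assert naive_row["n_failed"] == 1

    def test_all_failed_rejected(self):
        rows = [
            ["female", "naive", False, "fixed", "naive-norace-fixedyear",
             10, 1, np.nan, np.nan, 30, False],
        ]
        from saeval import EstimationError

        with pytest.raises(EstimationError):
            rank_models(self._result(rows))

    def test_levels_weighted_equally_not_by_replicates(self):
        # spec X: great at a level with many replicates, poor at the other;
        # spec Y: steady. Equal level weighting must rank Y first.
        rows = []
        for rep in range(1, 10):
            rows.append(["female", "naive", False, "fixed", "X", 100, rep,
                         0.9, 0.01, 30, True])
        rows.append(["female", "naive", False, "fixed", "X", 10, 1,
                     0.1, 0.10, 30, True])
        rows.append(["female", "covariate", False, "fixed", "Y", 100, 1,
                     0.6, 0.02, 30, True])
        rows.append(["female", "covariate", False, "fixed", "Y", 10, 1,
                     0.6, 0.02, 30, True])
        ranking = rank_models(self._result(rows))
        assert ranking.iloc[0]["spec"] == "Y"  # mean over levels 0.6 vs 0.5
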