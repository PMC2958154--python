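"""The Laplace GLMM engine: oracles, limits, prediction arithmetic, errors."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from saeval import (
    CountyTable,
    EstimationError,
    ModelSpec,
    SeparationError,
    SyntheticConfig,
    fit,
    predict_linear,
    simulate_dataset,
)
from saeval.glmm import _build_design
from saeval.schema import DEFAULT_SCHEMA

from conftest import make_hand_model
from oracles import agq_loglik, maximize_agq


def _sim(seed, sigma_delta, n_counties=30, n_per=120, gamma=(), **kw):
    cov = dict(
        gamma=gamma or (0.0,),
        covariate_names=("x",),
        covariate_means=(0.0,),
        covariate_sds=(1.0,),
    )
    cfg = SyntheticConfig(
        n_counties=n_counties,
        years=(2004,),
        mean_sample_per_county_year=n_per,
        sample_size_dispersion=50.0,
        alpha=-2.3,
        beta_age=(0.0,) * 9,
        beta_race=(0.0,) * 4,
        beta_year=(),
        sigma_delta=sigma_delta,
        spatial_mixing=0.0,
        covariate_risk_correlation=0.0,
        weight_cv=0.0,
        seed=seed,
        sexes=("female",),
        **cov,
        **kw,
    )
    return simulate_dataset(cfg)


class TestLaplaceAgainstQuadrature:
    def test_loglik_matches_51_node_agq_on_tiny_fixture(self, tiny_records):
        spec = ModelSpec("naive", include_race=False, year_effect="fixed", sex="female")
        model = fit(tiny_records, spec)
        X, _, _ = _build_design(tiny_records, spec, None, None, DEFAULT_SCHEMA)
        a = pd.Categorical(tiny_records["area_id"]).codes
        y = tiny_records["outcome"].to_numpy(float)
        # drop all-zero contrast columns so the oracle optimises a minimal design
        keep = np.abs(X).sum(axis=0) > 0
        agq_max, _ = maximize_agq(X[:, keep], y, a)
        assert model.loglik == pytest.approx(agq_max, abs=1e-2)

    def test_laplace_loglik_evaluated_at_own_optimum_close_to_agq_value(
        self, tiny_records
    ):
        spec = ModelSpec("naive", include_race=False, year_effect="fixed", sex="female")
        model = fit(tiny_records, spec)
        X, _, _ = _build_design(tiny_records, spec, None, None, DEFAULT_SCHEMA)
        keep = np.abs(X).sum(axis=0) > 0
        a = pd.Categorical(tiny_records["area_id"]).codes
        y = tiny_records["outcome"].to_numpy(float)
        beta_kept = model.fixed_effects.to_numpy()[keep]
        theta = np.concatenate(([np.log(model.sigma_delta)], beta_kept))
        assert model.loglik == pytest.approx(
            agq_loglik(theta, X[:, keep], y, a), abs=1e-2
        )


class TestDegenerateVariance:
    def test_zero_variance_data_reduces_to_plain_logistic(self):
        # small-scale version; the full-scale degenerate-limit check with the
        # 0.02 variance threshold lives in the acceptance suite
        records, truth = _sim(seed=101, sigma_delta=0.0, n_counties=40, n_per=300)
        spec = ModelSpec("covariate", include_race=False, year_effect="fixed",
                         sex="female")
        model = fit(records, spec, counties=truth.county_covariates)
        assert model.sigma_delta < 0.1
        X, _, _ = _build_design(
            records, spec, truth.county_covariates, None, DEFAULT_SCHEMA
        )
        glm = sm.GLM(
            records["outcome"].to_numpy(), X, family=sm.families.Binomial()
        ).fit()
        se = glm.bse
        keep = np.abs(X).sum(axis=0) > 0
        diff = np.abs(model.fixed_effects.to_numpy() - glm.params)[keep]
        assert (diff <= 3 * se[keep]).all()


class TestPredictLinear:
    def test_reference_cell_gives_intercept_exactly(self):
        model = make_hand_model(
            {"intercept": -2.0, "age:55-59": 0.4, "race:black_nh": 0.7},
            {"A": 0.0, "B": 0.3},
        )
        eta = predict_linear(model, "A", "50-54", "white_nh", 2000)
        assert eta == -2.0

    def test_hand_summed_linear_predictor(self):
        idx = ["A", "B"]
        comp = pd.DataFrame(
            np.full((2, 50), 0.02),
            index=idx,
            columns=pd.MultiIndex.from_product(
                [DEFAULT_SCHEMA.age_groups, DEFAULT_SCHEMA.race_groups],
                names=["age_group", "race_group"],
            ),
        )
        counties = CountyTable(
            Z=pd.DataFrame({"poverty_rate": [12.0, 20.0]}, index=idx),
            composition=comp,
        )
        model = make_hand_model(
            {
                "intercept": -2.1,
                "age:70-74": 0.9,
                "race:hispanic": 0.55,
                "year:2003": 0.16,
                "z:poverty_rate": 0.01,
                "spatial": 1.58,
            },
            {"A": 0.12, "B": -0.05},
            spec=ModelSpec("full", include_race=True, year_effect="fixed"),
            ref_year=2000,
            train_years=(2000, 2003),
        )
        spat = {"A": 0.08, "B": 0.0}
        eta = predict_linear(
            model, "A", "70-74", "hispanic", 2003, counties, spat
        )
        expected = -2.1 + 0.9 + 0.55 + 0.16 + 0.01 * 12.0 + 1.58 * 0.08 + 0.12
        assert eta == pytest.approx(expected, abs=1e-12)

    def test_unseen_area_differs_by_exactly_the_ranef(self):
        model = make_hand_model(
            {"intercept": -1.5, "age:55-59": 0.2}, {"A": 0.25}
        )
        seen = predict_linear(model, "A", "55-59", "white_nh", 2000)
        unseen = predict_linear(model, "ZZ", "55-59", "white_nh", 2000)
        assert seen - unseen == pytest.approx(0.25)

    def test_unknown_demographic_level_rejected(self):
        model = make_hand_model({"intercept": -1.5}, {"A": 0.0})
        with pytest.raises(Exception, match="age group"):
            predict_linear(model, "A", "20-24", "white_nh", 2000)

    def test_fixed_year_outside_training_rejected(self):
        model = make_hand_model(
            {"intercept": -1.5, "year:2003": 0.1}, {"A": 0.0},
            ref_year=2000, train_years=(2000, 2003),
        )
        with pytest.raises(EstimationError, match="year"):
            predict_linear(model, "A", "50-54", "white_nh", 2007)


class TestFitProperties:
    def test_shift_equivariance_of_covariate_centering(self):
        records, truth = _sim(
            seed=5, sigma_delta=0.2, gamma=(0.5,), n_counties=25, n_per=80
        )
        counties = truth.county_covariates
        spec = ModelSpec("covariate", include_race=False, year_effect="fixed",
                         sex="female")
        m1 = fit(records, spec, counties=counties, compute_cov=False)
        shifted = CountyTable(
            Z=counties.Z + 10.0,
            composition=counties.composition,
            population=counties.population,
        )
        m2 = fit(records, spec, counties=shifted, compute_cov=False)
        g1 = m1.fixed_effects["z:x"]
        assert m2.fixed_effects["z:x"] == pytest.approx(g1, abs=1e-4)
        assert m2.fixed_effects["intercept"] == pytest.approx(
            m1.fixed_effects["intercept"] - 10.0 * g1, abs=1e-4
        )

    def test_ranef_shrinks_more_for_smaller_areas(self):
        # two areas with identical empirical prevalence 0.4 vs overall 0.1,
        # one with 10x the sample size
        rows = []
        for k in range(500):
            rows.append(["BIG", 1 if k % 5 < 2 else 0])
        for k in range(50):
            rows.append(["SMALL", 1 if k % 5 < 2 else 0])
        for k in range(2000):
            rows.append(["REF1" if k % 2 else "REF2", 1 if k % 10 == 0 else 0])
        df = pd.DataFrame(rows, columns=["area_id", "outcome"])
        df["sex"] = "female"
        df["age_group"] = "50-54"
        df["race_group"] = "white_nh"
        df["survey_year"] = 2004
        df["weight"] = 1.0
        model = fit(
            df, ModelSpec("naive", include_race=False, year_effect="fixed"),
            compute_cov=False,
        )
        assert 0 < model.ranef_mean["SMALL"] < model.ranef_mean["BIG"]

    def test_random_year_fit_runs_and_reports_slope_variance(self):
        cfg = SyntheticConfig(
            n_counties=16, years=(2000, 2002, 2004),
            mean_sample_per_county_year=60, sample_size_dispersion=5.0,
            sigma_delta=0.2, seed=3, sexes=("female",),
            beta_year=(0.05, 0.10),
        )
        records, truth = simulate_dataset(cfg)
        spec = ModelSpec("naive", include_race=False, year_effect="random",
                         sex="female")
        model = fit(records, spec, compute_cov=False)
        assert model.converged
        assert model.sigma_year is not None and model.sigma_year >= 0
        assert "year_trend" in model.fixed_effects.index
        assert model.ranef_year_mean is not None

    def test_single_area_rejected(self):
        df = pd.DataFrame(
            {
                "area_id": ["A"] * 20,
                "sex": "female",
                "age_group": "50-54",
                "race_group": "white_nh",
                "survey_year": 2004,
                "outcome": [0, 1] * 10,
                "weight": 1.0,
            }
        )
        with pytest.raises(EstimationError, match="single area"):
            fit(df, ModelSpec("naive", include_race=False))

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame(
            {
                "area_id": ["A"] * 10 + ["B"] * 10,
                "sex": "female",
                "age_group": "50-54",
                "race_group": "white_nh",
                "survey_year": 2004,
                "outcome": 1,
                "weight": 1.0,
            }
        )
        with pytest.raises(EstimationError, match="constant"):
            fit(df, ModelSpec("naive", include_race=False))

    def test_complete_separation_names_term(self):
        rng = np.random.default_rng(4)
        n = 400
        age = rng.choice(["50-54", "75+"], size=n)
        df = pd.DataFrame(
            {
                "area_id": rng.choice(["A", "B", "C"], size=n),
                "sex": "female",
                "age_group": age,
                "race_group": "white_nh",
                "survey_year": 2004,
                "outcome": (age == "75+").astype(int),
                "weight": 1.0,
            }
        )
        with pytest.raises(SeparationError, match="age"):
            fit(df, ModelSpec("naive", include_race=False))
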