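import numpy as np
import pandas as pd
import pytest

from saeval import SyntheticConfig, simulate_dataset
from saeval.glmm import FittedModel, ModelSpec, _DesignInfo
from saeval.schema import DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def small_world():
    """A small multi-year synthetic dataset with known truth (shared, read-only)."""
    cfg = SyntheticConfig(
        n_counties=36,
        years=(2000, 2001, 2002, 2003, 2004),
        mean_sample_per_county_year=40,
        sample_size_dispersion=2.0,
        sigma_delta=0.2,
        spatial_mixing=0.4,
        weight_cv=0.5,
        seed=11,
    )
    records, truth = simulate_dataset(cfg)
    return records, truth, cfg


@pytest.fixture()
def tiny_records():
    """Deterministic 3-area x 30-record fixture for likelihood oracles."""
    rng = np.random.default_rng(12345)
    areas = np.repeat(["A1", "A2", "A3"], 10)
    ages = rng.choice(["50-54", "55-59"], size=30)
    delta = {"A1": -1.0, "A2": 0.2, "A3": 1.1}
    eta = -0.6 + 0.9 * (ages == "55-59") + np.array([delta[a] for a in areas])
    y = (rng.random(30) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {
            "area_id": areas,
            "sex": "female",
            "age_group": ages,
            "race_group": "white_nh",
            "survey_year": 2004,
            "outcome": y,
            "weight": 1.0,
        }
    )


def make_hand_model(
    coefs: dict[str, float],
    ranef: dict[str, float],
    spec: ModelSpec | None = None,
    ref_year: int = 2000,
    train_years: tuple[int, ...] = (2000,),
    ranef_var: float = 0.0,
) -> FittedModel:
    """A FittedModel with hand-set coefficients, for arithmetic oracles."""
    if spec is None:
        spec = ModelSpec("naive", include_race=True, year_effect="fixed")
    names = list(coefs)
    info = _DesignInfo(
        names=names,
        ref_year=ref_year,
        train_years=train_years,
        year_center=float(np.mean(train_years)),
        z_names=[n for n in names if n.startswith("z:")],
        include_race=spec.include_race,
        year_effect="fixed",
        schema=DEFAULT_SCHEMA,
    )
    areas = list(ranef)
    return FittedModel(
        spec=spec,
        fixed_effects=pd.Series(coefs),
        fixed_cov=pd.DataFrame(
            np.zeros((len(names), len(names))), index=names, columns=names
        ),
        sigma_delta=0.1,
        ranef_mean=pd.Series(ranef, dtype=float),
        ranef_var=pd.Series(ranef_var, index=areas, dtype=float),
        loglik=0.0,
        converged=True,
        n_used=0,
        design=info,
    )
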