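"""Demographic aggregation of model predictions and empirical credibility regions.

A fitted model gives a probability for one person in each age x race cell of
an area; those are combined into an area prevalence with weights = standard
age distribution x the area's race composition (age-only when the model
excludes individual race).  Uncertainty comes from re-drawing the model
parameters — fixed effects from their asymptotic normal, random intercepts
from their conditional normals, drawn independently — re-aggregating each
draw, and reading off empirical percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .direct import StandardPopulation
from .glmm import FittedModel, cell_design
from .rng import substream
from .schema import CountyTable, SchemaError

__all__ = ["PrevalenceEstimate", "aggregate_to_prevalence", "credibility_region"]


@dataclass(frozen=True)
class PrevalenceEstimate:
    area_id: str
    sex: str | None
    year: int
    point: float
    lo95: float
    hi95: float
    n_pooled: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo95 <= self.hi95 <= 1.0):
            raise ValueError("interval bounds must satisfy 0 <= lo <= hi <= 1")


def _cell_weights(
    model: FittedModel,
    area: str,
    std: StandardPopulation,
    counties: CountyTable,
) -> np.ndarray:
    """Aggregation weights over age x race cells, renormalised to 1.

    Weights are the standard age distribution crossed with the area's race
    marginal; when the model excludes individual race the race dimension is
    still averaged over (all race cells share a probability, so the result
    equals age-only standardisation).
    """
    schema = model.design.schema
    if area not in counties.Z.index:
        raise SchemaError(f"no composition data for area {area!r}")
    std_w = std.weights.reindex(schema.age_groups)
    if std_w.isna().any():
        raise SchemaError("standard population does not cover the age schema")
    race_marg = counties.race_marginal(area).reindex(schema.race_groups).to_numpy()
    w = std_w.to_numpy()[:, None] * race_marg[None, :]
    w = w.reshape(-1)
    total = w.sum()
    if total <= 0:
        raise SchemaError(f"degenerate composition for area {area!r}")
    return w / total


def aggregate_to_prevalence(
    model: FittedModel,
    area: str,
    year: int,
    std: StandardPopulation,
    counties: CountyTable,
    spatial_covariate: Mapping[str, float] | None = None,
) -> float:
    """Age (x race-composition) standardised prevalence for one area and year."""
    rows, _ = cell_design(model, area, year, counties, spatial_covariate)
    eta = rows @ model.fixed_effects.to_numpy() + float(model.ranef_mean.get(area, 0.0))
    if model.ranef_year_mean is not None:
        eta = eta + float(model.ranef_year_mean.get(area, 0.0)) * (
            year - model.design.year_center
        )
    w = _cell_weights(model, area, std, counties)
    return float(w @ expit(eta))


def _percentile_bounds(draws: np.ndarray) -> tuple[float, float]:
    """Empirical 2.5%/97.5% bounds via order statistics at ceil(q * n)."""
    n = len(draws)
    s = np.sort(draws)
    lo_rank = int(np.ceil(0.025 * n))
    hi_rank = int(np.ceil(0.975 * n))
    return float(s[lo_rank - 1]), float(s[hi_rank - 1])


def credibility_region(
    model: FittedModel,
    area: str,
    year: int,
    std: StandardPopulation,
    counties: CountyTable,
    spatial_covariate: Mapping[str, float] | None = None,
    draws: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical 95% credibility bounds for an area's standardised prevalence.

    Each draw samples the fixed effects from N(beta_hat, cov) and the area's
    random effect from its conditional normal (independently of the fixed
    effects; sigma_delta itself is held fixed), aggregates to a prevalence,
    and the empirical 2.5th/97.5th percentiles over draws are returned.
    """
    if draws < 40:
        raise ValueError("need at least 40 draws to resolve 2.5% percentiles")
    if not model.converged:
        raise ValueError("credibility region requested from a non-converged fit")
    rng = substream(seed, "credibility", area, int(year))

    rows, _ = cell_design(model, area, year, counties, spatial_covariate)
    beta = model.fixed_effects.to_numpy()
    cov = model.fixed_cov.to_numpy()
    if not np.isfinite(cov).all():
        raise ValueError("fixed-effect covariance is not available for this fit")
    # guard tiny negative eigenvalues from the numerical Hessian
    evals, evecs = np.linalg.eigh(cov)
    cov_psd = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    b_draws = rng.multivariate_normal(beta, cov_psd, size=draws, method="eigh")

    mu_d = float(model.ranef_mean.get(area, 0.0))
    var_d = float(model.ranef_var.get(area, model.sigma_delta**2))
    eta = rows @ b_draws.T  # cells x draws
    if model.ranef_year_mean is not None and area in model.ranef_mean.index:
        t = year - model.design.year_center
        mu = np.array([mu_d, float(model.ranef_year_mean[area])])
        c01 = float(model.ranef_cross_cov[area]) if model.ranef_cross_cov is not None else 0.0
        cov2 = np.array(
            [[var_d, c01], [c01, float(model.ranef_year_var[area])]]
        )
        uv = rng.multivariate_normal(mu, cov2, size=draws, method="eigh")
        eta = eta + uv[:, 0] + uv[:, 1] * t
    else:
        d_draws = rng.normal(mu_d, np.sqrt(max(var_d, 0.0)), size=draws)
        eta = eta + d_draws
    w = _cell_weights(model, area, std, counties)
    prev = w @ expit(eta)
    return _percentile_bounds(prev)


def estimate_with_interval(
    model: FittedModel,
    area: str,
    year: int,
    std: StandardPopulation,
    counties: CountyTable,
    spatial_covariate: Mapping[str, float] | None = None,
    draws: int = 1000,
    seed: int = 0,
    n_pooled: int = 0,
) -> PrevalenceEstimate:
    """Point estimate plus credibility bounds, as one record."""
    point = aggregate_to_prevalence(model, area, year, std, counties, spatial_covariate)
    lo, hi = credibility_region(
        model, area, year, std, counties, spatial_covariate, draws=draws, seed=seed
    )
    return PrevalenceEstimate(
        area_id=area,
        sex=model.spec.sex,
        year=year,
        point=point,
        lo95=lo,
        hi95=hi,
        n_pooled=n_pooled,
    )
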