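"""Synthetic multi-year, multi-county survey microdata with known truth.

The generator emulates the statistical structure of a large telephone-survey
dataset pooled over years and counties: highly skewed county sample sizes
(most counties small, a few very large, and persistently so across years),
county random intercepts with first-order neighbor correlation, county-level
covariates correlated with risk, strong age and race effects on the log-odds
scale, a gentle upward year trend, and noisy mean-1 poststratification
weights.  Every quantity the estimation pipeline tries to recover is stored
in :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .direct import StandardPopulation, us_2000_standard
from .rng import substream
from .schema import (
    AdjacencyGraph,
    CountyTable,
    DemographicSchema,
    DEFAULT_SCHEMA,
    SEXES,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_county_graph",
    "simulate_truth",
    "simulate_survey",
    "simulate_dataset",
]

#: National race mix used as the Dirichlet centre for county compositions.
_NATIONAL_RACE = {
    "white_nh": 0.755, "black_nh": 0.085, "aian_nh": 0.010,
    "hispanic": 0.100, "asian_other_nh": 0.050,
}

# Generator defaults for the demographic fixed effects are the magnitudes a
# large US risk-factor survey exhibits for an age-graded chronic condition:
# risk rises steeply with age (reference band 50-54) and is elevated in all
# non-White groups.
_DEFAULT_BETA_AGE = (-1.77, -1.25, -0.81, -0.40, 0.39, 0.66, 0.81, 0.91, 0.80)
_DEFAULT_BETA_RACE = (0.69, 0.65, 0.56, 0.41)  # black, aian, hispanic, asian/other

_DEFAULT_COV_NAMES = ("share_black", "share_hispanic", "share_bachelors", "poverty_rate")
_DEFAULT_COV_MEANS = (0.085, 0.10, 0.10, 13.3)
_DEFAULT_COV_SDS = (0.08, 0.10, 0.04, 5.5)
_DEFAULT_GAMMA = (0.7, 0.4, -2.5, 0.025)
#: Covariates read off the simulated race composition instead of drawn.
_COMPOSITION_COVARIATES = {"share_black": "black_nh", "share_hispanic": "hispanic"}


@dataclass
class SyntheticConfig:
    """Generative counterpart of the prevalence model.

    The linear predictor for a respondent in county *i*, year *t* is
    ``alpha + beta_age + beta_race + beta_year[t] + (Z_i - mean(Z)) . gamma
    + delta_i`` on the log-odds scale, with ``delta_i`` a spatially mixed
    county intercept of marginal SD ``sigma_delta``.  Covariates enter
    centred at their configured means so ``alpha`` is the reference-cell
    log-odds in an average county.
    """

    n_counties: int = 400
    years: tuple[int, ...] = tuple(range(1996, 2005))
    mean_sample_per_county_year: float = 30.0
    sample_size_dispersion: float = 0.3  # negative-binomial shape; small = skewed
    alpha: float = -2.4
    beta_age: tuple[float, ...] = _DEFAULT_BETA_AGE
    beta_race: tuple[float, ...] = _DEFAULT_BETA_RACE
    beta_year: tuple[float, ...] | None = None  # default: +0.04/year trend
    gamma: tuple[float, ...] = _DEFAULT_GAMMA
    sigma_delta: float = 0.15
    spatial_mixing: float = 0.5
    covariate_risk_correlation: float = 0.5
    weight_cv: float = 0.5
    seed: int = 0
    covariate_names: tuple[str, ...] = _DEFAULT_COV_NAMES
    covariate_means: tuple[float, ...] = _DEFAULT_COV_MEANS
    covariate_sds: tuple[float, ...] = _DEFAULT_COV_SDS
    sexes: tuple[str, ...] = SEXES
    schema: DemographicSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise ValueError("n_counties must be positive")
        self.years = tuple(int(y) for y in self.years)
        if not self.years:
            raise ValueError("years must be non-empty")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if self.beta_year is None:
            self.beta_year = tuple(0.04 * k for k in range(1, len(self.years)))
        if len(self.beta_age) != len(self.schema.nonref_ages):
            raise ValueError(
                f"beta_age must have length {len(self.schema.nonref_ages)}"
            )
        if len(self.beta_race) != len(self.schema.nonref_races):
            raise ValueError(
                f"beta_race must have length {len(self.schema.nonref_races)}"
            )
        if len(self.beta_year) != len(self.years) - 1:
            raise ValueError("beta_year must have one entry per non-reference year")
        if not (len(self.gamma) == len(self.covariate_names)
                == len(self.covariate_means) == len(self.covariate_sds)):
            raise ValueError("gamma/covariate_names/means/sds lengths must agree")
        if self.sigma_delta < 0:
            raise ValueError("sigma_delta must be nonnegative")
        if not (0 <= self.spatial_mixing < 1):
            raise ValueError("spatial_mixing must be in [0, 1)")
        if not (-1 <= self.covariate_risk_correlation <= 1):
            raise ValueError("covariate_risk_correlation must be in [-1, 1]")
        if self.weight_cv < 0:
            raise ValueError("weight_cv must be nonnegative")
        if self.mean_sample_per_county_year <= 0 or self.sample_size_dispersion <= 0:
            raise ValueError("sample size mean and dispersion must be positive")
        bad = set(self.sexes) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sexes: {sorted(bad)}")

    def year_effect(self, year: int) -> float:
        """Fixed year effect (0 for the earliest year)."""
        idx = self.years.index(year)
        return 0.0 if idx == 0 else self.beta_year[idx - 1]


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic dataset."""

    county_intercepts: pd.Series  # delta_i, indexed by area_id
    county_covariates: CountyTable
    county_true_prevalence: pd.Series  # age/race-standardised, final year
    graph: AdjacencyGraph
    config: SyntheticConfig

    def __post_init__(self) -> None:
        areas = set(self.county_intercepts.index)
        if areas != self.graph.areas or areas != set(self.county_covariates.areas):
            raise ValueError("truth components cover different area sets")
        p = self.county_true_prevalence.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("true prevalence outside [0, 1]")


def _area_ids(n: int) -> list[str]:
    return [f"{i + 1:05d}" for i in range(n)]


def make_county_graph(n_counties: int, n_islands: int = 0, seed: int = 0) -> AdjacencyGraph:
    """Near-square planar grid contiguity with ``n_islands`` isolated areas.

    Areas are laid out row-major on a ``rows x cols`` grid with
    ``rows = floor(sqrt(n))``; contiguity is a shared grid edge.  Island
    areas (chosen at random under ``seed``) have their edges removed.
    """
    if n_counties < 1:
        raise ValueError("n_counties must be positive")
    if n_islands >= n_counties and n_counties > 1:
        raise ValueError("n_islands must be smaller than n_counties")
    ids = _area_ids(n_counties)
    rows = max(1, int(np.floor(np.sqrt(n_counties))))
    cols = int(np.ceil(n_counties / rows))
    neighbors: dict[str, set[str]] = {a: set() for a in ids}
    for k in range(n_counties):
        r, c = divmod(k, cols)
        right = k + 1
        if c + 1 < cols and right < n_counties:
            neighbors[ids[k]].add(ids[right])
            neighbors[ids[right]].add(ids[k])
        down = k + cols
        if down < n_counties:
            neighbors[ids[k]].add(ids[down])
            neighbors[ids[down]].add(ids[k])
    if n_islands > 0:
        rng = substream(seed, "graph-islands")
        islands = rng.choice(n_counties, size=n_islands, replace=False)
        for k in islands:
            a = ids[k]
            for b in neighbors[a]:
                neighbors[b].discard(a)
            neighbors[a] = set()
    return AdjacencyGraph(neighbors)


def _neighbor_mean(values: np.ndarray, graph: AdjacencyGraph, ids: list[str]) -> np.ndarray:
    """Mean of ``values`` over each area's neighbors (islands -> own value)."""
    pos = {a: k for k, a in enumerate(ids)}
    out = values.copy()
    for k, a in enumerate(ids):
        nbrs = graph.neighbors[a]
        if nbrs:
            out[k] = values[[pos[b] for b in nbrs]].mean()
    return out


def simulate_truth(config: SyntheticConfig, graph: AdjacencyGraph) -> SyntheticTruth:
    """Draw the county-level world: intercepts, covariates, composition, truth."""
    ids = sorted(graph.areas)
    if len(ids) != config.n_counties:
        raise ValueError("graph area count does not match config.n_counties")
    n = config.n_counties
    rng = substream(config.seed, "truth")

    # --- spatially mixed county intercepts, rescaled to marginal SD sigma_delta
    delta = rng.normal(0.0, config.sigma_delta, size=n)
    m = config.spatial_mixing
    if m > 0 and config.sigma_delta > 0:
        nbr = _neighbor_mean(delta, graph, ids)
        mixed = delta.copy()
        for k, a in enumerate(ids):
            if graph.neighbors[a]:
                mixed[k] = (1 - m) * delta[k] + m * nbr[k]
        sd = mixed.std()
        if sd > 0:
            mixed *= config.sigma_delta / sd
        delta = mixed
    delta_s = pd.Series(delta, index=ids, name="delta")

    # --- demographic composition: Dirichlet around national age/race mixes
    schema = config.schema
    std_age = us_2000_standard().weights.reindex(schema.age_groups)
    if std_age.isna().any():  # custom schema: uniform age centre
        std_age = pd.Series(1.0 / len(schema.age_groups), index=schema.age_groups)
    race_centre = pd.Series(_NATIONAL_RACE).reindex(schema.race_groups)
    if race_centre.isna().any():
        race_centre = pd.Series(1.0 / len(schema.race_groups), index=schema.race_groups)
    age_marg = rng.dirichlet(std_age.to_numpy() * 300.0, size=n)
    race_marg = rng.dirichlet(race_centre.to_numpy() * 12.0, size=n)
    comp = np.einsum("ia,ir->iar", age_marg, race_marg).reshape(n, -1)
    comp_cols = pd.MultiIndex.from_product(
        [schema.age_groups, schema.race_groups], names=["age_group", "race_group"]
    )
    composition = pd.DataFrame(comp, index=ids, columns=comp_cols)

    # --- county covariates: composition shares, or Gaussians correlated with delta
    rho = config.covariate_risk_correlation
    delta_std = (
        delta / config.sigma_delta if config.sigma_delta > 0 else np.zeros(n)
    )
    Z = pd.DataFrame(index=ids)
    race_pos = {r: i for i, r in enumerate(schema.race_groups)}
    for name, mean, sd in zip(
        config.covariate_names, config.covariate_means, config.covariate_sds
    ):
        if name in _COMPOSITION_COVARIATES:
            Z[name] = race_marg[:, race_pos[_COMPOSITION_COVARIATES[name]]]
        else:
            z = rho * delta_std + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
            Z[name] = mean + sd * z

    population = np.round(np.exp(rng.normal(10.0, 1.2, size=n)))
    counties = CountyTable(
        Z=Z, composition=composition, population=pd.Series(population, index=ids)
    )

    truth_prev = _true_prevalence(config, counties, delta_s)
    return SyntheticTruth(
        county_intercepts=delta_s,
        county_covariates=counties,
        county_true_prevalence=truth_prev,
        graph=graph,
        config=config,
    )


def _cell_logits(
    config: SyntheticConfig, counties: CountyTable, delta: pd.Series, year: int
) -> pd.DataFrame:
    """Linear predictor for every area x (age, race) cell at ``year``."""
    schema = config.schema
    age_eff = pd.Series(0.0, index=schema.age_groups)
    age_eff[list(schema.nonref_ages)] = config.beta_age
    race_eff = pd.Series(0.0, index=schema.race_groups)
    race_eff[list(schema.nonref_races)] = config.beta_race
    zc = counties.Z.to_numpy() - np.asarray(config.covariate_means)
    county_part = (
        config.alpha
        + config.year_effect(year)
        + zc @ np.asarray(config.gamma)
        + delta.reindex(counties.Z.index).to_numpy()
    )
    cell = (
        age_eff.to_numpy()[:, None] + race_eff.to_numpy()[None, :]
    ).reshape(-1)  # ordered age-major like the composition columns
    cols = pd.MultiIndex.from_product(
        [schema.age_groups, schema.race_groups], names=["age_group", "race_group"]
    )
    return pd.DataFrame(
        county_part[:, None] + cell[None, :], index=counties.Z.index, columns=cols
    )


def _true_prevalence(
    config: SyntheticConfig, counties: CountyTable, delta: pd.Series
) -> pd.Series:
    """Exact age-standardised truth at the final year.

    Cell probabilities are combined with weights = standard age distribution
    x the county's race marginal, matching the aggregation used for model
    predictions.
    """
    schema = config.schema
    std_age = us_2000_standard().weights.reindex(schema.age_groups)
    if std_age.isna().any():
        std_age = pd.Series(1.0 / len(schema.age_groups), index=schema.age_groups)
    logits = _cell_logits(config, counties, delta, config.years[-1])
    probs = expit(logits.to_numpy())
    n_age, n_race = len(schema.age_groups), len(schema.race_groups)
    race_marg = (
        counties.composition.to_numpy().reshape(-1, n_age, n_race).sum(axis=1)
    )
    w = std_age.to_numpy()[None, :, None] * race_marg[:, None, :]
    w = w / w.sum(axis=(1, 2), keepdims=True)
    prev = (probs.reshape(-1, n_age, n_race) * w).sum(axis=(1, 2))
    return pd.Series(prev, index=counties.Z.index, name="true_prevalence")


def simulate_survey(
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    forced_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Draw person-level records from the truth.

    Per county-year sample sizes follow a gamma-Poisson (negative-binomial)
    law with the configured mean and dispersion; the gamma size factor is
    drawn once per county so large counties are large in every year, as in
    real surveillance data.  ``forced_sizes`` overrides the per-year sample
    size for selected areas (useful for consistency checks).
    """
    if config is None:
        config = truth.config
    if not config.years:
        raise ValueError("years must be non-empty")
    schema = config.schema
    ids = sorted(truth.graph.areas)
    n = len(ids)
    counties = truth.county_covariates

    rng_sizes = substream(config.seed, "survey-sizes")
    rng_demo = substream(config.seed, "survey-demo")
    rng_out = substream(config.seed, "survey-outcome")
    rng_w = substream(config.seed, "survey-weights")

    r = config.sample_size_dispersion
    size_factor = rng_sizes.gamma(shape=r, scale=1.0 / r, size=n)
    n_years = len(config.years)
    lam = config.mean_sample_per_county_year * size_factor
    sizes = rng_sizes.poisson(lam[:, None], size=(n, n_years))
    if forced_sizes:
        for area, forced in forced_sizes.items():
            sizes[ids.index(area), :] = int(forced)

    cols = pd.MultiIndex.from_product(
        [schema.age_groups, schema.race_groups], names=["age_group", "race_group"]
    )
    comp = counties.composition.reindex(ids).to_numpy()
    delta = truth.county_intercepts.reindex(ids).to_numpy()
    zc = counties.Z.reindex(ids).to_numpy() - np.asarray(config.covariate_means)
    county_base = config.alpha + zc @ np.asarray(config.gamma) + delta

    age_eff = pd.Series(0.0, index=schema.age_groups)
    age_eff[list(schema.nonref_ages)] = config.beta_age
    race_eff = pd.Series(0.0, index=schema.race_groups)
    race_eff[list(schema.nonref_races)] = config.beta_race
    cell_eff = (
        age_eff.to_numpy()[:, None] + race_eff.to_numpy()[None, :]
    ).reshape(-1)
    year_eff = np.array([config.year_effect(y) for y in config.years])

    frames = []
    age_labels = np.asarray(
        [a for a, _ in cols], dtype=object
    )
    race_labels = np.asarray([r_ for _, r_ in cols], dtype=object)
    sexes = np.asarray(config.sexes, dtype=object)
    for i, area in enumerate(ids):
        total = int(sizes[i].sum())
        if total == 0:
            continue
        years_rep = np.repeat(np.asarray(config.years), sizes[i])
        yeff_rep = np.repeat(year_eff, sizes[i])
        cell_idx = rng_demo.choice(len(cell_eff), size=total, p=comp[i])
        sex = sexes[rng_demo.integers(0, len(sexes), size=total)]
        eta = county_base[i] + cell_eff[cell_idx] + yeff_rep
        y = (rng_out.random(total) < expit(eta)).astype(int)
        if config.weight_cv > 0:
            shape = 1.0 / config.weight_cv**2
            w = rng_w.gamma(shape=shape, scale=1.0 / shape, size=total)
        else:
            w = np.ones(total)
        frames.append(
            pd.DataFrame(
                {
                    "area_id": area,
                    "sex": sex,
                    "age_group": age_labels[cell_idx],
                    "race_group": race_labels[cell_idx],
                    "survey_year": years_rep,
                    "outcome": y,
                    "weight": w,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["area_id", "sex", "age_group", "race_group",
                     "survey_year", "outcome", "weight"]
        )
    df = pd.concat(frames, ignore_index=True)
    # normalise weights to mean exactly 1 within each county-year cell
    if config.weight_cv > 0:
        means = df.groupby(["area_id", "survey_year"], observed=True)["weight"].transform("mean")
        df["weight"] = df["weight"] / means
    return df


def simulate_dataset(
    config: SyntheticConfig, n_islands: int = 0
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: graph -> truth -> survey records."""
    graph = make_county_graph(config.n_counties, n_islands, seed=config.seed)
    truth = simulate_truth(config, graph)
    records = simulate_survey(truth, config)
    return records, truth
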