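"""Demographic schemas, core containers, and error types.

Survey microdata are represented as pandas DataFrames with one row per
respondent (columns ``area_id, sex, age_group, race_group, survey_year,
outcome, weight``).  Area-level inputs live in :class:`CountyTable`
(covariates, age x race composition, population) and
:class:`AdjacencyGraph` (first-order contiguity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "REFERENCE_AGE",
    "RACE_GROUPS",
    "REFERENCE_RACE",
    "SEXES",
    "DEFAULT_COVARIATE_NAMES",
    "PERSON_COLUMNS",
    "DemographicSchema",
    "AdjacencyGraph",
    "CountyTable",
    "SaevalError",
    "SchemaError",
    "EstimationError",
    "SeparationError",
    "UndefinedEstimateError",
]


#: Five-year age bands for adults 30 and older; 50-54 is the reference band.
AGE_GROUPS: tuple[str, ...] = (
    "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75+",
)
REFERENCE_AGE = "50-54"

#: Mutually exclusive race/ethnicity groups; White non-Hispanic is the reference.
RACE_GROUPS: tuple[str, ...] = (
    "white_nh", "black_nh", "aian_nh", "hispanic", "asian_other_nh",
)
REFERENCE_RACE = "white_nh"

SEXES: tuple[str, ...] = ("male", "female")

#: Canonical roster of area-level covariates (names only; all configurable).
DEFAULT_COVARIATE_NAMES: tuple[str, ...] = (
    "share_black",
    "share_hispanic",
    "share_highschool",
    "share_bachelors",
    "poverty_rate",
    "median_income",
    "fastfood_per_100k",
    "physicians_per_1k",
    "dentists_per_1k",
)

PERSON_COLUMNS: tuple[str, ...] = (
    "area_id", "sex", "age_group", "race_group", "survey_year", "outcome", "weight",
)


class SaevalError(Exception):
    """Base class for package errors."""


class SchemaError(SaevalError):
    """Input data violates the declared schema."""


class EstimationError(SaevalError):
    """A model fit could not be carried out or did not converge."""


class SeparationError(EstimationError):
    """Complete (or quasi-complete) separation in a fixed effect."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"complete separation detected in fixed effect {term!r}")


class UndefinedEstimateError(SaevalError):
    """A direct estimate was requested from zero records."""


@dataclass(frozen=True)
class DemographicSchema:
    """Age and race category systems with their reference levels.

    The defaults follow the conventional BRFSS-style coding for adults aged
    30+: ten five-year age bands with 50-54 as reference, and five race/
    ethnicity groups with White non-Hispanic as reference.  Both axes can be
    overridden for other applications.
    """

    age_groups: tuple[str, ...] = AGE_GROUPS
    reference_age: str = REFERENCE_AGE
    race_groups: tuple[str, ...] = RACE_GROUPS
    reference_race: str = REFERENCE_RACE

    def __post_init__(self) -> None:
        if self.reference_age not in self.age_groups:
            raise SchemaError(f"reference age {self.reference_age!r} not in age groups")
        if self.reference_race not in self.race_groups:
            raise SchemaError(
                f"reference race {self.reference_race!r} not in race groups"
            )

    @property
    def nonref_ages(self) -> tuple[str, ...]:
        return tuple(a for a in self.age_groups if a != self.reference_age)

    @property
    def nonref_races(self) -> tuple[str, ...]:
        return tuple(r for r in self.race_groups if r != self.reference_race)


DEFAULT_SCHEMA = DemographicSchema()


@dataclass
class AdjacencyGraph:
    """Symmetric first-order contiguity between areas.

    ``neighbors`` maps every area id to the (possibly empty) set of adjacent
    area ids.  Islands — areas with no neighbors — are allowed; self-loops
    are not.
    """

    neighbors: dict[str, set[str]]

    def __post_init__(self) -> None:
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise SchemaError(f"self-loop on area {a!r}")
            for b in nbrs:
                if b not in self.neighbors:
                    raise SchemaError(f"neighbor {b!r} of {a!r} is not an area")
                if a not in self.neighbors[b]:
                    raise SchemaError(f"asymmetric adjacency between {a!r} and {b!r}")

    @property
    def areas(self) -> set[str]:
        return set(self.neighbors)

    def degree(self, area: str) -> int:
        return len(self.neighbors[area])

    def islands(self) -> set[str]:
        return {a for a, n in self.neighbors.items() if not n}

    def n_edges(self) -> int:
        return sum(len(n) for n in self.neighbors.values()) // 2


@dataclass
class CountyTable:
    """Area-level covariates, demographic composition and population.

    Attributes
    ----------
    Z : DataFrame indexed by area_id, one column per covariate.
    composition : DataFrame indexed by area_id with a (age_group, race_group)
        MultiIndex on columns; rows are proportions summing to 1.
    population : Series of nonnegative totals indexed by area_id.
    """

    Z: pd.DataFrame
    composition: pd.DataFrame
    population: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.population is None:
            self.population = pd.Series(0.0, index=self.Z.index)
        if not self.Z.index.equals(self.composition.index):
            raise SchemaError("Z and composition must be indexed by the same areas")
        vals = self.composition.to_numpy()
        if (vals < -1e-12).any():
            raise SchemaError("composition proportions must be nonnegative")
        sums = vals.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
        if bad.size:
            raise SchemaError(
                f"composition rows do not sum to 1 for areas "
                f"{list(self.composition.index[bad[:5]])}"
            )

    @property
    def areas(self) -> list[str]:
        return list(self.Z.index)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.Z.columns)

    def race_marginal(self, area: str) -> pd.Series:
        """Race composition of an area, marginalised over age."""
        row = self.composition.loc[area]
        return row.groupby(level="race_group").sum()

    def age_marginal(self, area: str) -> pd.Series:
        row = self.composition.loc[area]
        return row.groupby(level="age_group").sum()


def validate_person_frame(df: pd.DataFrame, schema: DemographicSchema = DEFAULT_SCHEMA) -> None:
    """Raise :class:`SchemaError` unless ``df`` is a valid person-record frame."""
    missing = [c for c in PERSON_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing person-record columns: {missing}")
    bad_age = set(df["age_group"].unique()) - set(schema.age_groups)
    if bad_age:
        raise SchemaError(f"unknown age_group labels: {sorted(bad_age)}")
    bad_race = set(df["race_group"].unique()) - set(schema.race_groups)
    if bad_race:
        raise SchemaError(f"unknown race_group labels: {sorted(bad_race)}")
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"unknown sex labels: {sorted(bad_sex)}")
    if not df["outcome"].isin((0, 1)).all():
        raise SchemaError("outcome must be 0/1")
    nonpos = np.flatnonzero(df["weight"].to_numpy() <= 0)
    if nonpos.size:
        raise SchemaError(f"nonpositive weight at row index {int(nonpos[0])}")
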