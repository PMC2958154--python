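"""The four model families and the two-stage spatial covariate.

The Naive and Covariate families are single-stage fits.  The Geospatial and
Full families add a spatial covariate — the mean of the estimated county
random intercepts over each county's contiguity neighbors, taken from a
first-stage Naive or Covariate fit respectively — and refit with that
covariate held fixed.  Islands, and neighbors absent from the first-stage
fit, take the random-effect prior mean of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import glmm
from .glmm import FittedModel, ModelSpec
from .schema import AdjacencyGraph, CountyTable, DemographicSchema, DEFAULT_SCHEMA

__all__ = ["SpatialCovariate", "compute_spatial_covariate", "fit_family", "enumerate_specs"]


@dataclass
class SpatialCovariate:
    """Neighbor-averaged first-stage random intercepts, one value per area."""

    values: dict[str, float]
    source_spec: ModelSpec

    def get(self, area: str, default: float = 0.0) -> float:
        return self.values.get(area, default)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.values.items()), columns=["area_id", "value"]
        )


def compute_spatial_covariate(
    base: FittedModel, graph: AdjacencyGraph
) -> SpatialCovariate:
    """Average the first-stage random intercepts over each area's neighbors.

    Neighbors that were not in the first-stage fit contribute 0 (the prior
    mean); islands receive 0.
    """
    if not graph.neighbors:
        raise ValueError("empty adjacency graph")
    ranef = base.ranef_mean
    values: dict[str, float] = {}
    for area, nbrs in graph.neighbors.items():
        if not nbrs:
            values[area] = 0.0
        else:
            values[area] = sum(float(ranef.get(b, 0.0)) for b in nbrs) / len(nbrs)
    return SpatialCovariate(values=values, source_spec=base.spec)


_BASE_FAMILY = {"geospatial": "naive", "full": "covariate"}


def fit_family(
    records: pd.DataFrame,
    spec: ModelSpec,
    counties: CountyTable | None = None,
    graph: AdjacencyGraph | None = None,
    schema: DemographicSchema = DEFAULT_SCHEMA,
    compute_cov: bool = True,
) -> tuple[FittedModel, SpatialCovariate | None]:
    """Fit one family, running the two-stage spatial procedure when required.

    Returns the fitted model and, for the Geospatial/Full families, the
    spatial covariate the second stage was conditioned on (``None``
    otherwise).
    """
    if not spec.uses_spatial:
        model = glmm.fit(
            records, spec, counties=counties, schema=schema, compute_cov=compute_cov
        )
        return model, None
    if graph is None:
        raise ValueError(f"{spec.family} family requires an adjacency graph")
    base_spec = ModelSpec(
        family=_BASE_FAMILY[spec.family],
        include_race=spec.include_race,
        year_effect=spec.year_effect,
        sex=spec.sex,
    )
    base = glmm.fit(
        records, base_spec, counties=counties, schema=schema, compute_cov=False
    )
    spat = compute_spatial_covariate(base, graph)
    model = glmm.fit(
        records,
        spec,
        counties=counties,
        spatial_covariate=spat.values,
        schema=schema,
        compute_cov=compute_cov,
    )
    model.spatial_base = base_spec.family
    return model, spat


def enumerate_specs(
    families: tuple[str, ...] = ("naive", "geospatial", "covariate", "full"),
    race_options: tuple[bool, ...] = (False, True),
    year_effects: tuple[str, ...] = ("fixed", "random"),
    sex: str | None = None,
) -> list[ModelSpec]:
    """Full crossing of family x race-in/out x fixed/random year."""
    specs = []
    for fam in families:
        for race in race_options:
            for yeff in year_effects:
                specs.append(
                    ModelSpec(family=fam, include_race=race, year_effect=yeff, sex=sex)
                )
    return specs
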