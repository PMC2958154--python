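"""Readers, writers and run configuration.

Canonical on-disk formats are plain CSV with explicit headers (survey
microdata have no standard binary container) plus a tab-separated adjacency
list ``area_id<TAB>comma-separated neighbor ids``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .schema import (
    DEFAULT_SCHEMA,
    PERSON_COLUMNS,
    AdjacencyGraph,
    CountyTable,
    DemographicSchema,
    SchemaError,
    validate_person_frame,
)

__all__ = [
    "read_person_records",
    "write_person_records",
    "read_adjacency",
    "write_adjacency",
    "read_county_table",
    "write_county_table",
    "RunConfig",
    "setup_logging",
    "write_data_dictionary",
]

logger = logging.getLogger("saeval")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# person records
# ---------------------------------------------------------------------------

def read_person_records(
    path: str | Path, schema: DemographicSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Read person-level survey records from CSV.

    Rows with a missing outcome (blank / NA) are dropped with a logged
    count; any other schema violation raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"area_id": str})
    missing_cols = [c for c in PERSON_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    n_missing = int(df["outcome"].isna().sum())
    if n_missing:
        logger.warning("%s: dropped %d records with missing outcome", path, n_missing)
        df = df.dropna(subset=["outcome"])
    df = df.astype({"outcome": int, "survey_year": int, "weight": float})
    df = df.reset_index(drop=True)
    validate_person_frame(df, schema)
    return df[list(PERSON_COLUMNS)]


def write_person_records(df: pd.DataFrame, path: str | Path) -> None:
    df[list(PERSON_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def read_adjacency(path: str | Path) -> AdjacencyGraph:
    """Read a contiguity list; asymmetric input is symmetrised with a warning."""
    neighbors: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            area, _, rest = line.partition("\t")
            area = area.strip()
            nbrs = {tok.strip() for tok in rest.split(",") if tok.strip()}
            if area in nbrs:
                raise SchemaError(f"self-loop on area {area!r}")
            neighbors[area] = nbrs
    # symmetrise
    asymmetric = False
    for a in list(neighbors):
        for b in neighbors[a]:
            if b not in neighbors:
                neighbors[b] = set()
            if a not in neighbors[b]:
                neighbors[b].add(a)
                asymmetric = True
    if asymmetric:
        logger.warning("adjacency input was asymmetric; symmetrised")
    return AdjacencyGraph(neighbors)


def write_adjacency(graph: AdjacencyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for area in sorted(graph.neighbors):
            fh.write(f"{area}\t{','.join(sorted(graph.neighbors[area]))}\n")


# ---------------------------------------------------------------------------
# county table
# ---------------------------------------------------------------------------

_COMP_PREFIX = "comp"
_Z_PREFIX = "z"


def write_county_table(table: CountyTable, path: str | Path) -> None:
    """Write covariates, composition and population as one wide CSV."""
    out = pd.DataFrame(index=table.Z.index)
    out["population"] = table.population
    for c in table.Z.columns:
        out[f"{_Z_PREFIX}:{c}"] = table.Z[c]
    for age, race in table.composition.columns:
        out[f"{_COMP_PREFIX}:{age}:{race}"] = table.composition[(age, race)]
    out.index.name = "area_id"
    out.to_csv(path)


def read_county_table(path: str | Path) -> CountyTable:
    df = pd.read_csv(path, dtype={"area_id": str}).set_index("area_id")
    z_cols = [c for c in df.columns if c.startswith(f"{_Z_PREFIX}:")]
    comp_cols = [c for c in df.columns if c.startswith(f"{_COMP_PREFIX}:")]
    Z = df[z_cols].rename(columns={c: c.split(":", 1)[1] for c in z_cols})
    comp = df[comp_cols]
    comp.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":")[1:3]) for c in comp_cols], names=["age_group", "race_group"]
    )
    pop = df["population"] if "population" in df.columns else None
    return CountyTable(Z=Z, composition=comp, population=pop)


def write_data_dictionary(path: str | Path) -> None:
    """Write a plain-text description of every output column."""
    text = """\
saeval data dictionary
======================

persons.csv — one row per survey respondent
  area_id      string area identifier (FIPS-like)
  sex          male | female
  age_group    one of the configured five-year bands (default 30-34 .. 75+)
  race_group   one of the configured race/ethnicity groups
  survey_year  integer survey year
  outcome      0/1 binary outcome (1 = condition present)
  weight       positive poststratification weight (mean 1 per area-year cell)

counties.csv — one row per area
  area_id        string area identifier
  population     area population total
  z:<name>       area-level covariate <name>
  comp:<age>:<race>  proportion of the area's 30+ population in the cell

adjacency.tsv — one line per area
  area_id <TAB> comma-separated ids of contiguous areas (blank = island)

truth.csv — one row per area (synthetic data only)
  area_id          string area identifier
  delta            true area random intercept on the log-odds scale
  true_prevalence  true age-standardised prevalence at the final year
"""
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    The defaults mirror the framework's canonical constants: downsampling
    levels 100/50/10 respondents per county-year, 10 replicates per level,
    gold-standard threshold of >900 pooled observations per sex in both
    reference windows, and 1,000 parameter draws for credibility regions.
    """

    families: tuple[str, ...] = ("naive", "geospatial", "covariate", "full")
    race_options: tuple[bool, ...] = (False, True)
    year_effects: tuple[str, ...] = ("fixed", "random")
    sampling_levels: tuple[int, ...] = (100, 50, 10)
    replicates: int = 10
    gold_threshold: int = 900
    window1: tuple[int, int] = (1996, 2004)
    window2: tuple[int, int] = (2000, 2008)
    prediction_year: int = 2004
    draws: int = 1000
    seed: int = 0
    persons_path: str = "persons.csv"
    counties_path: str = "counties.csv"
    adjacency_path: str = "adjacency.tsv"
    out_dir: str = "saeval_out"

    def __post_init__(self) -> None:
        levels = tuple(int(x) for x in self.sampling_levels)
        if any(l <= 0 for l in levels):
            raise ValueError("sampling levels must be positive")
        if list(levels) != sorted(levels, reverse=True) or len(set(levels)) != len(levels):
            raise ValueError("sampling levels must be strictly decreasing")
        self.sampling_levels = levels
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.families = tuple(self.families)
        self.race_options = tuple(bool(b) for b in self.race_options)
        self.year_effects = tuple(self.year_effects)
        bad = set(self.families) - {"naive", "geospatial", "covariate", "full"}
        if bad:
            raise ValueError(f"unknown model families: {sorted(bad)}")
        bad = set(self.year_effects) - {"fixed", "random"}
        if bad:
            raise ValueError(f"unknown year effects: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window1", "window2", "sampling_levels", "families",
                    "race_options", "year_effects"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for k, v in raw.items():
            if isinstance(v, tuple):
                raw[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)
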