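"""Downsampling validation: CCC/RMSE scoring against the gold standard.

The experiment mirrors the validation design: restrict to the gold-standard
areas, resample with replacement to a fixed number of respondents per
area-year (levels 100/50/10 by default), refit each model specification on
the reduced data, predict the target year's standardised prevalence for the
gold areas, and score concordance (Lin's CCC) and RMSE against the direct
gold-standard estimates.  A single-year direct estimator is scored the same
way as a baseline, and models are ranked by mean CCC (ties broken by RMSE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import aggregate_to_prevalence
from .direct import GoldStandard, StandardPopulation, direct_estimate
from .families import fit_family
from .glmm import ModelSpec
from .rng import substream
from .schema import (
    AdjacencyGraph,
    CountyTable,
    DemographicSchema,
    DEFAULT_SCHEMA,
    EstimationError,
    UndefinedEstimateError,
)

__all__ = [
    "ccc",
    "rmse",
    "downsample",
    "ValidationResult",
    "run_experiment",
    "score_direct_baseline",
    "rank_models",
    "best_spec",
]

logger = logging.getLogger("saeval")

_RESULT_COLUMNS = [
    "sex", "family", "include_race", "year_effect", "spec", "level",
    "replicate", "ccc", "rmse", "n_areas", "converged",
]


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``; measures
    agreement, penalising both imprecision and location/scale shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ccc requires two equal-length 1-d vectors")
    if len(x) < 2:
        raise ValueError("ccc requires at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ZeroDivisionError("ccc undefined: both vectors constant and equal")
    return float(2.0 * cov / denom)


def rmse(x, y) -> float:
    """Root mean squared error between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rmse requires equal-length vectors")
    if x.size == 0:
        raise ValueError("rmse requires at least one observation")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def downsample(records: pd.DataFrame, level: int, seed: int) -> pd.DataFrame:
    """Resample with replacement to exactly ``level`` records per area-year.

    Sampling is independent across area-year cells and deterministic given
    the seed.  Raises :class:`EstimationError` naming the first empty cell.
    """
    if level < 1:
        raise ValueError("level must be positive")
    rng = substream(seed, "downsample", int(level))
    pieces = []
    for (area, year), idx in sorted(
        records.groupby(["area_id", "survey_year"], observed=True).indices.items()
    ):
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty groups
            raise EstimationError(f"empty area-year cell ({area}, {year})")
        take = rng.choice(idx, size=level, replace=True)
        pieces.append(records.iloc[take])
    if not pieces:
        raise EstimationError("no records to downsample")
    return pd.concat(pieces, ignore_index=True)


@dataclass
class ValidationResult:
    """One row per spec x sampling level x replicate (plus 'all' rows)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing result columns: {missing}")

    def mean_scores(self) -> pd.DataFrame:
        """Mean CCC/RMSE per (sex, spec, level) over converged replicates."""
        ok = self.table[self.table["converged"]]
        return (
            ok.groupby(["sex", "family", "include_race", "year_effect", "spec", "level"],
                       observed=True)[["ccc", "rmse"]]
            .mean()
            .reset_index()
        )

    def concat(self, other: "ValidationResult") -> "ValidationResult":
        return ValidationResult(
            pd.concat([self.table, other.table], ignore_index=True)
        )


def _score_row(spec, sex, level, replicate, preds, gold_est) -> dict:
    aligned = preds.reindex(gold_est.index)
    return {
        "sex": sex,
        "family": spec.family if spec is not None else "direct",
        "include_race": spec.include_race if spec is not None else False,
        "year_effect": spec.year_effect if spec is not None else "none",
        "spec": spec.label() if spec is not None else "direct",
        "level": level,
        "replicate": replicate,
        "ccc": ccc(aligned.to_numpy(), gold_est.to_numpy()),
        "rmse": rmse(aligned.to_numpy(), gold_est.to_numpy()),
        "n_areas": len(gold_est),
        "converged": True,
    }


def _failed_row(spec, sex, level, replicate, n_areas, err) -> dict:
    logger.warning(
        "fit failed (spec=%s level=%s rep=%s): %s",
        spec.label() if spec is not None else "direct", level, replicate, err,
    )
    return {
        "sex": sex,
        "family": spec.family if spec is not None else "direct",
        "include_race": spec.include_race if spec is not None else False,
        "year_effect": spec.year_effect if spec is not None else "none",
        "spec": spec.label() if spec is not None else "direct",
        "level": level,
        "replicate": replicate,
        "ccc": np.nan,
        "rmse": np.nan,
        "n_areas": n_areas,
        "converged": False,
    }


def _fit_and_score(
    data, spec, sex, level, replicate, gold_est, target_year,
    counties, graph, std, schema,
) -> dict:
    try:
        model, spat = fit_family(
            data, spec, counties=counties, graph=graph, schema=schema,
            compute_cov=False,
        )
        if not model.converged:
            raise EstimationError("optimizer did not converge")
        spat_vals = spat.values if spat is not None else None
        preds = pd.Series(
            {
                area: aggregate_to_prevalence(
                    model, area, target_year, std, counties, spat_vals
                )
                for area in gold_est.index
            }
        )
        return _score_row(spec, sex, level, replicate, preds, gold_est)
    except (EstimationError, np.linalg.LinAlgError) as err:
        return _failed_row(spec, sex, level, replicate, len(gold_est), err)


def run_experiment(
    records: pd.DataFrame,
    gold: GoldStandard,
    specs: list[ModelSpec],
    levels: tuple[int, ...],
    replicates: int,
    target_year: int,
    seed: int,
    counties: CountyTable,
    std: StandardPopulation,
    graph: AdjacencyGraph | None = None,
    schema: DemographicSchema = DEFAULT_SCHEMA,
    sexes: tuple[str, ...] | None = None,
) -> ValidationResult:
    """The downsampling experiment, per sex.

    For every spec: one 'all' row fitted on the full gold-area data, plus
    one row per level x replicate fitted on resampled data.  Non-converged
    fits are recorded as flagged rows, never silently dropped.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    rows = []
    for sex in sexes if sexes is not None else gold.sexes():
        gold_est = gold.estimates(sex)
        sub = records[
            (records["sex"] == sex) & records["area_id"].isin(gold_est.index)
        ].reset_index(drop=True)
        for spec in specs:
            spec_sex = ModelSpec(spec.family, spec.include_race, spec.year_effect, sex)
            rows.append(
                _fit_and_score(
                    sub, spec_sex, sex, "all", 0, gold_est, target_year,
                    counties, graph, std, schema,
                )
            )
            for level in levels:
                for rep in range(1, replicates + 1):
                    sub_seed = substream(
                        seed, "experiment", sex, spec_sex.label(), int(level), rep
                    ).integers(0, 2**31 - 1)
                    ds = downsample(sub, level, int(sub_seed))
                    rows.append(
                        _fit_and_score(
                            ds, spec_sex, sex, level, rep, gold_est, target_year,
                            counties, graph, std, schema,
                        )
                    )
    return ValidationResult(pd.DataFrame(rows, columns=_RESULT_COLUMNS))


def score_direct_baseline(
    records: pd.DataFrame,
    gold: GoldStandard,
    levels: tuple[int, ...],
    replicates: int,
    target_year: int,
    seed: int,
    std: StandardPopulation,
    sexes: tuple[str, ...] | None = None,
) -> ValidationResult:
    """Score the single-year direct estimator in place of a model.

    ``records`` are restricted to the target year internally; downsampling
    levels then correspond to ``level`` observations for that single year.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    year_records = records[records["survey_year"] == target_year]
    rows = []
    for sex in sexes if sexes is not None else gold.sexes():
        gold_est = gold.estimates(sex)
        sub = year_records[
            (year_records["sex"] == sex)
            & year_records["area_id"].isin(gold_est.index)
        ].reset_index(drop=True)

        def _direct_preds(data: pd.DataFrame) -> pd.Series:
            out = {}
            for area in gold_est.index:
                cell = data[data["area_id"] == area]
                try:
                    out[area] = direct_estimate(cell, std)
                except UndefinedEstimateError:
                    out[area] = np.nan
            return pd.Series(out).dropna()

        preds = _direct_preds(sub)
        common = preds.index.intersection(gold_est.index)
        rows.append(
            _score_row(None, sex, "all", 0, preds.loc[common], gold_est.loc[common])
        )
        for level in levels:
            for rep in range(1, replicates + 1):
                sub_seed = substream(
                    seed, "baseline", sex, int(level), rep
                ).integers(0, 2**31 - 1)
                ds = downsample(sub, level, int(sub_seed))
                preds = _direct_preds(ds)
                common = preds.index.intersection(gold_est.index)
                rows.append(
                    _score_row(
                        None, sex, level, rep, preds.loc[common], gold_est.loc[common]
                    )
                )
    return ValidationResult(pd.DataFrame(rows, columns=_RESULT_COLUMNS))


def rank_models(result: ValidationResult) -> pd.DataFrame:
    """Rank specs by mean CCC (descending), ties broken by mean RMSE (ascending).

    Per-level means are averaged with equal weight across levels so that
    levels with more replicates do not dominate.  Returns the full ranking
    per sex; the best spec is rank 1.  Baseline ('direct') rows are ignored.
    """
    tab = result.table
    tab = tab[tab["spec"] != "direct"]
    ok = tab[tab["converged"]]
    if len(ok) == 0:
        raise EstimationError("no converged validation fits to rank")
    per_level = (
        ok.groupby(["sex", "family", "include_race", "year_effect", "spec", "level"],
                   observed=True)[["ccc", "rmse"]]
        .mean()
        .reset_index()
    )
    agg = (
        per_level.groupby(["sex", "family", "include_race", "year_effect", "spec"],
                          observed=True)[["ccc", "rmse"]]
        .mean()
        .reset_index()
    )
    n_failed = (
        tab[~tab["converged"]]
        .groupby(["sex", "spec"], observed=True)
        .size()
        .rename("n_failed")
        .reset_index()
    )
    agg = agg.merge(n_failed, on=["sex", "spec"], how="left")
    agg["n_failed"] = agg["n_failed"].fillna(0).astype(int)
    agg = agg.sort_values(
        ["sex", "ccc", "rmse"], ascending=[True, False, True]
    ).reset_index(drop=True)
    agg["rank"] = agg.groupby("sex", observed=True).cumcount() + 1
    return agg


def best_spec(ranking: pd.DataFrame, sex: str) -> ModelSpec:
    """The rank-1 specification for one sex, as a ModelSpec."""
    row = ranking[(ranking["sex"] == sex) & (ranking["rank"] == 1)].iloc[0]
    return ModelSpec(
        family=row["family"],
        include_race=bool(row["include_race"]),
        year_effect=row["year_effect"],
        sex=sex,
    )
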