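"""End-to-end orchestration: gold standard -> validation -> best model -> estimates.

``run_pipeline`` chains every stage on data read from the configured paths
and writes tidy CSV outputs.  All floats are written with a fixed format so
identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .aggregate import estimate_with_interval
from .direct import build_gold_standard, us_2000_standard
from .families import enumerate_specs, fit_family
from .io import RunConfig, read_adjacency, read_county_table, read_person_records
from .validate import best_spec, rank_models, run_experiment, score_direct_baseline

__all__ = ["run_pipeline"]

logger = logging.getLogger("saeval")

_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full measurement-and-validation pipeline; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name, fn):
        logger.info("pipeline stage: %s", name)
        try:
            return fn()
        except Exception as err:
            raise StageError(name, err) from err

    records = _stage("read-persons", lambda: read_person_records(config.persons_path))
    counties = _stage("read-counties", lambda: read_county_table(config.counties_path))
    graph = _stage("read-adjacency", lambda: read_adjacency(config.adjacency_path))
    std = us_2000_standard()

    gold = _stage(
        "gold-standard",
        lambda: build_gold_standard(
            records, (config.window1, config.window2), config.gold_threshold, std
        ),
    )
    gold_path = out_dir / "gold_standard.csv"
    gold.table.to_csv(gold_path, index=False, float_format=_FLOAT_FMT)
    outputs["gold_standard"] = gold_path

    specs = enumerate_specs(
        config.families, config.race_options, config.year_effects
    )
    w1 = config.window1
    fit_records = records[
        (records["survey_year"] >= w1[0]) & (records["survey_year"] <= w1[1])
    ]

    result = _stage(
        "validation-experiment",
        lambda: run_experiment(
            fit_records, gold, specs, config.sampling_levels, config.replicates,
            config.prediction_year, config.seed, counties, std, graph,
        ),
    )
    baseline = _stage(
        "direct-baseline",
        lambda: score_direct_baseline(
            fit_records, gold, config.sampling_levels, config.replicates,
            config.prediction_year, config.seed, std,
        ),
    )
    combined = result.concat(baseline)
    val_path = out_dir / "validation.csv"
    combined.table.to_csv(val_path, index=False, float_format=_FLOAT_FMT)
    outputs["validation"] = val_path

    ranking = _stage("rank-models", lambda: rank_models(result))
    rank_path = out_dir / "ranking.csv"
    ranking.to_csv(rank_path, index=False, float_format=_FLOAT_FMT)
    outputs["ranking"] = rank_path

    for sex in gold.sexes():
        spec = best_spec(ranking, sex)
        sex_records = records[records["sex"] == sex]

        def _predict():
            model, spat = fit_family(
                sex_records, spec, counties=counties, graph=graph
            )
            spat_vals = spat.values if spat is not None else None
            n_by_area = sex_records.groupby("area_id", observed=True).size()
            rows = []
            for area in counties.areas:
                est = estimate_with_interval(
                    model, area, config.prediction_year, std, counties, spat_vals,
                    draws=config.draws, seed=config.seed,
                    n_pooled=int(n_by_area.get(area, 0)),
                )
                rows.append(est.__dict__)
            return pd.DataFrame(rows)

        est_table = _stage(f"predict-{sex}", _predict)
        est_path = out_dir / f"estimates_{sex}.csv"
        est_table.to_csv(est_path, index=False, float_format=_FLOAT_FMT)
        outputs[f"estimates_{sex}"] = est_path

    logger.info("pipeline complete: %d outputs in %s", len(outputs), out_dir)
    return outputs
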