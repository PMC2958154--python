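"""Direct survey estimation and gold-standard construction.

The direct estimator is the design-based benchmark: within each survey-year
x age-group cell the outcome is averaged with poststratification weights,
cell estimates are averaged over years with equal year weights, and the
age-specific rates are then combined with a standard age distribution
(renormalised over the age groups actually present).  Areas whose pooled
sample size exceeds a threshold in two reference windows form the
gold-standard validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import AGE_GROUPS, SchemaError, UndefinedEstimateError

__all__ = [
    "StandardPopulation",
    "us_2000_standard",
    "direct_estimate",
    "GoldStandard",
    "build_gold_standard",
]

logger = logging.getLogger("saeval")


@dataclass(frozen=True)
class StandardPopulation:
    """A standard age distribution: nonnegative weights summing to 1."""

    weights: pd.Series  # index age_group

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < 0).any():
            raise SchemaError("standard population weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise SchemaError("standard population weights must sum to 1")


#: Share of the US 2000 population aged 30+ in each five-year band.
_US_2000_30PLUS = {
    "30-34": 0.125, "35-39": 0.137, "40-44": 0.137, "45-49": 0.122,
    "50-54": 0.107, "55-59": 0.083, "60-64": 0.066, "65-69": 0.058,
    "70-74": 0.054, "75+": 0.111,
}


def us_2000_standard() -> StandardPopulation:
    """US 2000 age distribution for the 30-and-older universe."""
    return StandardPopulation(pd.Series(_US_2000_30PLUS).reindex(AGE_GROUPS))


def direct_estimate(records: pd.DataFrame, std: StandardPopulation) -> float:
    """Weighted, age-standardised, equal-year-weighted prevalence.

    ``records`` should already be restricted to one area and one sex.
    Raises :class:`UndefinedEstimateError` on zero records.
    """
    if len(records) == 0:
        raise UndefinedEstimateError("direct estimate requested from zero records")

    tmp = records.assign(_wy=records["weight"] * records["outcome"])
    agg = tmp.groupby(["age_group", "survey_year"], observed=True).agg(
        num=("_wy", "sum"), den=("weight", "sum")
    )
    cell = agg["num"] / agg["den"]  # prevalence per age x year cell
    by_age = cell.groupby(level="age_group", observed=True).mean()  # equal year weights

    std_w = std.weights.reindex(by_age.index)
    if std_w.isna().any():
        raise SchemaError(
            f"age groups missing from standard population: "
            f"{list(by_age.index[std_w.isna()])}"
        )
    total = float(std_w.sum())
    if total <= 0:
        raise UndefinedEstimateError("standard weights vanish on the present age groups")
    return float((std_w / total * by_age).sum())


@dataclass
class GoldStandard:
    """Direct estimates for large-sample areas, per area and sex.

    ``table`` has one row per qualifying (area_id, sex) with columns
    ``estimate`` (direct age-standardised prevalence), ``n_pooled`` (sample
    size in the estimation window) and ``years`` (the pooled year range).
    """

    table: pd.DataFrame
    threshold: int

    def __len__(self) -> int:
        return len(self.table)

    def sexes(self) -> list[str]:
        return sorted(self.table["sex"].unique())

    def areas(self, sex: str) -> list[str]:
        sub = self.table[self.table["sex"] == sex]
        return sorted(sub["area_id"])

    def estimates(self, sex: str) -> pd.Series:
        sub = self.table[self.table["sex"] == sex]
        return sub.set_index("area_id")["estimate"].sort_index()


def build_gold_standard(
    records: pd.DataFrame,
    windows: tuple[tuple[int, int], tuple[int, int]],
    threshold: int,
    std: StandardPopulation,
    estimation_window: tuple[int, int] | None = None,
) -> GoldStandard:
    """Select area x sex cells exceeding ``threshold`` observations in BOTH windows.

    The estimate itself is computed on ``estimation_window`` (default: the
    second window, the pooled comparison window).
    """
    (a1, b1), (a2, b2) = windows
    if estimation_window is None:
        estimation_window = (a2, b2)
    ea, eb = estimation_window
    yr = records["survey_year"]
    in1 = records[(yr >= a1) & (yr <= b1)]
    in2 = records[(yr >= a2) & (yr <= b2)]
    c1 = in1.groupby(["area_id", "sex"], observed=True).size()
    c2 = in2.groupby(["area_id", "sex"], observed=True).size()
    counts = pd.concat({"w1": c1, "w2": c2}, axis=1).fillna(0)
    keep = counts[(counts["w1"] > threshold) & (counts["w2"] > threshold)].index

    est = records[(yr >= ea) & (yr <= eb)]
    rows = []
    for area, sex in sorted(keep):
        sub = est[(est["area_id"] == area) & (est["sex"] == sex)]
        rows.append(
            {
                "area_id": area,
                "sex": sex,
                "estimate": direct_estimate(sub, std),
                "n_pooled": len(sub),
                "years": f"{ea}-{eb}",
            }
        )
    if not rows:
        logger.warning("gold standard is empty at threshold %d", threshold)
        table = pd.DataFrame(
            columns=["area_id", "sex", "estimate", "n_pooled", "years"]
        )
    else:
        table = pd.DataFrame(rows)
    return GoldStandard(table=table, threshold=threshold)
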