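"""Population summaries: weighted mean intake and proportion reaching the
recommended fibre intake, by sex and by age band.

The summary table mirrors the standard presentation of UK dietary-survey
results: rows for males and females, then five age bands (pre-school 1.5-3 y,
junior school 4-10 y, adolescents 11-18 y, adults 19-65 y, older adults
>65 y), each with "mean (SE)" of daily fibre intake and the percentage of
the group at or above its recommended intake, under the current and the
reformulated composition tables.

Estimators
----------
Weighted mean:  x_bar = sum(w x) / sum(w).
Its standard error uses the design-based form

    se = sqrt( sum(w_i^2 (x_i - x_bar)^2) ) / sum(w_i)

which for unit weights reduces to sd/sqrt(n) with the population
(divide-by-n) standard deviation.  The percentage reaching the threshold is
a weighted proportion with the analogous binomial-style error

    se = 100 * sqrt( p (1-p) * sum(w_i^2) ) / sum(w_i).

Neither estimator corrects for clustering or stratification of a complex
survey design; with real survey data these SEs are approximations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import Dataset, Sex
from .scenario import IntakeResult

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BANDS",
    "age_band",
    "RecommendationSchedule",
    "GroupSummary",
    "SummaryRow",
    "SummaryTable",
    "weighted_mean_se",
    "percent_reaching",
    "summarize",
    "load_schedule",
]

#: (label, lower inclusive, upper exclusive).  Integer-year boundaries use a
#: half-open convention so the five bands are exhaustive and disjoint: a
#: child is "4-10 years" from their 4th until their 11th birthday.
AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("Pre-school (1.5-3 years)", 1.5, 4.0),
    ("Junior School (4-10 years)", 4.0, 11.0),
    ("Adolescents (11-18 years)", 11.0, 19.0),
    ("Adults (19-65 years)", 19.0, 66.0),
    ("Older Adults (>65 years)", 66.0, math.inf),
)


def age_band(age_years: float) -> str:
    """Map an age to its band label; ages below 1.5 y are out of scope."""
    if age_years < 1.5:
        raise ValueError(f"age {age_years} below 1.5 years is outside the surveyed population")
    for label, lo, hi in AGE_BANDS:
        if lo <= age_years < hi:
            return label
    raise AssertionError("age bands are exhaustive above 1.5 years")  # pragma: no cover


@dataclass(frozen=True)
class RecommendationSchedule:
    """Age-banded recommended fibre intakes, g/day.

    Bands are (lower inclusive, upper exclusive, threshold).  The default
    schedule uses the UK adult recommendation of 30 g/day from age 16, with
    SACN age-banded values for children: 15 g (2-5 y, extended down to
    1.5 y so the schedule covers the surveyed range), 20 g (5-11 y) and
    25 g (11-16 y).  All values are overridable via config.
    """

    bands: tuple[tuple[float, float, float], ...] = (
        (1.5, 5.0, 15.0),
        (5.0, 11.0, 20.0),
        (11.0, 16.0, 25.0),
        (16.0, math.inf, 30.0),
    )

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi, threshold in self.bands:
            if hi <= lo:
                raise ValueError(f"band ({lo}, {hi}) is empty")
            if threshold <= 0:
                raise ValueError(f"threshold {threshold} must be > 0")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError("recommendation bands overlap")
            prev_hi = hi

    def threshold_for(self, age_years: float) -> float:
        for lo, hi, threshold in self.bands:
            if lo <= age_years < hi:
                return threshold
        raise ValueError(f"no recommended intake defined for age {age_years}")


def weighted_mean_se(values: Sequence[float], weights: Sequence[float]) -> tuple[float, float]:
    """Weighted mean and its design-based standard error.

    Weights must be positive; a single observation has se = 0 by convention
    (the formula already yields 0 there).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0 or x.shape != w.shape:
        raise ValueError("values and weights must be equal-length and non-empty")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    se = float(np.sqrt((w**2 * (x - mean) ** 2).sum()) / wsum)
    return mean, se


def percent_reaching(
    values: Sequence[float], weights: Sequence[float], threshold: float
) -> tuple[float, float]:
    """Weighted percentage of observations at or above ``threshold``, with SE.

    Ties count as reaching the recommendation (x >= threshold).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0 or x.shape != w.shape:
        raise ValueError("values and weights must be equal-length and non-empty")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    wsum = w.sum()
    p = float((w * (x >= threshold)).sum() / wsum)
    se = 100.0 * float(np.sqrt(p * (1.0 - p) * (w**2).sum()) / wsum)
    return 100.0 * p, se


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one group under one composition table."""

    group_label: str
    n: int
    mean_g_per_day: float
    se_mean: float
    pct_reaching: float
    se_pct: float


@dataclass(frozen=True)
class SummaryRow:
    group_label: str
    n: int
    current: GroupSummary | None
    scenario: GroupSummary | None


@dataclass
class SummaryTable:
    """Fixed-order rows: Male, Female, then the five age bands."""

    sex_rows: list[SummaryRow] = field(default_factory=list)
    age_rows: list[SummaryRow] = field(default_factory=list)

    @property
    def rows(self) -> list[SummaryRow]:
        return [*self.sex_rows, *self.age_rows]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for section, rows in (("Gender", self.sex_rows), ("Age", self.age_rows)):
            for row in rows:
                for which, summary in (("current", row.current), ("scenario", row.scenario)):
                    records.append(
                        {
                            "section": section,
                            "group": row.group_label,
                            "diet": which,
                            "n": row.n,
                            "mean_g_per_day": summary.mean_g_per_day if summary else float("nan"),
                            "se_mean": summary.se_mean if summary else float("nan"),
                            "pct_reaching": summary.pct_reaching if summary else float("nan"),
                            "se_pct": summary.se_pct if summary else float("nan"),
                        }
                    )
        return pd.DataFrame(records)


def _group_summary(
    label: str,
    baseline: np.ndarray,
    weights: np.ndarray,
    thresholds: np.ndarray,
) -> GroupSummary | None:
    if baseline.size == 0:
        return None
    mean, se = weighted_mean_se(baseline, weights)
    # Each member is compared with their own age-specific threshold, so the
    # indicator is formed per person before weighting.
    reached = baseline >= thresholds
    wsum = weights.sum()
    p = float((weights * reached).sum() / wsum)
    se_pct = 100.0 * float(np.sqrt(p * (1.0 - p) * (weights**2).sum()) / wsum)
    return GroupSummary(label, int(baseline.size), mean, se, 100.0 * p, se_pct)


def summarize(
    dataset: Dataset,
    intakes: Iterable[IntakeResult],
    schedule: RecommendationSchedule | None = None,
    weighted: bool = False,
) -> SummaryTable:
    """Build the sex/age summary table for current and scenario diets.

    ``weighted=True`` applies the participants' survey weights; the default
    treats every participant equally.  Groups with no members produce a row
    with n = 0 and missing statistics.
    """
    schedule = schedule or RecommendationSchedule()
    by_id = {r.participant_id: r for r in intakes}
    missing = [p.participant_id for p in dataset.participants if p.participant_id not in by_id]
    if missing:
        raise ValueError(f"intake results missing for {len(missing)} participant(s), e.g. {missing[:3]}")

    records = pd.DataFrame(
        {
            "sex": [p.sex.value for p in dataset.participants],
            "band": [age_band(p.age_years) for p in dataset.participants],
            "weight": [p.survey_weight if weighted else 1.0 for p in dataset.participants],
            "threshold": [schedule.threshold_for(p.age_years) for p in dataset.participants],
            "baseline": [by_id[p.participant_id].baseline_g_per_day for p in dataset.participants],
            "scenario": [by_id[p.participant_id].scenario_g_per_day for p in dataset.participants],
        }
    )

    def build_row(label: str, mask: pd.Series) -> SummaryRow:
        sub = records[mask]
        if len(sub) == 0:
            logger.warning("group %r has no members", label)
            return SummaryRow(label, 0, None, None)
        w = sub["weight"].to_numpy()
        thresholds = sub["threshold"].to_numpy()
        return SummaryRow(
            label,
            len(sub),
            _group_summary(label, sub["baseline"].to_numpy(), w, thresholds),
            _group_summary(label, sub["scenario"].to_numpy(), w, thresholds),
        )

    table = SummaryTable()
    for sex, label in ((Sex.MALE, "Male"), (Sex.FEMALE, "Female")):
        table.sex_rows.append(build_row(label, records["sex"] == sex.value))
    for label, _, _ in AGE_BANDS:
        table.age_rows.append(build_row(label, records["band"] == label))
    return table


def load_schedule(path: str | Path) -> RecommendationSchedule:
    """Read a recommendation schedule from YAML: a list of
    {age_lower, age_upper, threshold_g_per_day} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: recommendation schedule must be a list of bands")
    bands = tuple(
        (
            float(b["age_lower"]),
            float(b["age_upper"]) if b["age_upper"] is not None else math.inf,
            float(b["threshold_g_per_day"]),
        )
        for b in raw
    )
    return RecommendationSchedule(bands=bands)
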