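"""Drug-efficacy normalization, PF classification and two-sample inference.

The comparative layer of a preclinical fibrosis study: each drug arm is
compared only against its matched vehicle arm.  Vehicle group means are
normalized to 100%, the drug mean is expressed relative to that, and the
attenuation of fibrosis is 100 minus the normalized mean — so a drug group
measuring 30% of control attenuated fibrosis by 70%.  Pulmonary fibrosis
(PF) is called per animal by the conjunction of a histology criterion and a
CT criterion; incidence and mortality are simple group percentages.
Between-group inference is the unpaired, two-tailed Student's t-test
(pooled variance; Welch available behind a flag).

Timecourse tables (ELISA, normalized mRNA) are summarized per day with the
day-0 mean anchored to a relative level of one and per-day significance
against baseline at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .histology import MAX_SCORE

ALPHA = 0.05


class DegenerateVarianceError(ValueError):
    """Raised when the pooled variance is zero and the t-test p is undefined."""


class NormalizationError(ValueError):
    """Raised when the vehicle mean is not positive."""


@dataclass
class GroupMeasurements:
    """Per-animal fibrosis measurements for one study arm (histology totals
    or CT V(-200) values)."""

    group: str
    values: np.ndarray
    matched_vehicle: str = ""
    animal_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise ValueError(f"group {self.group!r} has no measurements")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class EfficacyResult:
    """Drug-vs-matched-vehicle comparison on one readout."""

    drug_group: str
    vehicle_group: str
    normalized_mean_percent: float
    attenuation_percent: float
    t_statistic: float
    degrees_of_freedom: int
    p_two_sided: float
    n_drug: int
    n_vehicle: int


def students_t_test(x: Sequence[float], y: Sequence[float],
                    welch: bool = False) -> tuple[float, float, float]:
    """Unpaired two-tailed Student's t-test.

    Pooled-variance by default (df = n_x + n_y - 2); Welch's unequal-variance
    variant behind ``welch=True``.

    Returns ``(t, df, p_two_sided)``.

    Raises
    ------
    ValueError
        If either sample has fewer than 2 observations.
    DegenerateVarianceError
        If the pooled variance is zero (both samples constant).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise DegenerateVarianceError("zero pooled variance: p-value undefined")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def normalize_to_control(drug: GroupMeasurements, vehicle: GroupMeasurements) -> float:
    """Drug group mean as a percent of the matched vehicle mean (vehicle
    controls normalized to 100%)."""
    if vehicle.mean <= 0:
        raise NormalizationError(
            f"vehicle group {vehicle.group!r} mean {vehicle.mean} is not positive")
    return 100.0 * drug.mean / vehicle.mean


def attenuation(drug: GroupMeasurements, vehicle: GroupMeasurements) -> float:
    """Percent attenuation of fibrosis: 100 minus the normalized drug mean."""
    return 100.0 - normalize_to_control(drug, vehicle)


def compare_to_vehicle(drug: GroupMeasurements, vehicle: GroupMeasurements,
                       welch: bool = False) -> EfficacyResult:
    """Full drug-vs-matched-vehicle readout: normalization, attenuation and
    the Student's t-test."""
    t, df, p = students_t_test(drug.values, vehicle.values, welch=welch)
    norm = normalize_to_control(drug, vehicle)
    return EfficacyResult(
        drug_group=drug.group, vehicle_group=vehicle.group,
        normalized_mean_percent=norm, attenuation_percent=100.0 - norm,
        t_statistic=t, degrees_of_freedom=int(df) if float(df).is_integer() else df,
        p_two_sided=p, n_drug=drug.n, n_vehicle=vehicle.n)


# ---------------------------------------------------------------------------
# PF classification, incidence, mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PfCallCriteria:
    """Dual criterion for calling pulmonary fibrosis in one animal: a
    histology-score cut AND a CT V(-200) cut, both required.

    Defaults: full 12-point trichrome positivity, and V(-200) >= 10% (just
    above the normal-lung < 5% and 12-week < 10% ranges)."""

    histology_cut: float = float(MAX_SCORE)
    v200_cut: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.histology_cut <= MAX_SCORE:
            raise ValueError(f"histology_cut must be in [0, {MAX_SCORE}]")
        if not 0 <= self.v200_cut <= 100:
            raise ValueError("v200_cut must be in [0, 100]")


def classify_pf(histology_total: float, v200_percent: float,
                criteria: PfCallCriteria = PfCallCriteria()) -> bool:
    """True iff BOTH the histology total and the CT V(-200) reach their cuts."""
    return (histology_total >= criteria.histology_cut
            and v200_percent >= criteria.v200_cut)


def pf_incidence(calls: Sequence[bool]) -> float:
    """Percent of animals called PF-positive."""
    calls = list(calls)
    if not calls:
        raise ValueError("pf_incidence requires at least one animal")
    return 100.0 * sum(bool(c) for c in calls) / len(calls)


def mortality(survival: pd.DataFrame, group: str, horizon_week: float) -> float:
    """Percent of a group dead at or before the horizon week.

    ``survival`` has columns ``animal_id, group, death_week`` with empty
    (NaN) death_week for survivors.  Animals dead before the endpoint are
    excluded from endpoint fibrosis summaries and reported here instead.
    """
    rows = survival[survival["group"] == group]
    if rows.empty:
        raise ValueError(f"unknown group {group!r} in survival table")
    dw = pd.to_numeric(rows["death_week"], errors="coerce")
    dead = (dw <= horizon_week).fillna(False)
    return 100.0 * int(dead.sum()) / len(rows)


def surviving_animals(survival: pd.DataFrame, horizon_week: float) -> set[str]:
    """Animal ids alive after the horizon (for endpoint summaries)."""
    dw = pd.to_numeric(survival["death_week"], errors="coerce")
    alive = ~(dw <= horizon_week).fillna(False)
    return set(survival.loc[alive, "animal_id"])


# ---------------------------------------------------------------------------
# timecourses
# ---------------------------------------------------------------------------

@dataclass
class TimecoursePoint:
    """One assay day: replicate summary anchored to the day-0 baseline."""

    assay: str
    day: int
    values: np.ndarray
    mean: float
    sem: float
    relative_level: float
    significant_vs_day0: bool
    p_vs_day0: float


def timecourse_summarize(table: pd.DataFrame, assay: str, baseline_day: int = 0,
                         reference_column: str = "reference",
                         welch: bool = False) -> list[TimecoursePoint]:
    """Summarize an assay timecourse relative to its day-0 baseline.

    Per day: replicate mean, SEM, relative level = day mean / baseline mean
    (so day 0 is exactly 1), and a significance flag from the Student's
    t-test of the day's replicates against baseline at alpha = 0.05.  When a
    reference column is present (normalized-mRNA assays), each replicate is
    first divided by its paired reference value.
    """
    sub = table[table["assay"] == assay].copy()
    if sub.empty:
        raise ValueError(f"assay {assay!r} not found in table")
    values = sub["value"].astype(float)
    if reference_column in sub.columns:
        ref = pd.to_numeric(sub[reference_column], errors="coerce")
        if ref.notna().all():
            if (ref <= 0).any():
                raise ValueError("reference values must be positive")
            values = values / ref
    sub = sub.assign(_v=values)

    by_day = {int(d): g["_v"].to_numpy() for d, g in sub.groupby("day")}
    if baseline_day not in by_day:
        raise ValueError(f"baseline day {baseline_day} missing for assay {assay!r}")
    base = by_day[baseline_day]
    if base.size < 2:
        raise ValueError("baseline needs at least 2 replicates")
    base_mean = float(base.mean())
    if base_mean == 0:
        raise ValueError("baseline mean is zero; relative levels undefined")

    points = []
    for day in sorted(by_day):
        vals = by_day[day]
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        if day == baseline_day:
            sig, p = False, 1.0
        else:
            if vals.size < 2:
                raise ValueError(f"day {day} has fewer than 2 replicates")
            try:
                _, _, p = students_t_test(vals, base, welch=welch)
            except DegenerateVarianceError:
                # identical constant samples: no evidence of change
                p = 1.0 if np.isclose(mean, base_mean) else 0.0
            sig = p < ALPHA
        points.append(TimecoursePoint(
            assay=assay, day=day, values=vals, mean=mean, sem=sem,
            relative_level=mean / base_mean, significant_vs_day0=sig, p_vs_day0=p))
    return points
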