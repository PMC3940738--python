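"""Parameter bundles for the discectomy cost-effectiveness model.

All defaults are the published base-case estimates for privately insured,
working-age patients (2009 USD): clinical probabilities and health-state
utilities from the SPORT pooled cohorts and related literature, direct
medical costs at private-payer levels, and the productivity table (per
age group: SPORT functional-limitation index scores, household earnings,
and the dollar value of missed workdays).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_GROUPS",
    "AGE_WEIGHTS",
    "AGE_MIDPOINTS",
    "ClinicalParams",
    "UtilitySet",
    "CostParams",
    "ProductivityParams",
    "TimingConvention",
    "LifeTable",
    "ValidationError",
    "default_productivity_table",
    "productivity_params_for",
    "load_params_file",
]

AGE_GROUPS = ("<40", "40-44", "45-49", "50-54", "55-59", "60-64")

#: Age distribution of patients receiving discectomy (fractions sum to 1).
AGE_WEIGHTS: Mapping[str, float] = {
    "<40": 0.32, "40-44": 0.15, "45-49": 0.17,
    "50-54": 0.15, "55-59": 0.12, "60-64": 0.09,
}

#: Representative single age per band used for life-table lookup.
AGE_MIDPOINTS: Mapping[str, int] = {
    "<40": 35, "40-44": 42, "45-49": 47,
    "50-54": 52, "55-59": 57, "60-64": 62,
}


class ValidationError(ValueError):
    """A parameter violated its documented bounds."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{name}: {msg}")


@dataclass(frozen=True)
class ClinicalParams:
    """Transition parameters of the treatment-pathway Markov model."""

    p_satisfactory_surgical: float = 0.753
    p_satisfactory_nonsurgical: float = 0.485
    p_satisfactory_after_revision: float = 0.753
    revision_rate_year1: float = 0.06
    revision_rate_subsequent: float = 0.03
    surgical_mortality: float = 0.0013  # per operation
    max_revisions: int = 2

    def validate(self) -> "ClinicalParams":
        for name in ("p_satisfactory_surgical", "p_satisfactory_nonsurgical",
                     "p_satisfactory_after_revision", "revision_rate_year1",
                     "revision_rate_subsequent", "surgical_mortality"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"must be a probability in [0, 1], got {v}")
        _check(self.max_revisions >= 0, "max_revisions", "must be >= 0")
        return self


@dataclass(frozen=True)
class UtilitySet:
    """Health-state preference weights (0 = dead, 1 = perfect health)."""

    satisfactory: float = 0.89
    unsatisfactory: float = 0.56
    revision: float = 0.69  # temporary state during the revision cycle
    dead: float = 0.0

    def validate(self) -> "UtilitySet":
        for name in ("satisfactory", "unsatisfactory", "revision", "dead"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"utility must lie in [0, 1], got {v}")
        _check(self.dead == 0.0, "dead", "dead-state utility must be 0")
        lo, hi = sorted((self.satisfactory, self.unsatisfactory))
        _check(lo <= self.revision <= hi, "revision",
               f"revision utility {self.revision} must lie between "
               f"unsatisfactory ({self.unsatisfactory}) and satisfactory ({self.satisfactory})")
        return self


@dataclass(frozen=True)
class CostParams:
    """Direct medical costs, 2009 USD at private-payer payment levels."""

    surgery_cost_blended: float = 16_423.0
    surgery_cost_inpatient: float = 20_585.0
    surgery_cost_outpatient: float = 11_616.0
    annual_medical_cost_surgical: float = 3_208.0
    annual_medical_cost_nonsurgical: float = 3_794.0

    def surgery_cost(self, setting: str = "overall") -> float:
        try:
            return {
                "overall": self.surgery_cost_blended,
                "inpatient": self.surgery_cost_inpatient,
                "outpatient": self.surgery_cost_outpatient,
            }[setting]
        except KeyError:
            raise ValidationError(
                f"setting: unknown surgery setting {setting!r}; "
                "expected one of overall, inpatient, outpatient") from None

    def validate(self) -> "CostParams":
        for name in ("surgery_cost_blended", "surgery_cost_inpatient",
                     "surgery_cost_outpatient", "annual_medical_cost_surgical",
                     "annual_medical_cost_nonsurgical"):
            _check(getattr(self, name) >= 0, name, "cost must be >= 0")
        _check(self.surgery_cost_outpatient <= self.surgery_cost_blended
               <= self.surgery_cost_inpatient, "surgery_cost_blended",
               "blended surgery cost must lie between outpatient and inpatient costs")
        return self


@dataclass(frozen=True)
class ProductivityParams:
    """Indirect-cost (human-capital) inputs for one patient cohort.

    ``annual_missed_day_value_change`` is the dollar value of the annual
    missed-workday difference (nonsurgical minus surgical), each arm's days
    valued at that arm's earnings per workday.  ``annual_missed_day_reduction``
    is the same difference in days.  A missed day is worth 1/240th of annual
    earnings; recovery from the initial operation costs ``recovery_days``
    valued at the baseline (nonsurgical) wage.
    """

    annual_earnings_premium: float = 1_925.0
    annual_missed_day_reduction: float = 3.0
    annual_missed_day_value_change: float = 523.0
    annual_earnings_surgical: float = 47_619.0
    annual_earnings_nonsurgical: float = 45_694.0
    recovery_days: float = 20.0
    workdays_per_year: float = 240.0

    @property
    def baseline_daily_wage(self) -> float:
        return self.annual_earnings_nonsurgical / self.workdays_per_year

    def validate(self) -> "ProductivityParams":
        _check(self.recovery_days >= 0, "recovery_days", "must be >= 0")
        _check(self.workdays_per_year > 0, "workdays_per_year", "must be > 0")
        _check(self.annual_earnings_nonsurgical >= 0, "annual_earnings_nonsurgical",
               "must be >= 0")
        return self


@dataclass(frozen=True)
class TimingConvention:
    """Accrual timing per value stream and the annual discount rate.

    ``cycle_start`` discounts cycle t by (1+r)^-t (annuity-due),
    ``cycle_end`` by (1+r)^-(t+1) (ordinary annuity), ``half_cycle`` by the
    average of the two.  Productivity offsets may additionally be weighted by
    the surgical arm's alive fraction; the recovery-absenteeism charge can be
    taken undiscounted at t=0 or discounted one cycle.
    """

    utilities: str = "cycle_start"
    annual_costs: str = "cycle_start"
    offsets: str = "cycle_start"
    offsets_survival_weighted: bool = True
    recovery_timing: str = "cycle_0"  # or "cycle_1"
    discount_rate: float = 0.03

    def validate(self) -> "TimingConvention":
        for name in ("utilities", "annual_costs", "offsets"):
            v = getattr(self, name)
            _check(v in ("cycle_start", "cycle_end", "half_cycle"), name,
                   f"unknown accrual timing {v!r}")
        _check(self.recovery_timing in ("cycle_0", "cycle_1"), "recovery_timing",
               f"unknown recovery timing {self.recovery_timing!r}")
        _check(self.discount_rate > -1.0, "discount_rate", "must exceed -1")
        _check(self.discount_rate >= 0.0, "discount_rate", "must be >= 0")
        return self


#: The per-cohort productivity table: SPORT functional scores, predicted
#: household earnings, and predicted value of missed workdays (USD/year),
#: with the surgical-minus-nonsurgical change columns as published.
_PRODUCTIVITY_ROWS = [
    # group, weight, score_s, score_n, earn_s, earn_n, earn_chg, miss_s, miss_n, miss_chg
    ("<40",   0.32, 0.86, 0.77, 44_713, 42_903, 1_810, 1_367, 1_869, 503),
    ("40-44", 0.15, 0.85, 0.75, 50_524, 48_714, 1_810, 1_403, 1_917, 514),
    ("45-49", 0.17, 0.85, 0.75, 49_251, 47_441, 1_810, 1_509, 2_063, 553),
    ("50-54", 0.15, 0.87, 0.74, 48_973, 46_741, 2_232, 1_062, 1_561, 499),
    ("55-59", 0.12, 0.87, 0.74, 48_803, 46_571, 2_232, 1_263, 1_857, 593),
    ("60-64", 0.09, 0.86, 0.76, 46_289, 44_479, 1_810, 1_358, 1_855, 497),
    ("weighted", 1.00, 0.86, 0.76, 47_619, 45_694, 1_925, 1_337, 1_859, 523),
]

_PRODUCTIVITY_COLUMNS = [
    "weight", "score_surgical", "score_nonsurgical",
    "earnings_surgical", "earnings_nonsurgical", "earnings_change",
    "missed_value_surgical", "missed_value_nonsurgical", "missed_value_change",
]


def default_productivity_table() -> pd.DataFrame:
    """Published per-age-group productivity estimates, plus the weighted row."""
    df = pd.DataFrame(
        [row[1:] for row in _PRODUCTIVITY_ROWS],
        index=pd.Index([row[0] for row in _PRODUCTIVITY_ROWS], name="age_group"),
        columns=_PRODUCTIVITY_COLUMNS,
    ).astype(float)
    return df


#: Annual missed-workday reductions (days/year) consistent with the value
#: columns above: weighted 3.0 days; the <40 row's 2.7 days anchors the
#: 40-year-old sensitivity configuration.
MISSED_DAY_REDUCTIONS: Mapping[str, float] = {
    "<40": 2.7, "40-44": 2.4, "45-49": 2.7, "50-54": 2.5,
    "55-59": 2.9, "60-64": 2.6, "weighted": 3.0,
}


def productivity_params_for(group: str = "weighted",
                            table: pd.DataFrame | None = None,
                            recovery_days: float = 20.0,
                            workdays_per_year: float = 240.0) -> ProductivityParams:
    """Build ProductivityParams from one row of a productivity table."""
    table = default_productivity_table() if table is None else table
    if group not in table.index:
        raise ValidationError(f"age_group: unknown group {group!r}; "
                              f"expected one of {list(table.index)}")
    row = table.loc[group]
    return ProductivityParams(
        annual_earnings_premium=float(row["earnings_change"]),
        annual_missed_day_reduction=MISSED_DAY_REDUCTIONS.get(group, 3.0),
        annual_missed_day_value_change=float(row["missed_value_change"]),
        annual_earnings_surgical=float(row["earnings_surgical"]),
        annual_earnings_nonsurgical=float(row["earnings_nonsurgical"]),
        recovery_days=recovery_days,
        workdays_per_year=workdays_per_year,
    ).validate()


class LifeTable:
    """Annual probability of natural death by single year of age.

    The packaged default is a synthetic stand-in for the US life tables:
    log-linear interpolation through both-sex annual mortality anchors of
    roughly 2009 magnitude, ages 18-100.  Lookups outside the tabulated
    range clamp to the nearest endpoint.
    """

    def __init__(self, ages: np.ndarray, qx: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.ndim != 1 or ages.size == 0 or ages.size != qx.size:
            raise ValidationError("life_table: need matching 1-D age and qx columns")
        order = np.argsort(ages)
        self.ages, self.qx = ages[order], qx[order]
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValidationError("life_table: qx values must lie in [0, 1]")
        if not (self.ages.min() <= 18 and self.ages.max() >= 100):
            raise ValidationError("life_table: must cover ages 18-100")

    def q(self, age: float) -> float:
        """Annual death probability at (integer-floored, clamped) age."""
        a = int(np.clip(np.floor(age), self.ages.min(), self.ages.max()))
        return float(self.qx[np.searchsorted(self.ages, a)])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValidationError("life_table: CSV must have columns age,qx")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    @classmethod
    def default(cls) -> "LifeTable":
        ref = resources.files("spinecea.data") / "us_life_table_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


_SECTION_TYPES = {
    "clinical": ClinicalParams,
    "utilities": UtilitySet,
    "costs": CostParams,
    "timing": TimingConvention,
}


def load_params_file(path=None) -> dict:
    """Load a YAML/JSON parameter file, defaulting every missing entry.

    Returns a dict with keys clinical, utilities, costs, timing (validated
    dataclasses), life_table (LifeTable), and productivity_table (DataFrame).
    An empty or absent file yields the full base-case configuration.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("params file: top level must be a mapping")
    out = {}
    for section, cls in _SECTION_TYPES.items():
        overrides = raw.get(section, {}) or {}
        unknown = set(overrides) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"{section}: unknown parameter(s) {sorted(unknown)}")
        out[section] = cls(**overrides).validate()
    lt = raw.get("life_table")
    out["life_table"] = LifeTable.from_csv(lt) if lt else LifeTable.default()
    out["productivity_table"] = default_productivity_table()
    return out


def with_overrides(obj, **kwargs):
    """Return a copy of a frozen parameter dataclass with fields replaced."""
    return replace(obj, **kwargs).validate()
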