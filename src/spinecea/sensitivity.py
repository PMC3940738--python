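"""One-way sensitivity analysis of the 4-year cost-effectiveness result.

Each sweep re-runs the full pipeline twice with a single parameter moved
to the low and high end of its tested range (at least +/-10% around the
base estimate, or the published 95% CI for the productivity effects),
everything else held at base.  The reference patient is a 40-year-old:
the youngest cohort's productivity row (earnings premium $1810/yr, 2.7
fewer missed days/yr) with mortality evaluated from age 40.  Offsets for
this configuration accrue as an unweighted ordinary annuity with the
recovery absence charged at t=0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import pandas as pd

from .economics import ICERResult, run_cea
from .params import (
    ClinicalParams,
    CostParams,
    LifeTable,
    ProductivityParams,
    TimingConvention,
    UtilitySet,
    ValidationError,
    productivity_params_for,
)

__all__ = [
    "SensitivityRange",
    "BaseConfig",
    "base_config",
    "one_way",
    "run_table5",
    "DEFAULT_SWEEPS",
]


@dataclass(frozen=True)
class SensitivityRange:
    """One sweep row: parameter, base, tested range, resulting ICER range.

    ``icer_at_low``/``icer_at_high`` are the ICERs at the low and high end
    of the tested parameter range (the pair is inverted relative to the
    value range when the parameter relationship is negative).
    """

    parameter: str
    base_value: float
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    def validate(self) -> "SensitivityRange":
        if not self.low <= self.base_value <= self.high:
            raise ValidationError(
                f"{self.parameter}: base {self.base_value} outside "
                f"tested range [{self.low}, {self.high}]")
        return self


@dataclass(frozen=True)
class BaseConfig:
    """Base configuration for the reference (40-year-old) patient."""

    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostParams = field(default_factory=CostParams)
    timing: TimingConvention = field(default_factory=lambda: TimingConvention(
        offsets="cycle_end", offsets_survival_weighted=False,
        recovery_timing="cycle_0"))
    productivity: ProductivityParams = field(
        default_factory=lambda: productivity_params_for("<40"))
    start_age: float = 40.0
    horizon: int = 4
    setting: str = "overall"
    life_table: LifeTable | None = None

    def run(self) -> ICERResult:
        return run_cea(horizon=self.horizon, setting=self.setting,
                       clinical=self.clinical, utilities=self.utilities,
                       costs=self.costs, timing=self.timing,
                       life_table=self.life_table,
                       productivity=self.productivity,
                       start_age=self.start_age)


def base_config() -> BaseConfig:
    return BaseConfig()


def _set_missed_days(cfg: BaseConfig, days: float) -> BaseConfig:
    prod = cfg.productivity
    base_days = prod.annual_missed_day_reduction
    if base_days <= 0:
        raise ValidationError("annual_missed_day_reduction: base must be > 0")
    value = prod.annual_missed_day_value_change * days / base_days
    return replace(cfg, productivity=replace(
        prod, annual_missed_day_reduction=days,
        annual_missed_day_value_change=value))


#: parameter name -> function(config, value) -> new config
_SETTERS: dict[str, Callable[[BaseConfig, float], BaseConfig]] = {
    "revision_rate_year1": lambda c, v: replace(
        c, clinical=replace(c.clinical, revision_rate_year1=v)),
    "revision_rate_subsequent": lambda c, v: replace(
        c, clinical=replace(c.clinical, revision_rate_subsequent=v)),
    "p_satisfactory_surgical": lambda c, v: replace(
        c, clinical=replace(c.clinical, p_satisfactory_surgical=v,
                            p_satisfactory_after_revision=v)),
    "p_satisfactory_nonsurgical": lambda c, v: replace(
        c, clinical=replace(c.clinical, p_satisfactory_nonsurgical=v)),
    "u_satisfactory": lambda c, v: replace(
        c, utilities=replace(c.utilities, satisfactory=v)),
    "u_unsatisfactory": lambda c, v: replace(
        c, utilities=replace(c.utilities, unsatisfactory=v)),
    "earnings_premium": lambda c, v: replace(
        c, productivity=replace(c.productivity, annual_earnings_premium=v)),
    "missed_day_reduction": _set_missed_days,
    "surgery_cost": lambda c, v: replace(
        c, costs=replace(c.costs, surgery_cost_blended=v)),
    "annual_medical_cost_surgical": lambda c, v: replace(
        c, costs=replace(c.costs, annual_medical_cost_surgical=v)),
    "annual_medical_cost_nonsurgical": lambda c, v: replace(
        c, costs=replace(c.costs, annual_medical_cost_nonsurgical=v)),
    "recovery_days": lambda c, v: replace(
        c, productivity=replace(c.productivity, recovery_days=v)),
}

_BASE_GETTERS: dict[str, Callable[[BaseConfig], float]] = {
    "revision_rate_year1": lambda c: c.clinical.revision_rate_year1,
    "revision_rate_subsequent": lambda c: c.clinical.revision_rate_subsequent,
    "p_satisfactory_surgical": lambda c: c.clinical.p_satisfactory_surgical,
    "p_satisfactory_nonsurgical": lambda c: c.clinical.p_satisfactory_nonsurgical,
    "u_satisfactory": lambda c: c.utilities.satisfactory,
    "u_unsatisfactory": lambda c: c.utilities.unsatisfactory,
    "earnings_premium": lambda c: c.productivity.annual_earnings_premium,
    "missed_day_reduction": lambda c: c.productivity.annual_missed_day_reduction,
    "surgery_cost": lambda c: c.costs.surgery_cost_blended,
    "annual_medical_cost_surgical": lambda c: c.costs.annual_medical_cost_surgical,
    "annual_medical_cost_nonsurgical": lambda c: c.costs.annual_medical_cost_nonsurgical,
    "recovery_days": lambda c: c.productivity.recovery_days,
}

#: Tested ranges for the standard 12-row sweep (low, high).
DEFAULT_SWEEPS: dict[str, tuple[float, float]] = {
    "revision_rate_year1": (0.04, 0.08),
    "revision_rate_subsequent": (0.01, 0.05),
    "p_satisfactory_surgical": (0.703, 0.803),
    "p_satisfactory_nonsurgical": (0.435, 0.535),
    "u_satisfactory": (0.80, 0.98),
    "u_unsatisfactory": (0.50, 0.62),
    "earnings_premium": (1_054.0, 2_566.0),
    "missed_day_reduction": (2.2, 3.4),
    "surgery_cost": (14_781.0, 18_065.0),
    "annual_medical_cost_surgical": (2_887.0, 3_529.0),
    "annual_medical_cost_nonsurgical": (3_415.0, 4_177.0),
    "recovery_days": (10.0, 30.0),
}


def one_way(param_name: str, low: float, high: float,
            config: BaseConfig | None = None) -> SensitivityRange:
    """Re-run the pipeline at the low and high values of one parameter."""
    if param_name not in _SETTERS:
        raise ValidationError(
            f"parameter: unknown name {param_name!r}; valid names: "
            f"{sorted(_SETTERS)}")
    if low > high:
        raise ValidationError(f"{param_name}: low {low} exceeds high {high}")
    cfg = config if config is not None else base_config()
    setter = _SETTERS[param_name]
    icer_lo = setter(cfg, low).run().icer
    icer_hi = setter(cfg, high).run().icer
    return SensitivityRange(param_name, _BASE_GETTERS[param_name](cfg),
                            low, high, icer_lo, icer_hi).validate()


def run_table5(config: BaseConfig | None = None,
               sweeps: dict[str, tuple[float, float]] | None = None
               ) -> list[SensitivityRange]:
    """The standard one-way sweep over all twelve parameters."""
    cfg = config if config is not None else base_config()
    sweeps = DEFAULT_SWEEPS if sweeps is None else sweeps
    return [one_way(name, lo, hi, cfg) for name, (lo, hi) in sweeps.items()]


def table5_frame(ranges: list[SensitivityRange],
                 base_icer: float | None = None) -> pd.DataFrame:
    df = pd.DataFrame([{
        "parameter": r.parameter,
        "base_value": r.base_value,
        "low": r.low,
        "high": r.high,
        "icer_at_low": r.icer_at_low,
        "icer_at_high": r.icer_at_high,
    } for r in ranges])
    if base_icer is not None:
        df["base_icer"] = base_icer
    return df
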