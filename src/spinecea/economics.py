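"""Incremental cost-effectiveness computation with productivity offsets.

The societal perspective adds two indirect-cost streams to the surgical
arm: an annual household-earnings premium and the change in the dollar
value of missed workdays, net of the one-time 20-workday recovery absence
after the initial operation (a missed day is worth 1/240th of annual
earnings; recovery days are valued at the baseline, i.e. nonsurgical,
wage).  With offsets B (earnings) and C (missed workdays, signed), the net
surgical cost is D = A - B - C and the ICER is (D - F)/(E - G), where A/F
are the arms' discounted direct medical costs and E/G their discounted
QALYs.  A negative incremental net cost with a QALY gain is reported as
dominance (cost saving), never as a negative ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .markov import ArmSummary, discount_factors, run_weighted_arm
from .params import (
    AGE_WEIGHTS,
    ClinicalParams,
    CostParams,
    LifeTable,
    ProductivityParams,
    TimingConvention,
    UtilitySet,
    ValidationError,
    default_productivity_table,
    productivity_params_for,
)

__all__ = [
    "present_value_annuity",
    "earnings_offset",
    "missed_workday_offset",
    "ICERResult",
    "compute_icer",
    "run_cea",
    "horizon_sweep",
    "cost_saving_threshold",
]


def present_value_annuity(annual_amount: float, horizon: int, rate: float,
                          timing: str = "cycle_end") -> float:
    """Present value of a level annual stream over ``horizon`` cycles."""
    if horizon < 1:
        raise ValidationError(f"horizon: must be >= 1, got {horizon}")
    if rate <= -1.0:
        raise ValidationError(f"rate: must exceed -1, got {rate}")
    return float(annual_amount * discount_factors(horizon, rate, timing).sum())


def _pv_stream(annual_amount: float, horizon: int, rate: float, timing: str,
               survival_weights: np.ndarray | None) -> float:
    df = discount_factors(horizon, rate, timing)
    if survival_weights is None:
        return float(annual_amount * df.sum())
    w = np.asarray(survival_weights, dtype=float)
    if w.shape != df.shape:
        raise ValidationError(
            f"survival_weights: expected length {horizon}, got {w.shape}")
    return float(annual_amount * (df * w).sum())


def earnings_offset(productivity: ProductivityParams, horizon: int, rate: float,
                    timing: str = "cycle_start",
                    survival_weights: np.ndarray | None = None) -> float:
    """Present value of the annual earnings premium of surgery (offset B)."""
    return _pv_stream(productivity.annual_earnings_premium, horizon, rate,
                      timing, survival_weights)


def missed_workday_offset(productivity: ProductivityParams, horizon: int,
                          rate: float, daily_wage: float | None = None,
                          timing: str = "cycle_start",
                          survival_weights: np.ndarray | None = None,
                          recovery_timing: str = "cycle_0") -> float:
    """Signed missed-workday offset C (negative = net cost of surgery).

    The recurring part is the annual value of workdays no longer missed;
    the one-time part charges ``recovery_days`` at the baseline wage for the
    initial operation's recovery, either undiscounted at t=0 (``cycle_0``)
    or discounted one cycle (``cycle_1``).
    """
    if daily_wage is None:
        daily_wage = productivity.baseline_daily_wage
    if daily_wage < 0:
        raise ValidationError(f"daily_wage: must be >= 0, got {daily_wage}")
    recurring = _pv_stream(productivity.annual_missed_day_value_change, horizon,
                           rate, timing, survival_weights)
    recovery = productivity.recovery_days * daily_wage
    if recovery_timing == "cycle_1":
        recovery /= (1.0 + rate)
    elif recovery_timing != "cycle_0":
        raise ValidationError(f"recovery_timing: unknown {recovery_timing!r}")
    return recurring - recovery


@dataclass
class ICERResult:
    """Paired arm results and the incremental ratio (one analysis setting)."""

    setting: str
    horizon: int
    surgical_cost: float            # A
    earnings_offset: float          # B
    missed_workday_offset: float    # C (signed; negative = net cost)
    surgical_qaly: float            # E
    nonsurgical_cost: float         # F
    nonsurgical_qaly: float         # G
    include_productivity: bool = True

    @property
    def net_surgical_cost(self) -> float:
        """D = A - B - C when productivity is included, else A."""
        if not self.include_productivity:
            return self.surgical_cost
        return self.surgical_cost - self.earnings_offset - self.missed_workday_offset

    @property
    def incremental_cost(self) -> float:
        return self.net_surgical_cost - self.nonsurgical_cost

    @property
    def incremental_qaly(self) -> float:
        return self.surgical_qaly - self.nonsurgical_qaly

    @property
    def dominant(self) -> bool:
        """Surgery saves money while gaining QALYs (cost saving)."""
        return self.incremental_qaly > 0 and self.incremental_cost <= 0

    @property
    def icer(self) -> float:
        """USD per QALY; NaN when the QALY difference is 0, -inf if dominant."""
        dq = self.incremental_qaly
        if dq == 0:
            return math.nan
        if self.dominant:
            return -math.inf
        return self.incremental_cost / dq

    def to_dict(self) -> dict:
        return {
            "setting": self.setting,
            "horizon": self.horizon,
            "surgical_cost": self.surgical_cost,
            "earnings_offset": self.earnings_offset,
            "missed_workday_offset": self.missed_workday_offset,
            "net_surgical_cost": self.net_surgical_cost,
            "surgical_qaly": self.surgical_qaly,
            "nonsurgical_cost": self.nonsurgical_cost,
            "nonsurgical_qaly": self.nonsurgical_qaly,
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "include_productivity": self.include_productivity,
            "dominant": self.dominant,
            "icer": None if math.isnan(self.icer) else self.icer,
        }


def compute_icer(surgical: ArmSummary | Mapping[str, float],
                 nonsurgical: ArmSummary | Mapping[str, float],
                 offsets: tuple[float, float] = (0.0, 0.0),
                 include_productivity: bool = True,
                 setting: str = "overall") -> ICERResult:
    """Combine two arm summaries and (B, C) offsets into an ICERResult.

    Arms may be ArmSummary objects or mappings with keys ``cost``, ``qaly``
    and ``horizon`` (the latter supports published-table fixtures).
    """
    def unpack(arm):
        if isinstance(arm, ArmSummary):
            return arm.direct_cost, arm.qaly, arm.horizon
        return float(arm["cost"]), float(arm["qaly"]), int(arm["horizon"])

    a, e, h1 = unpack(surgical)
    f, g, h2 = unpack(nonsurgical)
    if h1 != h2:
        raise ValidationError(f"horizon: arms disagree ({h1} vs {h2})")
    b, c = offsets
    return ICERResult(setting=setting, horizon=h1, surgical_cost=a,
                      earnings_offset=b, missed_workday_offset=c,
                      surgical_qaly=e, nonsurgical_cost=f, nonsurgical_qaly=g,
                      include_productivity=include_productivity)


def run_cea(horizon: int = 4,
            setting: str = "overall",
            include_productivity: bool = True,
            age_group: str | None = None,
            clinical: ClinicalParams | None = None,
            utilities: UtilitySet | None = None,
            costs: CostParams | None = None,
            timing: TimingConvention | None = None,
            life_table: LifeTable | None = None,
            productivity: ProductivityParams | None = None,
            productivity_table: pd.DataFrame | None = None,
            start_age: float | None = None,
            age_weights: Mapping[str, float] | None = None,
            revision_accrues_annual_cost: bool = True) -> ICERResult:
    """Full pipeline for one setting/horizon: Markov arms + offsets -> ICER.

    With ``age_group=None`` both arms are run per age cohort and weighted by
    the surgical age distribution, using the weighted productivity row;
    a named ``age_group`` runs that single cohort with its own productivity
    row (``start_age`` overrides the band midpoint when given).
    """
    clinical = (clinical or ClinicalParams()).validate()
    utilities = (utilities or UtilitySet()).validate()
    costs = (costs or CostParams()).validate()
    timing = (timing or TimingConvention()).validate()
    life_table = life_table or LifeTable.default()
    table = default_productivity_table() if productivity_table is None else productivity_table
    group = age_group if age_group is not None else "weighted"
    if productivity is None:
        productivity = productivity_params_for(group, table)
    kwargs = dict(params=clinical, utilities=utilities, costs=costs,
                  life_table=life_table, timing=timing,
                  horizon_years=horizon, setting=setting,
                  revision_accrues_annual_cost=revision_accrues_annual_cost)
    if age_group is None and start_age is None:
        kwargs["age_weights"] = age_weights
    else:
        from .params import AGE_MIDPOINTS
        kwargs["start_age"] = (start_age if start_age is not None
                               else AGE_MIDPOINTS[age_group])
    surg = run_weighted_arm("surgical", **kwargs)
    nonsurg = run_weighted_arm("nonsurgical", **kwargs)
    sw = surg.alive if timing.offsets_survival_weighted else None
    b = earnings_offset(productivity, horizon, timing.discount_rate,
                        timing=timing.offsets, survival_weights=sw)
    c = missed_workday_offset(productivity, horizon, timing.discount_rate,
                              timing=timing.offsets, survival_weights=sw,
                              recovery_timing=timing.recovery_timing)
    return compute_icer(surg, nonsurg, (b, c),
                        include_productivity=include_productivity,
                        setting=setting)


def horizon_sweep(horizons=range(1, 16), setting: str = "overall",
                  include_productivity: bool = True, **kwargs) -> pd.DataFrame:
    """ICER per time horizon (the benefit-duration sweep).

    Returns a frame with one row per horizon: icer (NaN while the QALY
    difference is 0, -inf once dominant), incremental cost and QALYs, and a
    ``dominant`` flag.  Under base parameters the ICER is non-increasing in
    horizon and eventually turns cost saving.
    """
    rows = []
    for h in horizons:
        res = run_cea(horizon=int(h), setting=setting,
                      include_productivity=include_productivity, **kwargs)
        rows.append({"horizon": int(h), "icer": res.icer,
                     "incremental_cost": res.incremental_cost,
                     "incremental_qaly": res.incremental_qaly,
                     "dominant": res.dominant})
    return pd.DataFrame(rows)


def cost_saving_threshold(setting: str = "overall", max_horizon: int = 20,
                          **kwargs) -> int | None:
    """First horizon (years) at which surgery's net incremental cost <= 0."""
    for h in range(1, max_horizon + 1):
        res = run_cea(horizon=h, setting=setting, include_productivity=True,
                      **kwargs)
        if res.incremental_cost <= 0:
            return h
    return None
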