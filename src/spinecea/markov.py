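"""Deterministic annual-cycle Markov cohort model of discectomy outcomes.

Two treatment arms are simulated over yearly cycles.  Nonsurgical patients
split once into a satisfactory or unsatisfactory state and stay there until
natural death.  Surgical patients face a per-operation mortality risk, may
need revision surgery (6% in the first year, 3%/year thereafter, at most two
revisions), and spend the revision year in a temporary state before settling
into a satisfactory or unsatisfactory outcome with the same success
probability as the primary operation.  Death is absorbing.

States are expanded by revision count r: ``sat(r)``/``unsat(r)`` for
r = 0..max_revisions and a temporary ``rev(j)`` state (the cohort member is
undergoing their j-th revision).  Occupancy is tracked at the start of each
cycle; utilities and annual medical costs accrue per the configured timing
convention, the initial surgery cost accrues undiscounted at t=0, and each
cycle's revision-state occupancy is charged the revision surgery cost
(discounted), plus by default the annual medical cost as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    AGE_MIDPOINTS,
    AGE_WEIGHTS,
    ClinicalParams,
    CostParams,
    LifeTable,
    TimingConvention,
    UtilitySet,
    ValidationError,
)

__all__ = [
    "CohortTrace",
    "state_space",
    "build_transitions",
    "run_cohort",
    "age_weighted_traces",
    "run_weighted_arm",
]

DEAD = "dead"


def state_space(max_revisions: int, arm: str) -> list[str]:
    """Ordered state labels for one arm."""
    if arm == "nonsurgical":
        return ["sat0", "unsat0", DEAD]
    states = []
    for r in range(max_revisions + 1):
        states += [f"sat{r}", f"unsat{r}"]
    states += [f"rev{j}" for j in range(1, max_revisions + 1)]
    states.append(DEAD)
    return states


def _discount_exponent(t: np.ndarray, timing: str) -> np.ndarray:
    if timing == "cycle_start":
        return t.astype(float)
    if timing == "cycle_end":
        return t + 1.0
    if timing == "half_cycle":
        return t + 0.5
    raise ValidationError(f"timing: unknown accrual timing {timing!r}")


def discount_factors(horizon: int, rate: float, timing: str) -> np.ndarray:
    t = np.arange(horizon)
    return (1.0 + rate) ** -_discount_exponent(t, timing)


def build_transitions(params: ClinicalParams, life_table: LifeTable, age: float,
                      cycle_index: int, arm: str) -> dict[str, dict[str, float]]:
    """One-cycle transition mapping ``state -> {state: probability}``.

    ``age`` is the cohort age during the cycle; natural mortality applies to
    every alive state.  In the surgical arm, survivors of ``rev(j)`` resolve to
    ``sat(j)``/``unsat(j)``; survivors of ``sat(r)``/``unsat(r)`` with
    r < max_revisions undergo revision at the subsequent-year rate (the
    first-year rate applies in the initial cohort split, not here), incurring
    per-operation mortality on entry.  Every row sums to 1.
    """
    if arm not in ("surgical", "nonsurgical"):
        raise ValidationError(f"arm: unknown arm {arm!r}")
    q = life_table.q(age)
    m = params.surgical_mortality
    rev_rate = (params.revision_rate_year1 if cycle_index == 0
                else params.revision_rate_subsequent)
    out: dict[str, dict[str, float]] = {}
    if arm == "nonsurgical":
        for s in ("sat0", "unsat0"):
            out[s] = {s: 1.0 - q, DEAD: q}
        out[DEAD] = {DEAD: 1.0}
        return out
    R = params.max_revisions
    p_rev = params.p_satisfactory_after_revision
    for r in range(R + 1):
        for kind in ("sat", "unsat"):
            s = f"{kind}{r}"
            row = {DEAD: q}
            stay = 1.0 - q
            if r < R:
                entrants = stay * rev_rate
                stay -= entrants
                row[f"rev{r + 1}"] = entrants * (1.0 - m)
                row[DEAD] += entrants * m
            row[s] = stay
            out[s] = row
    for j in range(1, R + 1):
        out[f"rev{j}"] = {
            f"sat{j}": (1.0 - q) * p_rev,
            f"unsat{j}": (1.0 - q) * (1.0 - p_rev),
            DEAD: q,
        }
    out[DEAD] = {DEAD: 1.0}
    for s, row in out.items():
        if not np.isclose(sum(row.values()), 1.0, atol=1e-12):
            raise ValidationError(f"transitions: row {s} sums to {sum(row.values())}")
    return out


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accumulators for one arm."""

    arm: str
    states: list[str]
    occupancy: np.ndarray          # shape (horizon, n_states), cycle-start shares
    qaly_per_cycle: np.ndarray     # discounted QALY contribution per cycle
    cost_per_cycle: np.ndarray     # discounted direct-cost contribution per cycle
    alive: np.ndarray              # alive fraction at cycle start
    start_age: float
    discount_rate: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    @property
    def qaly(self) -> float:
        return float(self.qaly_per_cycle.sum())

    @property
    def direct_cost(self) -> float:
        return float(self.cost_per_cycle.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.states)
        df.insert(0, "cycle", np.arange(self.horizon))
        df["alive"] = self.alive
        df["qaly_discounted"] = self.qaly_per_cycle
        df["cost_discounted"] = self.cost_per_cycle
        return df


def _initial_distribution(arm: str, params: ClinicalParams,
                          states: list[str]) -> np.ndarray:
    occ = np.zeros(len(states))
    idx = {s: i for i, s in enumerate(states)}
    if arm == "nonsurgical":
        occ[idx["sat0"]] = params.p_satisfactory_nonsurgical
        occ[idx["unsat0"]] = 1.0 - params.p_satisfactory_nonsurgical
        return occ
    m = params.surgical_mortality
    alive = 1.0 - m
    dead = m
    rev_in = alive * params.revision_rate_year1
    if params.max_revisions >= 1:
        occ[idx["rev1"]] = rev_in * (1.0 - m)  # revision is itself an operation
        dead += rev_in * m
        alive -= rev_in
    occ[idx["sat0"]] = alive * params.p_satisfactory_surgical
    occ[idx["unsat0"]] = alive * (1.0 - params.p_satisfactory_surgical)
    occ[idx[DEAD]] = dead
    return occ


def run_cohort(arm: str,
               params: ClinicalParams,
               utilities: UtilitySet,
               costs: CostParams,
               life_table: LifeTable,
               timing: TimingConvention,
               start_age: float,
               horizon_years: int,
               setting: str = "overall",
               revision_cost: float | None = None,
               revision_accrues_annual_cost: bool = True) -> CohortTrace:
    """Simulate one arm for ``horizon_years`` annual cycles.

    The revision surgery cost defaults to the initial surgery cost for the
    chosen setting.  Age advances one year per cycle for life-table lookup.
    """
    if horizon_years < 1:
        raise ValidationError(f"horizon_years: must be >= 1, got {horizon_years}")
    params.validate(); utilities.validate(); costs.validate(); timing.validate()
    states = state_space(params.max_revisions, arm)
    idx = {s: i for i, s in enumerate(states)}
    util = np.array([
        utilities.dead if s == DEAD
        else utilities.revision if s.startswith("rev")
        else utilities.satisfactory if s.startswith("sat")
        else utilities.unsatisfactory
        for s in states
    ])
    surgery_cost = costs.surgery_cost(setting)
    if revision_cost is None:
        revision_cost = surgery_cost
    annual_cost = (costs.annual_medical_cost_surgical if arm == "surgical"
                   else costs.annual_medical_cost_nonsurgical)
    alive_mask = np.array([s != DEAD for s in states], dtype=float)
    annual_cost_mask = alive_mask.copy()
    if not revision_accrues_annual_cost:
        for s in states:
            if s.startswith("rev"):
                annual_cost_mask[idx[s]] = 0.0
    rev_mask = np.array([float(s.startswith("rev")) for s in states])

    occ = _initial_distribution(arm, params, states)
    occupancy = np.zeros((horizon_years, len(states)))
    qaly = np.zeros(horizon_years)
    cost = np.zeros(horizon_years)
    alive = np.zeros(horizon_years)
    df_util = discount_factors(horizon_years, timing.discount_rate, timing.utilities)
    df_cost = discount_factors(horizon_years, timing.discount_rate, timing.annual_costs)
    # Surgery costs are event costs tied to the operation date: the initial
    # operation at t=0 (undiscounted) and revision-state occupancy at its cycle.
    df_event = discount_factors(horizon_years, timing.discount_rate, "cycle_start")

    for t in range(horizon_years):
        occupancy[t] = occ
        alive[t] = float(occ @ alive_mask)
        qaly[t] = float(occ @ util) * df_util[t]
        cost[t] = float(occ @ annual_cost_mask) * annual_cost * df_cost[t]
        cost[t] += float(occ @ rev_mask) * revision_cost * df_event[t]
        if arm == "surgical" and t == 0:
            cost[t] += surgery_cost  # whole cohort operated on at t=0
        if t + 1 < horizon_years:
            # The first-year revision risk is part of the initial cohort split;
            # the transition out of cycle t governs events in year t+2.
            trans = build_transitions(params, life_table, start_age + t, t + 1, arm)
            nxt = np.zeros_like(occ)
            for s, row in trans.items():
                for s2, p in row.items():
                    nxt[idx[s2]] += occ[idx[s]] * p
            occ = nxt
    trace = CohortTrace(arm=arm, states=states, occupancy=occupancy,
                        qaly_per_cycle=qaly, cost_per_cycle=cost, alive=alive,
                        start_age=start_age, discount_rate=timing.discount_rate)
    _check_trace(trace)
    return trace


def _check_trace(trace: CohortTrace) -> None:
    sums = trace.occupancy.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise ValidationError(f"trace: occupancy sums deviate from 1 by "
                              f"{np.abs(sums - 1).max():.2e}")
    if np.any(trace.occupancy < -1e-15):
        raise ValidationError("trace: negative occupancy")
    dead = trace.occupancy[:, trace.states.index(DEAD)]
    if np.any(np.diff(dead) < -1e-12):
        raise ValidationError("trace: dead occupancy decreased")


@dataclass
class ArmSummary:
    """Discounted totals for one arm (possibly age-weighted)."""

    arm: str
    horizon: int
    qaly: float
    direct_cost: float
    alive: np.ndarray  # alive fraction at each cycle start
    discount_rate: float

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "ArmSummary":
        return cls(trace.arm, trace.horizon, trace.qaly, trace.direct_cost,
                   trace.alive.copy(), trace.discount_rate)


def age_weighted_traces(per_age_results: Mapping[str, CohortTrace | ArmSummary],
                        age_distribution: Mapping[str, float]) -> ArmSummary:
    """Weighted mean of per-age-cohort results under the surgery age mix."""
    wsum = sum(age_distribution.values())
    if not np.isclose(wsum, 1.0, atol=1e-9):
        raise ValidationError(f"age_distribution: weights sum to {wsum}, expected 1")
    missing = set(age_distribution) - set(per_age_results)
    if missing:
        raise ValidationError(f"per_age_results: missing age group(s) {sorted(missing)}")
    qaly = cost = 0.0
    alive = None
    arm = horizon = rate = None
    for g, w in age_distribution.items():
        res = per_age_results[g]
        summ = res if isinstance(res, ArmSummary) else ArmSummary.from_trace(res)
        if horizon is None:
            arm, horizon, rate = summ.arm, summ.horizon, summ.discount_rate
            alive = np.zeros(horizon)
        elif summ.horizon != horizon:
            raise ValidationError("per_age_results: mismatched horizons")
        qaly += w * summ.qaly
        cost += w * summ.direct_cost
        alive += w * summ.alive
    return ArmSummary(arm, horizon, qaly, cost, alive, rate)


def run_weighted_arm(arm: str,
                     params: ClinicalParams,
                     utilities: UtilitySet,
                     costs: CostParams,
                     life_table: LifeTable,
                     timing: TimingConvention,
                     horizon_years: int,
                     setting: str = "overall",
                     age_weights: Mapping[str, float] | None = None,
                     start_age: float | None = None,
                     revision_accrues_annual_cost: bool = True) -> ArmSummary:
    """Run one arm for every age cohort and weight, or for a single start age."""
    if start_age is not None:
        trace = run_cohort(arm, params, utilities, costs, life_table, timing,
                           start_age, horizon_years, setting,
                           revision_accrues_annual_cost=revision_accrues_annual_cost)
        return ArmSummary.from_trace(trace)
    weights = dict(age_weights if age_weights is not None else AGE_WEIGHTS)
    traces = {
        g: run_cohort(arm, params, utilities, costs, life_table, timing,
                      AGE_MIDPOINTS[g], horizon_years, setting,
                      revision_accrues_annual_cost=revision_accrues_annual_cost)
        for g in weights
    }
    return age_weighted_traces(traces, weights)
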