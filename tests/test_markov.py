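"""Markov cohort engine: transitions, conservation, closed forms, oracle."""

import numpy as np
import pytest
from helpers_oracle import enumerate_expectations

from conftest import flat_life_table, random_clinical, random_utilities
from spinecea.markov import (
    ArmSummary,
    age_weighted_traces,
    build_transitions,
    run_cohort,
)
from spinecea.params import (
    AGE_WEIGHTS,
    ClinicalParams,
    CostParams,
    LifeTable,
    TimingConvention,
    UtilitySet,
    ValidationError,
)


def run(arm="surgical", clinical=None, utilities=None, costs=None,
        life_table=None, timing=None, start_age=45, horizon=4, **kw):
    return run_cohort(arm, clinical or ClinicalParams(),
                      utilities or UtilitySet(), costs or CostParams(),
                      life_table or LifeTable.default(),
                      timing or TimingConvention(), start_age, horizon, **kw)


class TestTransitions:
    def test_nonsurgical_rows_are_stay_or_die(self, default_life_table):
        trans = build_transitions(ClinicalParams(), default_life_table, 50, 3,
                                  "nonsurgical")
        q = default_life_table.q(50)
        for s in ("sat0", "unsat0"):
            assert set(trans[s]) == {s, "dead"}
            assert trans[s]["dead"] == pytest.approx(q)
            assert sum(trans[s].values()) == pytest.approx(1.0)

    def test_no_mortality_no_revision_is_identity_on_alive_states(self,
                                                                  zero_mortality):
        params = ClinicalParams(revision_rate_year1=0.0,
                                revision_rate_subsequent=0.0,
                                surgical_mortality=0.0)
        trans = build_transitions(params, zero_mortality, 40, 2, "surgical")
        for s, row in trans.items():
            if s == "dead":
                continue
            if s.startswith("rev"):
                continue  # temporary state always resolves
            assert row[s] == pytest.approx(1.0)

    def test_first_year_vs_subsequent_revision_rates(self, zero_mortality):
        params = ClinicalParams(surgical_mortality=0.0)
        first = build_transitions(params, zero_mortality, 40, 0, "surgical")
        later = build_transitions(params, zero_mortality, 42, 2, "surgical")
        assert first["sat0"]["rev1"] == pytest.approx(0.06)
        assert later["sat0"]["rev1"] == pytest.approx(0.03)

    def test_capped_states_have_no_revision_exit(self, zero_mortality):
        trans = build_transitions(ClinicalParams(), zero_mortality, 40, 2,
                                  "surgical")
        assert "rev3" not in trans["sat2"]
        assert set(trans["sat2"]) == {"sat2", "dead"}

    def test_every_row_sums_to_one_under_random_params(self,
                                                       default_life_table):
        rng = np.random.default_rng(123)
        for _ in range(200):
            params = random_clinical(rng)
            for arm in ("surgical", "nonsurgical"):
                trans = build_transitions(params, default_life_table,
                                          rng.uniform(20, 90),
                                          int(rng.integers(0, 5)), arm)
                for row in trans.values():
                    assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)


class TestRunCohort:
    def test_perfect_utilities_no_mortality_conserve_person_years(self,
                                                                  zero_mortality):
        params = ClinicalParams(revision_rate_year1=0.0,
                                revision_rate_subsequent=0.0,
                                surgical_mortality=0.0)
        utils = UtilitySet(satisfactory=1.0, unsatisfactory=1.0, revision=1.0)
        timing = TimingConvention(discount_rate=0.0)
        trace = run(clinical=params, utilities=utils, timing=timing,
                    life_table=zero_mortality, horizon=4)
        assert trace.qaly == pytest.approx(4.0, abs=1e-12)

    def test_nonsurgical_closed_form_annuity(self, zero_mortality):
        # no mortality, cycle-start accrual: mixture utility times annuity-due
        trace = run(arm="nonsurgical", life_table=zero_mortality, horizon=4)
        mix = 0.485 * 0.89 + 0.515 * 0.56
        annuity = sum(1.03 ** -t for t in range(4))
        assert trace.qaly == pytest.approx(mix * annuity, abs=1e-9)

    def test_surgical_closed_form_without_revisions(self, zero_mortality):
        params = ClinicalParams(revision_rate_year1=0.0,
                                revision_rate_subsequent=0.0)
        trace = run(clinical=params, life_table=zero_mortality, horizon=5)
        m = params.surgical_mortality
        mix = 0.753 * 0.89 + 0.247 * 0.56
        annuity = sum(1.03 ** -t for t in range(5))
        assert trace.qaly == pytest.approx((1 - m) * mix * annuity, abs=1e-10)

    def test_occupancy_conserved_and_dead_monotone(self, default_life_table):
        trace = run(horizon=15, life_table=default_life_table)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        dead = trace.occupancy[:, trace.states.index("dead")]
        assert (np.diff(dead) >= -1e-15).all()
        assert (np.diff(trace.alive) <= 1e-15).all()

    def test_raising_utility_raises_qaly(self):
        lo = run(utilities=UtilitySet(satisfactory=0.85))
        hi = run(utilities=UtilitySet(satisfactory=0.95))
        assert hi.qaly > lo.qaly

    def test_raising_mortality_lowers_qaly(self):
        lo = run(life_table=flat_life_table(0.001))
        hi = run(life_table=flat_life_table(0.05))
        assert hi.qaly < lo.qaly

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValidationError, match="horizon"):
            run(horizon=0)

    def test_trace_frame_has_one_row_per_cycle(self):
        trace = run(horizon=6)
        df = trace.to_frame()
        assert list(df["cycle"]) == list(range(6))
        assert set(trace.states) <= set(df.columns)


class TestEnumerationOracle:
    @pytest.mark.parametrize("arm", ["surgical", "nonsurgical"])
    @pytest.mark.parametrize("horizon", [1, 2, 3])
    def test_engine_equals_path_enumeration(self, arm, horizon,
                                            default_life_table):
        rng = np.random.default_rng(2026)
        for _ in range(20):
            params = random_clinical(rng)
            params = ClinicalParams(**{**params.__dict__, "max_revisions": 1})
            utils = random_utilities(rng)
            costs = CostParams()
            timing = TimingConvention()
            trace = run_cohort(arm, params, utils, costs, default_life_table,
                               timing, 55, horizon)
            q, c = enumerate_expectations(arm, params, utils, costs,
                                          default_life_table, timing, 55,
                                          horizon)
            assert trace.qaly == pytest.approx(q, abs=1e-10)
            assert trace.direct_cost == pytest.approx(c, abs=1e-7)


class TestAgeWeighting:
    def _summary(self, qaly, cost, horizon=4):
        return ArmSummary("surgical", horizon, qaly, cost,
                          np.ones(horizon), 0.03)

    def test_identical_results_are_unchanged(self):
        res = {g: self._summary(3.0, 30_000.0) for g in AGE_WEIGHTS}
        out = age_weighted_traces(res, AGE_WEIGHTS)
        assert out.qaly == pytest.approx(3.0)
        assert out.direct_cost == pytest.approx(30_000.0)

    def test_degenerate_weights_select_one_group(self):
        res = {"a": self._summary(2.0, 10.0), "b": self._summary(5.0, 99.0)}
        out = age_weighted_traces(res, {"a": 1.0, "b": 0.0})
        assert out.qaly == 2.0 and out.direct_cost == 10.0

    def test_missing_group_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            age_weighted_traces({"a": self._summary(1, 1)}, {"a": 0.5, "b": 0.5})

    def test_weights_must_sum_to_one(self):
        res = {"a": self._summary(1, 1)}
        with pytest.raises(ValidationError, match="sum"):
            age_weighted_traces(res, {"a": 0.7})

    def test_published_weights_on_earnings_changes(self):
        # age weights applied to the per-age earnings-change column
        from spinecea.params import default_productivity_table
        table = default_productivity_table().drop(index="weighted")
        weighted = float(sum(AGE_WEIGHTS[g] * table.loc[g, "earnings_change"]
                             for g in AGE_WEIGHTS))
        assert weighted == pytest.approx(1_925, rel=0.001)
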