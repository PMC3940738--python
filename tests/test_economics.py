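"""Annuities, productivity offsets, ICER identities and the horizon sweep."""

import math

import numpy as np
import pytest

from spinecea.economics import (
    compute_icer,
    cost_saving_threshold,
    earnings_offset,
    horizon_sweep,
    missed_workday_offset,
    present_value_annuity,
    run_cea,
)
from spinecea.params import (
    ClinicalParams,
    CostParams,
    ProductivityParams,
    ValidationError,
)

#: Published 4-year cost-effectiveness row used for arithmetic-identity checks
#: (A, B, C, E, F, G as printed; C in parentheses in print = negative).
PRINTED_OVERALL = dict(A=30_900.0, B=7_251.0, C=-1_648.0, E=3.04,
                       F=14_402.0, G=2.73)


def printed_result(include_productivity=True, A=None):
    row = PRINTED_OVERALL
    return compute_icer(
        {"cost": A if A is not None else row["A"], "qaly": row["E"], "horizon": 4},
        {"cost": row["F"], "qaly": row["G"], "horizon": 4},
        offsets=(row["B"], row["C"]),
        include_productivity=include_productivity)


class TestAnnuity:
    def test_zero_rate_is_amount_times_horizon(self):
        assert present_value_annuity(100.0, 7, 0.0) == pytest.approx(700.0)

    @pytest.mark.parametrize("horizon", [1, 4, 8, 15])
    def test_cycle_end_matches_closed_form(self, horizon):
        expected = 1_925 * sum(1.03 ** -t for t in range(1, horizon + 1))
        got = present_value_annuity(1_925, horizon, 0.03, "cycle_end")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_cycle_start_exceeds_cycle_end_at_positive_rate(self):
        due = present_value_annuity(1.0, 5, 0.03, "cycle_start")
        ordinary = present_value_annuity(1.0, 5, 0.03, "cycle_end")
        assert due == pytest.approx(ordinary * 1.03)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            present_value_annuity(1.0, 0, 0.03)
        with pytest.raises(ValidationError):
            present_value_annuity(1.0, 4, -1.5)


class TestOffsets:
    def test_zero_premium_gives_zero_offset(self):
        prod = ProductivityParams(annual_earnings_premium=0.0)
        assert earnings_offset(prod, 4, 0.03, timing="cycle_end") == 0.0

    def test_eight_year_unweighted_premium_closed_form(self):
        prod = ProductivityParams()  # weighted premium $1925/yr
        expected = 1_925 * sum(1.03 ** -t for t in range(1, 9))
        got = earnings_offset(prod, 8, 0.03, timing="cycle_end")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_survival_weighting_shrinks_the_offset(self):
        prod = ProductivityParams()
        weights = np.array([1.0, 0.99, 0.98, 0.97])
        full = earnings_offset(prod, 4, 0.03)
        weighted = earnings_offset(prod, 4, 0.03, survival_weights=weights)
        assert weighted < full

    def test_no_recovery_no_reduction_is_zero(self):
        prod = ProductivityParams(annual_missed_day_value_change=0.0,
                                  recovery_days=0.0)
        assert missed_workday_offset(prod, 4, 0.03) == 0.0

    def test_recovery_dominates_over_short_horizon(self):
        # ~3 days/yr regained vs 20 recovery days: net cost at 4 years,
        # magnitude in the $1.5k-1.9k range
        prod = ProductivityParams()
        c = missed_workday_offset(prod, 4, 0.03, timing="cycle_end",
                                  recovery_timing="cycle_1")
        assert -1_900 < c < -1_400

    def test_negative_wage_rejected(self):
        with pytest.raises(ValidationError, match="daily_wage"):
            missed_workday_offset(ProductivityParams(), 4, 0.03, daily_wage=-1.0)


class TestICER:
    def test_identical_arms_have_undefined_ratio(self):
        arm = {"cost": 10_000.0, "qaly": 2.5, "horizon": 4}
        res = compute_icer(arm, dict(arm))
        assert res.incremental_qaly == 0.0
        assert math.isnan(res.icer)
        assert not res.dominant

    def test_published_overall_row_identities(self):
        res = printed_result()
        # D = A - B - C on unrounded values
        assert res.net_surgical_cost == pytest.approx(25_297.0, abs=1e-9)
        expected = (25_297.0 - 14_402.0) / (3.04 - 2.73)
        assert res.icer == pytest.approx(expected, rel=1e-12)
        assert res.icer == pytest.approx(35_146, abs=35)

    def test_outpatient_substitution_matches_published_ratio(self):
        res = printed_result(A=25_406.0)
        assert res.net_surgical_cost == pytest.approx(19_803.0)
        assert res.icer == pytest.approx(17_423, abs=18)

    def test_productivity_flag_drops_offsets(self):
        with_p = printed_result()
        without = printed_result(include_productivity=False)
        assert without.net_surgical_cost == PRINTED_OVERALL["A"]
        assert with_p.icer <= without.icer  # B + C > 0 here

    def test_dominance_reported_as_flag_not_negative_ratio(self):
        res = compute_icer({"cost": 9_000.0, "qaly": 3.0, "horizon": 4},
                           {"cost": 14_000.0, "qaly": 2.7, "horizon": 4})
        assert res.dominant
        assert res.icer == -math.inf

    def test_mismatched_horizons_rejected(self):
        with pytest.raises(ValidationError, match="horizon"):
            compute_icer({"cost": 1.0, "qaly": 1.0, "horizon": 4},
                         {"cost": 1.0, "qaly": 1.0, "horizon": 8})


class TestPipelineMonotonicity:
    def test_icer_increases_with_surgery_cost(self):
        icers = [run_cea(costs=CostParams(surgery_cost_blended=c)).icer
                 for c in (14_781.0, 16_423.0, 18_065.0)]
        assert icers[0] < icers[1] < icers[2]

    def test_icer_decreases_with_surgical_success(self):
        icers = [run_cea(clinical=ClinicalParams(p_satisfactory_surgical=p)).icer
                 for p in (0.703, 0.753, 0.803)]
        assert icers[0] > icers[1] > icers[2]

    def test_offsets_enter_surgical_arm_only(self):
        res = run_cea()
        base_f = res.nonsurgical_cost
        no_prod = run_cea(include_productivity=False)
        assert no_prod.nonsurgical_cost == pytest.approx(base_f)
        assert no_prod.net_surgical_cost > res.net_surgical_cost


@pytest.fixture(scope="module")
def sweep():
    return horizon_sweep(horizons=range(1, 16))


class TestHorizonSweep:
    def test_icer_non_increasing_in_horizon(self, sweep):
        vals = sweep["icer"].to_numpy()  # -inf once cost saving
        assert (vals[1:] <= vals[:-1] + 1e-9).all()

    def test_reports_first_cost_saving_horizon(self, sweep):
        threshold = cost_saving_threshold()
        assert threshold is not None
        assert sweep.loc[sweep["horizon"] == threshold, "dominant"].item()
        assert not sweep.loc[sweep["horizon"] == threshold - 1, "dominant"].item()
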