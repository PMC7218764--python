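"""Discounting, cost/DALY accrual, ICER and net monetary benefit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhdcea import LifeTable
from rhdcea.engine import CohortTrace
from rhdcea.outcomes import (
    ScenarioResult,
    accrue_costs,
    accrue_dalys,
    compare,
    discount_factor,
    evaluate_strategy,
)
from rhdcea.scenarios import build_standard_care
from rhdcea.synthetic import generate_toy_bundle
from tests.test_engine import space


def scenario(name, cost, dalys):
    return ScenarioResult(name=name, total_cost=cost, total_dalys=dalys,
                         one_time_costs=0.0, yld=dalys, yll=0.0)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        ("rate", "cycle", "expected"),
        [(0.03, 0, 1.0), (0.03, 1, 1 / 1.03), (0.0, 30, 1.0), (0.05, 2, 1.05**-2)],
    )
    def test_closed_form(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


def single_state_trace(occupants, n_cycles, n_states=2, state=0):
    occ = np.zeros((n_cycles + 1, n_states))
    occ[:, state] = occupants
    return CohortTrace(occ, space(n_states))


class TestAccrueCosts:
    def test_zero_costs_zero_total(self):
        trace = single_state_trace(5.0, 3)
        total, one_time, _ = accrue_costs(trace, np.zeros(2), [], 0.03)
        assert total == 0.0 and one_time == 0.0

    def test_one_person_one_cycle_undiscounted(self):
        """One person in the post-surgery state for one cycle costs $854."""
        trace = single_state_trace(1.0, 1)
        total, _, _ = accrue_costs(trace, np.array([854.0, 0.0]), [], 0.0)
        assert total == pytest.approx(854.0)

    def test_two_cycle_discounted_hand_computation(self):
        trace = single_state_trace(1.0, 2)
        total, _, _ = accrue_costs(trace, np.array([854.0, 0.0]), [], 0.03)
        assert total == pytest.approx(854.0 * (1 / 1.03 + 1 / 1.03**2), rel=1e-12)

    def test_one_time_amounts_discounted_at_their_cycle(self):
        trace = single_state_trace(0.0, 2)
        total, one_time, _ = accrue_costs(
            trace, np.zeros(2), [(0, 100.0, "scan"), (2, 103.0, "x")], 0.03
        )
        assert one_time == pytest.approx(100.0 + 103.0 / 1.03**2)
        assert total == one_time

    def test_half_cycle_correction_is_trapezoid(self):
        """Half-cycle totals integrate rows 0..n with endpoint weight 0.5."""
        trace = single_state_trace(1.0, 3)
        total, _, _ = accrue_costs(trace, np.array([100.0, 0.0]), [], 0.03,
                                   half_cycle=True)
        expected = 100.0 * (0.5 + 1.03**-1 + 1.03**-2 + 0.5 * 1.03**-3)
        assert total == pytest.approx(expected, rel=1e-12)
        lo_end, _, _ = accrue_costs(trace, np.array([100.0, 0.0]), [], 0.03, "end")
        hi_begin, _, _ = accrue_costs(trace, np.array([100.0, 0.0]), [], 0.03, "begin")
        assert lo_end <= total <= hi_begin

    def test_begin_accrual_uses_previous_row(self):
        occ = np.array([[1.0, 0.0], [0.0, 1.0]])
        trace = CohortTrace(occ, space(2))
        end, _, _ = accrue_costs(trace, np.array([10.0, 0.0]), [], 0.0, "end")
        begin, _, _ = accrue_costs(trace, np.array([10.0, 0.0]), [], 0.0, "begin")
        assert end == 0.0 and begin == 10.0


class TestAccrueDalys:
    lt = LifeTable([0, 100], [80.0, 10.0])

    def test_no_morbidity_no_mortality_zero(self):
        trace = single_state_trace(3.0, 5)
        total, yld, yll, _ = accrue_dalys(trace, np.zeros(2), self.lt, 11, 0.03)
        assert total == yld == yll == 0.0

    def test_single_death_undiscounted_equals_expectancy(self):
        lt = LifeTable([0, 100], [2.0, 2.0], monotonicity_tol=1e-9)
        occ = np.array([[1.0, 0.0], [0.0, 1.0]])
        trace = CohortTrace(occ, space(2))
        total, yld, yll, _ = accrue_dalys(trace, np.zeros(2), lt, 11, 0.0)
        assert yll == pytest.approx(2.0)
        assert yld == 0.0

    def test_single_death_discounted_stream(self):
        """Death at cycle 1, expectancy 2: years arrive at cycles 2 and 3."""
        lt = LifeTable([0, 100], [2.0, 2.0], monotonicity_tol=1e-9)
        occ = np.array([[1.0, 0.0], [0.0, 1.0]])
        trace = CohortTrace(occ, space(2))
        total, _, yll, _ = accrue_dalys(trace, np.zeros(2), lt, 11, 0.03)
        assert yll == pytest.approx(1.03**-2 + 1.03**-3, rel=1e-12)

    def test_fractional_final_year_prorated(self):
        lt = LifeTable([0, 100], [1.5, 1.5], monotonicity_tol=1e-9)
        occ = np.array([[1.0, 0.0], [0.0, 1.0]])
        trace = CohortTrace(occ, space(2))
        _, _, yll, _ = accrue_dalys(trace, np.zeros(2), lt, 11, 0.03)
        assert yll == pytest.approx(1.03**-2 + 0.5 * 1.03**-3, rel=1e-12)

    def test_lump_mode_discounts_at_death_cycle(self):
        lt = LifeTable([0, 100], [2.0, 2.0], monotonicity_tol=1e-9)
        occ = np.array([[1.0, 0.0], [0.0, 1.0]])
        trace = CohortTrace(occ, space(2))
        _, _, yll, _ = accrue_dalys(trace, np.zeros(2), lt, 11, 0.03,
                                    yll_mode="lump")
        assert yll == pytest.approx(2.0 / 1.03, rel=1e-12)

    def test_immortal_cohort_has_zero_yll(self):
        trace = single_state_trace(7.0, 10)
        _, _, yll, _ = accrue_dalys(trace, np.array([0.2, 0.0]), self.lt, 11, 0.03)
        assert yll == 0.0

    def test_dead_cohort_has_zero_yld(self):
        occ = np.zeros((4, 2))
        occ[:, 1] = 5.0  # all mass in the death state from the start
        trace = CohortTrace(occ, space(2))
        _, yld, _, _ = accrue_dalys(trace, np.array([0.3, 0.0]), self.lt, 11, 0.03)
        assert yld == 0.0


class TestCompare:
    def test_icer_from_deltas(self):
        c = compare(scenario("s", 100.0, 10.0), scenario("i", 160.0, 8.0), 50.0)
        assert c.delta_cost == pytest.approx(60.0)
        assert c.delta_effect == pytest.approx(2.0)
        assert c.icer == pytest.approx(30.0)
        assert c.label == "icer"
        assert c.nmb == pytest.approx(50.0 * 2 - 60.0)

    def test_cheaper_and_more_effective_is_dominant(self):
        c = compare(scenario("s", 100.0, 10.0), scenario("i", 90.0, 9.0), 50.0)
        assert c.label == "dominant"

    def test_costlier_and_less_effective_is_dominated(self):
        c = compare(scenario("s", 100.0, 10.0), scenario("i", 190.0, 12.0), 50.0)
        assert c.label == "dominated" and c.icer is None

    def test_equal_strategies_give_zero_nmb_any_threshold(self):
        for lam in (0.0, 1.0, 1e6):
            c = compare(scenario("s", 10.0, 5.0), scenario("i", 10.0, 5.0), lam)
            assert c.nmb == 0.0 and c.label == "equivalent"

    def test_zero_effect_nonzero_cost_undefined(self):
        c = compare(scenario("s", 10.0, 5.0), scenario("i", 20.0, 5.0), 50.0)
        assert c.icer is None and c.label == "undefined"
        assert c.delta_cost == 10.0 and c.delta_effect == 0.0


@given(st.floats(0.0, 0.2), st.floats(0.0, 0.2))
def test_discounted_totals_non_increasing_in_rate(r1, r2):
    """Raising the discount rate can only shrink positive flows."""
    lo, hi = sorted([r1, r2])
    toy = generate_toy_bundle(stay_sick=0.8, mortality=0.1, discount_rate=0.0)
    strat = build_standard_care(toy)
    import dataclasses

    res = {}
    for r in (lo, hi):
        p = dataclasses.replace(toy, discount_rate=r)
        res[r] = evaluate_strategy(strat, p)
    assert res[hi].total_cost <= res[lo].total_cost + 1e-12
    assert res[hi].total_dalys <= res[lo].total_dalys + 1e-12


def test_zero_rate_reproduces_raw_sums():
    toy = generate_toy_bundle(stay_sick=0.7, mortality=0.0, discount_rate=0.0,
                              n_cycles=10)
    res = evaluate_strategy(build_standard_care(toy), toy)
    raw = 100.0 * sum(0.7**t for t in range(1, 11))
    assert res.total_cost == pytest.approx(raw, rel=1e-12)


def test_icer_invariant_under_cohort_rescaling(bundle):
    import dataclasses

    from rhdcea import ScreeningCEA

    base = ScreeningCEA(bundle).run().comparison
    scaled = ScreeningCEA(
        dataclasses.replace(bundle, cohort_size=bundle.cohort_size * 7.5)
    ).run().comparison
    assert scaled.icer == pytest.approx(base.icer, rel=1e-9)
    assert scaled.label == base.label


@given(st.floats(1.0, 1e5))
def test_nmb_positive_iff_icer_below_threshold(lam):
    s = scenario("s", 100.0, 10.0)
    i = scenario("i", 160.0, 8.0)  # ICER 30 per DALY averted
    c = compare(s, i, lam)
    assert c.delta_effect > 0
    assert (c.nmb > 0) == (c.icer < lam)
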