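"""Parameter sampling, probabilistic analysis, CEAC and tornado sweeps."""

import dataclasses

import numpy as np
import pytest

from rhdcea import ScreeningCEA, UncertaintyDescriptor
from rhdcea.sensitivity import (
    ceac,
    default_threshold_grid,
    one_way_sweep,
    run_psa,
    sample_parameter,
    sweep_bounds,
    tornado,
)


def degenerate(bundle):
    """Strip all second-order uncertainty from a bundle."""
    transitions = tuple(
        dataclasses.replace(t, uncertainty=UncertaintyDescriptor.point(t.probability))
        for t in bundle.transitions
    )
    economics = tuple(
        dataclasses.replace(
            e,
            daly_lower=e.daly_weight,
            daly_upper=e.daly_weight,
            cost_uncertainty=UncertaintyDescriptor.point(e.annual_cost),
        )
        for e in bundle.economics
    )
    return dataclasses.replace(
        bundle, transitions=transitions, economics=economics, shared_cost_variance=0.0
    ).validate()


class TestSampleParameter:
    rng = np.random.default_rng(0)

    def test_point_always_returns_value(self):
        d = UncertaintyDescriptor.point(0.03)
        assert all(sample_parameter(d, self.rng) == 0.03 for _ in range(10))

    def test_degenerate_triangular(self):
        d = UncertaintyDescriptor.triangular(0.5, 0.5, 0.5)
        assert sample_parameter(d, self.rng) == 0.5

    def test_zero_variance_gamma_degenerates(self):
        d = UncertaintyDescriptor.gamma(4120.51, 0.0)
        assert sample_parameter(d, self.rng) == 4120.51

    def test_gamma_moments_recovered(self):
        """Moment-matched gamma: surgery-cost mean and variance come back
        within Monte-Carlo error at 1e5 draws."""
        mean, var = 4120.51, (0.3 * 4120.51) ** 2
        rng = np.random.default_rng(42)
        d = UncertaintyDescriptor.gamma(mean, var)
        draws = np.array([sample_parameter(d, rng) for _ in range(100_000)])
        se_mean = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_triangular_moments_recovered(self):
        lo, mode, hi = 0.031, 0.049, 0.072
        rng = np.random.default_rng(7)
        d = UncertaintyDescriptor.triangular(lo, mode, hi)
        draws = np.array([sample_parameter(d, rng) for _ in range(100_000)])
        expected_mean = (lo + mode + hi) / 3
        assert draws.mean() == pytest.approx(expected_mean, rel=0.01)
        assert draws.min() >= lo and draws.max() <= hi

    def test_beta_moments_recovered(self):
        rng = np.random.default_rng(3)
        d = UncertaintyDescriptor.beta(0.2, 100)
        draws = np.array([sample_parameter(d, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.2, abs=0.001)
        assert draws.var() == pytest.approx(0.2 * 0.8 / 101, rel=0.05)


class TestRunPsa:
    def test_same_seed_identical_results(self, bundle):
        a = run_psa(bundle, 25, seed=5)
        b = run_psa(bundle, 25, seed=5)
        assert np.array_equal(a.iterations, b.iterations)

    def test_different_seeds_differ(self, bundle):
        a = run_psa(bundle, 10, seed=1)
        b = run_psa(bundle, 10, seed=2)
        assert not np.array_equal(a.iterations, b.iterations)

    def test_degenerate_psa_equals_deterministic_exactly(self, bundle):
        """With every descriptor a point mass, each iteration reproduces
        the deterministic deltas bit for bit."""
        p = degenerate(bundle)
        det = ScreeningCEA(p).run().comparison
        psa = run_psa(p, 8, seed=11)
        assert np.all(psa.delta_cost == det.delta_cost)
        assert np.all(psa.delta_effect == det.delta_effect)

    def test_iterations_are_finite(self, bundle):
        psa = run_psa(bundle, 20, seed=9)
        assert np.all(np.isfinite(psa.iterations))


class TestCeac:
    def test_degenerate_psa_gives_step_function_at_icer(self, bundle):
        p = degenerate(bundle)
        det = ScreeningCEA(p).run().comparison
        psa = run_psa(p, 4, seed=0)
        # place grid points on both sides of the deterministic ICER
        icer = det.delta_cost / det.delta_effect
        grid = np.array([icer - 1.0, icer + 1.0])
        if grid[0] <= 0:  # dominant case: accepted everywhere above 0
            grid = np.array([1.0, abs(icer) + 1.0])
            curve = ceac(psa, grid)
            assert np.all(curve.probabilities == 1.0)
        else:
            curve = ceac(psa, grid)
            assert curve.probabilities.tolist() == [0.0, 1.0]

    def test_probabilities_within_unit_interval(self, bundle):
        psa = run_psa(bundle, 30, seed=2)
        curve = ceac(psa, default_threshold_grid(bundle.threshold, n=50))
        assert np.all((curve.probabilities >= 0) & (curve.probabilities <= 1))

    def test_monotone_when_all_iterations_avert_dalys(self, bundle):
        psa = run_psa(bundle, 30, seed=4)
        if np.all(psa.delta_effect >= 0):
            curve = ceac(psa, default_threshold_grid(bundle.threshold, n=100))
            assert np.all(np.diff(curve.probabilities) >= 0)

    def test_empty_grid_rejected(self, bundle):
        psa = run_psa(bundle, 5, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            ceac(psa, np.array([]))


class TestOneWaySweep:
    def test_degenerate_sweep_has_zero_spread(self, bundle):
        row = one_way_sweep(bundle, "discount_rate", 0.03, 0.03)
        assert row.spread == 0.0

    def test_discount_rate_sweep_endpoints_match_direct_recomputation(self, bundle):
        """Sweeping 0%..5% reproduces the ICERs of full reruns at the
        endpoints, and the discount rate genuinely moves the ICER.  (An
        ordering check lo<=mid<=hi only makes sense when the base case has
        an interior positive ICER; a dominant base case has no monotone
        ICER in the rate, so the sweep is verified against direct reruns.)"""
        icers = {}
        for r in (0.0, 0.03, 0.05):
            p = dataclasses.replace(bundle, discount_rate=r)
            icers[r] = ScreeningCEA(p).run().comparison.icer
        row = one_way_sweep(bundle, "discount_rate", 0.0, 0.05)
        assert row.low_icer == pytest.approx(icers[0.0])
        assert row.high_icer == pytest.approx(icers[0.05])
        assert row.spread > 0

    def test_cost_of_unreachable_state_has_zero_spread(self, bundle):
        """A state no cohort member can ever occupy cannot move the ICER."""
        transitions = tuple(
            dataclasses.replace(t, probability=0.0)
            if (t.from_state, t.to_state) == ("I", "RI")
            else t
            for t in bundle.transitions
        )
        p = dataclasses.replace(bundle, transitions=transitions).validate()
        row = one_way_sweep(p, "cost:RI", 100.0, 900.0)
        assert row.spread == pytest.approx(0.0, abs=1e-9)

    def test_invalid_sweep_value_names_parameter(self, bundle):
        with pytest.raises(Exception, match="transition:B->C"):
            one_way_sweep(bundle, "transition:B->C", 0.0, 1.4)

    def test_unknown_parameter_id_rejected(self, bundle):
        with pytest.raises(KeyError):
            one_way_sweep(bundle, "nonsense:thing", 0.0, 1.0)


class TestTornado:
    def test_rows_sorted_by_descending_spread(self, bundle):
        rows = tornado(bundle)
        spreads = [r.spread for r in rows if np.isfinite(r.spread)]
        assert spreads == sorted(spreads, reverse=True)

    def test_discount_sweep_present_exactly_once(self, bundle):
        rows = tornado(bundle)
        assert sum(r.parameter == "discount_rate" for r in rows) == 1
        assert rows and any(r.spread > 0 for r in rows)

    def test_spreads_match_independent_endpoint_recomputation(self, bundle):
        bounds = sweep_bounds(bundle)
        subset = ["discount_rate", "cost:X", "screening:sensitivity_definite"]
        rows = {r.parameter: r for r in tornado(bundle, {k: bounds[k] for k in subset})}
        for pid in subset:
            lo, hi = bounds[pid]
            again = one_way_sweep(bundle, pid, lo, hi)
            assert rows[pid].low_icer == pytest.approx(again.low_icer)
            assert rows[pid].high_icer == pytest.approx(again.high_icer)

    def test_all_point_bundle_has_all_zero_transition_cost_spreads(self, bundle):
        p = degenerate(bundle)
        bounds = sweep_bounds(p)
        assert not any(k.startswith(("transition:", "cost:", "daly:")) for k in bounds)
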