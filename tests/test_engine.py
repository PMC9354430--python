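"""Cohort trace, microsimulation, discounting and comparison rules."""

import numpy as np
import pytest

from tavicea import (
    Arm,
    CEResult,
    Event,
    compare,
    discount_factor,
    run_cohort,
    run_microsim,
    utility_at_cycle,
)
from tavicea.config import INDEPENDENT_AE_EVENTS
from tavicea.synthetic import SyntheticCohortSpec, make_synthetic_model_spec


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(47, 0.0) == 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestUtilityAtCycle:
    def test_published_nodes(self, base_spec):
        tavi = base_spec.utilities[Arm.TAVI]
        savr = base_spec.utilities[Arm.SAVR]
        assert utility_at_cycle(tavi, 1) == pytest.approx(0.81)
        assert utility_at_cycle(tavi, 12) == pytest.approx(0.79)
        assert utility_at_cycle(tavi, 24) == pytest.approx(0.78)
        # beyond 24 months both arms carry the last TAVI value
        assert utility_at_cycle(savr, 36) == pytest.approx(0.78)
        assert utility_at_cycle(savr, 1) == pytest.approx(0.73)

    def test_linear_interpolation_between_nodes(self, base_spec):
        savr = base_spec.utilities[Arm.SAVR]
        # SAVR rises 0.73 -> 0.80 over months 1..12 in equal steps
        expected = 0.73 + (0.80 - 0.73) * (6 - 1) / 11
        assert utility_at_cycle(savr, 6) == pytest.approx(expected)

    def test_cycle_zero_rejected(self, base_spec):
        with pytest.raises(ValueError):
            utility_at_cycle(base_spec.utilities[Arm.TAVI], 0)


class TestRunCohort:
    def test_occupancy_rows_sum_to_one(self, base_spec):
        for arm in Arm:
            trace, _ = run_cohort(base_spec, arm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    def test_death_occupancy_non_decreasing(self, base_spec):
        for arm in Arm:
            trace, _ = run_cohort(base_spec, arm)
            dead = trace.occupancy[:, -1]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_cost_decomposition_sums_exactly(self, base_spec):
        for arm in Arm:
            _, res = run_cohort(base_spec, arm)
            assert sum(res.cost_components.values()) == pytest.approx(res.cost, abs=1e-9)
            assert res.cost_components["index"] == base_spec.costs.index_episode[arm]

    def test_qaly_bounded_by_horizon(self, base_spec):
        for arm in Arm:
            _, res = run_cohort(base_spec, arm)
            assert 0 < res.qaly <= base_spec.settings.horizon_months / 12

    def test_zero_utilities_leave_costs_unchanged(self, base_spec):
        spec = base_spec.copy()
        for traj in spec.utilities.values():
            for node in traj.nodes.values():
                node.mean = 0.0
            traj.pooled_value = 0.0
        _, res0 = run_cohort(spec, Arm.TAVI)
        _, res1 = run_cohort(base_spec, Arm.TAVI)
        assert res0.qaly == 0.0
        assert res0.cost == pytest.approx(res1.cost)

    def test_immediate_extinction(self, base_spec):
        """Whole cohort dies in cycle 1: index cost plus cycle-1 AE expectation."""
        spec = base_spec.copy()
        for arm in Arm:
            spec.milestones[(Event.ALL_CAUSE_MORTALITY, arm)].milestones = [(1, 1.0)]
        _, res = run_cohort(spec, Arm.TAVI)
        d1 = discount_factor(1, 0.03)
        expected_ae = sum(
            spec.table(ev, Arm.TAVI).milestones[0][1] * spec.costs.ae_costs[ev].mean
            for ev in INDEPENDENT_AE_EVENTS
        ) + spec.table(Event.DISABLING_STROKE, Arm.TAVI).milestones[0][1] \
            * spec.costs.ae_costs[Event.DISABLING_STROKE].mean
        assert res.cost == pytest.approx(
            spec.costs.index_episode[Arm.TAVI] + d1 * expected_ae
        )
        # death forfeits the dying cycle's utility
        assert res.qaly <= 0.81 / 12

    def test_discounting_monotonicity(self, base_spec):
        totals = []
        for rate in (0.0, 0.03, 0.05):
            spec = base_spec.copy()
            spec.settings.annual_discount = rate
            _, res = run_cohort(spec, Arm.TAVI)
            totals.append((res.cost, res.qaly))
        costs, qalys = zip(*totals)
        assert costs[0] >= costs[1] >= costs[2]
        assert qalys[0] >= qalys[1] >= qalys[2]

    def test_expected_ae_counts_near_published_cumulative(self, base_spec):
        """Once-ever AE accrual lands close to (and below) the KM cumulative."""
        _, res = run_cohort(base_spec, Arm.SAVR)
        assert res.ae_counts[Event.BLEEDING] == pytest.approx(0.486, rel=0.15)
        assert res.ae_counts[Event.BLEEDING] < 0.486


class TestRunMicrosim:
    def test_same_seed_identical_result(self, base_spec):
        a = run_microsim(base_spec, Arm.TAVI, n=50, seed=123)
        b = run_microsim(base_spec, Arm.TAVI, n=50, seed=123)
        assert a.cost == b.cost and a.qaly == b.qaly
        assert np.array_equal(a.cumulative_mortality, b.cumulative_mortality)

    def test_single_patient(self, base_spec):
        res = run_microsim(base_spec, Arm.SAVR, n=1, seed=7)
        assert res.cost >= base_spec.costs.index_episode[Arm.SAVR]

    def test_agrees_with_cohort_within_monte_carlo_error(self, base_spec):
        _, exact = run_cohort(base_spec, Arm.TAVI)
        sim = run_microsim(base_spec, Arm.TAVI, n=10_000, seed=42)
        assert abs(sim.cost - exact.cost) < 3 * sim.cost_se
        assert abs(sim.qaly - exact.qaly) < 3 * sim.qaly_se

    def test_convergence_rate_to_cohort(self, base_spec):
        """Microsim error shrinks like 1/sqrt(n) towards the cohort expectation."""
        _, exact = run_cohort(base_spec, Arm.SAVR)
        for n in (100, 1_000, 10_000, 100_000):
            sim = run_microsim(base_spec, Arm.SAVR, n=n, seed=2024)
            assert abs(sim.qaly - exact.qaly) < 3 * sim.qaly_se
            assert abs(sim.cost - exact.cost) < 3 * sim.cost_se
            # the 3-SE envelope itself contracts as O(1/sqrt(n))
            assert sim.qaly_se < 3.0 / np.sqrt(n)

    def test_zero_stroke_hazard_keeps_everyone_out_of_stroke_state(self):
        syn = SyntheticCohortSpec(
            hazards={(Event.DISABLING_STROKE, arm): 0.0 for arm in Arm}
        )
        spec = make_synthetic_model_spec(syn)
        res = run_microsim(spec, Arm.TAVI, n=500, seed=3)
        assert res.ae_counts[Event.DISABLING_STROKE] == 0.0
        assert res.cost_components["neurologist"] == 0.0


def _stub(arm, cost, qaly):
    return CEResult(arm=arm, cost=cost, qaly=qaly, cumulative_mortality=np.zeros(1))


class TestCompare:
    def test_published_table_arithmetic(self):
        """Increments from the rounded published per-arm totals."""
        res = compare(_stub(Arm.TAVI, 70_959, 2.92), _stub(Arm.SAVR, 39_492, 2.82),
                      wtp=34_091)
        assert res.delta_cost == pytest.approx(31_467)
        assert res.delta_qaly == pytest.approx(0.10)
        assert res.icer == pytest.approx(314_670, rel=1e-6)
        assert res.inb() == pytest.approx(-28_057.9, abs=0.5)

    def test_dominance_labels(self):
        assert compare(_stub(Arm.TAVI, 99, 1.1), _stub(Arm.SAVR, 100, 1.0),
                       wtp=0).label == "dominant"
        assert compare(_stub(Arm.TAVI, 101, 0.9), _stub(Arm.SAVR, 100, 1.0),
                       wtp=0).label == "dominated"
        south_west = compare(_stub(Arm.TAVI, 90, 0.9), _stub(Arm.SAVR, 100, 1.0), wtp=0)
        assert south_west.label == "icer" and south_west.icer == pytest.approx(100.0)

    def test_identical_arms_flagged_undefined(self):
        res = compare(_stub(Arm.TAVI, 100, 1.0), _stub(Arm.SAVR, 100, 1.0), wtp=50_000)
        assert res.delta_cost == 0.0 and res.delta_qaly == 0.0
        assert res.icer_undefined
        assert res.inb() == 0.0

    def test_zero_qaly_increment_labelled_by_cost_sign(self):
        res = compare(_stub(Arm.TAVI, 101, 1.0), _stub(Arm.SAVR, 100, 1.0), wtp=0)
        assert res.label == "dominated" and res.icer_undefined

    def test_inb_linear_in_wtp(self):
        res = compare(_stub(Arm.TAVI, 110, 1.2), _stub(Arm.SAVR, 100, 1.0), wtp=0)
        w = np.array([0.0, 10_000.0, 50_000.0])
        inbs = np.array([res.inb(x) for x in w])
        slope = np.diff(inbs) / np.diff(w)
        assert np.allclose(slope, res.delta_qaly)
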