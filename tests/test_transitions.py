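"""Milestone-to-monthly conversion and the stroke mortality split."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tavicea import (
    Arm,
    Event,
    MilestoneKind,
    MilestoneTable,
    build_transition_schedule,
    interval_monthly_prob,
    km_schedule_to_monthly,
    split_mortality_by_stroke,
)
from tavicea.transitions import cumulative_incidence


def bisect_monthly_prob(s_start, s_end, n, tol=1e-12):
    """Independent oracle: solve (1-p)^n = s_end/s_start by bisection."""
    target = s_end / s_start
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if (1.0 - mid) ** n > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestIntervalMonthlyProb:
    def test_thirty_day_value_is_direct(self):
        assert interval_monthly_prob(1.0, 0.97, 1) == pytest.approx(0.03)

    def test_no_events_in_interval(self):
        assert interval_monthly_prob(0.42, 0.42, 7) == 0.0

    def test_matches_bisection_oracle(self):
        # TAVI mortality 10% -> 14.2% between 1 y and 2 y
        p = interval_monthly_prob(0.90, 0.858, 12)
        assert p == pytest.approx(bisect_monthly_prob(0.90, 0.858, 12), abs=1e-9)
        assert p == pytest.approx(0.0039746, abs=1e-6)

    def test_rejects_increasing_survival(self):
        with pytest.raises(ValueError):
            interval_monthly_prob(0.8, 0.9, 12)

    def test_extinction(self):
        assert interval_monthly_prob(0.5, 0.0, 3) == 1.0
        with pytest.raises(ValueError):
            interval_monthly_prob(0.0, 0.0, 3)


def _table(milestones, kind=MilestoneKind.CUMULATIVE_INCIDENCE,
           event=Event.BLEEDING, arm=Arm.TAVI):
    return MilestoneTable(event=event, arm=arm, kind=kind,
                          milestones=[(int(t), float(p)) for t, p in milestones])


class TestKmScheduleToMonthly:
    def test_mortality_milestones_reproduced_exactly(self):
        tab = _table([(1, 0.03), (12, 0.10), (24, 0.142), (60, 0.427)],
                     event=Event.ALL_CAUSE_MORTALITY)
        for bridging in ("linear", "constant"):
            q = km_schedule_to_monthly(tab, 60, late_mortality_bridging=bridging)
            cum = cumulative_incidence(q)
            for t, p in tab.milestones:
                assert cum[t - 1] == pytest.approx(p, abs=1e-9)

    def test_single_zero_milestone_gives_zero_vector(self):
        q = km_schedule_to_monthly(_table([(1, 0.0)]), 60)
        assert np.all(q == 0.0)

    def test_exponential_survival_recovered(self):
        lam = 0.01
        tab = _table(
            [(t, 1.0 - math.exp(-lam * t)) for t in (1, 12, 24, 60)],
            event=Event.ALL_CAUSE_MORTALITY,
        )
        q = km_schedule_to_monthly(tab, 60, late_mortality_bridging="constant")
        assert np.allclose(q, 1.0 - math.exp(-lam), atol=1e-6)

    def test_prevalence_positive_increments_only(self):
        # PAR-style: rises to 2 y then falls; the fall creates no new events
        tab = _table([(1, 0.0375), (12, 0.0375), (24, 0.0827), (60, 0.0644)],
                     kind=MilestoneKind.PREVALENCE, event=Event.PAR)
        q = km_schedule_to_monthly(tab, 60)
        assert np.all(q >= 0.0)
        assert np.all(q[24:] == 0.0)          # falling prevalence, no incidence
        assert np.all(q[1:12] == 0.0)         # flat prevalence, no incidence
        assert q[0] == pytest.approx(0.0375)

    def test_decreasing_cumulative_rejected(self):
        tab = _table([(1, 0.2), (12, 0.1)])
        with pytest.raises(ValueError):
            km_schedule_to_monthly(tab, 60)

    def test_extension_beyond_last_milestone(self):
        tab = _table([(1, 0.03), (12, 0.10), (24, 0.142), (60, 0.427)],
                     event=Event.ALL_CAUSE_MORTALITY)
        q = km_schedule_to_monthly(tab, 240, late_mortality_bridging="constant")
        # beyond month 60 the 2-5 y constant monthly rate continues
        expected = interval_monthly_prob(1 - 0.142, 1 - 0.427, 36)
        assert np.allclose(q[60:], expected)

    @given(
        probs=st.lists(st.floats(0.0, 0.95), min_size=4, max_size=4),
        horizon=st.sampled_from([60, 72]),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, probs, horizon):
        """Any valid cumulative table is reproduced at every milestone to 1e-9."""
        probs = sorted(probs)
        tab = _table(list(zip((1, 12, 24, 60), probs)))
        cum = cumulative_incidence(km_schedule_to_monthly(tab, horizon))
        for t, p in tab.milestones:
            assert cum[t - 1] == pytest.approx(p, abs=1e-9)

    @given(
        probs=st.lists(st.floats(0.01, 0.90), min_size=4, max_size=4),
        k=st.integers(0, 3),
        bump=st.floats(0.001, 0.05),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_in_milestones(self, probs, k, bump):
        """Raising one milestone never lowers per-cycle risk in its interval."""
        probs = sorted(probs)
        times = (1, 12, 24, 60)
        bumped = list(probs)
        bumped[k] = min(bumped[k] + bump, 1.0)
        bumped = [max(p, bumped[k]) if i > k else p for i, p in enumerate(bumped)]
        q0 = km_schedule_to_monthly(_table(list(zip(times, probs))), 60)
        q1 = km_schedule_to_monthly(_table(list(zip(times, bumped))), 60)
        lo = 0 if k == 0 else times[k - 1]
        assert np.all(q1[lo:times[k]] >= q0[lo:times[k]] - 1e-12)


class TestSplitMortalityByStroke:
    def test_worked_example(self):
        m_ns, m_s = split_mortality_by_stroke(0.01, 0.05, 8.5)
        assert m_ns == pytest.approx(0.0072727, abs=1e-6)
        assert m_s == pytest.approx(0.0618182, abs=1e-6)

    def test_unit_hazard_ratio_no_excess(self):
        m_ns, m_s = split_mortality_by_stroke(0.02, 0.3, 1.0)
        assert m_ns == m_s == pytest.approx(0.02)

    def test_empty_stroke_state(self):
        m_ns, _ = split_mortality_by_stroke(0.02, 0.0, 8.5)
        assert m_ns == pytest.approx(0.02)

    @given(
        m=st.floats(0.0, 0.5),
        x=st.floats(0.0, 1.0),
        rr=st.floats(1.0, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_mixture_conservation(self, m, x, rr):
        """Weighted recombination recovers cohort mortality to 1e-12 (uncapped)."""
        m_ns, m_s = split_mortality_by_stroke(m, x, rr)
        if rr * m_ns <= 1.0:
            assert x * m_s + (1 - x) * m_ns == pytest.approx(m, abs=1e-12)


class TestBuildTransitionSchedule:
    def test_cohort_mortality_reproduces_milestones(self, base_spec, base_schedules):
        for arm in Arm:
            cum = base_schedules[arm].cumulative_mortality()
            for t, p in base_spec.table(Event.ALL_CAUSE_MORTALITY, arm).milestones:
                assert cum[t - 1] == pytest.approx(p, abs=1e-9)
        # and the duration-stratified occupancy recursion preserves it too
        occ_dead = base_schedules[Arm.TAVI].occupancy[1:, -1]
        assert occ_dead[-1] == pytest.approx(0.427, abs=1e-9)

    def test_savr_first_cycle_mortality(self, base_schedules):
        assert base_schedules[Arm.SAVR].m_all[0] == pytest.approx(0.041)

    def test_stroke_state_death_exceeds_no_stroke(self, base_schedules):
        sched = base_schedules[Arm.TAVI]
        p_stroke_death = sched.p_death_stroke_by_duration
        # recent strokes (HR > 1) always at least the no-stroke probability
        assert np.all(p_stroke_death >= sched.p_death_no_stroke[:, None] - 1e-15)
        assert sched.p_death_stroke(1, 1) == pytest.approx(
            8.5 * sched.p_death_no_stroke[0]
        )

    def test_flat_hazard_ratios_collapse_the_split(self, base_spec):
        spec = base_spec.copy()
        spec.hazard_ratios.hr_by_cycle = [1.0] * 15
        sched = build_transition_schedule(spec, Arm.TAVI)
        assert np.allclose(sched.p_death_no_stroke, sched.m_all, atol=1e-12)
        assert np.allclose(
            sched.p_death_stroke_by_duration,
            sched.p_death_no_stroke[:, None],
            atol=1e-12,
        )

    def test_all_probabilities_in_unit_interval(self, base_schedules):
        for sched in base_schedules.values():
            for arr in (sched.m_all, sched.p_death_no_stroke,
                        sched.p_stroke_incidence, *sched.p_ae.values()):
                assert np.all((arr >= 0.0) & (arr <= 1.0))
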