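"""Markov engine: evaluate a transition schedule into discounted totals.

Two evaluation modes share one set of transition/accrual rules:

* :func:`run_cohort` — deterministic cohort trace, the exact expectation of
  the microsimulation (stroke occupancy is stratified by months since
  onset so the duration-indexed hazard ratios apply correctly);
* :func:`run_microsim` — first-order Monte Carlo microsimulation of
  individual patients walking through the same schedule.

Within a cycle the event order is: adverse events, then stroke onset, then
death.  A patient who dies in a cycle forfeits that cycle's utility and
follow-up cost but keeps any AE costs already incurred.  The index episode
charge is booked at model start, undiscounted; every per-cycle amount at
cycle ``t`` is discounted by ``(1 + r)^(-t/12)``.

Cost accrual: one-time AE treatment costs on each new incidence, an annual
cardiology follow-up (spread monthly over all alive patients) and a
quarterly neurologist visit (spread monthly over the stroke state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    Arm,
    Event,
    INDEPENDENT_AE_EVENTS,
    ModelSpec,
    UtilityTrajectory,
)
from .transitions import N_DURATION_STRATA, TransitionSchedule, build_transition_schedule

__all__ = [
    "discount_factor",
    "utility_at_cycle",
    "CohortTrace",
    "CEResult",
    "ComparisonResult",
    "run_cohort",
    "run_microsim",
    "compare",
]


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor ``(1 + r)^(-cycle/12)`` for a monthly cycle index."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


def utility_at_cycle(traj: UtilityTrajectory, cycle: int) -> float:
    """EQ-5D utility applied in a given cycle.

    Linear interpolation between the month-1, month-12 and month-24 nodes;
    the pooled value (the last TAVI utility) beyond ``pooled_after_month``.
    The model starts at cycle 1 with the month-1 utility.
    """
    if cycle < 1:
        raise ValueError("utilities are defined from cycle 1 onwards")
    if cycle > traj.pooled_after_month:
        return traj.pooled_value
    months = sorted(traj.nodes)
    values = [traj.nodes[m].mean for m in months]
    return float(np.interp(cycle, months, values))


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accrual streams.

    ``occupancy`` has one row per cycle (row 0 = model start) and columns
    no-stroke, stroke-by-duration strata (1..15 and 16+ months since
    onset), dead.  Increments are discounted.
    """

    occupancy: np.ndarray
    cost_increments: np.ndarray
    qaly_increments: np.ndarray

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, -1]

    @property
    def stroke_occupancy(self) -> np.ndarray:
        return self.occupancy[:, 1:-1].sum(axis=1)

    @property
    def cumulative_cost(self) -> np.ndarray:
        return np.cumsum(self.cost_increments)

    @property
    def cumulative_qaly(self) -> np.ndarray:
        return np.cumsum(self.qaly_increments)


@dataclass
class CEResult:
    """Total discounted cost (2020 US$) and QALYs for one arm."""

    arm: Arm
    cost: float
    qaly: float
    cumulative_mortality: np.ndarray = field(repr=False)
    ae_counts: dict[Event, float] = field(default_factory=dict, repr=False)
    cost_components: dict[str, float] = field(default_factory=dict, repr=False)
    n_patients: int | None = None
    cost_se: float | None = None
    qaly_se: float | None = None


@dataclass
class ComparisonResult:
    """Pairwise increments (TAVI - SAVR), ICER or dominance label, and INB."""

    tavi: CEResult
    savr: CEResult
    wtp: float
    delta_cost: float = field(init=False)
    delta_qaly: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_cost = self.tavi.cost - self.savr.cost
        self.delta_qaly = self.tavi.qaly - self.savr.qaly

    @property
    def label(self) -> str:
        dc, dq = self.delta_cost, self.delta_qaly
        if dq > 0 and dc <= 0:
            return "dominant"
        if dq < 0 and dc >= 0:
            return "dominated"
        if dq == 0:
            if dc == 0:
                return "equivalent"
            return "dominated" if dc > 0 else "dominant"
        return "icer"

    @property
    def icer(self) -> float | None:
        """Cost per QALY when the increments admit a ratio, else None."""
        if self.label != "icer":
            return None
        return self.delta_cost / self.delta_qaly

    @property
    def icer_undefined(self) -> bool:
        return self.icer is None

    def inb(self, wtp: float | None = None) -> float:
        """Incremental net monetary benefit ``wtp * dQALY - dCost``."""
        w = self.wtp if wtp is None else wtp
        return w * self.delta_qaly - self.delta_cost


def _accrual_inputs(spec: ModelSpec, arm: Arm):
    s = spec.settings
    c = spec.costs
    fu_monthly = c.followup_annual / 12.0
    neuro_monthly = c.neurologist_visit / 3.0
    util = np.array(
        [utility_at_cycle(spec.utilities[arm], t) for t in range(1, s.horizon_months + 1)]
    )
    disc = np.array(
        [discount_factor(t, s.annual_discount) for t in range(1, s.horizon_months + 1)]
    )
    ae_cost = np.array([c.ae_costs[e].mean for e in INDEPENDENT_AE_EVENTS])
    if s.apply_ae_disutilities and spec.ae_disutilities is not None:
        ae_disutil = np.array(
            [spec.ae_disutilities.one_off.get(e, 0.0) for e in INDEPENDENT_AE_EVENTS]
        )
        stroke_disutil = spec.ae_disutilities.stroke_per_cycle / 12.0
    else:
        ae_disutil = np.zeros(len(INDEPENDENT_AE_EVENTS))
        stroke_disutil = 0.0
    stroke_cost = c.ae_costs[Event.DISABLING_STROKE].mean
    return fu_monthly, neuro_monthly, util, disc, ae_cost, ae_disutil, stroke_disutil, stroke_cost


def run_cohort(
    spec: ModelSpec, arm: Arm, schedule: TransitionSchedule | None = None
) -> tuple[CohortTrace, CEResult]:
    """Deterministic cohort evaluation (exact expectation of the microsim).

    Adverse-event histories are tracked through per-event event-free
    fractions, assumed independent of the health state (the trials report AE
    risks unconditional on stroke status).
    """
    spec.require_valid()
    if schedule is None:
        schedule = build_transition_schedule(spec, arm)
    s = spec.settings
    H = s.horizon_months
    (fu_m, neuro_m, util, disc, ae_cost, ae_disutil, stroke_disutil, stroke_cost
     ) = _accrual_inputs(spec, arm)

    occ = schedule.occupancy
    alive = 1.0 - occ[:, -1]
    stroke_occ = occ[:, 1:-1].sum(axis=1)

    n_ae = len(INDEPENDENT_AE_EVENTS)
    q_ae = np.column_stack([schedule.p_ae[e] for e in INDEPENDENT_AE_EVENTS])
    event_free = np.ones(n_ae)

    cost_inc = np.zeros(H)
    qaly_inc = np.zeros(H)
    comp = {"index": spec.costs.index_episode[arm], "ae": 0.0,
            "followup": 0.0, "neurologist": 0.0}
    ae_counts = dict.fromkeys(INDEPENDENT_AE_EVENTS, 0.0)
    stroke_count = 0.0

    for t in range(1, H + 1):
        alive_start = alive[t - 1]
        d = disc[t - 1]
        # adverse events strike patients alive at cycle start, before deaths
        new_ae = alive_start * event_free * q_ae[t - 1]
        event_free *= 1.0 - q_ae[t - 1]
        ae_cost_t = float(new_ae @ ae_cost)
        new_stroke = occ[t - 1, 0] * schedule.p_stroke_incidence[t - 1]
        ae_cost_t += new_stroke * stroke_cost
        stroke_count += new_stroke
        for e, cnt in zip(INDEPENDENT_AE_EVENTS, new_ae):
            ae_counts[e] += float(cnt)

        alive_end = alive[t]
        stroke_end = stroke_occ[t]
        if s.half_cycle_correction:
            alive_eff = 0.5 * (alive_start + alive_end)
            stroke_eff = 0.5 * (stroke_occ[t - 1] + stroke_end)
        else:
            alive_eff, stroke_eff = alive_end, stroke_end

        fu_t = alive_eff * fu_m + stroke_eff * neuro_m
        cost_inc[t - 1] = d * (ae_cost_t + fu_t)
        comp["ae"] += d * ae_cost_t
        comp["followup"] += d * alive_eff * fu_m
        comp["neurologist"] += d * stroke_eff * neuro_m

        q_t = alive_eff * util[t - 1] / 12.0
        q_t -= stroke_eff * stroke_disutil
        q_t -= float(new_ae @ ae_disutil)
        qaly_inc[t - 1] = d * q_t

    cost_inc[0] += comp["index"]  # booked at start, undiscounted
    ae_counts[Event.DISABLING_STROKE] = stroke_count
    trace = CohortTrace(occupancy=occ, cost_increments=cost_inc, qaly_increments=qaly_inc)
    result = CEResult(
        arm=arm,
        cost=float(cost_inc.sum()),
        qaly=float(qaly_inc.sum()),
        cumulative_mortality=occ[1:, -1].copy(),
        ae_counts=ae_counts,
        cost_components=comp,
    )
    return trace, result


def run_microsim(
    spec: ModelSpec,
    arm: Arm,
    n: int | None = None,
    seed: int | None = None,
    schedule: TransitionSchedule | None = None,
) -> CEResult:
    """First-order microsimulation: ``n`` patients walk through the schedule.

    Identical seeds give identical results.  Per cycle and patient the draw
    order is fixed: one uniform per adverse event, one for stroke onset, one
    for death.  Each AE can strike a patient at most once (its monthly
    probability is conditional on being event-free).
    """
    spec.require_valid()
    s = spec.settings
    n = s.n_microsim if n is None else n
    seed = s.seed if seed is None else seed
    if n < 1:
        raise ValueError("n must be >= 1")
    if schedule is None:
        schedule = build_transition_schedule(spec, arm)
    H = s.horizon_months
    (fu_m, neuro_m, util, disc, ae_cost, ae_disutil, stroke_disutil, stroke_cost
     ) = _accrual_inputs(spec, arm)
    rng = np.random.default_rng(seed)

    n_ae = len(INDEPENDENT_AE_EVENTS)
    q_ae = np.column_stack([schedule.p_ae[e] for e in INDEPENDENT_AE_EVENTS])
    hrs = schedule.hr_by_duration

    alive = np.ones(n, dtype=bool)
    in_stroke = np.zeros(n, dtype=bool)
    onset = np.zeros(n, dtype=np.int64)
    had = np.zeros((n, n_ae), dtype=bool)
    cost = np.full(n, spec.costs.index_episode[arm])
    qaly = np.zeros(n)
    comp = {"index": spec.costs.index_episode[arm], "ae": 0.0,
            "followup": 0.0, "neurologist": 0.0}
    deaths_by_cycle = np.zeros(H)

    for t in range(1, H + 1):
        d = disc[t - 1]
        for j in range(n_ae):
            u = rng.random(n)
            new = alive & ~had[:, j] & (u < q_ae[t - 1, j])
            had[:, j] |= new
            k = int(new.sum())
            if k:
                cost[new] += ae_cost[j] * d
                qaly[new] -= ae_disutil[j] * d
                comp["ae"] += k * ae_cost[j] * d / n

        u = rng.random(n)
        new_s = alive & ~in_stroke & (u < schedule.p_stroke_incidence[t - 1])
        in_stroke |= new_s
        onset[new_s] = t
        k = int(new_s.sum())
        if k:
            cost[new_s] += stroke_cost * d
            comp["ae"] += k * stroke_cost * d / n

        m_ns = schedule.p_death_no_stroke[t - 1]
        p_death = np.full(n, m_ns)
        if in_stroke.any():
            dur = np.clip(t - onset[in_stroke] + 1, 1, N_DURATION_STRATA)
            p_death[in_stroke] = np.minimum(hrs[dur - 1] * m_ns, 1.0)
        u = rng.random(n)
        dying = alive & (u < p_death)
        alive &= ~dying
        deaths_by_cycle[t - 1] = dying.sum()

        # survivors accrue the cycle's utility and follow-up costs
        cost[alive] += fu_m * d
        qaly[alive] += util[t - 1] / 12.0 * d
        comp["followup"] += int(alive.sum()) * fu_m * d / n
        stroke_alive = alive & in_stroke
        k = int(stroke_alive.sum())
        if k:
            cost[stroke_alive] += neuro_m * d
            qaly[stroke_alive] -= stroke_disutil * d
            comp["neurologist"] += k * neuro_m * d / n

    ae_counts = {
        e: float(had[:, j].sum()) / n for j, e in enumerate(INDEPENDENT_AE_EVENTS)
    }
    ae_counts[Event.DISABLING_STROKE] = float(in_stroke.sum()) / n
    return CEResult(
        arm=arm,
        cost=float(cost.mean()),
        qaly=float(qaly.mean()),
        cumulative_mortality=np.cumsum(deaths_by_cycle) / n,
        ae_counts=ae_counts,
        cost_components=comp,
        n_patients=n,
        cost_se=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        qaly_se=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
    )


def compare(res_tavi: CEResult, res_savr: CEResult, wtp: float) -> ComparisonResult:
    """Pairwise TAVI-vs-SAVR comparison: increments, ICER/dominance, INB."""
    return ComparisonResult(tavi=res_tavi, savr=res_savr, wtp=wtp)
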