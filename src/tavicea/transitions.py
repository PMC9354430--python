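"""Convert Kaplan-Meier milestone probabilities into per-cycle transitions.

The trials report cumulative event probabilities at a handful of landmark
times (30 days, 1, 2 and 5 years).  The model needs a conditional monthly
probability for every cycle.  Within each landmark interval the monthly
event *rate* is taken as constant, so the conditional probability ``p``
satisfies ``(1 - p)^n = S(end) / S(start)``.  All-cause mortality across
intervals that extend beyond month 24 instead accrues a constant monthly
*increment of cumulative probability* (a linear rise of the KM curve),
reflecting how the five-year mortality points were projected from two-year
curves; either bridging reproduces every landmark value exactly.

All-cause mortality applies to the whole cohort; patients in the stroke
state carry an elevated hazard (a hazard ratio by month since stroke onset)
for 15 months.  Writing ``M`` for the cohort monthly mortality, ``X_d`` for
the fraction of survivors ``d`` months after a stroke and ``RR_d`` for the
corresponding hazard ratio, the no-stroke mortality is the unknown of the
mixture identity ``M = sum_d X_d RR_d M_NS + (1 - sum_d X_d) M_NS``, i.e.
``M_NS = M / [sum_d X_d RR_d + (1 - sum_d X_d)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    AE_EVENTS,
    Arm,
    Event,
    INDEPENDENT_AE_EVENTS,
    MilestoneKind,
    MilestoneTable,
    ModelSpec,
)

__all__ = [
    "interval_monthly_prob",
    "km_schedule_to_monthly",
    "split_mortality_by_stroke",
    "build_transition_schedule",
    "TransitionSchedule",
    "cumulative_incidence",
    "N_DURATION_STRATA",
]

#: stroke-duration strata tracked explicitly; the last bucket absorbs
#: durations past the hazard-ratio schedule (HR = hr_after there).
N_DURATION_STRATA = 16


def interval_monthly_prob(s_start: float, s_end: float, n_cycles: int) -> float:
    """Constant conditional monthly probability over a milestone interval.

    Returns ``p`` with ``(1 - p)^n_cycles = s_end / s_start``, the constant
    monthly event rate consistent with event-free probabilities ``s_start``
    and ``s_end`` at the interval ends.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not 0.0 <= s_end <= s_start <= 1.0:
        raise ValueError(
            f"need 0 <= s_end <= s_start <= 1, got s_start={s_start}, s_end={s_end} "
            "(decreasing event-free probability signals a non-monotone cumulative table)"
        )
    if s_start == 0.0:
        raise ValueError("s_start must be > 0")
    if s_end == 0.0:
        return 1.0
    return 1.0 - (s_end / s_start) ** (1.0 / n_cycles)


def _extend_rate(times: list[int], surv: list[float]) -> float:
    """Monthly rate used past the last milestone: the last interval's constant rate."""
    if len(times) == 1:
        t0, s0 = 0, 1.0
    else:
        t0, s0 = times[-2], surv[-2]
    return interval_monthly_prob(s0, surv[-1], times[-1] - t0)


def km_schedule_to_monthly(
    table: MilestoneTable,
    horizon_months: int,
    late_mortality_bridging: str = "linear",
) -> np.ndarray:
    """Per-cycle conditional incidence probabilities reproducing every milestone.

    Returns an array ``q`` of length ``horizon_months``; ``q[t-1]`` is the
    probability of the event in cycle ``t`` conditional on being event-free.
    Cumulative incidence ``1 - prod(1 - q)`` equals the table value at every
    milestone.  Prevalence tables (PAR) are first reduced to effective
    cumulative incidence by accumulating only the positive prevalence
    increments (a falling prevalence generates no new events and no refunds).
    Beyond the last milestone the last interval's constant rate continues.
    """
    problems = table.validate()
    if problems:
        raise ValueError("; ".join(problems))
    times = [t for t, _ in table.milestones]
    probs = [p for _, p in table.milestones]

    if table.kind is MilestoneKind.PREVALENCE:
        eff, prev = [], 0.0
        last = 0.0
        for p in probs:
            eff_inc = max(p - prev, 0.0)
            prev = p
            last = last + eff_inc * (1.0 - last)  # keep within [0, 1]
            eff.append(last)
        probs = eff

    surv = [1.0 - p for p in probs]
    q = np.zeros(horizon_months)
    linear_late = (
        table.event is Event.ALL_CAUSE_MORTALITY and late_mortality_bridging == "linear"
    )

    t_prev, s_prev, c_prev = 0, 1.0, 0.0
    for t_k, s_k in zip(times, surv):
        n = t_k - t_prev
        lo, hi = t_prev, min(t_k, horizon_months)  # cycles t_prev+1 .. t_k
        if lo >= horizon_months:
            break
        if linear_late and t_k > 24 and n > 1:
            # constant increment of cumulative probability across the interval
            c_k = 1.0 - s_k
            delta = (c_k - c_prev) / n
            c_grid = c_prev + delta * np.arange(0, hi - lo + 1)
            s_grid = 1.0 - c_grid
            with np.errstate(divide="ignore", invalid="ignore"):
                q[lo:hi] = np.where(s_grid[:-1] > 0, 1.0 - s_grid[1:] / s_grid[:-1], 1.0)
        else:
            q[lo:hi] = interval_monthly_prob(s_prev, s_k, n)
        t_prev, s_prev, c_prev = t_k, s_k, 1.0 - s_k

    if horizon_months > times[-1]:
        q[times[-1]:] = _extend_rate(times, surv)
    return q


def cumulative_incidence(q: np.ndarray) -> np.ndarray:
    """Cumulative incidence after each cycle implied by conditional probabilities."""
    return 1.0 - np.cumprod(1.0 - np.asarray(q))


def split_mortality_by_stroke(
    m_all: float, x_stroke: float, rr: float
) -> tuple[float, float]:
    """Split cohort mortality into no-stroke and stroke monthly probabilities.

    ``m_no_stroke = m_all / [x * rr + (1 - x)]`` and ``m_stroke = rr *
    m_no_stroke`` (capped at 1).  When uncapped, the mixture
    ``x * m_stroke + (1 - x) * m_no_stroke`` recovers ``m_all`` exactly.
    """
    if not 0.0 <= m_all <= 1.0:
        raise ValueError(f"m_all {m_all} outside [0, 1]")
    if not 0.0 <= x_stroke <= 1.0:
        raise ValueError(f"x_stroke {x_stroke} outside [0, 1]")
    if rr < 1.0:
        raise ValueError(f"rr {rr} must be >= 1")
    m_ns = m_all / (x_stroke * rr + (1.0 - x_stroke))
    return m_ns, min(rr * m_ns, 1.0)


@dataclass
class TransitionSchedule:
    """Per-cycle transition and incidence probabilities for one arm.

    Arrays are indexed so position ``t-1`` holds cycle ``t``.  The
    stroke-state death probability depends on months since stroke onset:
    stratum ``d`` (1-based) dies with ``min(hr_by_duration[d-1] *
    p_death_no_stroke, 1)``; the last stratum pools all longer durations.
    ``occupancy`` is the reference state mixture used to derive the
    no-stroke mortality from cohort mortality (columns: no-stroke, the
    duration strata, dead).
    """

    arm: Arm
    horizon_months: int
    m_all: np.ndarray                    # cohort monthly mortality
    p_death_no_stroke: np.ndarray
    p_stroke_incidence: np.ndarray       # conditional on alive & stroke-free
    p_ae: dict[Event, np.ndarray]        # conditional on alive & event-free
    hr_by_duration: np.ndarray           # length N_DURATION_STRATA
    occupancy: np.ndarray = field(repr=False, default=None)  # (H+1, strata+2)

    def p_death_stroke(self, cycle: int, months_since_stroke: int) -> float:
        d = min(months_since_stroke, N_DURATION_STRATA)
        return min(self.hr_by_duration[d - 1] * self.p_death_no_stroke[cycle - 1], 1.0)

    @property
    def p_death_stroke_by_duration(self) -> np.ndarray:
        """(H, strata) matrix of stroke-state death probabilities."""
        return np.minimum(self.p_death_no_stroke[:, None] * self.hr_by_duration[None, :], 1.0)

    def cumulative_mortality(self) -> np.ndarray:
        return cumulative_incidence(self.m_all)


def build_transition_schedule(spec: ModelSpec, arm: Arm) -> TransitionSchedule:
    """Build the full per-cycle schedule for one arm of a validated spec.

    Runs the stroke-duration-stratified state recursion to obtain, cycle by
    cycle, the mixture weights that turn cohort mortality into the no-stroke
    mortality; the implied cohort survival reproduces the mortality
    milestones exactly (capping of stroke-state probabilities at 1 never
    binds with the bundled inputs).
    """
    spec.require_valid()
    H = spec.settings.horizon_months
    bridge = spec.settings.late_mortality_bridging
    m_all = km_schedule_to_monthly(
        spec.table(Event.ALL_CAUSE_MORTALITY, arm), H, late_mortality_bridging=bridge
    )
    p_stroke = km_schedule_to_monthly(spec.table(Event.DISABLING_STROKE, arm), H)
    p_ae = {
        ev: km_schedule_to_monthly(spec.table(ev, arm), H)
        for ev in INDEPENDENT_AE_EVENTS
    }

    hrs = np.array(
        [spec.hazard_ratios.hr(d) for d in range(1, N_DURATION_STRATA)]
        + [spec.hazard_ratios.hr_after],
        dtype=float,
    )

    # reference occupancy recursion: columns 0 = no-stroke, 1..16 = stroke
    # duration strata (months since onset), 17 = dead.
    n_cols = N_DURATION_STRATA + 2
    occ = np.zeros((H + 1, n_cols))
    occ[0, 0] = 1.0
    m_ns = np.zeros(H)
    x_ns = 1.0
    x_s = np.zeros(N_DURATION_STRATA)
    dead = 0.0
    for t in range(1, H + 1):
        # stroke onsets precede deaths within the cycle (onset month = duration 1)
        new_stroke = x_ns * p_stroke[t - 1]
        x_ns -= new_stroke
        aged = x_s[:-2].copy()
        x_s[-1] += x_s[-2]
        x_s[1:-1] = aged
        x_s[0] = new_stroke
        alive = x_ns + x_s.sum()
        if alive <= 0.0:
            m_ns[t - 1] = 0.0
            occ[t] = occ[t - 1]
            continue
        denom = x_ns + float(x_s @ hrs)
        m = m_all[t - 1]
        m_ns_t = m * alive / denom
        p_s = np.minimum(hrs * m_ns_t, 1.0)
        if np.any(hrs * m_ns_t > 1.0):
            # redistribute the excess so the cohort mortality is preserved
            for _ in range(50):
                capped = hrs * m_ns_t >= 1.0
                fixed = float(x_s[capped].sum())
                den = x_ns + float(x_s[~capped] @ hrs[~capped])
                if den <= 0.0:
                    break
                m_ns_t = max((m * alive - fixed) / den, 0.0)
                if not np.any(hrs[~capped] * m_ns_t > 1.0):
                    break
            p_s = np.minimum(hrs * m_ns_t, 1.0)
        m_ns[t - 1] = m_ns_t
        deaths = x_ns * m_ns_t + float(x_s @ p_s)
        x_ns *= 1.0 - m_ns_t
        x_s *= 1.0 - p_s
        dead += deaths
        occ[t, 0] = x_ns
        occ[t, 1:-1] = x_s
        occ[t, -1] = dead

    return TransitionSchedule(
        arm=arm,
        horizon_months=H,
        m_all=m_all,
        p_death_no_stroke=m_ns,
        p_stroke_incidence=p_stroke,
        p_ae=p_ae,
        hr_by_duration=hrs,
        occupancy=occ,
    )
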