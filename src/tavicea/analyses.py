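"""Analysis orchestration: base case, OWSA/tornado, PSA/CEAC, scenarios.

* The base case evaluates the bundled parameter set either as a
  deterministic cohort trace (exact expectation) or as a first-order
  microsimulation.
* One-way sensitivity analysis (OWSA) moves one parameter at a time to its
  95% CI bounds where reported, otherwise +/-20% (discount rate: 0-5%),
  re-evaluating deterministically so the tornado reflects parameter effects
  rather than first-order noise.
* The probabilistic sensitivity analysis draws first-month event
  probabilities and utilities from beta distributions and AE treatment
  costs from gamma distributions (method of moments), evaluates each draw,
  and summarises the mean ICER (ratio of mean increments) and the
  cost-effectiveness acceptability curve CEAC(w) = P(INB(w) > 0).
* Scenarios: (1) PARTNER S3i clinical inputs, (2) SURTAVI clinical inputs,
  (3) 20-year horizon, (4) AE disutilities switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Arm, Event, ModelSpec, builtin_parameter_set
from .engine import CEResult, ComparisonResult, compare, run_cohort, run_microsim
from .transitions import build_transition_schedule

__all__ = [
    "base_case",
    "evaluate",
    "mortality_crossover_cycle",
    "OwsaResult",
    "owsa",
    "owsa_parameter_names",
    "sample_from_moments",
    "CeacCurve",
    "PsaResult",
    "psa",
    "SCENARIO_NAMES",
    "run_scenario",
]

SCENARIO_NAMES = {
    "scenario1": "s3i_scenario1",
    "scenario2": "surtavi_scenario2",
    "scenario3": "horizon20_scenario3",
    "scenario4": "base_with_disutilities",
}


def evaluate(spec: ModelSpec, mode: str = "cohort") -> ComparisonResult:
    """Evaluate both arms of a spec and compare them at the configured WTP."""
    if mode == "cohort":
        results = {arm: run_cohort(spec, arm)[1] for arm in Arm}
    elif mode == "microsim":
        seeds = np.random.SeedSequence(spec.settings.seed).spawn(2)
        results = {
            arm: run_microsim(spec, arm, seed=int(ss.generate_state(1)[0] % 2**31))
            for arm, ss in zip(Arm, seeds)
        }
    else:
        raise ValueError(f"unknown mode {mode!r} (use 'cohort' or 'microsim')")
    return compare(results[Arm.TAVI], results[Arm.SAVR], spec.settings.wtp)


def base_case(spec: ModelSpec | None = None, mode: str = "cohort") -> ComparisonResult:
    """Run the base-case comparison (bundled PARTNER 2A parameter set)."""
    if spec is None:
        spec = builtin_parameter_set("partner2a_base")
    return evaluate(spec, mode=mode)


def mortality_crossover_cycle(spec: ModelSpec | None = None) -> int | None:
    """First cycle at which cumulative TAVI mortality exceeds SAVR (cohort mode)."""
    if spec is None:
        spec = builtin_parameter_set("partner2a_base")
    cum = {
        arm: build_transition_schedule(spec, arm).cumulative_mortality() for arm in Arm
    }
    above = np.nonzero(cum[Arm.TAVI] > cum[Arm.SAVR])[0]
    return int(above[0]) + 1 if above.size else None


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OwsaResult:
    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    base_icer: float | None

    @property
    def width(self) -> float:
        """Tornado bar width: ICER span across the two bounds."""
        vals = [v for v in (self.icer_low, self.icer_high) if v is not None]
        if len(vals) < 2:
            return float("inf")  # a dominance flip outranks any finite bar
        return abs(vals[1] - vals[0])


def _owsa_bounds(spec: ModelSpec, name: str) -> tuple[float, float]:
    if name == "discount_rate":
        return 0.0, 0.05
    kind, _, rest = name.partition(".")
    if kind == "cost" and rest.startswith("index."):
        mean = spec.costs.index_episode[Arm(rest.removeprefix("index."))]
        return 0.8 * mean, 1.2 * mean
    if kind == "cost" and rest.startswith("ae."):
        cp = spec.costs.ae_costs[Event(rest.removeprefix("ae."))]
        if cp.ci_low is not None:
            return cp.ci_low, cp.ci_high
        if cp.mean is None:
            raise ValueError(f"{name}: no CI and no mean to form +/-20% bounds")
        return 0.8 * cp.mean, 1.2 * cp.mean
    if kind == "cost" and rest in ("followup_annual", "neurologist_visit"):
        mean = getattr(spec.costs, rest)
        return 0.8 * mean, 1.2 * mean
    if kind == "utility":
        arm_s, _, month_s = rest.partition(".month")
        node = spec.utilities[Arm(arm_s)].nodes[int(month_s)]
        if node.ci_low is not None:
            return node.ci_low, node.ci_high
        return 0.8 * node.mean, min(1.2 * node.mean, 1.0)
    raise ValueError(f"unknown OWSA parameter {name!r}")


def _owsa_apply(spec: ModelSpec, name: str, value: float) -> ModelSpec:
    out = spec.copy()
    if name == "discount_rate":
        out.settings.annual_discount = value
        return out
    kind, _, rest = name.partition(".")
    if kind == "cost" and rest.startswith("index."):
        out.costs.index_episode[Arm(rest.removeprefix("index."))] = value
        return out
    if kind == "cost" and rest.startswith("ae."):
        out.costs.ae_costs[Event(rest.removeprefix("ae."))].mean = value
        return out
    if kind == "cost":
        setattr(out.costs, rest, value)
        return out
    if kind == "utility":
        arm_s, _, month_s = rest.partition(".month")
        arm, month = Arm(arm_s), int(month_s)
        out.utilities[arm].nodes[month].mean = value
        if arm is Arm.TAVI and month == out.utilities[arm].pooled_after_month:
            # the pooled post-24-month utility is the last TAVI value
            for traj in out.utilities.values():
                traj.pooled_value = value
        return out
    raise ValueError(f"unknown OWSA parameter {name!r}")


def owsa_parameter_names(spec: ModelSpec) -> list[str]:
    """Default OWSA set: discount, index costs, AE costs, utility nodes."""
    names = ["discount_rate"]
    names += [f"cost.index.{arm.value}" for arm in Arm]
    names += [f"cost.ae.{ev.value}" for ev in spec.costs.ae_costs]
    names += [
        f"utility.{arm.value}.month{m}"
        for arm in Arm
        for m in sorted(spec.utilities[arm].nodes)
    ]
    return names


def owsa(
    spec: ModelSpec | None = None,
    parameters: list[str] | None = None,
    mode: str = "cohort",
) -> list[OwsaResult]:
    """One-way sensitivity analysis; results sorted by descending bar width."""
    if spec is None:
        spec = builtin_parameter_set("partner2a_base")
    spec.require_valid()
    if parameters is None:
        parameters = owsa_parameter_names(spec)
    base_icer = evaluate(spec, mode=mode).icer
    results = []
    for name in parameters:
        lo, hi = _owsa_bounds(spec, name)
        icer_lo = evaluate(_owsa_apply(spec, name, lo), mode=mode).icer
        icer_hi = evaluate(_owsa_apply(spec, name, hi), mode=mode).icer
        results.append(
            OwsaResult(parameter=name, low=lo, high=hi,
                       icer_low=icer_lo, icer_high=icer_hi, base_icer=base_icer)
        )
    results.sort(key=lambda r: -r.width)
    return results


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_from_moments(
    kind: str, mean: float, sd: float, rng: np.random.Generator
) -> float:
    """Draw from a beta or gamma distribution parameterised by its moments.

    ``sd = 0`` degenerates to the mean.  Infeasible beta moments
    (``sd^2 >= mean * (1 - mean)``) raise instead of being clamped.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0.0:
        return float(mean)
    if kind == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"beta mean {mean} must be in (0, 1)")
        if sd * sd >= mean * (1.0 - mean):
            raise ValueError(
                f"infeasible beta moments: sd^2 = {sd * sd:.6g} >= "
                f"mean*(1-mean) = {mean * (1.0 - mean):.6g}"
            )
        nu = mean * (1.0 - mean) / (sd * sd) - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    if kind == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be > 0")
        shape = (mean / sd) ** 2
        return float(rng.gamma(shape, sd * sd / mean))
    raise ValueError(f"unknown distribution kind {kind!r}")


#: spread assumed for first-month probabilities with no reported CI:
#: +/-20% read as a 95% interval, so sd = 0.2 * mean / 1.96.
_PROB_REL_SD = 0.2 / 1.96


@dataclass
class CeacCurve:
    """Probability that TAVI is cost-effective across a WTP grid."""

    wtp: np.ndarray
    prob_tavi: np.ndarray

    def crossing_wtp(self, level: float = 0.5) -> float | None:
        """Interpolated WTP where the acceptability curve first reaches ``level``."""
        idx = np.nonzero(self.prob_tavi >= level)[0]
        if idx.size == 0:
            return None
        i = int(idx[0])
        if i == 0:
            return float(self.wtp[0])
        w0, w1 = self.wtp[i - 1], self.wtp[i]
        p0, p1 = self.prob_tavi[i - 1], self.prob_tavi[i]
        if p1 == p0:
            return float(w1)
        return float(w0 + (level - p0) * (w1 - w0) / (p1 - p0))


@dataclass
class PsaResult:
    samples: pd.DataFrame = field(repr=False)
    mean_icer: float
    ceac: CeacCurve
    mean_icer_per_draw: float = float("nan")

    @property
    def n(self) -> int:
        return len(self.samples)


def _psa_draw_spec(
    spec: ModelSpec, rng: np.random.Generator, scale: float = 1.0, max_retries: int = 100
) -> tuple[ModelSpec, dict[str, float]]:
    """One second-order draw of all uncertain parameters.

    ``scale`` multiplies every sd (0 collapses the PSA onto the base case).
    """
    out = spec.copy()
    params: dict[str, float] = {}
    # first-month (first-milestone) event probabilities: beta
    for (ev, arm), table in out.milestones.items():
        t0, p0 = table.milestones[0]
        if p0 <= 0.0 or p0 >= 1.0:
            continue  # degenerate probability has no beta representation
        sd = _PROB_REL_SD * p0 * scale
        cap = table.milestones[1][1] if len(table.milestones) > 1 else 1.0
        for attempt in range(max_retries):
            draw = sample_from_moments("beta", p0, sd, rng)
            if table.kind.value != "cumulative_incidence" or draw <= cap:
                break
        else:
            raise RuntimeError(
                f"PSA: could not draw a monotone first milestone for "
                f"{ev.value}/{arm.value} in {max_retries} tries"
            )
        table.milestones[0] = (t0, draw)
        params[f"p.{ev.value}.{arm.value}"] = draw
    # utilities: beta with sd from the reported CI
    for arm, traj in out.utilities.items():
        for month in sorted(traj.nodes):
            node = traj.nodes[month]
            if node.ci_low is None:
                continue
            sd = (node.ci_high - node.ci_low) / 3.92 * scale
            draw = sample_from_moments("beta", node.mean, sd, rng)
            node.mean = draw
            params[f"u.{arm.value}.month{month}"] = draw
            if arm is Arm.TAVI and month == traj.pooled_after_month:
                for tr in out.utilities.values():
                    tr.pooled_value = draw
    # AE treatment costs: gamma
    for ev, cp in out.costs.ae_costs.items():
        if cp.sd <= 0:
            continue
        draw = sample_from_moments("gamma", cp.mean, cp.sd * scale, rng)
        cp.mean = draw
        cp.ci_low = cp.ci_high = None  # the CI described the pre-draw mean
        params[f"c.{ev.value}"] = draw
    return out, params


def psa(
    spec: ModelSpec | None = None,
    n_outer: int | None = None,
    seed: int | None = None,
    mode: str = "cohort",
    wtp_grid: np.ndarray | None = None,
    sd_scale: float = 1.0,
) -> PsaResult:
    """Probabilistic sensitivity analysis over ``n_outer`` parameter draws.

    Each draw is evaluated in cohort mode by default (the exact expectation,
    so all variance shown is second-order).  The headline mean ICER is the
    ratio of mean increments; the unstable mean of per-draw ICERs is also
    reported for reference.
    """
    if spec is None:
        spec = builtin_parameter_set("partner2a_base")
    spec.require_valid()
    n_outer = spec.settings.n_psa if n_outer is None else n_outer
    if n_outer < 2:
        raise ValueError("n_outer must be >= 2")
    seed = spec.settings.seed if seed is None else seed
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 650_001.0, 5_000.0)
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(n_outer):
        drawn, params = _psa_draw_spec(spec, rng, scale=sd_scale)
        res = evaluate(drawn, mode=mode)
        row = {
            "draw": i,
            "cost_tavi": res.tavi.cost,
            "cost_savr": res.savr.cost,
            "qaly_tavi": res.tavi.qaly,
            "qaly_savr": res.savr.qaly,
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "icer": np.nan if res.icer is None else res.icer,
            "inb": res.inb(),
        }
        row.update(params)
        rows.append(row)
    samples = pd.DataFrame(rows)

    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qaly"].to_numpy()
    mean_icer = float(dc.mean() / dq.mean())
    inb_grid = wtp_grid[None, :] * dq[:, None] - dc[:, None]
    ceac = CeacCurve(wtp=wtp_grid, prob_tavi=(inb_grid > 0).mean(axis=0))
    with np.errstate(invalid="ignore"):
        per_draw = float(np.nanmean(samples["icer"].to_numpy()))
    return PsaResult(samples=samples, mean_icer=mean_icer, ceac=ceac,
                     mean_icer_per_draw=per_draw)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def run_scenario(
    name: str, base: ModelSpec | None = None, mode: str = "cohort"
) -> ComparisonResult:
    """Evaluate one of the four scenario analyses (or a builtin set by name)."""
    builtin = SCENARIO_NAMES.get(name, name)
    if builtin not in (
        "s3i_scenario1", "surtavi_scenario2", "horizon20_scenario3",
        "base_with_disutilities", "partner2a_base",
    ):
        raise KeyError(f"unknown scenario {name!r}")
    if builtin == "horizon20_scenario3" and base is not None:
        spec = base.copy()
        spec.settings.horizon_months = 240
    else:
        spec = builtin_parameter_set(builtin)
    result = evaluate(spec, mode=mode)
    result.spec = spec  # handy for reporting
    return result
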