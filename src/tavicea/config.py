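"""Model inputs: validated, serialisable parameter sets.

The model consumes one flat YAML file per analysis.  Each file holds the
clinical milestone tables (Kaplan-Meier cumulative incidences, or prevalences
for paravalvular regurgitation, at 30 days / 1 y / 2 y / 5 y), the
stroke-vs-no-stroke mortality hazard-ratio schedule, episode and
adverse-event costs (2020 US$), EQ-5D utility trajectories, and the analysis
settings (horizon, cycle length, discounting, Monte Carlo sizes, seed).

Bundled parameter sets live in :mod:`tavicea.data` and are accessed through
:func:`builtin_parameter_set`.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "Arm",
    "Event",
    "AE_EVENTS",
    "MilestoneKind",
    "MilestoneTable",
    "HazardRatioSchedule",
    "CostParam",
    "CostTable",
    "UtilityNode",
    "UtilityTrajectory",
    "AnalysisSettings",
    "ModelSpec",
    "SpecValidationError",
    "load_model_spec",
    "save_model_spec",
    "builtin_parameter_set",
    "BUILTIN_NAMES",
]


class Arm(str, enum.Enum):
    """Treatment arm: transcatheter (TAVI) or surgical (SAVR) valve replacement."""

    TAVI = "tavi"
    SAVR = "savr"


class Event(str, enum.Enum):
    """Clinical outcomes tracked by the model (VARC-style endpoints)."""

    ALL_CAUSE_MORTALITY = "all_cause_mortality"
    DISABLING_STROKE = "disabling_stroke"
    REHOSPITALISATION = "rehospitalisation"
    MI = "mi"
    MAJOR_VASCULAR = "major_vascular"
    BLEEDING = "bleeding"
    ENDOCARDITIS = "endocarditis"
    AKI = "aki"
    NEW_PPI = "new_ppi"
    TIA = "tia"
    AF = "af"
    PAR = "par"


#: Events that carry a one-time treatment cost (everything except death).
AE_EVENTS: tuple[Event, ...] = tuple(e for e in Event if e is not Event.ALL_CAUSE_MORTALITY)

#: Adverse events drawn independently of the health state (stroke drives the
#: state transition instead and is handled by the engine).
INDEPENDENT_AE_EVENTS: tuple[Event, ...] = tuple(
    e for e in AE_EVENTS if e is not Event.DISABLING_STROKE
)


class MilestoneKind(str, enum.Enum):
    CUMULATIVE_INCIDENCE = "cumulative_incidence"
    PREVALENCE = "prevalence"


class SpecValidationError(ValueError):
    """Raised when a parameter set violates its invariants.

    ``problems`` lists every violation found; nothing is silently fixed.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid model spec:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class MilestoneTable:
    """Milestone probabilities for one event in one arm.

    ``milestones`` is an ordered list of ``(time_in_months, probability)``.
    ``kind`` distinguishes cumulative incidences (non-decreasing) from
    prevalences (PAR), whose values may fall over time.
    """

    event: Event
    arm: Arm
    milestones: list[tuple[int, float]]
    kind: MilestoneKind = MilestoneKind.CUMULATIVE_INCIDENCE

    def validate(self) -> list[str]:
        tag = f"{self.event.value}/{self.arm.value}"
        problems: list[str] = []
        if not self.milestones:
            return [f"{tag}: empty milestone table"]
        times = [t for t, _ in self.milestones]
        probs = [p for _, p in self.milestones]
        if times[0] < 1:
            problems.append(f"{tag}: first milestone time {times[0]} is before month 1")
        if any(b <= a for a, b in zip(times, times[1:])):
            problems.append(f"{tag}: milestone times not strictly increasing: {times}")
        for t, p in self.milestones:
            if not 0.0 <= p <= 1.0:
                problems.append(f"{tag}: probability {p} at month {t} outside [0, 1]")
        if self.kind is MilestoneKind.CUMULATIVE_INCIDENCE and any(
            b < a for a, b in zip(probs, probs[1:])
        ):
            problems.append(f"{tag}: cumulative incidence decreases over time: {probs}")
        return problems


@dataclass
class HazardRatioSchedule:
    """Hazard ratio of death for stroke vs no-stroke patients, by months since stroke.

    ``hr_by_cycle[d-1]`` applies in the d-th month after stroke onset;
    ``hr_after`` (1 in the base case: no excess hazard beyond 15 months)
    applies thereafter.
    """

    hr_by_cycle: list[float]
    hr_after: float = 1.0

    def hr(self, months_since_stroke: int) -> float:
        if months_since_stroke < 1:
            raise ValueError("months_since_stroke starts at 1 (the onset month)")
        if months_since_stroke <= len(self.hr_by_cycle):
            return self.hr_by_cycle[months_since_stroke - 1]
        return self.hr_after

    def validate(self) -> list[str]:
        problems = []
        for i, h in enumerate(self.hr_by_cycle, start=1):
            if h < 1.0:
                problems.append(f"hazard_ratios: HR {h} at post-stroke month {i} is < 1")
        if self.hr_after < 1.0:
            problems.append(f"hazard_ratios: hr_after {self.hr_after} is < 1")
        return problems


@dataclass
class CostParam:
    """Mean / SD / 95% CI of a one-time treatment cost, 2020 US$."""

    mean: float
    sd: float = 0.0
    ci_low: float | None = None
    ci_high: float | None = None

    def validate(self, tag: str) -> list[str]:
        problems = []
        if self.mean <= 0:
            problems.append(f"{tag}: mean cost {self.mean} not > 0")
        if self.sd < 0:
            problems.append(f"{tag}: sd {self.sd} < 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.mean <= self.ci_high:
                problems.append(
                    f"{tag}: CI ({self.ci_low}, {self.ci_high}) does not bracket mean {self.mean}"
                )
        return problems


@dataclass
class CostTable:
    """Index episode charges per arm plus AE / follow-up costs (2020 US$)."""

    index_episode: dict[Arm, float]
    ae_costs: dict[Event, CostParam]
    followup_annual: float
    neurologist_visit: float

    def validate(self) -> list[str]:
        problems = []
        for arm in Arm:
            if arm not in self.index_episode:
                problems.append(f"costs: missing index episode cost for arm {arm.value}")
            elif self.index_episode[arm] <= 0:
                problems.append(f"costs: index episode cost for {arm.value} not > 0")
        for ev, cp in self.ae_costs.items():
            problems += cp.validate(f"costs.ae.{ev.value}")
        if self.followup_annual <= 0:
            problems.append("costs: annual follow-up cost not > 0")
        if self.neurologist_visit <= 0:
            problems.append("costs: neurologist visit cost not > 0")
        return problems


@dataclass
class UtilityNode:
    mean: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class UtilityTrajectory:
    """EQ-5D utilities at months 1, 12 and 24, pooled to one value afterwards.

    The trial reported no utilities beyond 24 months, so the last TAVI value
    is applied to both arms in all later cycles (``pooled_value``).
    """

    arm: Arm
    nodes: dict[int, UtilityNode]
    pooled_after_month: int = 24
    pooled_value: float = 0.78

    def validate(self) -> list[str]:
        problems = []
        tag = f"utilities.{self.arm.value}"
        for month in (1, 12, 24):
            if month not in self.nodes:
                problems.append(f"{tag}: missing node at month {month}")
        for month, node in self.nodes.items():
            if not 0.0 <= node.mean <= 1.0:
                problems.append(f"{tag}: utility {node.mean} at month {month} outside [0, 1]")
        if not 0.0 <= self.pooled_value <= 1.0:
            problems.append(f"{tag}: pooled utility {self.pooled_value} outside [0, 1]")
        return problems


@dataclass
class AnalysisSettings:
    """Run settings: 5-y horizon, monthly cycles, 3%/y discounting, WTP, MC sizes."""

    horizon_months: int = 60
    cycle_length_months: int = 1
    annual_discount: float = 0.03
    wtp: float = 34091.0
    n_microsim: int = 10_000
    n_psa: int = 5_000
    seed: int = 1
    apply_ae_disutilities: bool = False
    #: bridging of all-cause mortality across milestone intervals that extend
    #: beyond month 24: "linear" (linear-in-cumulative-probability, default)
    #: or "constant" (constant monthly rate, like every other interval).
    late_mortality_bridging: str = "linear"
    half_cycle_correction: bool = False
    #: reporting-only conversion rate (US$1 = S$1.32); never applied internally.
    usd_to_sgd: float = 1.32

    def validate(self) -> list[str]:
        problems = []
        if self.horizon_months % 12 != 0:
            problems.append(f"settings: horizon_months {self.horizon_months} not a multiple of 12")
        if not 0.0 <= self.annual_discount <= 0.05:
            problems.append(f"settings: annual_discount {self.annual_discount} outside [0, 0.05]")
        if self.cycle_length_months != 1:
            problems.append("settings: only monthly cycles are supported")
        if self.late_mortality_bridging not in ("linear", "constant"):
            problems.append(
                f"settings: late_mortality_bridging {self.late_mortality_bridging!r} "
                "must be 'linear' or 'constant'"
            )
        return problems


@dataclass
class AeDisutilities:
    """QALY decrements for adverse events (scenario analysis only).

    ``stroke_per_cycle`` is a utility decrement applied every cycle spent in
    the stroke state; ``one_off`` are one-time QALY losses charged when an AE
    occurs.
    """

    stroke_per_cycle: float = 0.161
    one_off: dict[Event, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if not 0 <= self.stroke_per_cycle <= 1:
            problems.append("ae_disutilities: stroke_per_cycle outside [0, 1]")
        for ev, d in self.one_off.items():
            if d < 0:
                problems.append(f"ae_disutilities: one-off decrement for {ev.value} is negative")
        return problems


@dataclass
class ModelSpec:
    """Complete parameter bundle for one TAVI-vs-SAVR comparison."""

    name: str
    milestones: dict[tuple[Event, Arm], MilestoneTable]
    hazard_ratios: HazardRatioSchedule
    costs: CostTable
    utilities: dict[Arm, UtilityTrajectory]
    settings: AnalysisSettings
    ae_disutilities: AeDisutilities | None = None
    description: str = ""

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Return every invariant violation (empty list = valid)."""
        problems: list[str] = []
        for table in self.milestones.values():
            problems += table.validate()
        for ev in Event:
            for arm in Arm:
                if (ev, arm) not in self.milestones:
                    problems.append(f"missing milestone table for {ev.value}/{arm.value}")
        for ev in self.costs.ae_costs:
            for arm in Arm:
                if (ev, arm) not in self.milestones:
                    problems.append(
                        f"costs reference event {ev.value} with no milestone table for {arm.value}"
                    )
        problems += self.hazard_ratios.validate()
        problems += self.costs.validate()
        for arm in Arm:
            if arm not in self.utilities:
                problems.append(f"missing utility trajectory for arm {arm.value}")
            else:
                problems += self.utilities[arm].validate()
        problems += self.settings.validate()
        if self.ae_disutilities is not None:
            problems += self.ae_disutilities.validate()
        if self.settings.apply_ae_disutilities and self.ae_disutilities is None:
            problems.append("settings request AE disutilities but none are provided")
        return problems

    def require_valid(self) -> "ModelSpec":
        problems = self.validate()
        if problems:
            raise SpecValidationError(problems)
        return self

    # -- convenience --------------------------------------------------------

    def table(self, event: Event, arm: Arm) -> MilestoneTable:
        return self.milestones[(event, arm)]

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def to_frame(self) -> pd.DataFrame:
        """Flatten the spec into a tidy frame for CSV audit export."""
        rows = []
        for (ev, arm), tab in sorted(
            self.milestones.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            for t, p in tab.milestones:
                rows.append(
                    {"group": "milestone", "name": f"{ev.value}.{arm.value}.month{t}",
                     "value": p, "kind": tab.kind.value}
                )
        for i, h in enumerate(self.hazard_ratios.hr_by_cycle, start=1):
            rows.append({"group": "hazard_ratio", "name": f"post_stroke_month_{i}", "value": h})
        rows.append({"group": "hazard_ratio", "name": "after", "value": self.hazard_ratios.hr_after})
        for arm in Arm:
            rows.append({"group": "cost", "name": f"index_episode.{arm.value}",
                         "value": self.costs.index_episode[arm]})
        for ev, cp in self.costs.ae_costs.items():
            rows.append({"group": "cost", "name": f"ae.{ev.value}", "value": cp.mean})
        rows.append({"group": "cost", "name": "followup_annual", "value": self.costs.followup_annual})
        rows.append({"group": "cost", "name": "neurologist_visit",
                     "value": self.costs.neurologist_visit})
        for arm, traj in self.utilities.items():
            for month, node in sorted(traj.nodes.items()):
                rows.append({"group": "utility", "name": f"{arm.value}.month{month}",
                             "value": node.mean})
        for f in dataclasses.fields(self.settings):
            rows.append({"group": "setting", "name": f.name,
                         "value": getattr(self.settings, f.name)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: ModelSpec) -> dict:
    events: dict = {}
    for ev in Event:
        entry: dict = {}
        tav = spec.milestones.get((ev, Arm.TAVI))
        sav = spec.milestones.get((ev, Arm.SAVR))
        if tav is None or sav is None:
            continue
        entry["kind"] = tav.kind.value
        entry["tavi"] = [[int(t), float(p)] for t, p in tav.milestones]
        entry["savr"] = [[int(t), float(p)] for t, p in sav.milestones]
        events[ev.value] = entry
    out = {
        "name": spec.name,
        "description": spec.description,
        "settings": dataclasses.asdict(spec.settings),
        "events": events,
        "hazard_ratios": {
            "by_post_stroke_month": [float(h) for h in spec.hazard_ratios.hr_by_cycle],
            "after": float(spec.hazard_ratios.hr_after),
        },
        "costs": {
            "index_episode": {a.value: float(spec.costs.index_episode[a]) for a in Arm},
            "followup_annual": float(spec.costs.followup_annual),
            "neurologist_visit": float(spec.costs.neurologist_visit),
            "ae": {
                ev.value: {
                    "mean": cp.mean, "sd": cp.sd,
                    "ci": None if cp.ci_low is None else [cp.ci_low, cp.ci_high],
                }
                for ev, cp in spec.costs.ae_costs.items()
            },
        },
        "utilities": {
            arm.value: {
                "nodes": {
                    int(m): {"mean": n.mean,
                             "ci": None if n.ci_low is None else [n.ci_low, n.ci_high]}
                    for m, n in traj.nodes.items()
                },
                "pooled_after_month": traj.pooled_after_month,
                "pooled_value": traj.pooled_value,
            }
            for arm, traj in spec.utilities.items()
        },
    }
    if spec.ae_disutilities is not None:
        out["ae_disutilities"] = {
            "stroke_per_cycle": spec.ae_disutilities.stroke_per_cycle,
            "one_off": {ev.value: d for ev, d in spec.ae_disutilities.one_off.items()},
        }
    return out


def _spec_from_dict(doc: dict, name_hint: str = "") -> ModelSpec:
    try:
        milestones: dict[tuple[Event, Arm], MilestoneTable] = {}
        for ev_name, entry in doc.get("events", {}).items():
            ev = Event(ev_name)
            kind = MilestoneKind(entry.get("kind", "cumulative_incidence"))
            for arm in Arm:
                pts = entry[arm.value]
                milestones[(ev, arm)] = MilestoneTable(
                    event=ev, arm=arm, kind=kind,
                    milestones=[(int(t), float(p)) for t, p in pts],
                )
        hr_doc = doc["hazard_ratios"]
        hrs = HazardRatioSchedule(
            hr_by_cycle=[float(h) for h in hr_doc["by_post_stroke_month"]],
            hr_after=float(hr_doc.get("after", 1.0)),
        )
        cdoc = doc["costs"]
        ae_costs = {}
        for ev_name, c in cdoc.get("ae", {}).items():
            ci = c.get("ci")
            ae_costs[Event(ev_name)] = CostParam(
                mean=float(c["mean"]), sd=float(c.get("sd", 0.0)),
                ci_low=None if ci is None else float(ci[0]),
                ci_high=None if ci is None else float(ci[1]),
            )
        costs = CostTable(
            index_episode={a: float(cdoc["index_episode"][a.value]) for a in Arm},
            ae_costs=ae_costs,
            followup_annual=float(cdoc["followup_annual"]),
            neurologist_visit=float(cdoc["neurologist_visit"]),
        )
        utilities = {}
        for arm in Arm:
            udoc = doc["utilities"][arm.value]
            nodes = {}
            for m, n in udoc["nodes"].items():
                ci = n.get("ci")
                nodes[int(m)] = UtilityNode(
                    mean=float(n["mean"]),
                    ci_low=None if ci is None else float(ci[0]),
                    ci_high=None if ci is None else float(ci[1]),
                )
            utilities[arm] = UtilityTrajectory(
                arm=arm, nodes=nodes,
                pooled_after_month=int(udoc.get("pooled_after_month", 24)),
                pooled_value=float(udoc["pooled_value"]),
            )
        known = {f.name for f in dataclasses.fields(AnalysisSettings)}
        settings = AnalysisSettings(
            **{k: v for k, v in doc.get("settings", {}).items() if k in known}
        )
        disutil = None
        if "ae_disutilities" in doc and doc["ae_disutilities"] is not None:
            ddoc = doc["ae_disutilities"]
            disutil = AeDisutilities(
                stroke_per_cycle=float(ddoc.get("stroke_per_cycle", 0.161)),
                one_off={Event(ev): float(d) for ev, d in ddoc.get("one_off", {}).items()},
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise SpecValidationError([f"cannot parse model spec: {exc!r}"]) from exc
    return ModelSpec(
        name=str(doc.get("name", name_hint)),
        description=str(doc.get("description", "")),
        milestones=milestones,
        hazard_ratios=hrs,
        costs=costs,
        utilities=utilities,
        settings=settings,
        ae_disutilities=disutil,
    )


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load and fully validate a model spec from a YAML file.

    Raises :class:`SpecValidationError` listing every violated invariant.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SpecValidationError([f"YAML parse failure in {path}: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise SpecValidationError([f"{path} does not contain a mapping"])
    spec = _spec_from_dict(doc, name_hint=path.stem)
    spec.require_valid()
    return spec


def save_model_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a spec back to YAML (round-trips through :func:`load_model_spec`)."""
    Path(path).write_text(yaml.safe_dump(_spec_to_dict(spec), sort_keys=False))


# ---------------------------------------------------------------------------
# bundled parameter sets
# ---------------------------------------------------------------------------

_BUILTIN_FILES = {
    "partner2a_base": "partner2a_base.yaml",
    "s3i_scenario1": "s3i_scenario1_synthetic.yaml",
    "surtavi_scenario2": "surtavi_scenario2_synthetic.yaml",
}

BUILTIN_NAMES = (
    "partner2a_base",
    "s3i_scenario1",
    "surtavi_scenario2",
    "base_with_disutilities",
    "horizon20_scenario3",
)


def builtin_data_path(filename: str) -> Path:
    return Path(str(resources.files("tavicea.data") / filename))


def builtin_parameter_set(name: str) -> ModelSpec:
    """Return the packaged parameter set for a named analysis.

    ``partner2a_base`` is the base case; ``s3i_scenario1`` and
    ``surtavi_scenario2`` swap in alternative clinical evidence;
    ``horizon20_scenario3`` extends the base case to 20 years;
    ``base_with_disutilities`` switches on AE disutilities.
    """
    if name in _BUILTIN_FILES:
        return load_model_spec(builtin_data_path(_BUILTIN_FILES[name]))
    if name == "horizon20_scenario3":
        spec = builtin_parameter_set("partner2a_base")
        spec.name = "horizon20_scenario3"
        spec.settings.horizon_months = 240
        return spec
    if name == "base_with_disutilities":
        spec = builtin_parameter_set("partner2a_base")
        spec.name = "base_with_disutilities"
        spec.settings.apply_ae_disutilities = True
        disutil_doc = yaml.safe_load(
            builtin_data_path("ae_disutilities_synthetic.yaml").read_text()
        )
        spec.ae_disutilities = AeDisutilities(
            stroke_per_cycle=float(disutil_doc["stroke_per_cycle"]),
            one_off={Event(ev): float(d) for ev, d in disutil_doc["one_off"].items()},
        )
        spec.require_valid()
        return spec
    raise KeyError(
        f"unknown parameter set {name!r}; available: {', '.join(BUILTIN_NAMES)}"
    )
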