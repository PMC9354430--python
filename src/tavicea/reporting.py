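"""Result tables (CSV), tornado/CEAC figures, and run manifests.

Every output file carries a leading ``# manifest: ...`` comment line tying
it to the JSON manifest of the run that produced it.  Result tables are
deterministic byte-for-byte for a fixed manifest (fixed seeds, fixed row
ordering); only the manifest itself carries a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .analyses import OwsaResult, PsaResult
from .engine import ComparisonResult

__all__ = [
    "RunManifest",
    "write_manifest",
    "write_comparison",
    "write_owsa",
    "write_psa",
    "tornado_figure",
    "ceac_figure",
]

MANIFEST_NAME = "manifest.json"


@dataclass
class RunManifest:
    analysis: str
    config: str
    seed: int
    mode: str
    package_version: str
    timestamp: str = ""
    flags: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def create(cls, analysis: str, config: str, seed: int, mode: str, flags: dict):
        from . import __version__

        return cls(
            analysis=analysis, config=config, seed=seed, mode=mode,
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            flags=flags,
        )


def write_manifest(manifest: RunManifest, out_dir: Path) -> Path:
    path = Path(out_dir) / MANIFEST_NAME
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return path


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {MANIFEST_NAME}\n")
        frame.to_csv(fh, index=False, float_format="%.6g")


def comparison_frame(result: ComparisonResult, sgd_rate: float | None = None) -> pd.DataFrame:
    """Base-case-style results table (per-arm totals, increments, ICER)."""
    unit = "2020 S$" if sgd_rate else "2020 US$"
    fx = sgd_rate or 1.0
    icer = result.icer
    rows = [
        {
            "Comparison": "TAVI",
            f"Costs, {unit}": result.tavi.cost * fx,
            f"Incremental costs, {unit}": result.delta_cost * fx,
            "QALYs": result.tavi.qaly,
            "Incremental QALYs": result.delta_qaly,
            f"ICER (cost per QALY), {unit}": (
                result.label if icer is None else icer * fx
            ),
        },
        {
            "Comparison": "SAVR",
            f"Costs, {unit}": result.savr.cost * fx,
            f"Incremental costs, {unit}": "-",
            "QALYs": result.savr.qaly,
            "Incremental QALYs": "-",
            f"ICER (cost per QALY), {unit}": "-",
        },
    ]
    return pd.DataFrame(rows)


def write_comparison(
    result: ComparisonResult, out_dir: Path, sgd_rate: float | None = None
) -> None:
    out_dir = Path(out_dir)
    _write_csv(comparison_frame(result, sgd_rate), out_dir / "comparison.csv")
    summary = pd.DataFrame(
        [{
            "delta_cost_usd2020": result.delta_cost,
            "delta_qaly": result.delta_qaly,
            "icer_usd_per_qaly": "" if result.icer is None else result.icer,
            "label": result.label,
            "wtp_usd_per_qaly": result.wtp,
            "inb_usd": result.inb(),
            "cost_components_tavi": json.dumps(result.tavi.cost_components),
            "cost_components_savr": json.dumps(result.savr.cost_components),
        }]
    )
    _write_csv(summary, out_dir / "summary.csv")


def owsa_frame(results: list[OwsaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "parameter": r.parameter,
            "low_input": r.low,
            "high_input": r.high,
            "icer_at_low_usd2020": r.icer_low,
            "icer_at_high_usd2020": r.icer_high,
            "base_icer_usd2020": r.base_icer,
            "bar_width": r.width,
        } for r in results]
    )


def write_owsa(results: list[OwsaResult], out_dir: Path) -> None:
    _write_csv(owsa_frame(results), Path(out_dir) / "owsa.csv")


def tornado_figure(results: list[OwsaResult], path: Path, top: int = 10) -> None:
    """Tornado diagram of the ``top`` widest OWSA bars."""
    rows = [r for r in results if r.icer_low is not None and r.icer_high is not None]
    rows = rows[:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.45 * max(len(rows), 4) + 1.2))
    for i, r in enumerate(rows):
        lo, hi = sorted((r.icer_low, r.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(rows[0].base_icer if rows else 0.0, color="k", lw=1, ls="--",
               label="base-case ICER")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r.parameter for r in rows])
    ax.set_xlabel("ICER, 2020 US$ per QALY")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_psa(result: PsaResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    _write_csv(result.samples, out_dir / "psa_draws.csv")
    ceac = pd.DataFrame(
        {"wtp_usd_per_qaly": result.ceac.wtp, "prob_tavi_cost_effective": result.ceac.prob_tavi}
    )
    _write_csv(ceac, out_dir / "ceac.csv")
    crossing = result.ceac.crossing_wtp()
    summary = pd.DataFrame(
        [{
            "n_draws": result.n,
            "mean_icer_ratio_of_means_usd2020": result.mean_icer,
            "mean_icer_per_draw_usd2020": result.mean_icer_per_draw,
            "ceac_crossing_wtp_usd2020": "" if crossing is None else crossing,
        }]
    )
    _write_csv(summary, out_dir / "psa_summary.csv")


def ceac_figure(result: PsaResult, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(result.ceac.wtp / 1000.0, result.ceac.prob_tavi, label="TAVI")
    ax.plot(result.ceac.wtp / 1000.0, 1.0 - result.ceac.prob_tavi, label="SAVR")
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("Willingness to pay, thousand 2020 US$ per QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
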