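"""Full-report assembly: one call wiring every module together.

Produces the per-category time table, the savings-by-share money table,
the scenario evaluation with break-even columns, and (when an event log
is supplied) the usage metrics — as CSV files plus a single JSON summary
with stable key order and fixed float formatting, so identical inputs
give byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .analytics import usage_metrics
from .config import ModelParameters, load_parameters
from .economics import DEFAULT_S_GRID, breakeven_rate, savings_per_econsult, savings_table
from .scenarios import evaluate_scenarios, load_packaged_scenarios, saving_estimate
from .simulate import rosters_from_frame
from .timings import derive_per_type_resources, expected_resource, round_half_away

__all__ = ["RunConfig", "run_full_report"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for one report run."""

    out_dir: Path
    params_path: "Path | None" = None
    scenarios_path: "Path | None" = None
    log_path: "Path | None" = None
    roster_path: "Path | None" = None
    window_months: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.params_path, self.scenarios_path, self.log_path, self.roster_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file does not exist: {p}")


def _per_type_frame(params: ModelParameters) -> pd.DataFrame:
    per_type = derive_per_type_resources(params.timings, params.notes)
    rows = []
    for cat, res in per_type.items():
        rows.append(
            {
                "category": cat.value,
                "share": params.mix[cat],
                "admin_min": res.admin_minutes,
                "gp_min": res.gp_minutes,
            }
        )
    return pd.DataFrame(rows)


def run_full_report(config: RunConfig) -> dict:
    """Run the whole pipeline and write CSVs plus a JSON summary.

    Returns the summary dict. Economics is computed from the parameter
    file alone; the usage section appears only when an event log and a
    roster file are both supplied, and its presence never alters the
    economics section.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = load_parameters(config.params_path)

    per_type_df = _per_type_frame(params)
    per_type = derive_per_type_resources(params.timings, params.notes)
    expected = expected_resource(per_type, params.mix)
    admin_1dp, gp_1dp = expected.rounded(1)

    sav_df = savings_table(expected, params.costs, DEFAULT_S_GRID)

    if config.scenarios_path is not None:
        import yaml

        from .scenarios import CategoryMix, Scenario

        raw = yaml.safe_load(Path(config.scenarios_path).read_text())
        scenarios = [
            Scenario(
                name=i["name"],
                mix=CategoryMix.from_labels(i["mix"]),
                declared_admin_share=float(i["declared_admin_share"]),
                declared_recall_share=float(i["declared_recall_share"]),
            )
            for i in raw["scenarios"]
        ]
    else:
        scenarios = load_packaged_scenarios()
    scen_df = evaluate_scenarios(
        scenarios, params.timings, params.costs, params.induced, notes=params.notes
    )

    est = saving_estimate(params.mix, induced=params.induced)
    sav_at_raw = savings_per_econsult(expected, params.costs, est.raw_saved_fraction)
    be = breakeven_rate(sav_at_raw, params.costs)
    saved_pct, min_saved_pct = est.rounded_percent()

    summary: dict = {
        "version": __version__,
        "parameters": {
            "gp_cost_per_hour": params.costs.gp_cost_per_hour,
            "admin_cost_per_hour": params.costs.admin_cost_per_hour,
            "annual_charge_per_patient": params.costs.annual_charge_per_patient,
            "detailed_notes_fraction": params.notes.detailed_fraction,
            "induced_fraction": params.induced.induced_fraction,
        },
        "expected_resource": {
            "admin_minutes": round(expected.admin_minutes_per_econsult, 6),
            "gp_minutes": round(expected.gp_minutes_per_econsult, 6),
            "admin_minutes_1dp": admin_1dp,
            "gp_minutes_1dp": gp_1dp,
        },
        "appointments_saved": {
            "raw_fraction": round(est.raw_saved_fraction, 6),
            "adjusted_fraction": round(est.adjusted_saved_fraction, 6),
            "raw_pct": saved_pct,
            "min_pct": min_saved_pct,
        },
        "breakeven": {
            "at_raw_saved_fraction": (
                round(be.submissions_per_patient_per_year, 6) if be.defined else None
            ),
            "defined": be.defined,
        },
        "savings_grid": [
            {
                "saved_pct": float(r["appointments_saved_pct"]),
                "admin_gbp": float(r["admin_saving_gbp_1dp"]),
                "gp_gbp": float(r["gp_saving_gbp_1dp"]),
                "total_gbp": float(r["total_saving_gbp_1dp"]),
            }
            for _, r in sav_df.iterrows()
        ],
        "scenarios": [
            {
                "name": r["scenario"],
                "admin_min_1dp": round_half_away(r["admin_min"], 1),
                "gp_min_1dp": round_half_away(r["gp_min"], 1),
                "saved_pct": float(r["saved_pct"]),
                "min_saved_pct": float(r["min_saved_pct"]),
                "saving_gbp": round(r["saving_gbp"], 6),
                "min_saving_gbp": round(r["min_saving_gbp"], 6),
                "breakeven_rate": (
                    round(r["breakeven_rate"], 6) if pd.notna(r["breakeven_rate"]) else None
                ),
                "min_breakeven_rate": (
                    round(r["min_breakeven_rate"], 6)
                    if pd.notna(r["min_breakeven_rate"])
                    else None
                ),
            }
            for _, r in scen_df.iterrows()
        ],
    }

    per_type_df.to_csv(out_dir / "per_type_resources.csv", index=False)
    sav_df.to_csv(out_dir / "savings_table.csv", index=False)
    scen_df.to_csv(out_dir / "scenarios.csv", index=False)

    if config.log_path is not None and config.roster_path is not None:
        log = pd.read_csv(config.log_path, dtype=str)
        rosters = rosters_from_frame(pd.read_csv(config.roster_path))
        metrics = usage_metrics(log, rosters, config.window_months)
        metrics["per_practice"].to_csv(out_dir / "usage_per_practice.csv", index=False)
        pooled = metrics["pooled"]
        usage: dict = {
            "site_visits": pooled["site_visits"],
            "submissions": pooled["submissions"],
            "conversion_rate": (
                round(pooled["conversion_rate"], 6)
                if pooled["conversion_rate"] is not None
                else None
            ),
            "female_share": (
                round(pooled["female_share"], 6)
                if pooled["female_share"] is not None
                else None
            ),
            "share_18_44": (
                round(pooled["share_18_44"], 6)
                if pooled["share_18_44"] is not None
                else None
            ),
            "unknown_sex": pooled["unknown_sex"],
            "unknown_age": pooled["unknown_age"],
        }
        if "deprivation" in metrics:
            dep = metrics["deprivation"]
            usage["deprivation"] = {
                "simd_q1q2": {
                    "spearman_rho": round(dep["simd_q1q2_share"]["spearman_rho"], 6),
                    "p_value": round(dep["simd_q1q2_share"]["p_value"], 6),
                },
                "simd_q4q5": {
                    "spearman_rho": round(dep["simd_q4q5_share"]["spearman_rho"], 6),
                    "p_value": round(dep["simd_q4q5_share"]["p_value"], 6),
                },
                "degenerate": dep["degenerate"],
            }
            dep["table"].to_csv(out_dir / "deprivation_scatter.csv", index=False)
        summary["usage"] = usage

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
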