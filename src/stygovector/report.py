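"""One-shot recomputation of the study's headline quantities.

Runs the kinematics and capacity pipelines on the bundled measurements
(:mod:`stygovector.datasets`) and checks each derived quantity against the
published value at its printed precision.  This path is fully deterministic:
it involves no random number generation, so the report is byte-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from . import capacity as cap_mod
from . import kinematics as kin
from .capacity import Morphometrics, ProkaryoteGeometry, round_sig
from .datasets import STUDY_PARAMETERS, load_swimming_speeds

__all__ = ["compute_headline_values", "reproduce_report", "format_report"]


def compute_headline_values() -> dict[str, float]:
    """Every headline quantity, recomputed from the bundled inputs."""
    speeds = load_swimming_speeds()
    rep_cols = [c for c in speeds.columns if c.startswith("replicate_")]
    summary = kin.summarize_speeds(
        {ind: speeds.loc[ind, rep_cols].to_list() for ind in speeds.index}
    )
    p = STUDY_PARAMETERS
    # the bundled table is on the 1e4 m yr^-1 scale; transport wants m yr^-1
    corr, comp = kin.transport_comparison(
        summary.cohort_mean * 1e4,
        tau_min=p["tortuosity_min"],
        tau_max=p["tortuosity_max"],
        advection_min_m_yr=p["advection_min_m_yr"],
        advection_max_m_yr=p["advection_max_m_yr"],
    )

    morph = Morphometrics(
        length_mm=p["body_length_mm"],
        width_mm=p["body_width_mm"],
        height_mm=p["body_height_mm"],
        surface_area_mm2=p["surface_area_mm2"],
    )
    geom = ProkaryoteGeometry(
        cell_length_um=p["cell_length_um"],
        cell_width_um=p["cell_width_um"],
        ultrasmall_volume_factor=p["ultrasmall_volume_factor"],
    )
    est = cap_mod.capacity_estimate(morph, geom, p["groundwater_cells_per_l"])

    values = {
        "cohort_mean_speed_1e4_m_yr": summary.cohort_mean,
        "cohort_sd_speed_1e4_m_yr": summary.cohort_sd,
        "migration_speed_tau_min_1e4_m_yr": corr.corrected_at_tau_min / 1e4,
        "migration_speed_tau_max_1e4_m_yr": corr.corrected_at_tau_max / 1e4,
        "enhancement_max_fold": comp.enhancement_max,
        "enhancement_min_fold": comp.enhancement_min,
        "attachable_cells": est.attachable_cells,
        "attachable_cells_2sf": round_sig(est.attachable_cells, 2),
        "ultrasmall_attachable_cells": est.ultrasmall_attachable_cells,
        "body_volume_ul": est.body_volume_ul,
        "groundwater_equivalent_cells": est.equivalent_cells,
        "enrichment_orders_of_magnitude": est.enrichment_orders,
    }
    for ind in ("Amphipoda 1", "Amphipoda 9"):
        key = ind.lower().replace(" ", "_")
        values[f"{key}_mean_speed_1e4_m_yr"] = summary.per_individual.loc[ind, "mean"]
        values[f"{key}_sd_speed_1e4_m_yr"] = summary.per_individual.loc[ind, "sd"]
    return values


#: Published values and the absolute tolerance implied by their printed
#: precision (half an ulp of the printed figure, plus propagated input
#: rounding for statistics of already-rounded replicates).
_EXPECTED: dict[str, tuple[float, float]] = {
    "cohort_mean_speed_1e4_m_yr": (6.86, 0.011),
    "cohort_sd_speed_1e4_m_yr": (4.58, 0.011),
    "migration_speed_tau_min_1e4_m_yr": (3.43, 0.011),
    "migration_speed_tau_max_1e4_m_yr": (1.72, 0.011),
    "enhancement_max_fold": (34, 0),
    "enhancement_min_fold": (17, 0),
    "attachable_cells_2sf": (4.4e7, 0),
    "body_volume_ul": (0.675, 1e-12),
    "groundwater_equivalent_cells": (162, 0),
    "enrichment_orders_of_magnitude": (5, 0),
    "amphipoda_1_mean_speed_1e4_m_yr": (9.48, 0.011),
    "amphipoda_1_sd_speed_1e4_m_yr": (3.44, 0.011),
    "amphipoda_9_mean_speed_1e4_m_yr": (3.30, 0.011),
    "amphipoda_9_sd_speed_1e4_m_yr": (2.02, 0.011),
}


@dataclass(frozen=True)
class ReportEntry:
    name: str
    computed: float
    expected: float
    tolerance: float
    passed: bool


def reproduce_report() -> list[ReportEntry]:
    """Compare every recomputed headline quantity with its published value."""
    values = compute_headline_values()
    entries = []
    for name, (expected, tol) in _EXPECTED.items():
        computed = values[name]
        entries.append(
            ReportEntry(
                name=name,
                computed=float(computed),
                expected=float(expected),
                tolerance=tol,
                passed=bool(abs(computed - expected) <= tol),
            )
        )
    return entries


def format_report(entries: list[ReportEntry]) -> str:
    """Human-readable fixed-order report (deterministic byte-for-byte)."""
    width = max(len(e.name) for e in entries)
    lines = [f"{'quantity':<{width}}  {'computed':>14}  {'expected':>12}  status"]
    for e in entries:
        status = "pass" if e.passed else "FAIL"
        lines.append(f"{e.name:<{width}}  {e.computed:>14.6g}  {e.expected:>12.6g}  {status}")
    n_pass = sum(e.passed for e in entries)
    lines.append(f"{n_pass}/{len(entries)} quantities reproduced")
    return "\n".join(lines)


def report_json(entries: list[ReportEntry]) -> str:
    return json.dumps(
        {
            e.name: {
                "computed": e.computed,
                "expected": e.expected,
                "tolerance": e.tolerance,
                "passed": e.passed,
            }
            for e in entries
        },
        indent=2,
        sort_keys=True,
    )
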