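"""Sequential scenario runs, cohort resource totals, deltas and reports.

The scenario engine applies the protocol changes in order, recomputing the
cohort's resource totals after each change.  Reported "staff time" in delta
tables is machine slot minutes plus non-linac staff minutes: the machine
slot is counted once per fraction even though two radiation therapists
deliver it, which is the convention under which the per-change figures are
internally consistent with the per-regimen resource table.

Rendered percentages truncate toward zero (a 12.96 % reduction renders as
"12.9 %"); the infrastructure percentage is rendered at two decimals.  Full-
precision values are always carried alongside the rendered strings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import PatientRecord, RegimenRegistry
from .costing import RegimenResourceProfile
from .rules import (
    Assignment,
    ProtocolChange,
    apply_change,
    baseline_assignment,
)


@dataclass(frozen=True)
class ResourceTotals:
    """Cohort-level resource aggregates."""

    machine_min: float
    non_linac_min: float
    staff_eur: float
    infra_eur: float
    n_patients: int

    @property
    def total_eur(self) -> float:
        return self.staff_eur + self.infra_eur

    @property
    def staff_time_min(self) -> float:
        """Machine slot minutes plus non-linac staff minutes."""
        return self.machine_min + self.non_linac_min

    def __add__(self, other: "ResourceTotals") -> "ResourceTotals":
        return ResourceTotals(
            machine_min=self.machine_min + other.machine_min,
            non_linac_min=self.non_linac_min + other.non_linac_min,
            staff_eur=self.staff_eur + other.staff_eur,
            infra_eur=self.infra_eur + other.infra_eur,
            n_patients=self.n_patients + other.n_patients,
        )


@dataclass(frozen=True)
class ScenarioState:
    """One point along the trajectory: after ``change_id`` (None=baseline)."""

    change_id: Optional[int]
    description: str
    counts: dict[str, int]
    totals: ResourceTotals


@dataclass
class ScenarioTrajectory:
    """Baseline state followed by one state per applied change."""

    states: list[ScenarioState] = field(default_factory=list)

    @property
    def baseline(self) -> ScenarioState:
        return self.states[0]

    @property
    def final(self) -> ScenarioState:
        return self.states[-1]

    def state_after(self, change_id: int) -> ScenarioState:
        for state in self.states:
            if state.change_id == change_id:
                return state
        raise KeyError(f"no state for change {change_id}")


_DELTA_FIELDS = (
    "machine_min", "non_linac_min", "staff_time_min",
    "staff_eur", "infra_eur", "total_eur",
)


@dataclass(frozen=True)
class DeltaReport:
    """Exact after-minus-before differences with full-precision percentages.

    ``pct`` entries are None when the baseline value is zero (undefined).
    """

    before: ResourceTotals
    after: ResourceTotals
    delta: dict[str, float]
    pct: dict[str, Optional[float]]


def cohort_totals(assignment: Assignment,
                  profiles: Mapping[str, RegimenResourceProfile]
                  ) -> ResourceTotals:
    """Sum per-patient profile fields over an assignment."""
    machine = non_linac = staff = infra = 0.0
    for patient_id, regimen_id in assignment.items():
        try:
            profile = profiles[regimen_id]
        except KeyError:
            raise KeyError(
                f"no resource profile for regimen {regimen_id!r} "
                f"(patient {patient_id!r})"
            ) from None
        machine += profile.machine_min
        non_linac += profile.non_linac_min
        staff += profile.staff_cost_eur
        infra += profile.infrastructure_cost_eur
    return ResourceTotals(
        machine_min=machine, non_linac_min=non_linac,
        staff_eur=staff, infra_eur=infra, n_patients=len(assignment),
    )


def assignment_counts(assignment: Assignment) -> dict[str, int]:
    counts: dict[str, int] = {}
    for regimen_id in assignment.values():
        counts[regimen_id] = counts.get(regimen_id, 0) + 1
    return counts


def run_scenario(cohort: list[PatientRecord],
                 changes: Sequence[ProtocolChange],
                 profiles: Mapping[str, RegimenResourceProfile],
                 registry: RegimenRegistry) -> ScenarioTrajectory:
    """Apply changes in order, recording counts and totals after each."""
    assignment = baseline_assignment(cohort)
    states = [ScenarioState(
        change_id=None,
        description="baseline (as treated)",
        counts=assignment_counts(assignment),
        totals=cohort_totals(assignment, profiles),
    )]
    for change in changes:
        assignment = apply_change(cohort, assignment, change, registry)
        states.append(ScenarioState(
            change_id=change.change_id,
            description=change.description,
            counts=assignment_counts(assignment),
            totals=cohort_totals(assignment, profiles),
        ))
    return ScenarioTrajectory(states=states)


def delta_report(before: ResourceTotals, after: ResourceTotals
                 ) -> DeltaReport:
    delta = {
        name: getattr(after, name) - getattr(before, name)
        for name in _DELTA_FIELDS
    }
    pct = {
        name: (
            None if getattr(before, name) == 0
            else 100.0 * delta[name] / getattr(before, name)
        )
        for name in _DELTA_FIELDS
    }
    return DeltaReport(before=before, after=after, delta=delta, pct=pct)


def per_change_deltas(trajectory: ScenarioTrajectory) -> list[DeltaReport]:
    """Step-by-step deltas; these telescope to the baseline-to-final delta."""
    return [
        delta_report(before.totals, after.totals)
        for before, after in zip(trajectory.states, trajectory.states[1:])
    ]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def truncate_pct(value: float, decimals: int = 1) -> str:
    """Percentage rendering: truncate toward zero at ``decimals`` places."""
    scale = 10 ** decimals
    truncated = math.trunc(value * scale) / scale
    return f"{truncated:.{decimals}f}"


def round_half_up(value: float) -> int:
    """Round to whole euros with ties away from zero (ledger convention)."""
    return int(math.floor(value + 0.5)) if value >= 0 else -round_half_up(-value)


def _totals_row(totals: ResourceTotals) -> dict:
    return {
        "n_patients": totals.n_patients,
        "machine_min": totals.machine_min,
        "non_linac_min": totals.non_linac_min,
        "staff_eur": round_half_up(totals.staff_eur),
        "infra_eur": round_half_up(totals.infra_eur),
        "total_eur": round_half_up(totals.total_eur),
    }


def regimen_resource_table(state: ScenarioState,
                           profiles: Mapping[str, RegimenResourceProfile]
                           ) -> pd.DataFrame:
    """Per-regimen resource table (totals by regimen plus a totals row)."""
    rows = []
    for regimen_id in sorted(state.counts):
        n = state.counts[regimen_id]
        p = profiles[regimen_id]
        rows.append({
            "regimen_id": regimen_id,
            "n": n,
            "machine_min": p.machine_min * n,
            "non_linac_min": p.non_linac_min * n,
            "staff_eur": round_half_up(p.staff_cost_eur * n),
            "infra_eur": round_half_up(p.infrastructure_cost_eur * n),
            "total_eur": round_half_up(p.total_eur * n),
        })
    totals = _totals_row(state.totals)
    totals["regimen_id"] = "TOTAL"
    totals["n"] = totals.pop("n_patients")
    rows.append(totals)
    return pd.DataFrame(rows, columns=[
        "regimen_id", "n", "machine_min", "non_linac_min",
        "staff_eur", "infra_eur", "total_eur",
    ])


def assignment_trajectory_table(trajectory: ScenarioTrajectory
                                ) -> pd.DataFrame:
    """Regimen-by-state patient counts (protocol-change trajectory)."""
    regimen_ids = sorted({
        rid for state in trajectory.states for rid in state.counts
    })
    columns = {}
    for state in trajectory.states:
        label = (
            "baseline" if state.change_id is None
            else f"after_change_{state.change_id}"
        )
        columns[label] = [state.counts.get(rid, 0) for rid in regimen_ids]
    df = pd.DataFrame({"regimen_id": regimen_ids, **columns})
    total = {"regimen_id": "TOTAL"}
    total.update({label: sum(col) for label, col in columns.items()})
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def delta_table(trajectory: ScenarioTrajectory) -> pd.DataFrame:
    """Per-change deltas plus running totals after each change."""
    rows = []
    for state, report in zip(trajectory.states[1:],
                             per_change_deltas(trajectory)):
        row = {
            "change_id": state.change_id,
            "description": state.description,
        }
        for name in _DELTA_FIELDS:
            row[f"delta_{name}"] = report.delta[name]
            pct = report.pct[name]
            row[f"delta_{name}_pct"] = "" if pct is None else truncate_pct(pct)
        row.update({
            f"after_{k}": v for k, v in _totals_row(state.totals).items()
        })
        rows.append(row)
    return pd.DataFrame(rows)


def staff_time_series(trajectory: ScenarioTrajectory) -> pd.DataFrame:
    """Changes from baseline in linac and non-linac staff time per state."""
    base = trajectory.baseline.totals
    rows = []
    for state in trajectory.states:
        rows.append({
            "state": (
                "baseline" if state.change_id is None
                else f"after_change_{state.change_id}"
            ),
            "machine_min": state.totals.machine_min,
            "non_linac_min": state.totals.non_linac_min,
            "machine_min_vs_baseline":
                state.totals.machine_min - base.machine_min,
            "non_linac_min_vs_baseline":
                state.totals.non_linac_min - base.non_linac_min,
        })
    return pd.DataFrame(rows)


def run_summary(trajectory: ScenarioTrajectory) -> dict:
    """Machine-readable summary holding every headline number."""
    base, final = trajectory.baseline.totals, trajectory.final.totals
    overall = delta_report(base, final)
    summary = {
        "n_patients": base.n_patients,
        "baseline": _totals_row(base),
        "final": _totals_row(final),
        "baseline_total_eur_full_precision": base.total_eur,
        "final_total_eur_full_precision": final.total_eur,
        "reduction_machine_min": base.machine_min - final.machine_min,
        "reduction_machine_pct_rendered": truncate_pct(
            100.0 * (base.machine_min - final.machine_min) / base.machine_min
        ) if base.machine_min else None,
        "reduction_non_linac_min": base.non_linac_min - final.non_linac_min,
        "reduction_non_linac_pct_rendered": truncate_pct(
            100.0 * (base.non_linac_min - final.non_linac_min)
            / base.non_linac_min
        ) if base.non_linac_min else None,
        "reduction_total_eur": round_half_up(base.total_eur - final.total_eur),
        "reduction_total_eur_full_precision": base.total_eur - final.total_eur,
        "reduction_total_pct_rendered": truncate_pct(
            100.0 * (base.total_eur - final.total_eur) / base.total_eur
        ) if base.total_eur else None,
        "reduction_infra_eur_full_precision": base.infra_eur - final.infra_eur,
        "reduction_infra_pct_rendered": truncate_pct(
            100.0 * (base.infra_eur - final.infra_eur) / base.infra_eur, 2
        ) if base.infra_eur else None,
        "per_change": [
            {
                "change_id": state.change_id,
                "description": state.description,
                "delta_staff_time_min": report.delta["staff_time_min"],
                "delta_machine_min": report.delta["machine_min"],
                "delta_non_linac_min": report.delta["non_linac_min"],
                "delta_total_eur": report.delta["total_eur"],
            }
            for state, report in zip(trajectory.states[1:],
                                     per_change_deltas(trajectory))
        ],
        "overall_delta": {k: overall.delta[k] for k in _DELTA_FIELDS},
    }
    return summary


def render_reports(trajectory: ScenarioTrajectory,
                   profiles: Mapping[str, RegimenResourceProfile],
                   out_dir) -> dict[str, Path]:
    """Write the report files; returns {name: path}.

    Emits the per-regimen baseline resource table, the assignment-count
    trajectory, the per-change delta table, the staff-time breakdown series,
    and a JSON run summary with every headline number.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "regimen_resources": out / "regimen_resources_baseline.csv",
        "assignment_trajectory": out / "assignment_trajectory.csv",
        "per_change_deltas": out / "per_change_deltas.csv",
        "staff_time_series": out / "staff_time_series.csv",
        "run_summary": out / "run_summary.json",
    }
    regimen_resource_table(trajectory.baseline, profiles).to_csv(
        paths["regimen_resources"], index=False, lineterminator="\n"
    )
    assignment_trajectory_table(trajectory).to_csv(
        paths["assignment_trajectory"], index=False, lineterminator="\n"
    )
    delta_table(trajectory).to_csv(
        paths["per_change_deltas"], index=False, lineterminator="\n"
    )
    staff_time_series(trajectory).to_csv(
        paths["staff_time_series"], index=False, lineterminator="\n"
    )
    with open(paths["run_summary"], "w", encoding="utf-8") as fh:
        json.dump(run_summary(trajectory), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
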