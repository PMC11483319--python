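"""Care-path process maps: per-patient staff time, machine time, staff cost.

A care path is an ordered list of tasks (minutes x staff role x staffing
count x frequency).  Task frequencies are per course, per fraction, or per
treatment week; treatment weeks follow the standard five-fractions-per-week
delivery calendar.  Machine (linac) time is appointment-slot driven: each
fraction occupies a standard slot whose length depends on the nodal target
volume and on whether the patient is treated in deep inspiration breath
hold (DIBH), with tumour-bed boost fractions booked at the breast-only slot
for the same breathing technique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .cohort import NODAL_CLASSES, Regimen, ValidationError

STAFF_ROLES = ("physician", "radiation_therapist", "physicist", "other")
LOCATIONS = ("linac", "non_linac")
FREQUENCIES = ("per_course", "per_fraction", "per_treatment_week")


@dataclass(frozen=True)
class Task:
    """One activity in the planning/delivery pathway."""

    name: str
    minutes: float
    role: str
    n_staff: int = 1
    location: str = "non_linac"
    frequency: str = "per_course"

    def validate(self) -> None:
        if self.minutes < 0:
            raise ValidationError(f"task {self.name!r}: minutes must be >= 0")
        if self.n_staff < 1:
            raise ValidationError(f"task {self.name!r}: n_staff must be >= 1")
        if self.role not in STAFF_ROLES:
            raise ValidationError(
                f"task {self.name!r}: role {self.role!r} not in {STAFF_ROLES}"
            )
        if self.location not in LOCATIONS:
            raise ValidationError(
                f"task {self.name!r}: location {self.location!r} invalid"
            )
        if self.frequency not in FREQUENCIES:
            raise ValidationError(
                f"task {self.name!r}: frequency {self.frequency!r} invalid"
            )


@dataclass
class CarePath:
    """The process map for one regimen."""

    regimen_id: str
    tasks: list[Task] = field(default_factory=list)

    def validate(self, regimen: Regimen | None = None) -> None:
        for task in self.tasks:
            task.validate()
        if regimen is not None and regimen.total_fractions > 0:
            if not any(
                t.location == "linac" and t.frequency == "per_fraction"
                for t in self.tasks
            ):
                raise ValidationError(
                    f"care path {self.regimen_id!r}: a fractionated regimen "
                    "needs at least one per-fraction linac task"
                )


@dataclass
class StaffRateTable:
    """Annual salaries per role and the annual working-hours divisor."""

    annual_salaries: dict[str, float]
    annual_working_hours: float

    def validate(self) -> None:
        if self.annual_working_hours <= 0:
            raise ValidationError("annual_working_hours must be > 0")
        for role, salary in self.annual_salaries.items():
            if salary <= 0:
                raise ValidationError(f"salary for {role!r} must be > 0")


@dataclass
class SlotTimeTable:
    """Per-fraction appointment-slot minutes keyed by (nodal class, DIBH)."""

    slots: dict[tuple[str, bool], float]

    def validate(self) -> None:
        for (nodal, dibh), minutes in self.slots.items():
            if nodal not in NODAL_CLASSES:
                raise ValidationError(f"unknown nodal class {nodal!r}")
            if minutes <= 0:
                raise ValidationError(
                    f"slot ({nodal}, dibh={dibh}) must be > 0 minutes"
                )
        for nodal in NODAL_CLASSES:
            fb, dibh = (nodal, False), (nodal, True)
            if fb in self.slots and dibh in self.slots:
                if self.slots[dibh] < self.slots[fb]:
                    raise ValidationError(
                        f"DIBH slot must be >= free-breathing slot ({nodal})"
                    )

    def slot_minutes(self, nodal_class: str, dibh: bool) -> float:
        try:
            return self.slots[(nodal_class, dibh)]
        except KeyError:
            raise KeyError(
                f"no slot time for nodal_class={nodal_class!r}, dibh={dibh}"
            ) from None


def hourly_rate(role: str, rates: StaffRateTable) -> float:
    """Salary euros per worked hour for one staff role."""
    try:
        salary = rates.annual_salaries[role]
    except KeyError:
        raise KeyError(f"no salary for role {role!r}") from None
    return salary / rates.annual_working_hours


def treatment_weeks(regimen: Regimen) -> int:
    """Calendar weeks on treatment at five fractions per week (boost incl.)."""
    if regimen.total_fractions <= 0:
        raise ValidationError("treatment_weeks requires fractions > 0")
    return math.ceil(regimen.total_fractions / 5)


def occurrences(task: Task, regimen: Regimen) -> int:
    """How many times a task happens over one treatment course."""
    if task.frequency == "per_course":
        return 1
    if task.frequency == "per_fraction":
        return regimen.total_fractions
    return treatment_weeks(regimen)


def staff_minutes(carepath: CarePath, regimen: Regimen
                  ) -> tuple[float, float]:
    """Total staff minutes for one patient, split (linac, non-linac).

    Every listed staff member is counted: a 15-minute fraction delivered by
    two radiation therapists contributes 30 staff-minutes of linac time.
    """
    linac = 0.0
    non_linac = 0.0
    for task in carepath.tasks:
        total = task.minutes * task.n_staff * occurrences(task, regimen)
        if task.location == "linac":
            linac += total
        else:
            non_linac += total
    return linac, non_linac


def machine_minutes(regimen: Regimen, slots: SlotTimeTable) -> float:
    """Linac slot minutes for one patient's full course.

    The machine is occupied once per fraction regardless of how many staff
    attend; boost fractions are booked at the breast-only (nodal class
    ``none``) slot for the patient's breathing technique.
    """
    total = regimen.primary_fractions * slots.slot_minutes(
        regimen.nodal_class, regimen.dibh
    )
    if regimen.boost_fractions:
        total += regimen.boost_fractions * slots.slot_minutes(
            "none", regimen.dibh
        )
    return total


def staff_cost(carepath: CarePath, regimen: Regimen,
               rates: StaffRateTable) -> float:
    """Euro cost of all staff time in the care path for one patient."""
    total = 0.0
    for task in carepath.tasks:
        total += (
            (task.minutes / 60.0)
            * hourly_rate(task.role, rates)
            * task.n_staff
            * occurrences(task, regimen)
        )
    return total


def calibrated_carepath(regimen: Regimen, non_linac_target: float,
                        slots: SlotTimeTable) -> CarePath:
    """Build a task list reproducing a known per-patient non-linac total.

    The pathway template is the standard one (consultation, simulation,
    contouring, target delineation, plan design, physics plan analysis,
    pre-treatment checks, daily fractions, weekly chart check); the plan-
    design task absorbs whatever minutes the fixed tasks do not account
    for, reflecting that planning effort is the main driver of pathway
    differences between regimens.
    """
    weeks = treatment_weeks(regimen)
    fixed = 30 + 45 * 2 + 40 + 20 + 35 + 35 + 20 * weeks
    plan_design = non_linac_target - fixed
    if plan_design < 0:
        raise ValidationError(
            f"non_linac_target={non_linac_target} below the fixed-task floor "
            f"({fixed} min) for regimen {regimen.regimen_id!r}"
        )
    slot = slots.slot_minutes(regimen.nodal_class, regimen.dibh)
    tasks = [
        Task("physician consultation", 30, "physician"),
        Task("simulation scan", 45, "radiation_therapist", n_staff=2),
        Task("contour OARs and transfer images", 40, "radiation_therapist"),
        Task("target volume delineation", 20, "physician"),
        Task("plan design", plan_design, "radiation_therapist"),
        Task("plan analysis", 35, "physicist"),
        Task("pre-treatment tasks", 35, "radiation_therapist"),
        Task("daily fraction", slot, "radiation_therapist", n_staff=2,
             location="linac", frequency="per_fraction"),
        Task("weekly chart check", 20, "radiation_therapist",
             frequency="per_treatment_week"),
    ]
    return CarePath(regimen_id=regimen.regimen_id, tasks=tasks)


# ---------------------------------------------------------------------------
# Config IO (YAML)
# ---------------------------------------------------------------------------

def carepath_from_dict(doc: Mapping) -> CarePath:
    tasks = [Task(**task) for task in doc.get("tasks", [])]
    path = CarePath(regimen_id=str(doc["regimen_id"]), tasks=tasks)
    for task in tasks:
        task.validate()
    return path


def load_carepaths(path) -> dict[str, CarePath]:
    """Load one or more care-path documents from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        docs = [d for d in yaml.safe_load_all(fh) if d]
    paths = [carepath_from_dict(d) for d in docs]
    return {p.regimen_id: p for p in paths}


def load_staff_rates(path) -> StaffRateTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    table = StaffRateTable(
        annual_salaries={
            str(k): float(v) for k, v in doc["annual_salaries"].items()
        },
        annual_working_hours=float(doc["annual_working_hours"]),
    )
    table.validate()
    return table


def load_slot_table(path) -> SlotTimeTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    slots = {}
    for entry in doc["slots"]:
        key = (str(entry["nodal_class"]), bool(entry["dibh"]))
        slots[key] = float(entry["slot_minutes"])
    table = SlotTimeTable(slots=slots)
    table.validate()
    return table


def _packaged(name: str):
    return resources.as_file(resources.files("rtcost.data").joinpath(name))


def default_slot_table() -> SlotTimeTable:
    with _packaged("slots.yaml") as path:
        return load_slot_table(path)


def default_staff_rates() -> StaffRateTable:
    with _packaged("staff_rates.yaml") as path:
        return load_staff_rates(path)


def default_carepaths() -> dict[str, CarePath]:
    """The packaged pathway documented task-by-task (one-week whole breast)."""
    with _packaged("carepath_26_5.yaml") as path:
        return load_carepaths(path)
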