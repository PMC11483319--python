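"""Deterministic synthetic cohort construction under marginal constraints.

The generator is constructive.  A cohort spec lists, per baseline regimen,
how many patients follow each *role* — a named baseline-to-final transition
through the six protocol changes (keep a boost, lose it and move to the
one-week schedule, gain internal mammary irradiation, convert to breath
hold, ...).  Phase one instantiates one patient slot per role and forces
exactly the covariates the role's transition requires (an IMN gainer gets
N2-3 disease or N1 with an adverse factor; a boost loser gets age >= 50 and
no boost risk factor; a breath-hold convert is under 60 with left-sided
disease; ...).  Phase two, when marginal targets are given, distributes the
remaining free covariates to hit the target category counts.  Phase three
samples ages within the forced bands and shuffles record order using the
seeded pseudo-random stream — the only stochastic steps, so a seed fixes
the cohort byte for byte.

Transition counts are hard constraints; a handful of printed marginals are
internally inconsistent with the printed totals and are validated as soft
(report-only): see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import yaml

from .cohort import (
    DcisProfile,
    PatientRecord,
    Regimen,
    RegimenRegistry,
    default_registry,
    summarize_cohort,
)
from .rules import apply_change, baseline_assignment, get_changes

ROLES = (
    "boost_loser_ultra",
    "boost_loser_nodal_stay",
    "boost_keeper",
    "boost_keeper_dibh_convert",
    "boost_keeper_special_imn",
    "boost_keeper_imn_mover",
    "boost_keeper_imn_mover_dibh_convert",
    "boost_keeper_nodal_stay",
    "dcis_boosted",
    "dcis_gain",
    "dcis_stay",
    "ultra",
    "ultra_dibh_convert",
    "imn_mover",
    "imn_mover_dibh_convert",
    "nodal_stay",
    "plain",
)

#: Marginal categories whose printed counts are inconsistent with the
#: printed cohort total (or with subgroup sizes) and are therefore
#: validated as report-only.
SOFT_MARGINALS = frozenset({
    ("lvi", "no"),
    ("molecular_subtype", "luminalA"),
    ("dcis_comedonecrosis", "no"),
    ("dcis_central_necrosis", "no"),
    ("dcis_symptomatic", "no"),
})


class GenerationError(RuntimeError):
    """The spec cannot be satisfied; the message lists binding constraints."""


@dataclass
class GroupSpec:
    regimen_id: str
    roles: dict[str, int]


@dataclass
class CohortSpec:
    """Targets the generated cohort must (or should) reproduce."""

    seed: int
    groups: list[GroupSpec]
    marginal_targets: Optional[dict[str, dict[str, int]]] = None
    mean_age_target: Optional[float] = None
    transition_targets: Optional[dict] = None

    @property
    def total_n(self) -> int:
        return sum(n for g in self.groups for n in g.roles.values())

    def baseline_counts(self) -> dict[str, int]:
        return {
            g.regimen_id: sum(g.roles.values())
            for g in self.groups if sum(g.roles.values()) > 0
        }


def load_cohort_spec(path=None) -> CohortSpec:
    if path is None:
        with resources.as_file(
            resources.files("rtcost.data").joinpath("cohort_spec.yaml")
        ) as p:
            return load_cohort_spec(p)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    groups = [
        GroupSpec(regimen_id=str(g["regimen_id"]),
                  roles={str(k): int(v) for k, v in g["roles"].items()})
        for g in doc["groups"]
    ]
    return CohortSpec(
        seed=int(doc["seed"]),
        groups=groups,
        marginal_targets=doc.get("marginal_targets"),
        mean_age_target=doc.get("mean_age_target"),
        transition_targets=doc.get("transition_targets"),
    )


@dataclass
class GenerationReport:
    """Constraint-by-constraint outcome of a generation or validation run."""

    seed: Optional[int]
    satisfied: list[str] = field(default_factory=list)
    unsatisfied: list[str] = field(default_factory=list)
    soft_notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unsatisfied


# ---------------------------------------------------------------------------
# Patient slots
# ---------------------------------------------------------------------------

@dataclass
class _Slot:
    role: str
    base: Regimen
    final: Regimen
    # covariates (phase-1 defaults, phase-2 adjustments)
    sex: str = "female"
    age_lo: int = 35
    age_hi: int = 70
    age: int = 0
    t_stage: str = ""
    n_stage: str = "N0"
    chemotherapy: bool = False
    surgery: str = "mastectomy"
    reconstruction: bool = False
    nodal_surgery: str = "SLNB"
    laterality: str = "left"
    central_or_medial: bool = False
    histology: str = ""
    molecular_subtype: str = "luminalA"
    grade: int = 2
    lvi: bool = False
    margin_positive: bool = False
    margin_le_2mm: bool = False
    dcis: Optional[dict] = None
    # markers
    stay_fb: bool = False          # final regimen is free breathing
    final_imn: bool = False
    convert: bool = False          # gains DIBH at the breath-hold change
    needs_boost_risk: bool = False
    needs_imn_risk: bool = False   # set when an IMN mover is re-staged to N1
    frozen_flags: bool = False     # losers/stayers/non-indicated: no risk flags
    surgery_pool: bool = False     # surgery may be reassigned to hit targets
    wle_nonindicated: bool = False
    mover: bool = False            # gains IMN at change 5


def _final_regimen(role: str, base: Regimen,
                   registry: RegimenRegistry) -> Regimen:
    dose, fx = base.primary_dose_gy, base.primary_fractions
    if dose == 50:  # conventional fractionation is rewritten at change 1
        dose, fx = 40, 15
    look = registry.lookup
    if role in ("boost_loser_ultra",):
        return look(26, 5, "none", base.dibh, False)
    if role == "ultra":
        return look(26, 5, "none", base.dibh, False)
    if role == "ultra_dibh_convert":
        return look(26, 5, "none", True, False)
    if role == "boost_loser_nodal_stay":
        return look(dose, fx, base.nodal_class, base.dibh, False)
    if role in ("boost_keeper", "dcis_boosted", "dcis_stay",
                "boost_keeper_nodal_stay"):
        return look(dose, fx, base.nodal_class, base.dibh, base.boost)
    if role == "boost_keeper_dibh_convert":
        return look(dose, fx, base.nodal_class, True, base.boost)
    if role in ("boost_keeper_special_imn", "boost_keeper_imn_mover",
                "imn_mover"):
        return look(dose, fx, "scax_imn", base.dibh, base.boost)
    if role in ("boost_keeper_imn_mover_dibh_convert",
                "imn_mover_dibh_convert"):
        return look(dose, fx, "scax_imn", True, base.boost)
    if role == "dcis_gain":
        return look(dose, fx, base.nodal_class, base.dibh, True)
    if role in ("nodal_stay", "plain"):
        return look(dose, fx, base.nodal_class, base.dibh, base.boost)
    raise GenerationError(f"unknown role {role!r}")


_HIGH_RISK_DCIS = dict(
    nuclear_grade="high", comedonecrosis=True, central_necrosis=False,
    symptomatic=True, size_mm=18.0, multifocal=False, radial_margin_mm=5.0,
    extensive_intraductal_component=False,
)
_LOW_RISK_DCIS = dict(
    nuclear_grade="low", comedonecrosis=False, central_necrosis=False,
    symptomatic=False, size_mm=8.0, multifocal=False, radial_margin_mm=12.0,
    extensive_intraductal_component=False,
)


def _check_role_base(role: str, base: Regimen) -> None:
    """A role only makes sense on a compatible baseline regimen."""
    boost_roles = role.startswith("boost_")
    if boost_roles and not base.boost:
        raise GenerationError(f"role {role!r} requires a boosted baseline")
    if role.startswith("ultra") or role == "dcis_stay" or role == "dcis_gain":
        if base.boost or base.nodal_class != "none":
            raise GenerationError(
                f"role {role!r} requires a breast-only, non-boosted baseline"
            )
    if role in ("imn_mover", "imn_mover_dibh_convert", "nodal_stay"):
        if base.nodal_class != "scax" or base.boost:
            raise GenerationError(
                f"role {role!r} requires a non-boosted sc/ax baseline"
            )
    if role in ("boost_loser_nodal_stay", "boost_keeper_nodal_stay"):
        if base.nodal_class != "scax":
            raise GenerationError(f"role {role!r} requires a sc/ax baseline")
    if role in ("boost_keeper_imn_mover",
                "boost_keeper_imn_mover_dibh_convert") \
            and base.nodal_class != "scax":
        raise GenerationError(f"role {role!r} requires a sc/ax baseline")
    if role == "boost_keeper_special_imn" and base.nodal_class != "none":
        raise GenerationError(
            f"role {role!r} requires a breast-only baseline"
        )
    if role == "plain" and base.nodal_class != "scax_imn":
        raise GenerationError(
            f"role {role!r} requires an IMN baseline (a breast-only "
            "non-boosted patient would be rewritten at the one-week change)"
        )
    if role in ("boost_loser_ultra", "boost_keeper",
                "boost_keeper_dibh_convert") and base.nodal_class not in (
                    "none", "scax_imn"):
        if role != "boost_keeper":
            raise GenerationError(
                f"role {role!r} requires a breast-only baseline"
            )


def _make_slot(role: str, base: Regimen,
               registry: RegimenRegistry) -> _Slot:
    _check_role_base(role, base)
    final = _final_regimen(role, base, registry)
    slot = _Slot(role=role, base=base, final=final)
    slot.stay_fb = not final.dibh
    slot.final_imn = final.nodal_class == "scax_imn"
    slot.histology = "DCIS" if role.startswith("dcis") else "ductal"
    slot.mover = role in (
        "boost_keeper_special_imn", "boost_keeper_imn_mover",
        "boost_keeper_imn_mover_dibh_convert", "imn_mover",
        "imn_mover_dibh_convert",
    ) and base.nodal_class != "scax_imn"
    slot.convert = role.endswith("dibh_convert")
    if base.primary_dose_gy == 50:
        slot.reconstruction = True
        slot.surgery = "mastectomy"

    if role in ("boost_loser_ultra", "boost_loser_nodal_stay"):
        # boost withdrawn when individualised: >= 50 with no risk factor
        slot.surgery = "WLE"
        slot.frozen_flags = True
        slot.age_lo, slot.age_hi = 50, 69
    elif role in ("boost_keeper", "boost_keeper_special_imn",
                  "boost_keeper_imn_mover"):
        slot.surgery = "WLE"
        slot.needs_boost_risk = True
        slot.age_lo, slot.age_hi = 50, 69
    elif role == "boost_keeper_dibh_convert":
        slot.surgery = "WLE"
        slot.age_lo, slot.age_hi = 40, 49  # indicated by age alone
    elif role == "boost_keeper_imn_mover_dibh_convert":
        slot.surgery = "WLE"
        slot.age_lo, slot.age_hi = 40, 49
    elif role == "boost_keeper_nodal_stay":
        # keeps the boost (age < 50) but must fail every IMN criterion
        slot.surgery = "WLE"
        slot.frozen_flags = True
        slot.age_lo, slot.age_hi = 40, 49
    elif role in ("nodal_stay", "boost_loser_nodal_stay"):
        slot.frozen_flags = True
        slot.age_lo, slot.age_hi = 40, 69
    elif role.startswith("dcis"):
        slot.surgery = "WLE"
        slot.nodal_surgery = "SLNB"
        slot.age_lo, slot.age_hi = 50, 69
        slot.dcis = dict(
            _LOW_RISK_DCIS if role == "dcis_stay" else _HIGH_RISK_DCIS
        )
    elif role in ("ultra", "plain"):
        if base.primary_dose_gy != 50:
            slot.surgery_pool = True
        slot.age_lo, slot.age_hi = 35, 70
    elif role in ("ultra_dibh_convert", "imn_mover_dibh_convert"):
        slot.age_lo, slot.age_hi = 45, 59
    elif role == "imn_mover":
        slot.age_lo, slot.age_hi = 35, 70

    if role == "nodal_stay":
        slot.frozen_flags = True
        slot.age_lo = max(slot.age_lo, 40)  # under 40 is an IMN criterion

    # staging defaults: movers carry N2 until (re)distributed; patients on
    # nodal radiotherapy who must not gain IMN are N1 without risk factors
    if role == "boost_keeper_special_imn":
        slot.n_stage = "N2"
    elif slot.mover:
        slot.n_stage = "N2"
    elif base.nodal_class != "none" or slot.role == "plain":
        slot.n_stage = "N1"
    if slot.histology == "DCIS":
        slot.n_stage = "N0"
        slot.t_stage = "Tis"
        slot.grade = {"low": 1, "intermediate": 2, "high": 3}[
            slot.dcis["nuclear_grade"]
        ]

    # final free-breathing patients must not meet a breath-hold criterion:
    # with internal mammary coverage that forces age >= 60; otherwise
    # right-sided (or bilateral) disease suffices at any age
    if slot.convert:
        slot.laterality = "left"
        slot.age_hi = min(slot.age_hi, 59)
    elif slot.stay_fb:
        slot.laterality = "right"
        if slot.final_imn:
            slot.age_lo, slot.age_hi = 60, 75

    if slot.needs_boost_risk:
        slot.grade = 3  # default risk factor; phase 2 rebalances
    return slot


def _build_slots(spec: CohortSpec,
                 registry: RegimenRegistry) -> list[_Slot]:
    slots: list[_Slot] = []
    for group in spec.groups:
        base = registry.get(group.regimen_id)
        for role, count in group.roles.items():
            if role not in ROLES:
                raise GenerationError(f"unknown role {role!r}")
            if count < 0:
                raise GenerationError(f"role {role!r}: negative count")
            slots.extend(
                _make_slot(role, base, registry) for _ in range(count)
            )
    return slots


# ---------------------------------------------------------------------------
# Phase 2: marginal-target allocation
# ---------------------------------------------------------------------------

def _take(slots: Iterable[_Slot], predicate, k: int, constraint: str
          ) -> list[_Slot]:
    chosen = [s for s in slots if predicate(s)][:k]
    if len(chosen) < k:
        raise GenerationError(
            f"infeasible spec: needed {k} patients for {constraint}, "
            f"found {len(chosen)}"
        )
    return chosen


def _assign_categories(slots: list[_Slot], attr: str,
                       wanted: list[tuple[str, int]], eligible,
                       constraint: str) -> None:
    """Assign categories in order to the first eligible unassigned slots."""
    remaining = [s for s in slots if eligible(s)]
    for category, count in wanted:
        if count > len(remaining):
            raise GenerationError(
                f"infeasible spec: needed {count} patients for "
                f"{constraint}={category}, found {len(remaining)}"
            )
        for slot in remaining[:count]:
            setattr(slot, attr, category)
        remaining = remaining[count:]


def _apply_marginals(slots: list[_Slot], spec: CohortSpec) -> None:
    targets = spec.marginal_targets

    # surgery: promote pool patients to breast conservation, which requires
    # them to fail the boost indication (>= 50, no risk factors)
    wle_target = targets.get("surgery", {}).get("WLE")
    if wle_target is not None:
        have = sum(1 for s in slots if s.surgery == "WLE")
        for slot in _take(
            slots, lambda s: s.surgery_pool and s.surgery == "mastectomy",
            wle_target - have, "surgery=WLE",
        ):
            slot.surgery = "WLE"
            slot.wle_nonindicated = True
            slot.frozen_flags = True
            slot.age_lo = max(slot.age_lo, 50)

    # nodal staging: movers default to N2; convert the surplus to N3 and to
    # N1-with-risk-factor, then stage the free remainder
    n_targets = targets.get("n_stage")
    if n_targets is not None:
        movers = [s for s in slots if s.mover or
                  s.role == "boost_keeper_special_imn"]
        n2_now = sum(1 for s in movers if s.n_stage == "N2")
        surplus = n2_now - n_targets.get("N2", 0)
        if surplus < 0:
            raise GenerationError(
                "infeasible spec: fewer IMN gainers than the N2 target"
            )
        demote = [s for s in movers if s.n_stage == "N2"
                  and s.role in ("imn_mover", "imn_mover_dibh_convert")]
        if surplus > len(demote):
            raise GenerationError(
                "infeasible spec: not enough re-stageable IMN gainers"
            )
        n3 = n_targets.get("N3", 0)
        for slot in demote[:min(n3, surplus)]:
            slot.n_stage = "N3"
        for slot in demote[min(n3, surplus):surplus]:
            slot.n_stage = "N1"
            slot.needs_imn_risk = True
        n1_short = n_targets.get("N1", 0) - sum(
            1 for s in slots if s.n_stage == "N1"
        )
        n3_short = n3 - sum(1 for s in slots if s.n_stage == "N3")
        if n1_short < 0 or n3_short != 0:
            raise GenerationError(
                "infeasible spec: nodal-stage targets conflict with the "
                "role plan"
            )
        _assign_categories(
            slots, "n_stage",
            [("N1", n1_short), ("NX", n_targets.get("NX", 0))],
            lambda s: s.n_stage == "N0" and s.histology != "DCIS"
            and not s.mover and not s.frozen_flags and not s.needs_boost_risk
            and s.surgery == "mastectomy",
            "n_stage",
        )

    # laterality: breath-hold converts are forced left; final free-breathing
    # patients default right; top the left count up from patients for whom
    # left is safe (in breath hold already, or 60+ on free breathing)
    lat_targets = targets.get("laterality")
    if lat_targets is not None:
        left_now = sum(1 for s in slots if s.laterality == "left")
        need = lat_targets.get("left", 0) - left_now
        if need < 0:
            raise GenerationError(
                "infeasible spec: more forced-left patients than the target"
            )
        for slot in _take(
            slots,
            lambda s: s.laterality == "right"
            and (not s.stay_fb or s.age_lo >= 60),
            need, "laterality=left",
        ):
            slot.laterality = "left"
        for slot in _take(
            slots,
            lambda s: s.laterality == "right" and s.stay_fb
            and not s.convert,
            lat_targets.get("bilateral", 0), "laterality=bilateral",
        ):
            slot.laterality = "bilateral"

    # risk factors: every boost keeper aged 50+ needs one boost risk factor
    # (grade 3, LVI, positive margin); every N1 IMN gainer needs one adverse
    # factor.  Spread the obligations so the category totals can be met.
    grade_targets = targets.get("grade", {})
    gr3_target = int(grade_targets.get("3", 0))
    lvi_target = targets.get("lvi", {}).get("yes", 0)
    mpos_target = targets.get("margin_positive", {}).get("yes", 0)
    keepers = [s for s in slots if s.needs_boost_risk]
    n_gr3_keep = min(len(keepers), max(0, gr3_target - 25))
    for slot in keepers:
        slot.grade = 2
    for slot in keepers[:n_gr3_keep]:
        slot.grade = 3
    rest = keepers[n_gr3_keep:]
    n_lvi_keep = min(len(rest), 25)
    for slot in rest[:n_lvi_keep]:
        slot.lvi = True
    for slot in rest[n_lvi_keep:]:
        slot.margin_positive = True
        slot.margin_le_2mm = True
    def _gr3_count():
        return sum(
            1 for s in slots if s.grade == 3 and s.histology != "DCIS"
        )

    for slot in (s for s in slots if s.needs_imn_risk):
        if slot.grade != 3 and not slot.lvi:
            if _gr3_count() < gr3_target:
                slot.grade = 3
            else:
                slot.lvi = True
    # top remaining category counts up on unconstrained invasive patients
    def flag_room(attr_count, target):
        return max(0, target - attr_count)

    _assign_flag = lambda pred, k, setter, name: [
        setter(s) for s in _take(slots, pred, k, name)
    ]
    free_ok = lambda s: s.histology != "DCIS" and not s.frozen_flags
    _assign_flag(
        lambda s: free_ok(s) and s.grade == 2 and not s.needs_boost_risk
        and not s.needs_imn_risk,
        flag_room(_gr3_count(), gr3_target),
        lambda s: setattr(s, "grade", 3), "grade=3",
    )
    _assign_flag(
        lambda s: free_ok(s) and not s.lvi,
        flag_room(sum(1 for s in slots if s.lvi), lvi_target),
        lambda s: setattr(s, "lvi", True), "lvi=yes",
    )

    def set_margin(s):
        s.margin_positive = True
        s.margin_le_2mm = True

    _assign_flag(
        lambda s: free_ok(s) and not s.margin_positive,
        flag_room(sum(1 for s in slots if s.margin_positive), mpos_target),
        set_margin, "margin_positive=yes",
    )
    _assign_flag(
        lambda s: not s.margin_le_2mm and s.histology != "DCIS",
        flag_room(sum(1 for s in slots if s.margin_le_2mm),
                  targets.get("margin_le_2mm", {}).get("yes", 0)),
        lambda s: setattr(s, "margin_le_2mm", True), "margin_le_2mm=yes",
    )

    # grade 1 among the remaining invasive grade-2 patients
    _assign_flag(
        lambda s: s.histology != "DCIS" and s.grade == 2,
        int(grade_targets.get("1", 0)),
        lambda s: setattr(s, "grade", 1), "grade=1",
    )

    # molecular subtype (invasive only; triple negative is an IMN adverse
    # factor so it must avoid nodal patients who stay off IMN)
    subtype = targets.get("molecular_subtype")
    if subtype is not None:
        _assign_categories(
            slots, "molecular_subtype",
            [("triple_negative", subtype.get("triple_negative", 0))],
            lambda s: s.histology != "DCIS" and not s.frozen_flags
            and s.molecular_subtype == "luminalA",
            "molecular_subtype",
        )
        _assign_categories(
            slots, "molecular_subtype",
            [("HER2pos", subtype.get("HER2pos", 0)),
             ("luminalB", subtype.get("luminalB", 0))],
            lambda s: s.histology != "DCIS"
            and s.molecular_subtype == "luminalA",
            "molecular_subtype",
        )

    # central/medial tumour location (invasive; an IMN adverse factor)
    cm = targets.get("central_or_medial", {}).get("yes")
    if cm is not None:
        _assign_flag(
            lambda s: s.histology != "DCIS" and not s.frozen_flags
            and not s.central_or_medial,
            cm, lambda s: setattr(s, "central_or_medial", True),
            "central_or_medial=yes",
        )

    # invasive histological subtypes
    hist = targets.get("histology")
    if hist is not None:
        _assign_categories(
            slots, "histology",
            [("lobular", hist.get("lobular", 0)),
             ("mixed", hist.get("mixed", 0)),
             ("other", hist.get("other", 0))],
            lambda s: s.histology == "ductal",
            "histology",
        )

    # chemotherapy: node-positive patients first
    chemo = targets.get("chemotherapy", {}).get("yes")
    if chemo is not None:
        positive = [s for s in slots if s.n_stage in ("N1", "N2", "N3")]
        if chemo < len(positive):
            raise GenerationError(
                "infeasible spec: chemotherapy target below the node-"
                "positive count"
            )
        for slot in positive:
            slot.chemotherapy = True
        _assign_flag(
            lambda s: not s.chemotherapy,
            chemo - len(positive),
            lambda s: setattr(s, "chemotherapy", True), "chemotherapy=yes",
        )

    # tumour stage: advanced stages preferentially post-mastectomy
    t_targets = targets.get("t_stage")
    if t_targets is not None:
        def t_eligible(s):
            return s.histology != "DCIS" and not s.t_stage

        _assign_categories(
            slots, "t_stage",
            [("T4", t_targets.get("T4", 0)), ("T3", t_targets.get("T3", 0))],
            lambda s: t_eligible(s) and s.surgery == "mastectomy",
            "t_stage",
        )
        _assign_categories(
            slots, "t_stage",
            [("T0", t_targets.get("T0", 0))],
            lambda s: t_eligible(s) and s.chemotherapy,
            "t_stage",
        )
        _assign_categories(
            slots, "t_stage",
            [("T1", t_targets.get("T1", 0)), ("T2", t_targets.get("T2", 0))],
            t_eligible, "t_stage",
        )

    # axillary surgery: no surgery for unstageable axillae, dissection for
    # node-positive disease
    ns = targets.get("nodal_surgery")
    if ns is not None:
        for slot in slots:
            slot.nodal_surgery = "SLNB"
        for slot in _take(slots, lambda s: s.n_stage == "NX",
                          ns.get("none", 0), "nodal_surgery=none"):
            slot.nodal_surgery = "none"
        _assign_categories(
            slots, "nodal_surgery", [("ALND", ns.get("ALND", 0))],
            lambda s: s.nodal_surgery == "SLNB"
            and s.n_stage in ("N1", "N2", "N3"),
            "nodal_surgery",
        )

    # sex and the extra reconstruction patient
    males = targets.get("sex", {}).get("male", 0)
    for slot in _take(
        slots, lambda s: s.surgery == "mastectomy" and not s.reconstruction
        and s.histology != "DCIS" and s.laterality != "bilateral",
        males, "sex=male",
    ):
        slot.sex = "male"
    recon = targets.get("reconstruction", {}).get("yes")
    if recon is not None:
        have = sum(1 for s in slots if s.reconstruction)
        for slot in _take(
            slots, lambda s: s.surgery == "mastectomy" and s.sex == "female"
            and not s.reconstruction,
            recon - have, "reconstruction=yes",
        ):
            slot.reconstruction = True

    # DCIS feature quotas over the in-situ subgroup (high-risk patients all
    # carry size > 15 mm, so feature redistribution cannot de-risk them)
    dcis_slots = [s for s in slots if s.histology == "DCIS"]
    high = [s for s in dcis_slots if s.role != "dcis_stay"]
    dg = targets.get("dcis_nuclear_grade")
    if dg is not None and dcis_slots:
        for slot in high:
            slot.dcis["nuclear_grade"] = "low"
        for slot in high[:dg.get("high", 0)]:
            slot.dcis["nuclear_grade"] = "high"
        for slot in high:
            slot.grade = {"low": 1, "intermediate": 2, "high": 3}[
                slot.dcis["nuclear_grade"]
            ]
    for key, attr in (("dcis_comedonecrosis", "comedonecrosis"),
                      ("dcis_central_necrosis", "central_necrosis"),
                      ("dcis_symptomatic", "symptomatic")):
        quota = targets.get(key, {}).get("yes")
        if quota is None or not dcis_slots:
            continue
        if quota > len(high):
            raise GenerationError(
                f"infeasible spec: {key} target exceeds the high-risk "
                "DCIS count"
            )
        for slot in high:
            slot.dcis[attr] = False
        for slot in high[:quota]:
            slot.dcis[attr] = True


# ---------------------------------------------------------------------------
# Generation entry points
# ---------------------------------------------------------------------------

def _sample_ages(slots: list[_Slot], rng: np.random.Generator) -> None:
    for slot in slots:
        slot.age = int(rng.integers(slot.age_lo, slot.age_hi + 1))


def _records(slots: list[_Slot], rng: np.random.Generator
             ) -> list[PatientRecord]:
    order = rng.permutation(len(slots))
    records = []
    width = max(3, len(str(len(slots))))
    for rank, idx in enumerate(order, start=1):
        slot = slots[idx]
        dcis = DcisProfile(**slot.dcis) if slot.dcis is not None else None
        record = PatientRecord(
            patient_id=f"P{rank:0{width}d}",
            age=slot.age,
            sex=slot.sex,
            t_stage=slot.t_stage or ("Tis" if slot.histology == "DCIS"
                                     else "T1"),
            n_stage=slot.n_stage,
            chemotherapy=slot.chemotherapy,
            surgery=slot.surgery,
            reconstruction=slot.reconstruction,
            nodal_surgery=slot.nodal_surgery,
            laterality=slot.laterality,
            central_or_medial=slot.central_or_medial,
            histology=slot.histology,
            molecular_subtype=slot.molecular_subtype,
            grade=slot.grade,
            lvi=slot.lvi,
            margin_positive=slot.margin_positive,
            margin_le_2mm=slot.margin_le_2mm,
            fb_plan_unsatisfactory=False,
            baseline_regimen_id=slot.base.regimen_id,
            dcis_features=dcis,
        )
        record.validate()
        records.append(record)
    return records


def generate_cohort(spec: CohortSpec,
                    registry: Optional[RegimenRegistry] = None,
                    seed: Optional[int] = None
                    ) -> tuple[list[PatientRecord], GenerationReport]:
    """Construct a cohort satisfying the spec; deterministic per seed.

    Raises :class:`GenerationError` when the spec is infeasible (the
    message lists the binding constraints) or when the generated cohort
    fails any hard constraint on validation.
    """
    if registry is None:
        registry = default_registry()
    used_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    slots = _build_slots(spec, registry)
    if spec.marginal_targets is not None:
        _apply_marginals(slots, spec)
    _sample_ages(slots, rng)
    cohort = _records(slots, rng)
    report = validate_cohort(cohort, spec, registry)
    report.seed = used_seed
    if not report.ok:
        raise GenerationError(
            "generated cohort violates hard constraints:\n  "
            + "\n  ".join(report.unsatisfied)
        )
    return cohort, report


# ---------------------------------------------------------------------------
# Brute-force validation
# ---------------------------------------------------------------------------

def _expected_transitions(spec: CohortSpec,
                          registry: RegimenRegistry) -> dict:
    """Transition targets implied by the role plan (used when the spec does
    not state them explicitly)."""
    final_counts: dict[str, int] = {}
    boost_removals = ultra = dcis_add = imn_add = 0
    for group in spec.groups:
        base = registry.get(group.regimen_id)
        for role, count in group.roles.items():
            final = _final_regimen(role, base, registry)
            final_counts[final.regimen_id] = (
                final_counts.get(final.regimen_id, 0) + count
            )
            if role.startswith("boost_loser"):
                boost_removals += count
            if final.primary_dose_gy == 26:
                ultra += count
            if role == "dcis_gain":
                dcis_add += count
            if role in ("boost_keeper_special_imn", "boost_keeper_imn_mover",
                        "boost_keeper_imn_mover_dibh_convert", "imn_mover",
                        "imn_mover_dibh_convert") \
                    and base.nodal_class != "scax_imn":
                imn_add += count
    imn_total = sum(
        n for rid, n in final_counts.items()
        if registry.get(rid).nodal_class == "scax_imn"
    )
    return {
        "boost_removals_change_2": boost_removals,
        "ultra_total_after_change_3": ultra,
        "dcis_boost_additions_change_4": dcis_add,
        "imn_additions_change_5": imn_add,
        "imn_total_after_change_5": imn_total,
        "final_counts": final_counts,
    }


def validate_cohort(cohort: list[PatientRecord], spec: CohortSpec,
                    registry: Optional[RegimenRegistry] = None
                    ) -> GenerationReport:
    """Recount every constraint by brute force over the patient list.

    Hard constraints: record invariants, baseline assignment counts, the
    rule-engine transition counts, and the consistent marginal targets.
    Inconsistent marginals (``SOFT_MARGINALS``) and the mean-age target are
    reported, not enforced.
    """
    if registry is None:
        registry = default_registry()
    report = GenerationReport(seed=None)

    def check(ok: bool, label: str) -> None:
        (report.satisfied if ok else report.unsatisfied).append(label)

    for record in cohort:
        try:
            record.validate()
        except Exception as err:  # noqa: BLE001 - surfaced in the report
            report.unsatisfied.append(f"invariant: {err}")
    check(len(cohort) == spec.total_n,
          f"total_n == {spec.total_n} (actual {len(cohort)})")

    baseline = {}
    for record in cohort:
        baseline[record.baseline_regimen_id] = (
            baseline.get(record.baseline_regimen_id, 0) + 1
        )
    for rid, n in sorted(spec.baseline_counts().items()):
        check(baseline.get(rid, 0) == n,
              f"baseline[{rid}] == {n} (actual {baseline.get(rid, 0)})")

    # marginals
    if spec.marginal_targets is not None:
        summary = summarize_cohort(cohort)
        for variable, cats in spec.marginal_targets.items():
            for category, target in cats.items():
                actual = summary.count(variable, str(category))
                label = (f"marginal {variable}={category}: target {target}, "
                         f"actual {actual}")
                if (variable, str(category)) in SOFT_MARGINALS:
                    report.soft_notes.append(
                        label + (" [ok]" if actual == target else " [miss]")
                    )
                else:
                    check(actual == int(target), label)
        if spec.mean_age_target is not None:
            report.soft_notes.append(
                f"mean age: target {spec.mean_age_target}, "
                f"actual {summary.mean_age}"
            )

    # transitions, recomputed with the actual rule engine
    targets = spec.transition_targets or _expected_transitions(spec, registry)
    assignment = baseline_assignment(cohort)
    states = [assignment]
    for change in get_changes():
        assignment = apply_change(cohort, assignment, change, registry)
        states.append(assignment)

    def n_with(assignment, predicate):
        return sum(
            1 for rid in assignment.values() if predicate(registry.get(rid))
        )

    removals = sum(
        1 for pid in states[1]
        if registry.get(states[1][pid]).boost
        and not registry.get(states[2][pid]).boost
    )
    check(removals == targets["boost_removals_change_2"],
          f"boost removals at change 2 == "
          f"{targets['boost_removals_change_2']} (actual {removals})")
    ultra = n_with(states[3], lambda r: r.primary_dose_gy == 26)
    check(ultra == targets["ultra_total_after_change_3"],
          f"one-week patients after change 3 == "
          f"{targets['ultra_total_after_change_3']} (actual {ultra})")
    additions = sum(
        1 for pid in states[3]
        if not registry.get(states[3][pid]).boost
        and registry.get(states[4][pid]).boost
    )
    check(additions == targets["dcis_boost_additions_change_4"],
          f"DCIS boost additions at change 4 == "
          f"{targets['dcis_boost_additions_change_4']} (actual {additions})")
    imn_gain = sum(
        1 for pid in states[4]
        if registry.get(states[4][pid]).nodal_class != "scax_imn"
        and registry.get(states[5][pid]).nodal_class == "scax_imn"
    )
    check(imn_gain == targets["imn_additions_change_5"],
          f"IMN additions at change 5 == "
          f"{targets['imn_additions_change_5']} (actual {imn_gain})")
    imn_total = n_with(states[5], lambda r: r.nodal_class == "scax_imn")
    check(imn_total == targets["imn_total_after_change_5"],
          f"IMN-treated after change 5 == "
          f"{targets['imn_total_after_change_5']} (actual {imn_total})")
    final_counts: dict[str, int] = {}
    for rid in states[6].values():
        final_counts[rid] = final_counts.get(rid, 0) + 1
    for rid, n in sorted(targets["final_counts"].items()):
        check(final_counts.get(rid, 0) == int(n),
              f"final[{rid}] == {n} (actual {final_counts.get(rid, 0)})")

    changed = sum(
        1 for pid in states[0] if states[0][pid] != states[6][pid]
    )
    report.soft_notes.append(
        f"patients whose final regimen differs from baseline: {changed}"
    )
    return report
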