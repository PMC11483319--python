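"""The six guideline protocol changes as predicates plus regimen rewrites.

Each change tests patient covariates (and sometimes the current regimen) and
rewrites the regimen assignment only — patient records are never mutated.
Changes are applied strictly in numbered order and each later change sees
the rewrites of the earlier ones (e.g. boosts are individualised before
one-week ultrahypofractionation eligibility is assessed).  Where a rule is
ambiguous the more resource-intensive option is kept: in particular the
breath-hold change only ever adds DIBH, never removes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .cohort import PatientRecord, Regimen, RegimenRegistry

Assignment = dict[str, str]
"""Map patient_id -> regimen_id."""


# ---------------------------------------------------------------------------
# Patient-level predicates
# ---------------------------------------------------------------------------

def boost_indicated(patient: PatientRecord) -> bool:
    """Tumour-bed boost indication for invasive disease after breast
    conservation: under 50, or 50 and over with at least one risk factor
    (grade 3, lymphovascular invasion, extensive intraductal component,
    positive margin)."""
    if not patient.invasive:
        raise ValueError(
            "boost_indicated applies to invasive disease; "
            "use dcis_boost_indicated for DCIS"
        )
    if patient.age < 50:
        return True
    return (
        patient.grade == 3
        or patient.lvi
        or patient.extensive_intraductal_component
        or patient.margin_positive
    )


def dcis_boost_indicated(patient: PatientRecord) -> bool:
    """High-risk DCIS boost indication after breast conservation: any of
    age under 50, symptomatic presentation, size over 15 mm, multifocality,
    intermediate or high nuclear grade, comedonecrosis, or radial margin
    under 10 mm."""
    features = patient.dcis_features
    if patient.invasive or features is None:
        raise ValueError("dcis_boost_indicated requires DCIS features")
    return (
        patient.age < 50
        or features.symptomatic
        or features.size_mm > 15
        or features.multifocal
        or features.nuclear_grade in ("intermediate", "high")
        or features.comedonecrosis
        or features.radial_margin_mm < 10
    )


def imn_indicated(patient: PatientRecord) -> bool:
    """Internal mammary node irradiation indication: N2-3 disease, or N1
    disease with at least one adverse factor (grade 3, lymphovascular
    invasion, triple-negative subtype, age under 40, central or medial
    primary tumour)."""
    if patient.n_stage in ("N2", "N3"):
        return True
    if patient.n_stage != "N1":
        return False
    return (
        patient.grade == 3
        or patient.lvi
        or patient.molecular_subtype == "triple_negative"
        or patient.age < 40
        or patient.central_or_medial
    )


def dibh_indicated(patient: PatientRecord, regimen: Regimen) -> bool:
    """Deep-inspiration breath hold indication: under 60 with left-sided
    treatment; under 60 with right-sided treatment including the internal
    mammary chain; or 60 and over when a satisfactory free-breathing plan
    cannot be achieved."""
    imn = regimen.nodal_class == "scax_imn"
    if patient.age < 60:
        if patient.laterality == "left":
            return True
        if patient.laterality == "right" and imn:
            return True
        return False
    return patient.fb_plan_unsatisfactory


def ultra_eligible(patient: PatientRecord, regimen: Regimen) -> bool:
    """One-week 26 Gy / 5 fraction eligibility: invasive disease on a
    breast/chest-wall-only schedule with no boost and no nodal target."""
    return (
        regimen.nodal_class == "none"
        and not regimen.boost
        and patient.invasive
    )


# ---------------------------------------------------------------------------
# Regimen rewrites
# ---------------------------------------------------------------------------

def _with_attrs(regimen: Regimen, registry: RegimenRegistry, *,
                primary_dose_gy=None, primary_fractions=None,
                nodal_class=None, dibh=None, boost=None) -> Regimen:
    return registry.lookup(
        primary_dose_gy=(
            regimen.primary_dose_gy if primary_dose_gy is None
            else primary_dose_gy
        ),
        primary_fractions=(
            regimen.primary_fractions if primary_fractions is None
            else primary_fractions
        ),
        nodal_class=regimen.nodal_class if nodal_class is None else nodal_class,
        dibh=regimen.dibh if dibh is None else dibh,
        boost=regimen.boost if boost is None else boost,
    )


def _change_1(patient: PatientRecord, regimen: Regimen,
              registry: RegimenRegistry) -> Regimen:
    # Moderate hypofractionation (40/15) replaces 50 Gy conventional
    # fractionation, used at baseline in the reconstruction setting.
    if regimen.primary_dose_gy == 50:
        return _with_attrs(
            regimen, registry, primary_dose_gy=40, primary_fractions=15
        )
    return regimen


def _change_2(patient: PatientRecord, regimen: Regimen,
              registry: RegimenRegistry) -> Regimen:
    # Individualised tumour-bed boost for invasive breast-conserving
    # patients; mastectomy and in-situ assignments are left as given.
    if not patient.invasive or patient.surgery != "WLE":
        return regimen
    wanted = boost_indicated(patient)
    if wanted == regimen.boost:
        return regimen
    return _with_attrs(regimen, registry, boost=wanted)


def _change_3(patient: PatientRecord, regimen: Regimen,
              registry: RegimenRegistry) -> Regimen:
    # One-week ultrahypofractionation for eligible early disease,
    # preserving the breathing technique.
    if ultra_eligible(patient, regimen):
        return _with_attrs(
            regimen, registry, primary_dose_gy=26, primary_fractions=5,
            nodal_class="none", boost=False,
        )
    return regimen


def _change_4(patient: PatientRecord, regimen: Regimen,
              registry: RegimenRegistry) -> Regimen:
    # Tumour-bed boost for high-risk DCIS after breast conservation.
    if patient.invasive or patient.surgery != "WLE":
        return regimen
    wanted = dcis_boost_indicated(patient)
    if wanted == regimen.boost:
        return regimen
    return _with_attrs(regimen, registry, boost=wanted)


def _change_5(patient: PatientRecord, regimen: Regimen,
              registry: RegimenRegistry) -> Regimen:
    # Internal mammary irradiation for all meeting the updated criteria.
    # Applied to patients already receiving nodal radiotherapy; a patient
    # with frank N2-3 disease is additionally escalated from breast-only
    # to full locoregional coverage.
    if not imn_indicated(patient):
        return regimen
    if regimen.nodal_class == "none" and patient.n_stage not in ("N2", "N3"):
        return regimen
    if regimen.nodal_class == "scax_imn":
        return regimen
    return _with_attrs(regimen, registry, nodal_class="scax_imn")


def _change_6(patient: PatientRecord, regimen: Regimen,
              registry: RegimenRegistry) -> Regimen:
    # Breath-hold criteria; DIBH is only ever added (the more resource-
    # intensive option), never withdrawn from a patient already planned
    # in breath hold.
    if regimen.dibh or not dibh_indicated(patient, regimen):
        return regimen
    return _with_attrs(regimen, registry, dibh=True)


@dataclass(frozen=True)
class ProtocolChange:
    """One guideline change: an assignment rewrite over the whole cohort."""

    change_id: int
    description: str
    rewrite: Callable[[PatientRecord, Regimen, RegimenRegistry], Regimen]

    def apply_to_patient(self, patient: PatientRecord, regimen: Regimen,
                         registry: RegimenRegistry) -> Regimen:
        return self.rewrite(patient, regimen, registry)


DEFAULT_CHANGES: tuple[ProtocolChange, ...] = (
    ProtocolChange(1, "40 Gy/15 fx replaces 50 Gy/25 fx (reconstruction "
                      "setting)", _change_1),
    ProtocolChange(2, "individualised tumour-bed boost for invasive "
                      "breast-conserving patients", _change_2),
    ProtocolChange(3, "26 Gy/5 fx for early disease without boost or nodal "
                      "radiotherapy", _change_3),
    ProtocolChange(4, "tumour-bed boost for high-risk DCIS", _change_4),
    ProtocolChange(5, "internal mammary node radiotherapy for all meeting "
                      "updated criteria", _change_5),
    ProtocolChange(6, "deep inspiration breath hold per defined criteria",
                   _change_6),
)


def get_changes(change_ids=None) -> tuple[ProtocolChange, ...]:
    """The built-in changes, optionally restricted to a subset of ids
    (order is always ascending by id)."""
    if change_ids is None:
        return DEFAULT_CHANGES
    wanted = set(change_ids)
    unknown = wanted - {c.change_id for c in DEFAULT_CHANGES}
    if unknown:
        raise KeyError(f"unknown change ids {sorted(unknown)}")
    return tuple(c for c in DEFAULT_CHANGES if c.change_id in wanted)


def baseline_assignment(cohort: list[PatientRecord]) -> Assignment:
    return {p.patient_id: p.baseline_regimen_id for p in cohort}


def apply_change(cohort: list[PatientRecord], assignment: Assignment,
                 change: ProtocolChange,
                 registry: RegimenRegistry) -> Assignment:
    """Apply one protocol change to every patient; returns a new assignment.

    Patients whose predicate does not fire keep their regimen; patient
    covariates are never altered.  Raises ``KeyError`` when a rewrite
    targets a regimen absent from the registry.
    """
    out: Assignment = {}
    for patient in cohort:
        regimen = registry.get(assignment[patient.patient_id])
        out[patient.patient_id] = change.apply_to_patient(
            patient, regimen, registry
        ).regimen_id
    return out
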