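"""Patient, regimen and cohort-summary data model, with delimited-text IO.

One :class:`PatientRecord` carries every covariate the protocol eligibility
rules read (age, staging, histology, surgery, margins, DCIS features, ...)
plus the fractionation regimen the patient actually received at baseline.
Regimens live in a :class:`RegimenRegistry` so that rule transforms can be
expressed as attribute rewrites ("same schedule, add internal mammary
nodes") that must resolve to a registered regimen.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

SEXES = ("female", "male")
T_STAGES = ("T0", "Tis", "T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2", "N3", "NX")
SURGERIES = ("WLE", "mastectomy")
NODAL_SURGERIES = ("none", "SLNB", "ALND")
LATERALITIES = ("left", "right", "bilateral")
HISTOLOGIES = ("DCIS", "ductal", "lobular", "mixed", "other")
MOLECULAR_SUBTYPES = ("luminalA", "luminalB", "HER2pos", "triple_negative")
NUCLEAR_GRADES = ("low", "intermediate", "high")
NODAL_CLASSES = ("none", "scax", "scax_imn")


class ValidationError(ValueError):
    """A record violates a data-model invariant; the message names the field."""


class CohortSchemaError(ValueError):
    """A cohort file cannot be interpreted (bad header, unknown regimen, ...)."""


def _check_enum(value: str, allowed: tuple, field_name: str) -> None:
    if value not in allowed:
        raise ValidationError(
            f"{field_name}={value!r} not in {sorted(allowed)}"
        )


@dataclass(frozen=True)
class DcisProfile:
    """In-situ disease features driving the high-risk DCIS boost rule."""

    nuclear_grade: str
    comedonecrosis: bool
    central_necrosis: bool
    symptomatic: bool
    size_mm: float
    multifocal: bool
    radial_margin_mm: float
    extensive_intraductal_component: bool = False

    def validate(self) -> None:
        _check_enum(self.nuclear_grade, NUCLEAR_GRADES, "nuclear_grade")
        if self.size_mm < 0:
            raise ValidationError(f"size_mm={self.size_mm} must be >= 0")
        if self.radial_margin_mm < 0:
            raise ValidationError(
                f"radial_margin_mm={self.radial_margin_mm} must be >= 0"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One patient's rule-relevant covariates plus the baseline regimen.

    ``dcis_features`` is mandatory for in-situ (DCIS) histology.  For
    invasive histology an attached profile is optional and is used only as
    the carrier of ``extensive_intraductal_component``, a tumour-bed boost
    risk factor that can accompany invasive disease.
    """

    patient_id: str
    age: int
    sex: str
    t_stage: str
    n_stage: str
    chemotherapy: bool
    surgery: str
    reconstruction: bool
    nodal_surgery: str
    laterality: str
    central_or_medial: bool
    histology: str
    molecular_subtype: str
    grade: int
    lvi: bool
    margin_positive: bool
    margin_le_2mm: bool
    fb_plan_unsatisfactory: bool
    baseline_regimen_id: str
    dcis_features: Optional[DcisProfile] = None

    def validate(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.age < 0:
            raise ValidationError(f"age={self.age} must be >= 0")
        _check_enum(self.sex, SEXES, "sex")
        _check_enum(self.t_stage, T_STAGES, "t_stage")
        _check_enum(self.n_stage, N_STAGES, "n_stage")
        _check_enum(self.surgery, SURGERIES, "surgery")
        _check_enum(self.nodal_surgery, NODAL_SURGERIES, "nodal_surgery")
        _check_enum(self.laterality, LATERALITIES, "laterality")
        _check_enum(self.histology, HISTOLOGIES, "histology")
        _check_enum(
            self.molecular_subtype, MOLECULAR_SUBTYPES, "molecular_subtype"
        )
        if self.grade not in (1, 2, 3):
            raise ValidationError(f"grade={self.grade} must be 1, 2 or 3")
        if self.histology == "DCIS" and self.dcis_features is None:
            raise ValidationError(
                "dcis_features required when histology=DCIS"
            )
        if self.margin_positive and not self.margin_le_2mm:
            raise ValidationError(
                "margin_positive implies margin_le_2mm (tumour on ink is "
                "within any close-margin definition)"
            )
        if self.dcis_features is not None:
            self.dcis_features.validate()

    @property
    def invasive(self) -> bool:
        return self.histology != "DCIS"

    @property
    def extensive_intraductal_component(self) -> bool:
        if self.dcis_features is None:
            return False
        return self.dcis_features.extensive_intraductal_component


@dataclass(frozen=True)
class Regimen:
    """A fractionation schedule: the unit of assignment and of costing."""

    regimen_id: str
    primary_dose_gy: float
    primary_fractions: int
    nodal_class: str
    dibh: bool
    boost: bool
    boost_fractions: int = 0

    def validate(self) -> None:
        if not self.regimen_id:
            raise ValidationError("regimen_id must be non-empty")
        if self.primary_dose_gy <= 0:
            raise ValidationError("primary_dose_gy must be > 0")
        if self.primary_fractions <= 0:
            raise ValidationError("primary_fractions must be > 0")
        _check_enum(self.nodal_class, NODAL_CLASSES, "nodal_class")
        if self.boost and self.boost_fractions <= 0:
            raise ValidationError("boost implies boost_fractions > 0")
        if not self.boost and self.boost_fractions != 0:
            raise ValidationError("boost_fractions must be 0 when boost false")

    @property
    def total_fractions(self) -> int:
        return self.primary_fractions + self.boost_fractions


class RegimenRegistry:
    """Unique-id regimen collection with attribute-based lookup."""

    def __init__(self, regimens: Iterable[Regimen]):
        self._by_id: dict[str, Regimen] = {}
        for reg in regimens:
            reg.validate()
            if reg.regimen_id in self._by_id:
                raise ValidationError(
                    f"duplicate regimen_id {reg.regimen_id!r}"
                )
            self._by_id[reg.regimen_id] = reg

    def __contains__(self, regimen_id: str) -> bool:
        return regimen_id in self._by_id

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def get(self, regimen_id: str) -> Regimen:
        try:
            return self._by_id[regimen_id]
        except KeyError:
            raise KeyError(f"unknown regimen_id {regimen_id!r}") from None

    def lookup(
        self,
        primary_dose_gy: float,
        primary_fractions: int,
        nodal_class: str,
        dibh: bool,
        boost: bool,
    ) -> Regimen:
        """Find the unique regimen with the given attributes.

        Raises ``KeyError`` naming the attribute combination when no
        registered regimen matches (a rule transform targeting an
        unregistered schedule is a hard error, not a silent no-op).
        """
        for reg in self._by_id.values():
            if (
                reg.primary_dose_gy == primary_dose_gy
                and reg.primary_fractions == primary_fractions
                and reg.nodal_class == nodal_class
                and reg.dibh == dibh
                and reg.boost == boost
            ):
                return reg
        raise KeyError(
            "no registered regimen with "
            f"dose={primary_dose_gy}, fractions={primary_fractions}, "
            f"nodal_class={nodal_class}, dibh={dibh}, boost={boost}"
        )

    @classmethod
    def from_csv(cls, path) -> "RegimenRegistry":
        df = pd.read_csv(path, comment="#")
        required = {
            "regimen_id", "primary_dose_gy", "primary_fractions",
            "nodal_class", "dibh", "boost", "boost_fractions",
        }
        missing = required - set(df.columns)
        if missing:
            raise CohortSchemaError(
                f"regimen registry {path} missing columns {sorted(missing)}"
            )
        regimens = [
            Regimen(
                regimen_id=str(row.regimen_id),
                primary_dose_gy=float(row.primary_dose_gy),
                primary_fractions=int(row.primary_fractions),
                nodal_class=str(row.nodal_class),
                dibh=_parse_bool(row.dibh, "dibh"),
                boost=_parse_bool(row.boost, "boost"),
                boost_fractions=int(row.boost_fractions),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(regimens)


def default_registry() -> RegimenRegistry:
    """The packaged registry covering every schedule used in the analysis."""
    with resources.as_file(
        resources.files("rtcost.data").joinpath("regimens.csv")
    ) as path:
        return RegimenRegistry.from_csv(path)


# ---------------------------------------------------------------------------
# Cohort CSV schema: comma-separated, UTF-8, one header row, booleans
# written as true/false, DCIS feature columns prefixed dcis_ and left blank
# when no profile is attached.
# ---------------------------------------------------------------------------

_BOOL_FIELDS = {
    "chemotherapy", "reconstruction", "central_or_medial", "lvi",
    "margin_positive", "margin_le_2mm", "fb_plan_unsatisfactory",
}
_DCIS_COLUMNS = (
    "dcis_nuclear_grade", "dcis_comedonecrosis", "dcis_central_necrosis",
    "dcis_symptomatic", "dcis_size_mm", "dcis_multifocal",
    "dcis_radial_margin_mm", "dcis_extensive_intraductal_component",
)

COHORT_COLUMNS = tuple(
    f.name for f in dc_fields(PatientRecord) if f.name != "dcis_features"
) + _DCIS_COLUMNS


def _parse_bool(value, field_name: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text == "true":
        return True
    if text == "false":
        return False
    raise CohortSchemaError(
        f"{field_name}={value!r} is not a true/false boolean"
    )


def _fmt_bool(value: bool) -> str:
    return "true" if value else "false"


def _record_from_row(row: Mapping[str, str], line_no: int,
                     registry: Optional[RegimenRegistry]) -> PatientRecord:
    def boolean(name: str) -> bool:
        return _parse_bool(row[name], name)

    dcis = None
    if str(row.get("dcis_nuclear_grade", "") or "").strip():
        dcis = DcisProfile(
            nuclear_grade=str(row["dcis_nuclear_grade"]),
            comedonecrosis=boolean("dcis_comedonecrosis"),
            central_necrosis=boolean("dcis_central_necrosis"),
            symptomatic=boolean("dcis_symptomatic"),
            size_mm=float(row["dcis_size_mm"]),
            multifocal=boolean("dcis_multifocal"),
            radial_margin_mm=float(row["dcis_radial_margin_mm"]),
            extensive_intraductal_component=boolean(
                "dcis_extensive_intraductal_component"
            ),
        )
    try:
        record = PatientRecord(
            patient_id=str(row["patient_id"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            t_stage=str(row["t_stage"]),
            n_stage=str(row["n_stage"]),
            chemotherapy=boolean("chemotherapy"),
            surgery=str(row["surgery"]),
            reconstruction=boolean("reconstruction"),
            nodal_surgery=str(row["nodal_surgery"]),
            laterality=str(row["laterality"]),
            central_or_medial=boolean("central_or_medial"),
            histology=str(row["histology"]),
            molecular_subtype=str(row["molecular_subtype"]),
            grade=int(row["grade"]),
            lvi=boolean("lvi"),
            margin_positive=boolean("margin_positive"),
            margin_le_2mm=boolean("margin_le_2mm"),
            fb_plan_unsatisfactory=boolean("fb_plan_unsatisfactory"),
            baseline_regimen_id=str(row["baseline_regimen_id"]),
            dcis_features=dcis,
        )
        record.validate()
    except ValidationError as err:
        raise ValidationError(f"row {line_no}: {err}") from None
    if registry is not None and record.baseline_regimen_id not in registry:
        raise CohortSchemaError(
            f"row {line_no}: unknown regimen id "
            f"{record.baseline_regimen_id!r}"
        )
    return record


def read_cohort(path, registry: Optional[RegimenRegistry] = None
                ) -> list[PatientRecord]:
    """Read and validate a cohort CSV; every row must satisfy the invariants.

    When ``registry`` is given, each ``baseline_regimen_id`` must resolve.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortSchemaError(
            f"cohort file {path} missing columns {sorted(missing)}"
        )
    return [
        _record_from_row(row, line_no=i + 2, registry=registry)
        for i, row in enumerate(df.to_dict(orient="records"))
    ]


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {}
        for f in dc_fields(PatientRecord):
            if f.name == "dcis_features":
                continue
            value = getattr(rec, f.name)
            row[f.name] = _fmt_bool(value) if f.name in _BOOL_FIELDS else value
        if rec.dcis_features is None:
            row.update({col: "" for col in _DCIS_COLUMNS})
        else:
            d = rec.dcis_features
            row.update({
                "dcis_nuclear_grade": d.nuclear_grade,
                "dcis_comedonecrosis": _fmt_bool(d.comedonecrosis),
                "dcis_central_necrosis": _fmt_bool(d.central_necrosis),
                "dcis_symptomatic": _fmt_bool(d.symptomatic),
                "dcis_size_mm": d.size_mm,
                "dcis_multifocal": _fmt_bool(d.multifocal),
                "dcis_radial_margin_mm": d.radial_margin_mm,
                "dcis_extensive_intraductal_component": _fmt_bool(
                    d.extensive_intraductal_component
                ),
            })
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Iterable[PatientRecord], path) -> None:
    """Write the cohort in the fixed CSV dialect (round-trips exactly)."""
    cohort_to_frame(cohort).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Cohort summary (the patient-characteristics table)
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Category counts per cohort variable.

    Variables that only apply to a subgroup (grade, molecular subtype and
    central/medial location to invasive disease; nuclear grade and related
    features to DCIS) are counted over that subgroup, so their categories
    sum to the subgroup size, not to ``total_n``.
    """

    total_n: int
    mean_age: float
    counts: dict[str, dict[str, int]]

    def count(self, variable: str, category: str) -> int:
        return self.counts.get(variable, {}).get(category, 0)

    def percentage(self, variable: str, category: str) -> float:
        if self.total_n == 0:
            return 0.0
        return round(100.0 * self.count(variable, category) / self.total_n, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": var,
                "category": cat,
                "n": n,
                "percent_of_cohort": self.percentage(var, cat),
            }
            for var, cats in self.counts.items()
            for cat, n in cats.items()
        ]
        return pd.DataFrame(
            rows, columns=["variable", "category", "n", "percent_of_cohort"]
        )


def _tally(values: Iterable[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return out


def _yesno(flags: Iterable[bool]) -> dict[str, int]:
    flags = list(flags)
    return {"yes": sum(flags), "no": len(flags) - sum(flags)}


def summarize_cohort(cohort: list[PatientRecord]) -> CohortSummary:
    """Tabulate the cohort's patient and disease characteristics."""
    invasive = [p for p in cohort if p.invasive]
    dcis = [p for p in cohort if not p.invasive]
    counts = {
        "sex": _tally(p.sex for p in cohort),
        "t_stage": _tally(p.t_stage for p in cohort),
        "n_stage": _tally(p.n_stage for p in cohort),
        "chemotherapy": _yesno(p.chemotherapy for p in cohort),
        "surgery": _tally(p.surgery for p in cohort),
        "reconstruction": _yesno(p.reconstruction for p in cohort),
        "nodal_surgery": _tally(p.nodal_surgery for p in cohort),
        "laterality": _tally(p.laterality for p in cohort),
        "central_or_medial": _yesno(p.central_or_medial for p in invasive),
        "histology": _tally(p.histology for p in cohort),
        "molecular_subtype": _tally(p.molecular_subtype for p in invasive),
        "grade": _tally(str(p.grade) for p in invasive),
        "lvi": _yesno(p.lvi for p in cohort),
        "margin_positive": _yesno(p.margin_positive for p in cohort),
        "margin_le_2mm": _yesno(p.margin_le_2mm for p in cohort),
        "dcis_nuclear_grade": _tally(
            p.dcis_features.nuclear_grade for p in dcis
        ),
        "dcis_comedonecrosis": _yesno(
            p.dcis_features.comedonecrosis for p in dcis
        ),
        "dcis_central_necrosis": _yesno(
            p.dcis_features.central_necrosis for p in dcis
        ),
        "dcis_symptomatic": _yesno(
            p.dcis_features.symptomatic for p in dcis
        ),
    }
    mean_age = (
        sum(p.age for p in cohort) / len(cohort) if cohort else 0.0
    )
    return CohortSummary(
        total_n=len(cohort), mean_age=round(mean_age, 2), counts=counts
    )
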