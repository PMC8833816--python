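"""Cohort data model, validation and CSV serialization.

A cohort is an ordered collection of :class:`PatientRecord`, one per woman
scheduled for surgery for a pelvic mass.  Each record carries the serum
markers (CA125 in U/mL, HE4 in pmol/L), menopausal status, the ten IOTA
simple-rules ultrasound feature flags plus colour score, the five RMI
ultrasound feature flags, an optional expert-ultrasound call, and the
histology reference standard (benign / borderline / malignant).

For evaluation the truth label is "malignant" iff histology is borderline
or malignant: borderline tumours count as malignant in the reference
standard.

The on-disk format is a plain UTF-8 CSV with a mandatory header row, flags
encoded 0/1 and missing optional values as empty cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import pandas as pd

IOTA_B_FLAGS = (
    "b_unilocular",
    "b_solid_lt7mm",
    "b_acoustic_shadows",
    "b_smooth_multiloc_lt100",
    "b_no_flow",
)
IOTA_M_FLAGS = (
    "m_irregular_solid",
    "m_ascites",
    "m_papillary_ge4",
    "m_irregular_multiloc_solid_ge100",
    "m_strong_flow",
)
RMI_FLAGS = (
    "rmi_multilocular",
    "rmi_solid_areas",
    "rmi_metastases",
    "rmi_ascites",
    "rmi_bilateral",
)

MENOPAUSAL_VALUES = ("pre", "post")
HISTOLOGY_VALUES = ("benign", "borderline", "malignant")
SITE_VALUES = ("cancer_centre", "general_unit")
EXPERT_VALUES = ("malignant", "benign")
FIGO_VALUES = ("I", "II", "III", "IV", "unstaged")

#: Column order of the cohort CSV.
CSV_COLUMNS = (
    "patient_id",
    "age",
    "menopausal",
    "ca125",
    "he4",
    *IOTA_B_FLAGS,
    *IOTA_M_FLAGS,
    "colour_score",
    *RMI_FLAGS,
    "expert_call",
    "histology",
    "ovarian",
    "site",
    "figo_stage",
)


class CohortFormatError(ValueError):
    """Raised when a cohort CSV is structurally unreadable."""


class CohortValidationError(ValueError):
    """Raised in strict mode when a record violates a data invariant."""


@dataclass(frozen=True)
class UltrasoundExam:
    """Ultrasound feature flags recorded at the pre-operative scan.

    The five B-features and five M-features follow the IOTA simple-rules
    definitions; ``colour_score`` is the IOTA colour Doppler score (1 = no
    flow ... 4 = very strong flow).  ``b_no_flow`` must agree with
    ``colour_score == 1`` and ``m_strong_flow`` with ``colour_score == 4``.
    The five ``rmi_*`` flags are the features entering the RMI ultrasound
    score; when ascites is recorded it is the same clinical finding for
    both rule sets, so ``m_ascites == rmi_ascites``.
    """

    b_unilocular: bool = False
    b_solid_lt7mm: bool = False
    b_acoustic_shadows: bool = False
    b_smooth_multiloc_lt100: bool = False
    b_no_flow: bool = False
    m_irregular_solid: bool = False
    m_ascites: bool = False
    m_papillary_ge4: bool = False
    m_irregular_multiloc_solid_ge100: bool = False
    m_strong_flow: bool = False
    colour_score: int = 2
    rmi_multilocular: bool = False
    rmi_solid_areas: bool = False
    rmi_metastases: bool = False
    rmi_ascites: bool = False
    rmi_bilateral: bool = False


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    menopausal: str
    ca125: float
    exam: UltrasoundExam
    histology: str
    ovarian: bool
    site: str
    he4: float | None = None
    expert_call: str | None = None
    figo_stage: str | None = None

    @property
    def truth_malignant(self) -> bool:
        """Reference-standard label: borderline counts as malignant."""
        return self.histology in ("borderline", "malignant")


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ``patient_id``."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""
    read_log: list[str] = field(default_factory=list, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def subset(self, predicate: Callable[[PatientRecord], bool]) -> "Cohort":
        kept = [r for r in self.records if predicate(r)]
        return Cohort(records=kept, provenance=self.provenance)

    def by_id(self) -> dict[str, PatientRecord]:
        return {r.patient_id: r for r in self.records}


def validate_exam(exam: UltrasoundExam) -> list[str]:
    """Return invariant violations for an ultrasound exam (empty if valid)."""
    violations: list[str] = []
    if exam.colour_score not in (1, 2, 3, 4):
        violations.append(f"colour_score: must be in 1..4, got {exam.colour_score}")
    if exam.b_no_flow != (exam.colour_score == 1):
        violations.append("b_no_flow: must hold exactly when colour_score == 1")
    if exam.m_strong_flow != (exam.colour_score == 4):
        violations.append("m_strong_flow: must hold exactly when colour_score == 4")
    if exam.b_no_flow and exam.m_strong_flow:
        violations.append("b_no_flow/m_strong_flow: flow flags are mutually exclusive")
    if exam.m_ascites != exam.rmi_ascites:
        violations.append("m_ascites/rmi_ascites: ascites flags must agree")
    return violations


def validate_record(record: PatientRecord) -> list[str]:
    """Return a list of named invariant violations (empty iff valid).

    Violations are data, not exceptions: callers decide whether to raise
    (strict read) or drop and log.
    """
    violations: list[str] = []
    if not record.patient_id:
        violations.append("patient_id: must be non-empty")
    if record.menopausal not in MENOPAUSAL_VALUES:
        violations.append(f"menopausal: must be one of {MENOPAUSAL_VALUES}")
    if not record.ca125 >= 0:
        violations.append(f"ca125: must be non-negative, got {record.ca125}")
    if record.he4 is not None and not record.he4 >= 0:
        violations.append(f"he4: must be non-negative when present, got {record.he4}")
    if record.histology not in HISTOLOGY_VALUES:
        violations.append(f"histology: must be one of {HISTOLOGY_VALUES}")
    if record.site not in SITE_VALUES:
        violations.append(f"site: must be one of {SITE_VALUES}")
    if record.expert_call is not None and record.expert_call not in EXPERT_VALUES:
        violations.append(f"expert_call: must be one of {EXPERT_VALUES} or absent")
    if record.figo_stage is not None:
        if record.figo_stage not in FIGO_VALUES:
            violations.append(f"figo_stage: must be one of {FIGO_VALUES} or absent")
        if record.histology == "benign":
            violations.append("figo_stage: present only for borderline/malignant histology")
    violations.extend(validate_exam(record.exam))
    return violations


# ---------------------------------------------------------------------------
# CSV serialization

_FLAG_FIELDS = (*IOTA_B_FLAGS, *IOTA_M_FLAGS, *RMI_FLAGS)


def record_to_row(record: PatientRecord) -> dict:
    row: dict = {
        "patient_id": record.patient_id,
        "age": record.age,
        "menopausal": record.menopausal,
        "ca125": record.ca125,
        "he4": "" if record.he4 is None else record.he4,
        "colour_score": record.exam.colour_score,
        "expert_call": record.expert_call or "",
        "histology": record.histology,
        "ovarian": int(record.ovarian),
        "site": record.site,
        "figo_stage": record.figo_stage or "",
    }
    for name in _FLAG_FIELDS:
        row[name] = int(getattr(record.exam, name))
    return row


def _parse_flag(value: str, column: str) -> bool:
    if value not in ("0", "1"):
        raise CohortFormatError(f"column {column}: flag must be 0 or 1, got {value!r}")
    return value == "1"


def row_to_record(row: dict) -> PatientRecord:
    exam = UltrasoundExam(
        colour_score=int(row["colour_score"]),
        **{name: _parse_flag(row[name], name) for name in _FLAG_FIELDS},
    )
    return PatientRecord(
        patient_id=row["patient_id"],
        age=float(row["age"]),
        menopausal=row["menopausal"],
        ca125=float(row["ca125"]),
        he4=float(row["he4"]) if row["he4"] != "" else None,
        exam=exam,
        expert_call=row["expert_call"] if row["expert_call"] != "" else None,
        histology=row["histology"],
        ovarian=_parse_flag(row["ovarian"], "ovarian"),
        site=row["site"],
        figo_stage=row["figo_stage"] if row["figo_stage"] != "" else None,
    )


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [record_to_row(r) for r in cohort.records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    In strict mode any record failing :func:`validate_record` (or a
    duplicate ``patient_id``) raises :class:`CohortValidationError`.  With
    ``strict=False`` invalid records are dropped; each drop is counted in
    the returned cohort's ``read_log``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory columns: {', '.join(missing)}")

    records: list[PatientRecord] = []
    log: list[str] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            record = row_to_record(row)
            violations = validate_record(record)
        except (ValueError, CohortFormatError) as exc:
            record, violations = None, [str(exc)]
        if record is not None and record.patient_id in seen:
            violations = violations + [f"patient_id: duplicate {record.patient_id!r}"]
        if violations:
            msg = f"row {i}: " + "; ".join(violations)
            if strict:
                raise CohortValidationError(msg)
            log.append(msg)
            continue
        assert record is not None
        seen.add(record.patient_id)
        records.append(record)
    return Cohort(records=records, provenance=str(path), read_log=log)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV readable by :func:`read_cohort` (lossless round-trip)."""
    cohort_to_frame(cohort).to_csv(Path(path), index=False)


def make_cohort(records: Sequence[PatientRecord], provenance: str = "") -> Cohort:
    """Build a cohort, enforcing patient_id uniqueness."""
    seen: set[str] = set()
    for r in records:
        if r.patient_id in seen:
            raise CohortValidationError(f"patient_id: duplicate {r.patient_id!r}")
        seen.add(r.patient_id)
    return Cohort(records=list(records), provenance=provenance)
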