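"""Domain types and file I/O for month-granular administrative claims.

The claims system studied here is monthly: every claim, enrollment event and
death is dated by calendar month only.  All timestamps therefore reduce to a
:class:`MonthStamp`, and survival-style quantities (blank periods, zombie
gaps, observation length) are whole-month differences.

Two delimited text files define a cohort:

``claims.csv``
    ``patient_id, claim_month (YYYY-MM), setting (inpatient|outpatient),
    status (death|cure|termination|others), icd10_codes (semicolon-separated),
    drug_codes (semicolon-separated, optional)``

``enrollment.csv``
    ``patient_id, sex (M|F), birth_year, beneficiary_type (employee|family),
    enroll_month, disenroll_month (blank = still enrolled),
    disenroll_reason (death|other|blank), death_month (blank = alive)``

Both are UTF-8 with a header row; blank fields mean missing.  The enrollment
file carries the insurer's own record of death and is treated throughout the
package as the gold standard against which claims-based calls are judged.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MonthStamp",
    "Setting",
    "ClaimStatus",
    "Sex",
    "BeneficiaryType",
    "DisenrollReason",
    "Claim",
    "EnrollmentRecord",
    "PatientHistory",
    "SchemaError",
    "CohortValidationError",
    "observation_end",
    "read_cohort",
    "build_cohort",
    "write_cohort",
]


@functools.total_ordering
@dataclass(frozen=True)
class MonthStamp:
    """A calendar month, the finest time unit in the claims system.

    Totally ordered; subtraction yields a difference in whole months.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")

    @property
    def index(self) -> int:
        return self.year * 12 + (self.month - 1)

    def __lt__(self, other: "MonthStamp") -> bool:
        return self.index < other.index

    def __sub__(self, other: "MonthStamp") -> int:
        """Difference in whole months."""
        return self.index - other.index

    def add(self, months: int) -> "MonthStamp":
        i = self.index + months
        return MonthStamp(i // 12, i % 12 + 1)

    @classmethod
    def parse(cls, text: str) -> "MonthStamp":
        """Parse ``YYYY-MM`` (also accepts ``YYYY/MM``); a trailing day part
        (``YYYY-MM-DD``) is truncated to the month with a logged note."""
        raw = text.strip().replace("/", "-")
        parts = raw.split("-")
        if len(parts) == 3:
            logger.info("day-level date %r truncated to month", text)
            parts = parts[:2]
        if len(parts) != 2:
            raise ValueError(f"cannot parse month stamp {text!r}")
        return cls(int(parts[0]), int(parts[1]))

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


class Setting(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class ClaimStatus(str, Enum):
    """Discharge status (inpatient) or disease status (outpatient).

    Only ``death`` refers to the disease outcome; the other three describe
    the state of care provision (cured/improved, care stopped for now,
    therapy continuing on next month's claim).
    """

    DEATH = "death"
    CURE = "cure"
    TERMINATION = "termination"
    OTHERS = "others"


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


class BeneficiaryType(str, Enum):
    EMPLOYEE = "employee"
    FAMILY = "family"


class DisenrollReason(str, Enum):
    DEATH = "death"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Claim:
    """One monthly claim. ``icd10_codes`` may be empty; duplicates of
    (patient, month, setting) are legal and kept distinct."""

    patient_id: str
    claim_month: MonthStamp
    setting: Setting
    status: ClaimStatus
    icd10_codes: tuple[str, ...] = ()
    drug_codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnrollmentRecord:
    patient_id: str
    sex: Sex
    birth_year: int
    beneficiary_type: BeneficiaryType
    enroll_month: MonthStamp
    disenroll_month: Optional[MonthStamp] = None
    disenroll_reason: Optional[DisenrollReason] = None
    death_month: Optional[MonthStamp] = None

    def __post_init__(self) -> None:
        if self.disenroll_month is not None and self.enroll_month > self.disenroll_month:
            raise ValueError(
                f"{self.patient_id}: enroll_month {self.enroll_month} after "
                f"disenroll_month {self.disenroll_month}"
            )


@dataclass
class PatientHistory:
    """Enrollment record plus that patient's claims, sorted by month.

    ``observation_end`` is the earlier of the disenrollment month and the
    administrative study end; ``gold_dead`` is true iff the enrollment file
    records a death month.  Claims dated after ``observation_end`` are
    rejected at load time.
    """

    enrollment: EnrollmentRecord
    claims: list[Claim]
    observation_end: MonthStamp
    study_end: MonthStamp
    gold_dead: bool = field(init=False)

    def __post_init__(self) -> None:
        self.claims = sorted(self.claims, key=lambda c: c.claim_month.index)
        self.gold_dead = self.enrollment.death_month is not None

    @property
    def patient_id(self) -> str:
        return self.enrollment.patient_id

    @property
    def observation_months(self) -> int:
        """Enrolled months through observation end, inclusive of both ends."""
        return self.observation_end - self.enrollment.enroll_month + 1


class SchemaError(ValueError):
    """A required column is missing or a file does not match the schema."""


class CohortValidationError(ValueError):
    """A row has an out-of-vocabulary or inconsistent value."""


def observation_end(record: EnrollmentRecord, study_end: MonthStamp) -> MonthStamp:
    """End of a patient's observation: disenrollment month or the study end,
    whichever comes first; the study end when the patient never disenrolled."""
    if record.disenroll_month is None:
        return study_end
    return min(record.disenroll_month, study_end, key=lambda m: m.index)


_CLAIM_COLUMNS = ["patient_id", "claim_month", "setting", "status", "icd10_codes"]
_ENROLL_COLUMNS = [
    "patient_id",
    "sex",
    "birth_year",
    "beneficiary_type",
    "enroll_month",
    "disenroll_month",
    "disenroll_reason",
    "death_month",
]


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _split_codes(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(c.strip() for c in str(cell).split(";") if c.strip())


def _parse_enum(cls, value: str, row: int, column: str, path: str):
    try:
        return cls(value)
    except ValueError:
        raise CohortValidationError(
            f"{path} row {row}: unknown {column} value {value!r} "
            f"(allowed: {[m.value for m in cls]})"
        ) from None


def read_claims(claims_path: str) -> list[Claim]:
    """Read the claims file; rows are validated against the closed status and
    setting vocabularies, and errors name the offending row (1-based data
    row, i.e. line number minus the header)."""
    df = pd.read_csv(claims_path, dtype=str, keep_default_na=False)
    _require_columns(df, _CLAIM_COLUMNS, claims_path)
    claims: list[Claim] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            month = MonthStamp.parse(rec.claim_month)
        except ValueError as exc:
            raise CohortValidationError(f"{claims_path} row {i}: {exc}") from None
        claims.append(
            Claim(
                patient_id=str(rec.patient_id),
                claim_month=month,
                setting=_parse_enum(Setting, rec.setting, i, "setting", claims_path),
                status=_parse_enum(ClaimStatus, rec.status, i, "status", claims_path),
                icd10_codes=_split_codes(rec.icd10_codes),
                drug_codes=_split_codes(getattr(rec, "drug_codes", "")),
            )
        )
    return claims


def read_enrollment(enrollment_path: str) -> list[EnrollmentRecord]:
    df = pd.read_csv(enrollment_path, dtype=str, keep_default_na=False)
    _require_columns(df, _ENROLL_COLUMNS, enrollment_path)
    records: list[EnrollmentRecord] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                EnrollmentRecord(
                    patient_id=str(rec.patient_id),
                    sex=_parse_enum(Sex, rec.sex, i, "sex", enrollment_path),
                    birth_year=int(rec.birth_year),
                    beneficiary_type=_parse_enum(
                        BeneficiaryType, rec.beneficiary_type, i, "beneficiary_type", enrollment_path
                    ),
                    enroll_month=MonthStamp.parse(rec.enroll_month),
                    disenroll_month=(
                        MonthStamp.parse(rec.disenroll_month) if rec.disenroll_month else None
                    ),
                    disenroll_reason=(
                        _parse_enum(DisenrollReason, rec.disenroll_reason, i, "disenroll_reason", enrollment_path)
                        if rec.disenroll_reason
                        else None
                    ),
                    death_month=MonthStamp.parse(rec.death_month) if rec.death_month else None,
                )
            )
        except CohortValidationError:
            raise
        except ValueError as exc:
            raise CohortValidationError(f"{enrollment_path} row {i}: {exc}") from None
    return records


def build_cohort(
    enrollment: Iterable[EnrollmentRecord],
    claims: Iterable[Claim],
    study_end: MonthStamp,
) -> list[PatientHistory]:
    """Assemble one :class:`PatientHistory` per enrollment record.

    Patients with no claims are retained — they can never be
    definition-positive but belong in the specificity denominator.  Claims
    dated after the administrative study end, and claims for patients absent
    from the enrollment file, are dropped with a warning.  Claims issued
    between disenrollment and the study end are kept: reimbursement lag
    routinely produces claims after a decedent's disenrollment month, and
    those trailing ("zombie") claims are exactly what the definitions
    examine.
    """
    by_patient: dict[str, list[Claim]] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)

    histories: list[PatientHistory] = []
    seen: set[str] = set()
    n_late = 0
    for rec in enrollment:
        if rec.patient_id in seen:
            raise CohortValidationError(f"duplicate enrollment record for {rec.patient_id}")
        seen.add(rec.patient_id)
        end = observation_end(rec, study_end)
        own = by_patient.pop(rec.patient_id, [])
        kept = [c for c in own if c.claim_month <= study_end]
        n_late += len(own) - len(kept)
        histories.append(PatientHistory(rec, kept, end, study_end))
    if n_late:
        logger.warning("dropped %d claim(s) dated after the study end", n_late)
    if by_patient:
        logger.warning(
            "dropped claims for %d patient id(s) absent from enrollment: %s",
            len(by_patient),
            sorted(by_patient)[:5],
        )
    return histories


def read_cohort(
    claims_path: str, enrollment_path: str, study_end: MonthStamp
) -> list[PatientHistory]:
    """Load a cohort from the two CSV files (see module docstring schema)."""
    return build_cohort(read_enrollment(enrollment_path), read_claims(claims_path), study_end)


def claims_frame(claims: Iterable[Claim]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "claim_month": str(c.claim_month),
            "setting": c.setting.value,
            "status": c.status.value,
            "icd10_codes": ";".join(c.icd10_codes),
            "drug_codes": ";".join(c.drug_codes),
        }
        for c in claims
    ]
    return pd.DataFrame(rows, columns=_CLAIM_COLUMNS + ["drug_codes"])


def enrollment_frame(records: Iterable[EnrollmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "sex": r.sex.value,
            "birth_year": r.birth_year,
            "beneficiary_type": r.beneficiary_type.value,
            "enroll_month": str(r.enroll_month),
            "disenroll_month": str(r.disenroll_month) if r.disenroll_month else "",
            "disenroll_reason": r.disenroll_reason.value if r.disenroll_reason else "",
            "death_month": str(r.death_month) if r.death_month else "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_ENROLL_COLUMNS)


def write_cohort(
    histories: Iterable[PatientHistory], claims_path: str, enrollment_path: str
) -> None:
    """Write a cohort back to the two-file CSV schema (round-trips with
    :func:`read_cohort`)."""
    histories = list(histories)
    claims_frame(c for h in histories for c in h.claims).to_csv(claims_path, index=False)
    enrollment_frame(h.enrollment for h in histories).to_csv(enrollment_path, index=False)
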