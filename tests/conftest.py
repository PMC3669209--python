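"""Shared test utilities: a brute-force ascertainment oracle and a random
patient-history generator.

The oracle re-states the nine definition rules directly from their textual
form, independently of the package's implementation, so that equivalence
tests genuinely exercise two routes.  Charlson scoring itself is shared
(its correctness is pinned by golden hand-scored tests).
"""

from __future__ import annotations

import numpy as np
import pytest

from deathproxy.cci import cci_score
from deathproxy.data_model import (
    BeneficiaryType,
    Claim,
    ClaimStatus,
    DisenrollReason,
    EnrollmentRecord,
    MonthStamp,
    PatientHistory,
    Setting,
    Sex,
    build_cohort,
)

STUDY_START = MonthStamp(2005, 1)
STUDY_END = MonthStamp(2009, 8)

# code pool spanning unmapped, low-weight and >=6-weight diagnoses
CODE_POOL = [
    "J06.9", "I10", "Z00.0",          # unmapped
    "I21.9", "K25.0", "E11.9",        # weight 1
    "E11.2", "C50.9", "N18.5",        # weight 2
    "K72.9",                          # weight 3
    "C78.7", "B20",                   # weight 6
]


def oracle_positive(history: PatientHistory) -> dict[str, bool]:
    """Literal restatement of the nine rules, evaluated by exhaustive scan."""
    claims = history.claims
    study_end = history.study_end

    death_months = [c.claim_month for c in claims if c.status is ClaimStatus.DEATH]
    if death_months:
        index_month = min(death_months, key=lambda m: m.index)
        zombie_gaps = [
            c.claim_month - index_month
            for c in claims
            if c.status is not ClaimStatus.DEATH and c.claim_month - index_month >= 1
        ]
        d11 = True
        d12 = not zombie_gaps
        d13 = all(g <= 2 for g in zombie_gaps)
    else:
        d11 = d12 = d13 = False

    inpatient = [c for c in claims if c.setting is Setting.INPATIENT]
    if inpatient:
        last_inp = max((c.claim_month for c in inpatient), key=lambda m: m.index)
        pooled = [
            code for c in inpatient if c.claim_month == last_inp for code in c.icd10_codes
        ]
        d21 = cci_score(pooled) >= 6
    else:
        last_inp = None
        d21 = False

    if claims:
        last_any = max((c.claim_month for c in claims), key=lambda m: m.index)
    else:
        last_any = history.enrollment.enroll_month
    d22 = d21 and (study_end - last_any) >= 6
    d23 = d22 and any(
        1 <= (last_inp - c.claim_month) <= 12 and cci_score(c.icd10_codes) >= 6
        for c in claims
    )
    return {
        "1.1": d11, "1.2": d12, "1.3": d13,
        "2.1": d21, "2.2": d22, "2.3": d23,
        "3.1": d13 or d21, "3.2": d13 or d22, "3.3": d13 or d23,
    }


def random_history(pid: str, rng: np.random.Generator) -> PatientHistory:
    """A random patient history exercising every rule component: random
    statuses (death included), settings, months, code mixes, disenrollment."""
    horizon = STUDY_END - STUDY_START
    enroll = STUDY_START.add(int(rng.integers(0, horizon)))
    n_claims = int(rng.integers(0, 9))
    claims = []
    for _ in range(n_claims):
        month = enroll.add(int(rng.integers(0, STUDY_END - enroll + 1)))
        status = ClaimStatus.DEATH if rng.random() < 0.15 else ClaimStatus(
            str(rng.choice(["cure", "termination", "others"]))
        )
        setting = Setting.INPATIENT if rng.random() < 0.4 else Setting.OUTPATIENT
        codes = tuple(
            str(rng.choice(CODE_POOL)) for _ in range(int(rng.integers(0, 4)))
        )
        claims.append(Claim(pid, month, setting, status, codes))
    dead = rng.random() < 0.3
    death_month = enroll.add(int(rng.integers(0, STUDY_END - enroll + 1))) if dead else None
    record = EnrollmentRecord(
        patient_id=pid,
        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        birth_year=int(rng.integers(1931, 1986)),
        beneficiary_type=BeneficiaryType.EMPLOYEE if rng.random() < 0.6 else BeneficiaryType.FAMILY,
        enroll_month=enroll,
        disenroll_month=death_month,
        disenroll_reason=DisenrollReason.DEATH if dead else None,
        death_month=death_month,
    )
    return build_cohort([record], claims, STUDY_END)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort(rng):
    return [random_history(f"R{i:05d}", rng) for i in range(300)]
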