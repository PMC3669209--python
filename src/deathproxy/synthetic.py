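"""Seeded generator of synthetic claims + enrollment cohorts with truth labels.

The generator emulates the statistical structure that claims-based death
ascertainment exploits in a monthly private-insurance claims system:

* claim issuance as a monthly Bernoulli process with patient-specific
  outpatient intensity and a small flat inpatient intensity;
* death recording — a true death yields a final death-status claim with
  probability ``p_status_recorded`` (the target sensitivity of the direct
  definition); unrecorded deaths simply stop claiming;
* short-term "zombie" claims: reimbursement lag places 1–2 non-death claims
  in the one or two months after a recorded death;
* long-term "zombie" false positives: a rare living patient carries a
  miscoded death-status claim and keeps claiming 3+ months later;
* severity concentration: a configurable fraction of decedents end with a
  high-Charlson (metastatic cancer) inpatient admission, a subset of whom
  also carry equally severe claims through their final year; living
  patients have a tiny rate of equally severe admissions;
* disenrollment, including the occasional death recorded only as a
  reasonless disenrollment (death month absent from the enrollment file,
  making the patient a gold-standard false positive).

Every mechanism is written to a truth table so each generated patient's
expected classification can be audited from the claims alone.

Defaults are calibrated to the validation study conditions: 0.35% of
patients die over follow-up, 58.1% of deaths are recorded on a claim,
2.3% of recorded deaths trail short zombies, ~2 per 100,000 living
patients carry a long-zombie miscode, 3.4% of recorded deaths appear only
as reasonless disenrollment, 31.6% of decedents have a severe terminal
admission and 72% of those had severe claims in the preceding year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BeneficiaryType,
    Claim,
    ClaimStatus,
    DisenrollReason,
    EnrollmentRecord,
    MonthStamp,
    PatientHistory,
    Sex,
    Setting,
    build_cohort,
    claims_frame,
    enrollment_frame,
)

__all__ = [
    "SimConfig",
    "generate_cohort",
    "generate_histories",
    "summarize_cohort",
    "audit_truth",
    "mechanism_benchmark_cohort",
]

# Benign diagnosis pool: none of these map to any Charlson category.
_BENIGN_CODES = ("J06.9", "M54.5", "K29.7", "I10", "E78.5", "L30.9", "H10.9")
# Non-metastatic cancer: Charlson weight 2, below the severity threshold.
_CANCER_CODES = ("C50.9", "C16.9", "C61")
# Metastatic disease + primary: scores 6 after hierarchy suppression.
_SEVERE_CODES = ("C18.9", "C78.7")
_SEVERE_EXTRA = "E11.2"  # diabetes with complications, lifts the score to 8
_DRUG_BENIGN = ("NSAID01", "PPI02")
_DRUG_ANTICANCER = "ANTICAN01"


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_patients: int = 20_000
    study_start: MonthStamp = MonthStamp(2005, 1)
    study_end: MonthStamp = MonthStamp(2009, 8)
    # demography
    p_male: float = 0.599
    age_band_probs: tuple[float, float, float] = (0.577, 0.312, 0.111)
    age_bands: tuple[tuple[int, int], ...] = ((20, 39), (40, 59), (60, 74))
    p_employee: float = 0.657
    # enrollment dynamics
    p_enroll_at_start: float = 0.29
    monthly_disenroll_rate: float = 0.002
    # claim process
    mean_monthly_outpatient_rate: float = 0.17
    monthly_inpatient_rate: float = 0.003
    # death + recording mechanisms
    p_death: float = 680 / 195_193
    p_status_recorded: float = 395 / 680
    p_short_zombie: float = 9 / 395
    p_long_zombie_false_positive: float = 4 / 194_513
    p_disenroll_no_reason: float = 14 / 409
    # severity mechanisms
    p_severe_terminal: float = 215 / 680
    p_prolonged_severe: float = 155 / 215
    p_severe_admission_alive: float = 4e-4
    p_cancer_alive: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "p_male", "p_employee", "p_enroll_at_start", "p_death",
            "p_status_recorded", "p_short_zombie", "p_long_zombie_false_positive",
            "p_disenroll_no_reason", "p_severe_terminal", "p_prolonged_severe",
            "p_severe_admission_alive", "p_cancer_alive",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.mean_monthly_outpatient_rate < 0 or self.monthly_inpatient_rate < 0:
            raise ValueError("claim intensities must be non-negative")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not abs(sum(self.age_band_probs) - 1.0) < 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        if self.study_start > self.study_end:
            raise ValueError("study_start must not follow study_end")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _truth_row(pid: str) -> dict:
    return {
        "patient_id": pid,
        "truly_dead": False,
        "death_month": "",
        "status_recorded": False,
        "short_zombie": False,
        "long_zombie_miscode": False,
        "reasonless_disenroll": False,
        "severe_terminal": False,
        "prolonged_severe": False,
        "cancer": False,
    }


def _simulate_patient(
    pid: str, config: SimConfig, rng: np.random.Generator
) -> tuple[EnrollmentRecord, list[Claim], dict]:
    start, end = config.study_start, config.study_end
    horizon = end - start  # months, window spans horizon+1 months

    sex = Sex.MALE if rng.random() < config.p_male else Sex.FEMALE
    band = config.age_bands[rng.choice(len(config.age_bands), p=config.age_band_probs)]
    age = int(rng.integers(band[0], band[1] + 1))  # age at cohort entry
    beneficiary = (
        BeneficiaryType.EMPLOYEE if rng.random() < config.p_employee else BeneficiaryType.FAMILY
    )

    if rng.random() < config.p_enroll_at_start:
        enroll = start
    else:
        enroll = start.add(int(rng.integers(0, horizon + 1)))
    birth_year = enroll.year - age
    enrolled_months = end - enroll + 1

    truth = _truth_row(pid)
    truly_dead = rng.random() < config.p_death
    death_month: Optional[MonthStamp] = None
    if truly_dead:
        death_month = enroll.add(int(rng.integers(0, enrolled_months)))
        truth["truly_dead"] = True
        truth["death_month"] = str(death_month)

    # non-death disenrollment (living patients only)
    disenroll: Optional[MonthStamp] = None
    reason: Optional[DisenrollReason] = None
    if not truly_dead and config.monthly_disenroll_rate > 0:
        t = rng.geometric(config.monthly_disenroll_rate)
        if t <= enrolled_months - 1:
            disenroll = enroll.add(int(t))
            reason = DisenrollReason.OTHER

    last_claim_month = death_month or disenroll or end
    active_months = last_claim_month - enroll + 1

    cancer = (not truly_dead) and rng.random() < config.p_cancer_alive
    lam = rng.exponential(config.mean_monthly_outpatient_rate)
    p_out = 1.0 - np.exp(-lam)
    draws_out = rng.random(active_months) < p_out
    draws_in = rng.random(active_months) < config.monthly_inpatient_rate

    claims: list[Claim] = []

    def benign_codes() -> tuple[str, ...]:
        codes = (str(rng.choice(_BENIGN_CODES)),)
        if cancer:
            codes = codes + (str(rng.choice(_CANCER_CODES)),)
        return codes

    for off in range(active_months):
        month = enroll.add(off)
        if draws_out[off]:
            claims.append(
                Claim(pid, month, Setting.OUTPATIENT, ClaimStatus.OTHERS, benign_codes(),
                      (str(rng.choice(_DRUG_BENIGN)),))
            )
        if draws_in[off]:
            claims.append(
                Claim(pid, month, Setting.INPATIENT, ClaimStatus.OTHERS, benign_codes(), ())
            )

    if truly_dead:
        severe = rng.random() < config.p_severe_terminal
        recorded = rng.random() < config.p_status_recorded
        truth["severe_terminal"] = severe
        truth["status_recorded"] = recorded
        if severe:
            truth["cancer"] = True
            codes = _SEVERE_CODES + ((_SEVERE_EXTRA,) if rng.random() < 0.3 else ())
            status = ClaimStatus.DEATH if recorded else ClaimStatus.OTHERS
            claims.append(
                Claim(pid, death_month, Setting.INPATIENT, status, codes, (_DRUG_ANTICANCER,))
            )
            if rng.random() < config.p_prolonged_severe:
                truth["prolonged_severe"] = True
                n_prior = int(rng.integers(1, 4))
                for _ in range(n_prior):
                    back = int(rng.integers(1, 13))
                    if death_month - enroll >= back:
                        claims.append(
                            Claim(pid, death_month.add(-back), Setting.OUTPATIENT,
                                  ClaimStatus.OTHERS, _SEVERE_CODES, (_DRUG_ANTICANCER,))
                        )
        elif recorded:
            claims.append(
                Claim(pid, death_month, Setting.OUTPATIENT, ClaimStatus.DEATH,
                      (str(rng.choice(_BENIGN_CODES)),), ())
            )
        if recorded and rng.random() < config.p_short_zombie:
            lag = int(rng.integers(1, 3))  # 1 or 2 months after the index claim
            zmonth = death_month.add(lag)
            if zmonth <= end:
                truth["short_zombie"] = True
                claims.append(
                    Claim(pid, zmonth, Setting.OUTPATIENT, ClaimStatus.OTHERS,
                          (str(rng.choice(_BENIGN_CODES)),), ())
                )
        reasonless = recorded and rng.random() < config.p_disenroll_no_reason
        truth["reasonless_disenroll"] = reasonless
        disenroll = death_month
        if reasonless:
            reason = None
            death_month = None
        else:
            reason = DisenrollReason.DEATH
    else:
        obs_end = disenroll or end
        if rng.random() < config.p_severe_admission_alive:
            month = enroll.add(int(rng.integers(0, obs_end - enroll + 1)))
            claims.append(
                Claim(pid, month, Setting.INPATIENT, ClaimStatus.OTHERS, _SEVERE_CODES,
                      (_DRUG_ANTICANCER,))
            )
            truth["cancer"] = True
        if rng.random() < config.p_long_zombie_false_positive and obs_end - enroll >= 4:
            m_off = int(rng.integers(0, obs_end - enroll - 3))
            miscode_month = enroll.add(m_off)
            truth["long_zombie_miscode"] = True
            claims.append(
                Claim(pid, miscode_month, Setting.OUTPATIENT, ClaimStatus.DEATH,
                      (str(rng.choice(_BENIGN_CODES)),), ())
            )
            gap = int(rng.integers(3, min(7, obs_end - miscode_month) + 1))
            claims.append(
                Claim(pid, miscode_month.add(gap), Setting.OUTPATIENT, ClaimStatus.OTHERS,
                      (str(rng.choice(_BENIGN_CODES)),), ())
            )
    # flag reflects codes actually issued: a cancer-prone patient who never
    # claimed carries no cancer code
    truth["cancer"] = any(
        code.upper().startswith("C") for c in claims for code in c.icd10_codes
    )

    record = EnrollmentRecord(
        patient_id=pid,
        sex=sex,
        birth_year=birth_year,
        beneficiary_type=beneficiary,
        enroll_month=enroll,
        disenroll_month=disenroll,
        disenroll_reason=reason,
        death_month=death_month,
    )
    claims.sort(key=lambda c: c.claim_month.index)
    return record, claims, truth


def generate_histories(
    config: SimConfig = SimConfig(), seed: int = 0
) -> tuple[list[PatientHistory], pd.DataFrame]:
    """Generate a cohort as assembled patient histories plus the truth table."""
    rng = np.random.default_rng(seed)
    records, claims, truths = [], [], []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        rec, cl, tr = _simulate_patient(pid, config, rng)
        records.append(rec)
        claims.extend(cl)
        truths.append(tr)
    histories = build_cohort(records, claims, config.study_end)
    return histories, pd.DataFrame(truths)


def generate_cohort(
    config: SimConfig = SimConfig(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (claims, enrollment, truth) data frames in the CSV schema.

    Reproducible: identical config and seed give identical frames.
    """
    histories, truth = generate_histories(config, seed)
    claims_df = claims_frame(c for h in histories for c in h.claims)
    enrollment_df = enrollment_frame(h.enrollment for h in histories)
    return claims_df, enrollment_df, truth


def summarize_cohort(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    study_end: MonthStamp = SimConfig.study_end,
) -> pd.DataFrame:
    """Descriptive summary: sex and age-band percentages (age at study
    start), beneficiary mix, mean observation months, % with ≥1 claim."""
    if len(enrollment) == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = len(enrollment)
    enroll = enrollment["enroll_month"].map(MonthStamp.parse)
    disenroll = enrollment["disenroll_month"].map(
        lambda s: MonthStamp.parse(s) if s else None
    )
    obs_end = [
        min(d, study_end, key=lambda m: m.index) if d else study_end for d in disenroll
    ]
    obs_months = [e - s + 1 for s, e in zip(enroll, obs_end)]
    # age at cohort entry, the reference for the 20-74 eligibility range
    age = np.array(
        [m.year - by for m, by in zip(enroll, enrollment["birth_year"].astype(int))]
    )
    has_claim = enrollment["patient_id"].isin(set(claims["patient_id"]))
    rows = [
        ("n_patients", float(n)),
        ("male_pct", 100.0 * (enrollment["sex"] == "M").mean()),
        ("age_20_39_pct", 100.0 * ((age >= 20) & (age <= 39)).mean()),
        ("age_40_59_pct", 100.0 * ((age >= 40) & (age <= 59)).mean()),
        ("age_60_74_pct", 100.0 * ((age >= 60) & (age <= 74)).mean()),
        ("mean_age", float(age.mean())),
        ("employee_pct", 100.0 * (enrollment["beneficiary_type"] == "employee").mean()),
        ("family_pct", 100.0 * (enrollment["beneficiary_type"] == "family").mean()),
        ("mean_observation_months", float(np.mean(obs_months))),
        ("any_claim_pct", 100.0 * has_claim.mean()),
        ("gold_deaths", float((enrollment["death_month"] != "").sum())),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def audit_truth(histories: Sequence[PatientHistory], truth: pd.DataFrame) -> pd.DataFrame:
    """Verify every truth-table mechanism flag against the generated claims.

    Returns rows that fail (empty frame = fully consistent).
    """
    by_id = {h.patient_id: h for h in histories}
    failures = []
    for row in truth.itertuples(index=False):
        h = by_id[row.patient_id]
        death_claims = [c for c in h.claims if c.status is ClaimStatus.DEATH]
        problems = []
        if row.status_recorded and not death_claims:
            problems.append("status_recorded but no death-status claim")
        if not (row.status_recorded or row.long_zombie_miscode) and death_claims:
            problems.append("unexpected death-status claim")
        if row.truly_dead:
            gold = h.enrollment.death_month is not None
            if gold == bool(row.reasonless_disenroll):
                problems.append("gold death month inconsistent with reasonless flag")
        if row.short_zombie:
            index = death_claims[0]
            gaps = [
                c.claim_month - index.claim_month
                for c in h.claims
                if c.status is not ClaimStatus.DEATH and c.claim_month > index.claim_month
            ]
            if not gaps or max(gaps) > 2:
                problems.append("short_zombie flag without a 1-2 month trailing claim")
        if row.long_zombie_miscode:
            index = death_claims[0]
            if not any(
                c.status is not ClaimStatus.DEATH and c.claim_month - index.claim_month >= 3
                for c in h.claims
            ):
                problems.append("long_zombie_miscode without a >=3 month trailing claim")
        cancer_coded = any(
            code.upper().startswith("C") for c in h.claims for code in c.icd10_codes
        )
        if bool(row.cancer) != cancer_coded:
            problems.append("cancer flag inconsistent with C-prefix codes")
        if problems:
            failures.append({"patient_id": row.patient_id, "problems": "; ".join(problems)})
    return pd.DataFrame(failures, columns=["patient_id", "problems"])


def mechanism_benchmark_cohort(
    n_tp_plain: int = 386,
    n_tp_short_zombie: int = 9,
    n_fp_long_zombie: int = 4,
    n_fp_reasonless: int = 14,
    n_fn: int = 285,
    n_tn: int = 194_495,
    study_end: MonthStamp = MonthStamp(2009, 8),
) -> list[PatientHistory]:
    """Deterministic micro-cohort encoding the ascertainment mechanisms.

    Synthetic stand-in for the proprietary validation cohort: each argument
    sets how many patients follow one mechanism — recorded deaths with no
    trailing claims, recorded deaths trailed by short-term zombies, living
    patients with a miscoded death claim and long-term zombies, recorded
    deaths whose disenrollment lacks a death reason (gold-standard false
    positives), unrecorded deaths, and plain survivors.  Defaults reproduce
    the published cross-classification of the direct definition against the
    enrollment gold standard.  All diagnoses are benign, so the severity
    definitions stay silent.
    """
    start = MonthStamp(2005, 1)
    dm = MonthStamp(2007, 6)  # death / index month used throughout
    records: list[EnrollmentRecord] = []
    claims: list[Claim] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"M{counter:06d}"

    def enroll(pid, disenroll=None, reason=None, death=None):
        records.append(
            EnrollmentRecord(pid, Sex.MALE, 1960, BeneficiaryType.EMPLOYEE, start,
                             disenroll, reason, death)
        )

    benign = ("Z00.0",)
    for _ in range(n_tp_plain):
        pid = new_id()
        enroll(pid, disenroll=dm, reason=DisenrollReason.DEATH, death=dm)
        claims.append(Claim(pid, MonthStamp(2006, 1), Setting.OUTPATIENT, ClaimStatus.OTHERS, benign))
        claims.append(Claim(pid, dm, Setting.OUTPATIENT, ClaimStatus.DEATH, benign))
    for k in range(n_tp_short_zombie):
        pid = new_id()
        enroll(pid, disenroll=dm, reason=DisenrollReason.DEATH, death=dm)
        claims.append(Claim(pid, dm, Setting.OUTPATIENT, ClaimStatus.DEATH, benign))
        claims.append(Claim(pid, dm.add(1 + k % 2), Setting.OUTPATIENT, ClaimStatus.OTHERS, benign))
    for _ in range(n_fp_long_zombie):
        pid = new_id()
        enroll(pid)
        claims.append(Claim(pid, dm, Setting.OUTPATIENT, ClaimStatus.DEATH, benign))
        claims.append(Claim(pid, dm.add(3), Setting.OUTPATIENT, ClaimStatus.OTHERS, benign))
        claims.append(Claim(pid, dm.add(12), Setting.OUTPATIENT, ClaimStatus.OTHERS, benign))
    for _ in range(n_fp_reasonless):
        pid = new_id()
        enroll(pid, disenroll=dm, reason=None, death=None)
        claims.append(Claim(pid, dm, Setting.OUTPATIENT, ClaimStatus.DEATH, benign))
    for _ in range(n_fn):
        pid = new_id()
        enroll(pid, disenroll=dm, reason=DisenrollReason.DEATH, death=dm)
        claims.append(Claim(pid, MonthStamp(2006, 8), Setting.OUTPATIENT, ClaimStatus.OTHERS, benign))
    for _ in range(n_tn):
        pid = new_id()
        enroll(pid)
        claims.append(Claim(pid, MonthStamp(2006, 5), Setting.OUTPATIENT, ClaimStatus.OTHERS, benign))
    return build_cohort(records, claims, study_end)
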