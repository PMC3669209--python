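"""Validation of claims-based death calls against the enrollment gold standard.

Agreement is at patient level: a definition-positive patient counts as a
true positive when the enrollment file records any death month, without
matching the called month to the recorded month.  Patients whose
disenrollment month coincides with the index claim but whose disenrollment
reason is not death count as false positives under this conservative rule;
``reclassify_ambiguous_disenrollment=True`` flips such patients to gold-dead
before cross-classification, for sensitivity-underestimation analyses.

Point estimates are sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and
PPV = TP/(TP+FP), reported as percentages.  Confidence intervals use the
exact (Clopper–Pearson) binomial method by default; Wilson score intervals
are available behind a flag.  Display rounding is half-up to one decimal
(two for specificity, which lives within rounding distance of 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .data_model import MonthStamp, PatientHistory, Setting
from .definitions import DeathCall, find_index_claim

__all__ = [
    "ConfusionTable",
    "ValidityMetrics",
    "SubgroupSpec",
    "confusion",
    "validity_metrics",
    "clopper_pearson",
    "wilson",
    "standardized_difference",
    "subgroup_validate",
    "round_half_up",
    "standard_subgroups",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching conventional table display
    (Python's built-in round is banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """Patient-level 2×2 cross-classification of a definition against the
    enrollment gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n_gold_dead(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class ValidityMetrics:
    """Sensitivity/specificity/PPV (percent) with 95% CIs.

    A metric whose denominator is empty is None (flagged, never silently 0).
    """

    sensitivity_pct: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity_pct: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    ppv_pct: Optional[float]
    ppv_ci: Optional[tuple[float, float]]
    n_positive: int
    n_true_positive: int

    def rounded(self) -> dict[str, Optional[float]]:
        """Display values: one decimal, except specificity at two."""
        return {
            "sensitivity_pct": None if self.sensitivity_pct is None else round_half_up(self.sensitivity_pct, 1),
            "specificity_pct": None if self.specificity_pct is None else round_half_up(self.specificity_pct, 2),
            "ppv_pct": None if self.ppv_pct is None else round_half_up(self.ppv_pct, 1),
        }


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) interval for a proportion, as Beta
    quantiles; lo = 0 at k = 0 and hi = 1 at k = n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def wilson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (the non-exact alternative)."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def _is_ambiguous_disenrollment(history: PatientHistory) -> bool:
    """Claims-positive patient disenrolled in the index-claim month without
    a recorded death: possibly an unamended death in the enrollment file."""
    rec = history.enrollment
    if history.gold_dead or rec.disenroll_month is None:
        return False
    from .data_model import DisenrollReason

    if rec.disenroll_reason is DisenrollReason.DEATH:
        return False
    index = find_index_claim(history)
    return index is not None and index.claim_month == rec.disenroll_month


def confusion(
    calls: Iterable[DeathCall],
    cohort: Sequence[PatientHistory],
    reclassify_ambiguous_disenrollment: bool = False,
) -> ConfusionTable:
    """Cross-classify definition-positive patients against gold-standard
    death.  Dates are not matched.  A call for a patient absent from the
    cohort raises a consistency error."""
    ids = {h.patient_id for h in cohort}
    positive = set()
    for call in calls:
        if call.patient_id not in ids:
            raise ValueError(f"call for unknown patient {call.patient_id!r}")
        positive.add(call.patient_id)
    tp = fp = fn = tn = 0
    for h in cohort:
        dead = h.gold_dead or (
            reclassify_ambiguous_disenrollment and _is_ambiguous_disenrollment(h)
        )
        if h.patient_id in positive:
            if dead:
                tp += 1
            else:
                fp += 1
        else:
            if dead:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def validity_metrics(
    table: ConfusionTable,
    ci_level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> ValidityMetrics:
    """Sensitivity, specificity and PPV with binomial CIs from a 2×2 table."""
    interval = {"clopper-pearson": clopper_pearson, "wilson": wilson}[ci_method]

    def metric(k: int, n: int):
        if n == 0:
            return None, None
        lo, hi = interval(k, n, ci_level)
        return 100.0 * k / n, (100.0 * lo, 100.0 * hi)

    sens, sens_ci = metric(table.tp, table.tp + table.fn)
    spec, spec_ci = metric(table.tn, table.tn + table.fp)
    ppv, ppv_ci = metric(table.tp, table.tp + table.fp)
    return ValidityMetrics(
        sensitivity_pct=sens,
        sensitivity_ci=sens_ci,
        specificity_pct=spec,
        specificity_ci=spec_ci,
        ppv_pct=ppv,
        ppv_ci=ppv_ci,
        n_positive=table.n_positive,
        n_true_positive=table.tp,
    )


def standardized_difference(p1: float, p2: float) -> float:
    """Standardized difference between two proportions:
    |p1 − p2| / sqrt((p1(1−p1) + p2(1−p2)) / 2).

    Returns 0 when both proportions are degenerate and equal (the
    denominator would vanish).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    denom = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
    if denom == 0.0:
        return 0.0
    return abs(p1 - p2) / denom


@dataclass(frozen=True)
class SubgroupSpec:
    """A named, deterministic, total predicate over patient histories."""

    name: str
    predicate: Callable[[PatientHistory], bool]

    def members(self, cohort: Iterable[PatientHistory]) -> list[PatientHistory]:
        return [h for h in cohort if self.predicate(h)]


def subgroup_validate(
    cohort: Sequence[PatientHistory],
    calls: Iterable[DeathCall],
    specs: Sequence[SubgroupSpec],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Validity metrics within each subgroup, using the stratum's own
    denominators for all three metrics.  Empty strata and empty
    denominators yield NaN cells, never a division by zero."""
    calls = list(calls)
    rows = []
    for spec in specs:
        members = spec.members(cohort)
        ids = {h.patient_id for h in members}
        sub_calls = [c for c in calls if c.patient_id in ids]
        if not members:
            rows.append({"subgroup": spec.name, "n": 0})
            continue
        table = confusion(sub_calls, members)
        m = validity_metrics(table, ci_level)
        r = m.rounded()
        rows.append(
            {
                "subgroup": spec.name,
                "n": len(members),
                "n_gold_dead": table.n_gold_dead,
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
                "sensitivity_pct": r["sensitivity_pct"],
                "sensitivity_lo": None if m.sensitivity_ci is None else m.sensitivity_ci[0],
                "sensitivity_hi": None if m.sensitivity_ci is None else m.sensitivity_ci[1],
                "specificity_pct": r["specificity_pct"],
                "ppv_pct": r["ppv_pct"],
            }
        )
    return pd.DataFrame(rows)


def _entry_age(history: PatientHistory) -> int:
    """Age at cohort entry (enrollment year minus birth year) — the
    reference at which the cohort's 20-74 age range is defined, so the
    bands partition the cohort exactly."""
    return history.enrollment.enroll_month.year - history.enrollment.birth_year


def standard_subgroups(
    age_bands: Sequence[tuple[int, int]] = ((20, 39), (40, 59), (60, 74)),
    icd10_flags: dict[str, str] | None = None,
    drug_flags: dict[str, str] | None = None,
) -> list[SubgroupSpec]:
    """The stock stratification set: sex, age band at cohort entry,
    beneficiary type, any admission in the year before observation end,
    setting of the last claim, plus configurable ICD-10-prefix and
    drug-code flags."""
    from .data_model import BeneficiaryType, Sex

    specs: list[SubgroupSpec] = [
        SubgroupSpec("male", lambda h: h.enrollment.sex is Sex.MALE),
        SubgroupSpec("female", lambda h: h.enrollment.sex is Sex.FEMALE),
        SubgroupSpec("employee", lambda h: h.enrollment.beneficiary_type is BeneficiaryType.EMPLOYEE),
        SubgroupSpec("family_member", lambda h: h.enrollment.beneficiary_type is BeneficiaryType.FAMILY),
    ]
    for lo, hi in age_bands:
        specs.append(
            SubgroupSpec(
                f"age_{lo}_{hi}",
                lambda h, lo=lo, hi=hi: lo <= _entry_age(h) <= hi,
            )
        )
    specs.append(
        SubgroupSpec(
            "hospitalized_preceding_year",
            lambda h: any(
                c.setting is Setting.INPATIENT and 0 <= h.observation_end - c.claim_month <= 12
                for c in h.claims
            ),
        )
    )
    specs.append(
        SubgroupSpec(
            "last_claim_inpatient",
            lambda h: bool(h.claims) and h.claims[-1].setting is Setting.INPATIENT,
        )
    )
    specs.append(
        SubgroupSpec(
            "last_claim_outpatient",
            lambda h: bool(h.claims) and h.claims[-1].setting is Setting.OUTPATIENT,
        )
    )
    for name, prefix in (icd10_flags or {}).items():
        norm = prefix.replace(".", "").upper()
        specs.append(
            SubgroupSpec(
                name,
                lambda h, norm=norm: any(
                    code.replace(".", "").upper().startswith(norm)
                    for c in h.claims
                    for code in c.icd10_codes
                ),
            )
        )
    for name, code in (drug_flags or {}).items():
        specs.append(
            SubgroupSpec(
                name,
                lambda h, code=code: any(code in c.drug_codes for c in h.claims),
            )
        )
    return specs
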