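"""The nine claims-based definitions of death.

Monthly claims carry a discharge status (inpatient) or disease status
(outpatient) whose value ``death`` is the direct death signal.  The earliest
such claim is the *index claim*.  Claims without death status issued after
the index claim ("zombie" claims) undermine it: zombies within 1–2 months
are usually reimbursement lag for a real death, while zombies 3 or more
months later suggest the index claim was miscoded and the patient is alive.

A second, indirect signal is a terminal-looking admission: a last inpatient
claim whose Charlson comorbidity index is high (default ≥6), optionally
followed by a blank period (no claims of any kind through the study end,
default ≥6 months) and preceded by equally severe claims in the prior year.

The nine definitions compose these signals:

=====  ==========================================================
id     rule
=====  ==========================================================
1.1    a death-status claim exists
1.2    1.1 and no zombie claims at all
1.3    1.1 and no long-term (≥3 month) zombie claims
2.1    CCI of the last inpatient claim ≥ threshold
2.2    2.1 and blank period to study end ≥ minimum
2.3    2.2 and a CCI≥threshold claim in the preceding 12 months
3.k    1.3 or 2.k   (k = 1, 2, 3)
=====  ==========================================================

Positives nest: 1.2 ⊆ 1.3 ⊆ 1.1 and 2.3 ⊆ 2.2 ⊆ 2.1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .cci import CCIMap, cci_score, default_cci_map
from .data_model import Claim, ClaimStatus, MonthStamp, PatientHistory, Setting

logger = logging.getLogger(__name__)

__all__ = [
    "DEFINITION_IDS",
    "DefinitionParams",
    "DeathCall",
    "CallBasis",
    "ZombieStatus",
    "find_index_claim",
    "zombie_status",
    "last_inpatient_cci",
    "blank_months",
    "lookback_cci_met",
    "ascertain",
    "ascertain_cohort",
]

DEFINITION_IDS = ("1.1", "1.2", "1.3", "2.1", "2.2", "2.3", "3.1", "3.2", "3.3")


@dataclass(frozen=True)
class DefinitionParams:
    """Tunable thresholds, defaulting to the published rules."""

    zombie_short_max_months: int = 2
    cci_threshold: int = 6
    blank_min_months: int = 6
    lookback_months: int = 12

    def __post_init__(self) -> None:
        for name in ("zombie_short_max_months", "cci_threshold", "blank_min_months", "lookback_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


class CallBasis(str, Enum):
    STATUS_CLAIM = "status_claim"
    CCI_ADMISSION = "cci_admission"
    EITHER = "either"


class ZombieStatus(str, Enum):
    NONE = "none"
    SHORT_TERM = "short_term"  # all zombies within 1–2 months of the index claim
    LONG_TERM = "long_term"  # some zombie ≥3 months after the index claim


@dataclass(frozen=True)
class DeathCall:
    patient_id: str
    definition_id: str
    call_month: MonthStamp
    basis: CallBasis


def find_index_claim(history: PatientHistory) -> Optional[Claim]:
    """The earliest claim (either setting) with death status, or None.

    When several death-status claims exist the earliest is THE index claim;
    later ones are neither zombies nor new indices.
    """
    for claim in history.claims:  # claims are sorted by month
        if claim.status is ClaimStatus.DEATH:
            return claim
    return None


def zombie_status(
    history: PatientHistory, index: Claim, params: DefinitionParams = DefinitionParams()
) -> ZombieStatus:
    """Classify the patient's zombie claims relative to the index claim.

    Zombies are non-death-status claims dated strictly after the index
    month.  The classification uses the maximum month gap: none if there are
    no zombies, short-term if all fall within ``zombie_short_max_months``,
    long-term otherwise.
    """
    max_gap = 0
    for claim in history.claims:
        if claim.status is ClaimStatus.DEATH:
            continue
        gap = claim.claim_month - index.claim_month
        if gap > max_gap:
            max_gap = gap
    if max_gap == 0:
        return ZombieStatus.NONE
    if max_gap <= params.zombie_short_max_months:
        return ZombieStatus.SHORT_TERM
    return ZombieStatus.LONG_TERM


def last_inpatient_cci(
    history: PatientHistory, cci_map: Optional[CCIMap] = None
) -> Optional[tuple[MonthStamp, int]]:
    """Month of the latest inpatient claim and the CCI of that month's
    pooled inpatient diagnoses; None for outpatient-only histories.

    Monthly claims fragment a single admission, so all inpatient claims in
    the last inpatient month pool their ICD-10 codes before scoring.
    """
    inpatient = [c for c in history.claims if c.setting is Setting.INPATIENT]
    if not inpatient:
        return None
    last_month = inpatient[-1].claim_month
    codes = [
        code
        for c in inpatient
        if c.claim_month == last_month
        for code in c.icd10_codes
    ]
    return last_month, cci_score(codes, cci_map)


def blank_months(history: PatientHistory, study_end: Optional[MonthStamp] = None) -> int:
    """Whole months with no claim of any kind between the patient's last
    claim and the study end month (both exclusive of the last-claim month,
    inclusive of the study end month).

    Returns 0 when a claim falls in the study end month.  A claimless
    history counts from the enrollment month instead.
    """
    study_end = study_end or history.study_end
    if history.claims:
        anchor = history.claims[-1].claim_month
    else:
        anchor = history.enrollment.enroll_month
    return max(0, study_end - anchor)


def lookback_cci_met(
    history: PatientHistory,
    anchor: MonthStamp,
    cci_map: Optional[CCIMap] = None,
    params: DefinitionParams = DefinitionParams(),
) -> bool:
    """True iff some claim in the window [anchor − lookback, anchor − 1]
    (anchor month excluded, window start inclusive) scores CCI ≥ threshold
    on its own diagnosis codes.  Claims in either setting qualify."""
    cci_map = cci_map or default_cci_map()
    for claim in history.claims:
        gap = anchor - claim.claim_month
        if 1 <= gap <= params.lookback_months:
            if cci_score(claim.icd10_codes, cci_map) >= params.cci_threshold:
                return True
    return False


def _components(
    history: PatientHistory,
    params: DefinitionParams,
    cci_map: Optional[CCIMap],
) -> dict:
    """Evaluate the shared primitives once per patient."""
    index = find_index_claim(history)
    zs = zombie_status(history, index, params) if index is not None else None
    li = last_inpatient_cci(history, cci_map)
    out = {
        "index": index,
        "1.1": index is not None,
        "1.2": index is not None and zs is ZombieStatus.NONE,
        "1.3": index is not None and zs is not ZombieStatus.LONG_TERM,
        "li_month": li[0] if li else None,
        "2.1": li is not None and li[1] >= params.cci_threshold,
    }
    out["2.2"] = out["2.1"] and blank_months(history) >= params.blank_min_months
    out["2.3"] = out["2.2"] and lookback_cci_met(history, li[0], cci_map, params)
    for k in "123":
        out[f"3.{k}"] = out["1.3"] or out[f"2.{k}"]
    return out


def ascertain(
    history: PatientHistory,
    definition_id: str,
    params: DefinitionParams = DefinitionParams(),
    cci_map: Optional[CCIMap] = None,
) -> Optional[DeathCall]:
    """Apply one definition to one patient; a :class:`DeathCall` when
    positive, else None.

    The call month is the index-claim month for definitions 1.x, the
    last-inpatient-claim month for 2.x, and the earlier of the two firing
    components for 3.x.
    """
    if definition_id not in DEFINITION_IDS:
        raise ValueError(f"unknown definition id {definition_id!r}; expected one of {DEFINITION_IDS}")
    comp = _components(history, params, cci_map)
    if not comp[definition_id]:
        return None
    family = definition_id[0]
    if family == "1":
        return DeathCall(history.patient_id, definition_id, comp["index"].claim_month, CallBasis.STATUS_CLAIM)
    if family == "2":
        return DeathCall(history.patient_id, definition_id, comp["li_month"], CallBasis.CCI_ADMISSION)
    # 3.k = 1.3 or 2.k
    sub = f"2.{definition_id[2]}"
    if comp["1.3"] and comp[sub]:
        month = min(comp["index"].claim_month, comp["li_month"], key=lambda m: m.index)
        basis = CallBasis.EITHER
    elif comp["1.3"]:
        month, basis = comp["index"].claim_month, CallBasis.STATUS_CLAIM
    else:
        month, basis = comp["li_month"], CallBasis.CCI_ADMISSION
    return DeathCall(history.patient_id, definition_id, month, basis)


def ascertain_cohort(
    cohort: Iterable[PatientHistory],
    definition_id: str,
    params: DefinitionParams = DefinitionParams(),
    cci_map: Optional[CCIMap] = None,
) -> list[DeathCall]:
    """Apply one definition to every patient; deterministic given inputs."""
    cci_map = cci_map or default_cci_map()
    calls = [
        call
        for h in cohort
        if (call := ascertain(h, definition_id, params, cci_map)) is not None
    ]
    logger.info("definition %s: %d positive call(s)", definition_id, len(calls))
    return calls


def ascertain_all(
    cohort: Iterable[PatientHistory],
    params: DefinitionParams = DefinitionParams(),
    cci_map: Optional[CCIMap] = None,
) -> dict[str, list[DeathCall]]:
    """All nine definitions on one pass over the cohort."""
    cci_map = cci_map or default_cci_map()
    calls: dict[str, list[DeathCall]] = {d: [] for d in DEFINITION_IDS}
    for h in cohort:
        comp = _components(h, params, cci_map)
        for d in DEFINITION_IDS:
            if comp[d]:
                calls[d].append(ascertain(h, d, params, cci_map))
    counts = Counter({d: len(v) for d, v in calls.items()})
    logger.info("per-definition positives: %s", dict(counts))
    return calls
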