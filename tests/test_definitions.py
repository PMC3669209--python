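"""The nine definitions: primitives, composition, nesting, oracle equivalence."""

import pytest

from conftest import STUDY_END, oracle_positive, random_history
from deathproxy.data_model import (
    BeneficiaryType,
    Claim,
    ClaimStatus,
    EnrollmentRecord,
    MonthStamp,
    Setting,
    Sex,
    build_cohort,
)
from deathproxy.definitions import (
    DEFINITION_IDS,
    CallBasis,
    DefinitionParams,
    ZombieStatus,
    ascertain,
    ascertain_all,
    ascertain_cohort,
    blank_months,
    find_index_claim,
    last_inpatient_cci,
    lookback_cci_met,
    zombie_status,
)

M = MonthStamp


def make_history(claims_spec, death_month=None, enroll=M(2005, 1)):
    """claims_spec: list of (month, setting, status, codes)."""
    record = EnrollmentRecord(
        "x", Sex.MALE, 1955, BeneficiaryType.EMPLOYEE, enroll,
        disenroll_month=death_month, death_month=death_month,
    )
    claims = [Claim("x", m, s, st, tuple(codes)) for m, s, st, codes in claims_spec]
    return build_cohort([record], claims, STUDY_END)[0]


OUT, INP = Setting.OUTPATIENT, Setting.INPATIENT
OTH, DEA = ClaimStatus.OTHERS, ClaimStatus.DEATH


class TestIndexClaim:
    def test_no_death_status_claims(self):
        h = make_history([(M(2006, 1), OUT, OTH, [])])
        assert find_index_claim(h) is None

    def test_single_death_claim_found_in_either_setting(self):
        h = make_history([(M(2007, 3), INP, DEA, [])])
        assert find_index_claim(h).claim_month == M(2007, 3)

    def test_earliest_death_claim_wins(self):
        h = make_history([(M(2007, 5), OUT, DEA, []), (M(2007, 3), OUT, DEA, [])])
        assert find_index_claim(h).claim_month == M(2007, 3)


class TestZombieStatus:
    def _with_trailer(self, gap, status=OTH):
        return make_history([(M(2007, 3), OUT, DEA, []), (M(2007, 3).add(gap), OUT, status, [])])

    def test_two_month_gap_is_short_term(self):
        h = self._with_trailer(2)
        assert zombie_status(h, find_index_claim(h)) is ZombieStatus.SHORT_TERM

    def test_three_month_gap_is_long_term(self):
        h = self._with_trailer(3)
        assert zombie_status(h, find_index_claim(h)) is ZombieStatus.LONG_TERM

    def test_later_death_claims_are_not_zombies(self):
        h = self._with_trailer(5, status=DEA)
        assert zombie_status(h, find_index_claim(h)) is ZombieStatus.NONE

    def test_claims_before_index_are_not_zombies(self):
        h = make_history([(M(2006, 1), OUT, OTH, []), (M(2007, 3), OUT, DEA, [])])
        assert zombie_status(h, find_index_claim(h)) is ZombieStatus.NONE


class TestLastInpatientCci:
    def test_latest_inpatient_month_scored(self):
        h = make_history([
            (M(2008, 1), INP, OTH, ["I21"]),
            (M(2008, 4), INP, OTH, ["C78.0"]),
        ])
        assert last_inpatient_cci(h) == (M(2008, 4), 6)

    def test_same_month_claims_pool_their_codes(self):
        h = make_history([
            (M(2008, 4), INP, OTH, ["C78.0"]),
            (M(2008, 4), INP, OTH, ["E11.2"]),
        ])
        assert last_inpatient_cci(h) == (M(2008, 4), 8)

    def test_outpatient_only_history(self):
        h = make_history([(M(2008, 4), OUT, OTH, ["C78.0"])])
        assert last_inpatient_cci(h) is None


class TestBlankMonths:
    @pytest.mark.parametrize("last_month, expected", [
        (M(2009, 1), 7),
        (M(2009, 4), 4),
        (M(2009, 8), 0),
    ])
    def test_months_after_last_claim_to_study_end(self, last_month, expected):
        h = make_history([(last_month, OUT, OTH, [])])
        assert blank_months(h) == expected

    def test_any_claim_counts_not_just_inpatient(self):
        h = make_history([
            (M(2008, 1), INP, OTH, ["C78.0"]),
            (M(2009, 6), OUT, OTH, []),
        ])
        assert blank_months(h) == 2


class TestLookback:
    def _history(self, back):
        anchor = M(2008, 6)
        return make_history([
            (anchor.add(-back), OUT, OTH, ["C78.0"]),
            (anchor, INP, OTH, ["C78.0"]),
        ]), anchor

    @pytest.mark.parametrize("back, expected", [(10, True), (12, True), (13, False)])
    def test_window_boundaries(self, back, expected):
        h, anchor = self._history(back)
        assert lookback_cci_met(h, anchor) is expected

    def test_anchor_month_itself_excluded(self):
        anchor = M(2008, 6)
        h = make_history([(anchor, INP, OTH, ["C78.0"])])
        assert lookback_cci_met(h, anchor) is False

    def test_low_score_claims_do_not_qualify(self):
        anchor = M(2008, 6)
        h = make_history([
            (anchor.add(-3), OUT, OTH, ["C50.9"]),  # weight 2 < threshold
            (anchor, INP, OTH, ["C78.0"]),
        ])
        assert lookback_cci_met(h, anchor) is False


class TestAscertain:
    def test_plain_recorded_death_positive_under_direct_family(self):
        h = make_history([(M(2007, 3), OUT, DEA, [])], death_month=M(2007, 3))
        for d in ("1.1", "1.2", "1.3"):
            call = ascertain(h, d)
            assert call is not None
            assert call.call_month == M(2007, 3)
            assert call.basis is CallBasis.STATUS_CLAIM

    def test_long_zombie_voids_12_and_13_but_not_11(self):
        h = make_history([
            (M(2007, 3), OUT, DEA, []),
            (M(2007, 6), OUT, OTH, []),
        ])
        assert ascertain(h, "1.1") is not None
        assert ascertain(h, "1.2") is None
        assert ascertain(h, "1.3") is None

    def test_severe_last_admission_composition(self):
        # high-CCI last admission, blank 7 months, no prior severe claim:
        # positive 2.1, 2.2, 3.1, 3.2; negative 2.3, 3.3 (and all 1.x)
        h = make_history([(M(2009, 1), INP, OTH, ["C78.0"])])
        expected = {"1.1": False, "1.2": False, "1.3": False,
                    "2.1": True, "2.2": True, "2.3": False,
                    "3.1": True, "3.2": True, "3.3": False}
        got = {d: ascertain(h, d) is not None for d in DEFINITION_IDS}
        assert got == expected
        call = ascertain(h, "2.1")
        assert call.call_month == M(2009, 1)
        assert call.basis is CallBasis.CCI_ADMISSION

    def test_combined_definition_takes_earlier_month_and_either_basis(self):
        h = make_history([
            (M(2008, 11), INP, OTH, ["C78.0"]),
            (M(2009, 1), OUT, DEA, []),
        ])
        call = ascertain(h, "3.2")
        assert call.call_month == M(2008, 11)
        assert call.basis is CallBasis.EITHER

    def test_unknown_definition_id(self):
        h = make_history([])
        with pytest.raises(ValueError, match="unknown definition"):
            ascertain(h, "4.1")

    def test_custom_thresholds_respected(self):
        params = DefinitionParams(cci_threshold=2, blank_min_months=3)
        h = make_history([(M(2009, 4), INP, OTH, ["C50.9"])])
        assert ascertain(h, "2.2", params) is not None
        assert ascertain(h, "2.2") is None


class TestCohortLevel:
    def test_all_negative_cohort_yields_no_calls(self):
        cohort = [make_history([(M(2006, 1), OUT, OTH, ["I10"])])]
        for d in DEFINITION_IDS:
            assert ascertain_cohort(cohort, d) == []

    def test_nesting_and_union_on_random_cohort(self, small_cohort):
        calls = ascertain_all(small_cohort)
        ids = {d: {c.patient_id for c in calls[d]} for d in DEFINITION_IDS}
        assert ids["1.2"] <= ids["1.3"] <= ids["1.1"]
        assert ids["2.3"] <= ids["2.2"] <= ids["2.1"]
        for k in "123":
            assert ids[f"3.{k}"] == ids["1.3"] | ids[f"2.{k}"]

    def test_matches_brute_force_oracle(self, small_cohort):
        for h in small_cohort:
            expected = oracle_positive(h)
            got = {d: ascertain(h, d) is not None for d in DEFINITION_IDS}
            assert got == expected, h.patient_id

    def test_ascertain_all_consistent_with_per_definition_calls(self, small_cohort):
        merged = ascertain_all(small_cohort)
        for d in DEFINITION_IDS:
            assert merged[d] == ascertain_cohort(small_cohort, d)
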