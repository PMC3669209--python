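"""Validation machinery: confusion tables, metrics, CIs, subgroups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_history
from deathproxy.data_model import (
    BeneficiaryType,
    Claim,
    ClaimStatus,
    DisenrollReason,
    EnrollmentRecord,
    MonthStamp,
    Setting,
    Sex,
    build_cohort,
)
from deathproxy.definitions import DEFINITION_IDS, ascertain_all, ascertain_cohort
from deathproxy.synthetic import SimConfig, generate_histories
from deathproxy.validation import (
    ConfusionTable,
    SubgroupSpec,
    clopper_pearson,
    confusion,
    round_half_up,
    standard_subgroups,
    standardized_difference,
    subgroup_validate,
    validity_metrics,
    wilson,
)

M = MonthStamp
STUDY_END = M(2009, 8)


def _patient(pid, dead=False, call=False, disenroll=None, reason=None):
    death = M(2007, 1) if dead else None
    rec = EnrollmentRecord(pid, Sex.MALE, 1960, BeneficiaryType.EMPLOYEE, M(2005, 1),
                           disenroll or death,
                           reason or (DisenrollReason.DEATH if dead else None), death)
    claims = [Claim(pid, M(2007, 1), Setting.OUTPATIENT, ClaimStatus.DEATH)] if call else []
    return build_cohort([rec], claims, STUDY_END)[0]


class TestConfusion:
    def test_empty_calls_all_alive(self):
        cohort = [_patient(f"p{i}") for i in range(7)]
        t = confusion([], cohort)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 7)

    def test_calls_equal_gold_dead(self):
        cohort = [_patient("a", dead=True, call=True), _patient("b")]
        calls = ascertain_cohort(cohort, "1.1")
        t = confusion(calls, cohort)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_call_for_unknown_patient_is_an_error(self):
        cohort = [_patient("a")]
        calls = ascertain_cohort([_patient("zzz", dead=True, call=True)], "1.1")
        with pytest.raises(ValueError, match="unknown patient"):
            confusion(calls, cohort)

    def test_ambiguous_disenrollment_counts_as_fp_unless_reclassified(self):
        # disenrolled in the index-claim month, reason not death, no death record
        amb = _patient("a", call=True, disenroll=M(2007, 1))
        cohort = [amb, _patient("b")]
        calls = ascertain_cohort(cohort, "1.1")
        t = confusion(calls, cohort)
        assert (t.tp, t.fp) == (0, 1)
        t2 = confusion(calls, cohort, reclassify_ambiguous_disenrollment=True)
        assert (t2.tp, t2.fp) == (1, 0)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(-1, 0, 0, 0)


class TestValidityMetrics:
    def test_undefined_metrics_are_flagged_not_zero(self):
        m = validity_metrics(ConfusionTable(tp=0, fp=0, fn=5, tn=95))
        assert m.sensitivity_pct == 0.0
        assert m.ppv_pct is None  # no positives at all

    def test_ci_contains_point_estimate(self):
        m = validity_metrics(ConfusionTable(tp=30, fp=10, fn=20, tn=940))
        for point, ci in [
            (m.sensitivity_pct, m.sensitivity_ci),
            (m.specificity_pct, m.specificity_ci),
            (m.ppv_pct, m.ppv_ci),
        ]:
            assert ci[0] <= point <= ci[1]
            assert 0.0 <= ci[0] and ci[1] <= 100.0

    def test_wilson_flag(self):
        cp = validity_metrics(ConfusionTable(5, 5, 5, 85))
        wi = validity_metrics(ConfusionTable(5, 5, 5, 85), ci_method="wilson")
        assert cp.sensitivity_pct == wi.sensitivity_pct
        assert cp.sensitivity_ci != wi.sensitivity_ci

    def test_tp_nondecreasing_along_nested_definitions(self, small_cohort):
        calls = ascertain_all(small_cohort)
        tp = {d: confusion(calls[d], small_cohort).tp for d in DEFINITION_IDS}
        assert tp["1.2"] <= tp["1.3"] <= tp["1.1"]
        assert tp["2.3"] <= tp["2.2"] <= tp["2.1"]


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)

    def test_matches_independent_exact_interval(self):
        # statsmodels' beta method is an independent implementation
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(395, 680), (3, 10), (0, 25), (25, 25), (194, 218)]:
            lo, hi = clopper_pearson(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 200), st.data())
    def test_interval_brackets_the_proportion(self, n, data):
        k = data.draw(st.integers(0, n))
        lo, hi = clopper_pearson(k, n)
        assert lo <= k / n <= hi

    def test_wilson_within_unit_interval(self):
        lo, hi = wilson(0, 10)
        assert lo == 0.0 and 0 < hi < 1


class TestStandardizedDifference:
    def test_symmetry_and_zero(self):
        assert standardized_difference(0.3, 0.3) == 0.0
        assert standardized_difference(0.2, 0.5) == standardized_difference(0.5, 0.2)

    def test_degenerate_equal_proportions_guarded(self):
        assert standardized_difference(1.0, 1.0) == 0.0
        assert standardized_difference(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            standardized_difference(1.2, 0.5)


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(88.95, 1) == 89.0
        assert round_half_up(88.85, 1) == 88.9
        assert round_half_up(99.985, 2) == 99.99


class TestSubgroups:
    @pytest.fixture()
    def cohort_calls(self):
        cfg = SimConfig(n_patients=3000, p_death=0.05)
        cohort, truth = generate_histories(cfg, seed=11)
        return cohort, ascertain_all(cohort)["3.3"], truth

    def test_sex_strata_partition_true_positives(self, cohort_calls):
        cohort, calls, _ = cohort_calls
        from deathproxy.validation import confusion as conf

        overall = conf(calls, cohort)
        df = subgroup_validate(cohort, calls, standard_subgroups())
        by = df.set_index("subgroup")
        assert by.loc["male", "tp"] + by.loc["female", "tp"] == overall.tp
        assert by.loc["male", "n"] + by.loc["female", "n"] == len(cohort)

    def test_age_bands_partition_without_overlap(self, cohort_calls):
        cohort, calls, _ = cohort_calls
        df = subgroup_validate(cohort, calls, standard_subgroups()).set_index("subgroup")
        bands = ["age_20_39", "age_40_59", "age_60_74"]
        assert sum(df.loc[b, "n"] for b in bands) == len(cohort)

    def test_icd10_prefix_flag_matches_generator_truth(self, cohort_calls):
        cohort, _, truth = cohort_calls
        spec = standard_subgroups(icd10_flags={"cancer": "C"})[-1]
        flagged = {h.patient_id for h in spec.members(cohort)}
        expected = set(truth.loc[truth.cancer, "patient_id"])
        assert flagged == expected

    def test_empty_stratum_flagged_without_division(self):
        cohort = [_patient("a"), _patient("b")]
        df = subgroup_validate(cohort, [], [SubgroupSpec("nobody", lambda h: False)])
        assert df.loc[0, "n"] == 0
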