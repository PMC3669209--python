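# Methods

## Setting and model

The package models a monthly administrative claims system: every claim,
enrollment event and death is dated by calendar month, so all derived times
(zombie gaps, blank periods, observation length) are whole-month
differences. Day-level inputs are truncated to the month with a logged
note. A patient's observation ends at the earlier of the disenrollment
month and the administrative study end; the enrollment file's death month
is the gold standard, and agreement with claims-based calls is judged at
patient level without matching the called month to the recorded month.

One loading rule deserves emphasis: claims dated *after* a patient's
disenrollment month are **kept** (only claims after the administrative study
end are dropped). Reimbursement lag routinely produces claims one or two
months after a decedent's disenrollment, and those trailing claims are
precisely the "zombie" phenomenon the definition family examines; dropping
them at load would collapse definitions 1.1–1.3 into one.

## Definitions

The earliest claim with death status (either setting) is the index claim;
later death-status claims are neither zombies nor new indices — earliest is
the deterministic, conservative choice. Zombie classification uses the
maximum month gap among non-death claims after the index month: none /
short-term (all within the 2-month window) / long-term (any gap ≥ 3
months), matching the "more than 2 months" reading of the long-term rule.

For the severity definitions, all inpatient claims in the last inpatient
month pool their ICD-10 codes before Charlson scoring, because monthly
claims fragment a single admission. The blank period is anchored at the
patient's last claim of **any** kind and counted through the study end
month (a claim in the study end month gives 0). The 12-month lookback is
anchored at the last-inpatient month, includes month anchor−12, excludes
the anchor month itself, and accepts a qualifying CCI on any single claim
in either setting. For definitions 2.x the called death month is the
last-inpatient month (the admission, not the end of the blank period): it
is the last month in which the patient demonstrably interacted with care,
and it keeps the call month within the observation window.

## Charlson scoring

The packaged mapping (`data/cci_map.csv`) follows the Sundararajan ICD-10
adaptation with the original Charlson weights (1, 2, 3, 6) over 17
categories. Matching is dot- and case-insensitive by longest prefix, so
`I25.2` hits the specific acute-MI prefix rather than a broader one, and
unmapped codes are silently ignored. Three pairs are hierarchical
(diabetes without/with complications, mild vs moderate/severe liver
disease, any malignancy vs metastatic solid tumour); by default only the
severe member counts when both appear, which is standard Charlson practice.
Whether the original validation applied this suppression is not documented,
so it is a flag (`apply_hierarchy`); none of the reproduced counts depend
on it. Suppression can only raise a category's weight, so adding codes
never lowers a score. An alternate mapping table can be supplied in the
same CSV format.

## Validation

Sensitivity, specificity and PPV are binomial proportions with exact
Clopper–Pearson 95% CIs (Beta quantiles); Wilson intervals are available
behind a flag. The exact method was chosen because several validated cells
are extreme (specificity within rounding distance of 100%, strata with
zero false positives) where normal approximations fail. Display rounding
is half-up to one decimal, two decimals for specificity. Metrics with an
empty denominator are returned as None, never silently zero.

A claims-positive patient who disenrolled in the index-claim month without
a recorded death reason counts as a false positive — the conservative rule,
since the enrollment file may simply not have been amended. The
`reclassify_ambiguous_disenrollment` flag flips such patients to gold-dead
to bound the resulting sensitivity underestimation.

Subgroup stratification uses each stratum's own denominators. Age bands
(20–39 / 40–59 / 60–74) are referenced to age at cohort entry (enrollment
year minus birth year): that is the reference at which the cohort's 20–74
eligibility range is defined, and it is the only reference under which the
three bands exactly partition the cohort — at observation end a patient
aged 74 at entry may have aged out of the top band. "Hospitalized in the
preceding year" means any inpatient claim within the 12 months before
observation end. Diagnosis and drug strata are configurable predicates
(ICD-10 prefix, drug-code membership), not hard-coded dictionaries.

## Synthetic cohorts

The generator emulates the mechanisms the definitions exploit, with every
mechanism written to a truth table so each patient's expected
classification is auditable from the claims alone (`audit_truth` verifies
this on 100% of patients). Defaults are the validation-study conditions:
a 2005-01 to 2009-08 window; 59.9% male, age mix 57.7/31.2/11.1% across
the three bands, 65.7% employees; death probability 680/195,193; recording
probability 395/680; short-zombie probability 9/395 among recorded deaths;
long-zombie miscode probability 4/194,513 among survivors; reasonless
disenrollment 14/409 among recorded deaths; severe terminal admission in
215/680 of decedents, of whom 155/215 also carry severe claims in their
final year; severe admissions in 4×10⁻⁴ of survivors. Where the study
conditions fix no value, defaults were set once to plausible working-age
insured-population values: 29% of patients enrolled at the study start and
the rest uniformly over the window with a 0.002/month non-death
disenrollment hazard (mean observation ≈ 36 months), patient-specific
monthly outpatient claim probabilities drawn exponentially with mean 0.17
(≈ 86% of patients with ≥ 1 claim), a flat 0.003/month inpatient rate, and
2% background cancer prevalence.

Deliberate simplifications: claim intensity is time-homogeneous (no
seasonality, no pre-death utilisation ramp other than the severe-terminal
mechanism); diagnosis codes are drawn from a small pool sufficient for
Charlson scoring rather than realistic ICD-10 frequencies; ages are drawn
independently of death risk. Passing tests therefore show that the
definitions and metrics behave correctly under the stated mechanisms, not
that the generator reproduces the full covariance structure of real claims.

`mechanism_benchmark_cohort` is a separate, fully deterministic synthetic
stand-in for the proprietary validation cohort: it instantiates exact
mechanism counts (by default 386 clean recorded deaths, 9 short-zombie
deaths, 4 long-zombie miscodes, 14 reasonless disenrollments, 285
unrecorded deaths, 194,495 plain survivors) so the direct definitions'
positive counts and cross-classification are reproduced exactly through
the real pipeline.

## Misclassification bias

Event times are exponential at group-specific hazards with administrative
censoring (plus optional random censoring); the observed indicator keeps a
true event with the group's sensitivity and flips a non-event with
1 − specificity, leaving times unchanged. Specificity defaults to 1, since
the validated definitions' specificity exceeds 99.96% and false events are
negligible at these scales. Hazard ratios come from lifelines'
Cox partial likelihood, adjusted for age and sex (generated independently
of group by default; a confounded design is out of scope). Replicates in
which a group has zero observed events are dropped and counted rather than
imputed.

The presets emulate the two example drug comparisons at their published
group sizes: `study1` (146 vs 27, true HR 0.71, baseline 34/100 py,
non-differential sensitivity 0.907) and `study2` (3,362 vs 878, true HR
0.27, baseline 2.07/100 py, differential sensitivity 0.368 vs 0.833 from
the corresponding drug-user subgroup validation). Both use 24 months of
administrative follow-up, chosen to give per-group person-time near the
published death rates. The Monte-Carlo summary reports the mean log-HR bias
against the thinning closed form HR_true × sens_e/sens_r, empirical
precision (inverse across-replicate variance of log HR), its Monte-Carlo
standard error, and CI coverage.

## Problem sizes and numerical choices

The test suite exercises the stochastic claims generator at 300–4,000
patients for mechanism checks and 20,000 patients for parameter recovery
(binomial 3σ tolerances at the configured probabilities); oracle
equivalence uses 1,000 random histories against an independently written
brute-force restatement of the rules; bias experiments use 500 replicates
with Monte-Carlo 3σ tolerances. The acceptance script runs the
mechanism-benchmark cohort at its full 195,193-patient scale and 300
replicates per bias experiment. Ties and degenerate inputs: equal-month
claims keep input order after the stable sort; duplicate
(patient, month, setting) claims are legal and distinct; a claimless
patient can never be definition-positive but stays in the specificity
denominator; the standardized difference of two equal degenerate
proportions is defined as 0.

## Known limitations

Month granularity caps time resolution at ±1 month everywhere; the
package does not model day-level survival. The generator's independence
assumptions (age vs death risk, group vs covariates) make it unsuitable for
studying confounding. The severity definitions depend on the Charlson map
in use; alternative maps will shift definition-2.x counts. Subgroup
sensitivity heterogeneity in real populations (e.g., out-of-hospital deaths
in young patients) is represented only through the mechanism probabilities,
not through cause-of-death structure.
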