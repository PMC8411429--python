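# Methods

This note documents the models, conventions and defaults behind `cardonc`:
what the pipeline computes, what the synthetic cohort generator does and does
not emulate, and the numerical choices a maintainer would want stated.

## Value-set semantics

A concept hierarchy is a DAG of coded concepts (child → parent edges;
multiple parents are allowed, as in any polyhierarchical terminology). A
value-set rule is a list of include terms and exclude terms, each a concept
code with a `with_descendants` flag. A term expansion is **self-inclusive**:
"X, including descendants" contains X itself. The expanded set is the union
of include expansions minus the union of exclude expansions, so exclusion
always wins regardless of listing order. Codes are opaque strings compared
by exact equality; hierarchies with cycles, unresolved parents or duplicate
codes are rejected at load time. A Problem List matches a value set iff at
least one entry's code is in the expanded set.

The bundled terminology (`cardonc.terminology`) is synthetic: the anchor
concepts reuse well-known SNOMED CT identifiers for readability, but the
subtrees beneath them are invented. Real terminology release files are out
of scope; any hierarchy in the documented CSV format (concepts + edge list)
can be substituted.

## Cohort construction

Three filters, with conservation (`|input| = |output| + |removed|`) asserted
through the attrition report:

1. **Cancer population** — Problem-List match against the cancer value set.
2. **Treated registry** — at least one treatment episode starting inside the
   **closed** window [2011-01-01, 2017-06-30]. The source registry's
   oncology-module membership criterion is represented by the existence of a
   treatment-episode row, since synthetic data has no EHR-module concept.
3. **Baseline exclusion** — any LVEF < 50% measured **strictly before** the
   initial exposure date (earliest episode start), or any heart-failure /
   dilated-cardiomyopathy Problem-List entry with onset strictly before it.

Same-day events are post-treatment by convention, applied consistently here
and in the phenotyping module (`same_day_is_post`, default true): a patient
whose only low LVEF falls on the exposure date itself is *not* excluded, and
that study counts as a post-exposure assessment. Problem-List entries with
no onset date predate nothing (the patient is kept at this stage) but do
count as present for post-treatment HFrEF detection — absence of a date is
treated as absence of evidence of priority, not of the diagnosis.

## Care measures

* **Exposure profile**: class flags (anthracycline, HER2 antibody, TKI, ICI)
  are set from *all* episodes; a patient can carry several.
* **LVD**: minimum post-exposure LVEF strictly below 50%, by any modality.
  The threshold is strict: LVEF = 50.0 is not dysfunction.
* **HFrEF**: Problem-List-only phenotype (systolic HF and/or dilated
  cardiomyopathy, with descendants). No concurrent reduced-LVEF requirement
  is imposed — the operational definition is documentation-based.
* **GDMT**: beta-blockers by case-insensitive ingredient substring
  (carvedilol, metoprolol **succinate**, bisoprolol — tartrate deliberately
  excluded); ACE inhibitors by "ACE Inhibitor" phrase containment in class
  or subclass titles, or membership in an editable combination-product list;
  ARBs by three "Angiotensin … Receptor …" phrases or the token "ARB"
  matched on word boundaries (so "BARBITURATE" can never match), plus
  aliskiren/valsartan; MRAs by "Aldosterone Receptor Antagonist" subclass
  containment. Title matching is whitespace-normalized and case-insensitive,
  and monotone in list growth. The default title lists are synthetic
  stand-ins carrying the conventional cardinalities (2 ACEi classes + 7
  subclasses, 8 combination products, 6 ARB classes, 2 MRA subclasses);
  since matching is by phrase containment, any formulary vocabulary with the
  same phrases behaves identically.

## Validation statistics

Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
NPV = tn/(tn+fn), each with an exact Clopper–Pearson 95% CI computed by
beta-quantile inversion of the binomial tails; a zero denominator yields an
undefined-flagged estimate, never a sentinel string. Exact intervals are
conservative — attained coverage is at least nominal for every true
proportion — which the test suite verifies by Monte-Carlo at
p ∈ {0.1, 0.5, 0.9}, n ∈ {20, 50, 100}.

`confusion_from_predictive_values` back-derives a review-arm confusion
matrix from stratum sizes and PPV/NPV and refuses non-integral products
(tolerance 1e-6) rather than silently inventing chart counts.

Published PPV/NPV intervals for this design are not reproducible by
Clopper–Pearson, Wilson, or plain logit intervals (e.g. 40/50 has
Clopper–Pearson bounds 66.3–90.0, not 69.4–87.6); the CI method behind them
is unstated upstream. This package computes Clopper–Pearson uniformly and
makes no attempt to reverse-engineer the unknown method, so PPV/NPV interval
bounds are not asserted anywhere in the tests.

Interrater agreement is raw percent agreement (no kappa); adjudication takes
the first reviewer's label where the two agree and the third reviewer's
label otherwise, and fails loudly on an uncovered disagreement.

## Descriptive statistics

Percentages are rounded half-up (`Decimal`, not banker's rounding), at the
precision of the surface that displays them. The 2×2 test is Pearson's χ²
with 1 df and **no continuity correction** by default: the reference
comparison of pre-exposure screening between anthracycline and HER2 groups
(381/1472 vs 114/410) gives p = 0.434 uncorrected and 0.473 corrected, and
only the uncorrected form reproduces the reference value of .43. Quartiles
use linear interpolation (NumPy's default), so median (IQR) of 1..5 is
3 (2–4).

Two known upstream display inconsistencies are deliberately not chased: a
prevalence cell whose printed percentage disagrees with half-up rounding of
its own counts (50/1401 as 3.5), and a sensitivity-analysis proportion
printed as 13.7% where the ratio is 14.0%. The reporting module always
recomputes rates from its own numerators and denominators.

## The synthetic cohort generator

The generator emulates the statistical structure of a treated cardio-
oncology registry, not clinical realism. Defaults (all overridable in
`CohortConfig`) define the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_patients | 10,000 | with cancer prevalence 0.92 and treated fraction 0.90, the expected treated registry is ≈ 8,280, matching the reference registry's scale |
| exposure marginals | AC .1778, HER2 .0495, TKI .0882, ICI .0031, other .68 | reference exposure mix; drawn as independent Bernoullis, so overlap is possible and every treated patient has ≥ 1 episode |
| baseline dysfunction | 0.045 | ≈ 372/8,275; realized half as a pre-exposure LVEF < 50, half as a pre-onset HF Problem-List entry |
| pre/post screening | per class: HER2 .278/.851, AC .2588/.691, other .1794/.3202 | class-specific reference rates; the "other" pair is back-solved once so the cohort marginals land at 19.77% / 40.91% |
| LVD risk (among screened) | AC .042, HER2 .049, other .126 | class-specific prevalence among post-assessed patients |
| true HFrEF risk | AC .035, HER2 .090, other .0198 | class-specific documented-prevalence pattern |
| documentation channel | sens .953, spec .835 | Problem-List HFrEF documentation as a per-patient Bernoulli channel over true status |
| referral | .639 given outcome; .02 background | reference referral rate among outcome patients |
| GDMT (referred / not) | BB .441/.188, ACEi-ARB .474/.306, MRA .118/.024 | reference prescription rates by referral stratum |
| age | normal, median 63, sd 14, clipped 18–95 | sd chosen so the IQR width (≈ 19y) matches the reference 52–71 |
| LVEF | N(40, 6) truncated below 50 if LVD; N(60, 5) truncated at/above 50 otherwise; clipped to [5, 80] | no distribution is specified upstream; values straddle the 50% threshold realistically. `lvef_noise_overlap` (default 0) flips the measured side |

Risk and screening class assignment uses a priority order HER2 >
anthracycline > TKI/ICI/other, since overlapping exposures are possible and
HER2 carries the most intensive surveillance.

Determinism: the dataset is fully determined by `(config, seed)`; identical
configs produce byte-identical CSVs. The truth table is generated alongside
but never consumed by any downstream module — the EHR tables alone are
sufficient input for the whole pipeline.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: clinical text, multi-episode recurrences, treatment
stop dates and dosing, correlated comorbidity structure, informative
screening (imaging ordered *because* a patient is symptomatic), and
out-of-network care. One structural consequence deserves emphasis: with a
documentation channel of specificity .835 applied to a population whose true
HFrEF prevalence is a few percent, most documented-positive patients are
channel false positives, so the cohort-level documented-HFrEF rate (~18%)
far exceeds the true prevalence, and a stratified chart review of this
synthetic cohort yields a low PPV. Stratified sensitivity/specificity
estimates from a verification-biased sample are not portable across
prevalence; the channel parameters themselves are recovered correctly, which
the 100-seed channel-recovery test demonstrates against generated truth.

## Test-suite problem sizes

Cohort-level statistical tests run at n = 5,000 patients, where a 3-standard-
error binomial band is tight enough to detect real rate errors while keeping
the whole suite fast; the channel-recovery property uses 100 seeds of 5,000
HFrEF-enriched patients; interval coverage uses 10,000 Monte-Carlo
replicates per (p, n) cell. The analysis scripts run the full 10,000-patient
study in under a minute on a laptop.

## Known limitations

* Patient-level, single initial exposure date; episode-level analyses are
  out of scope.
* No NLP over imaging reports; LVEF values are assumed structured.
* No contraindication logic in GDMT classification (a patient off
  beta-blockers for hypotension still appears in the care-gap worklist).
* The attrition report reproduces filter structure and conservation; the
  upstream registry's full pre-filter population counts are not modeled.
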