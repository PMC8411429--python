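# cardonc — EHR-based cardio-oncology registry phenotyping

`cardonc` is a tested re-implementation of an EHR computational-phenotyping
pipeline for cardio-oncology: it builds a treated-cancer registry from coded
patient records, measures how consistently left-ventricular ejection fraction
(LVEF) is assessed before and after cardiotoxic cancer therapy, detects
post-treatment cardiomyopathy outcomes, classifies guideline-directed medical
therapy (GDMT), validates the EHR-derived outcome flags against chart review,
and reports care gaps. Because institutional EHR extracts cannot be shared,
the package includes a synthetic EHR generator with known per-patient ground
truth, so every stage is exercised end to end and checked against what was
actually generated.

## Who it is for

Clinical informaticists and outcomes researchers who want a reference
implementation of registry phenotyping mechanics — value-set expansion over a
SNOMED-style polyhierarchy, CONSORT-style attrition accounting, rule-based
outcome detection, and diagnostic-performance validation with exact binomial
confidence intervals — that can be unit-tested without access to patient data.

## The method

**Cohort definition.** Diagnoses live on the Problem List as codes from a
polyhierarchical terminology. A cohort rule is a computable value set:

```
[Malignant neoplastic disease, incl. descendants  OR  Carcinoma in situ, incl. descendants
 OR  Neoplasm of brain, incl. descendants]
AND NOT
[Benign neoplasm of brain, incl. descendants  OR  Family history of clinical finding, incl. descendants]
```

Expansion is ∪(include-term closures) ∖ ∪(exclude-term closures), each term
closure being the anchor concept plus its transitive descendants; exclusion
always wins. The treated registry is the subset with a chemotherapy episode
starting in the closed window [2011-01-01, 2017-06-30]; patients whose low
LVEF (< 50%) or heart-failure Problem-List entry strictly predates their
initial exposure date are excluded, with conservation asserted at every
filter (`n_final = n_registry − n_excluded`).

**Care measures.** For each member: pre-exposure assessment = any LVEF study
strictly before the initial exposure date; post = any study on/after it.
Post-treatment LVD = minimum post-exposure LVEF < 50% by any modality
(echo, MUGA, cardiac MRI); HFrEF = a systolic-heart-failure or
dilated-cardiomyopathy Problem-List entry. GDMT is classified from the
active medication list by formulary-title rules (beta-blockers by ingredient:
carvedilol, metoprolol succinate, bisoprolol; ACE inhibitors / ARBs / MRAs by
phrase containment over pharmaceutical class and subclass titles, with
word-boundary handling so "ARB" never matches "BARBITURATE").

**Validation.** Stratified chart review (flagged-positive and
flagged-negative strata), two reviewers with percent agreement, third-reviewer
adjudication of disagreements, and a confusion matrix giving sensitivity,
specificity, PPV and NPV. Intervals are exact Clopper–Pearson, by inversion
of the binomial tails: for k successes in n trials at 95%,
lower = BetaInv(0.025; k, n−k+1), upper = BetaInv(0.975; k+1, n−k). For
example, 40/40 gives a lower bound of 91.2%. Two-group comparisons of
dichotomous variables use the Pearson χ² test without continuity correction;
continuous variables are reported as median (IQR).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
10,000-patient cohort (seed 42) and write their tables under `results/`:

```bash
python analysis/01_generate_cohort.py     # synthetic EHR + ground truth
python analysis/02_build_registry.py      # value-set cohort + attrition
python analysis/03_phenotype_members.py   # per-member care measures
python analysis/04_validate_outcomes.py   # simulated chart review
python analysis/05_report_care_gaps.py    # screening/prevalence/care gaps
```

With the default configuration this prints (script 02 and 03 output):

```
attrition: {'n_cancer_population': 9177, 'n_treated_registry': 8279,
            'n_excluded_baseline': 381, 'n_final': 7898}
pre_assessed:  1546 / 7898  (19.57%)
post_assessed: 3268 / 7898  (41.38%)
```

i.e. of 10,000 simulated patients, 9,177 match the cancer value set, 8,279
were treated in-window, 381 are excluded for baseline dysfunction, and the
final population is 7,898 — only a fifth of whom have a baseline LVEF, versus
two-fifths after therapy, the central screening care gap. Script 05 then
reports, among members with post-treatment LVD or HFrEF, GDMT prescription
rates stratified by cardiology referral, e.g. beta-blockers 42.5% (referred)
vs 2.4% (not referred), χ² p < 0.001 — referral is strongly associated with
guideline-directed treatment.

## Layout

```
src/cardonc/        library: ontology, terminology, synthetic_ehr, dataset,
                    registry, phenotyping, vocab, validation, reporting
analysis/           numbered study drivers (thin wrappers over the library)
scripts/            acceptance.py
tests/              pytest suite (unit, hypothesis properties, acceptance)
docs/methods.md     model, assumptions, parameter defaults, limitations
```
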