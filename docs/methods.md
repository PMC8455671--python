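# Methods

## Scope and data model

The package operates on four tab-delimited exchange tables — lesion-level
PET measurements, scan-level QC metadata, variant-level plasma ctDNA calls,
and a clinical outcome table — plus an optional plasma-sample manifest. It
deliberately starts *downstream* of image reconstruction and variant
calling: SUV statistics and somatic calls are inputs, never computed.
Lesions are matched across timepoints by caller-supplied `lesion_id`; no
spatial matching is attempted.

## Metabolic response

**Evaluability.** A lesion is evaluable when its SUVmax is at least
1.5 × (liver SUVmean + 2 SD) from a 3 cm right-liver ROI; when the liver is
itself involved, the rule switches to strictly above 2.0 × (blood-pool
SUVmean + 2 SD) from a 1 cm descending-aorta ROI. The inclusive/strict
split mirrors the wording of each rule ("at least" vs ">"); boundary
equality is resolved with a 1e-12 relative tolerance so that a threshold
like 1.5 × 2.6 = 3.9 behaves as written rather than as its binary
representation.

**Consist (dominance) classification.** Per-lesion response is a strict
"> c%" SUVmax reduction (a −25.0% lesion does **not** respond at c = 25).
Class 4 is triggered by *any* progression event — a new FDG-positive
lesion, any SUVmax increase in a known lesion, or zero responding lesions.
The source wording ("all target lesions do not respond or a progressive
lesion occurs") is ambiguous about whether an isolated SUVmax increase
among otherwise-responding lesions suffices; this package takes the literal
any-progression reading and records the choice here rather than asserting
it as the criterion authors' intent. The class 2/3 split ("majority of
whole-body tumor load") is not operationalised in the source; we weight
responding lesions by baseline MATV (the stated burden surrogate), fall
back to baseline SUVmax weights when any MATV is missing, then to
unweighted counts when weights sum to zero (logged); a responding share of
exactly 0.5 is class 3. New lesions are taken as FDG-positive by assertion
of the input table and are not re-checked for evaluability.

**PERCIST.** Targets require diameter ≥ 1.5 cm, an SUVpeak, and
evaluability; two per organ and ten overall are kept, hottest SUVpeak
first, with lexicographic `lesion_id` as the deterministic tie-break.
Response compares the maximum baseline SUVpeak over targets with the
maximum follow-up SUVpeak over the same targets — the hottest lesion may
change identity, which is the usual convention — and requires a strict
> 30% decrease.

**QC.** Scan-pair checks (activity within 25% of baseline, uptake time
60–70 min and within 10 min between scans, same scanner, baseline within
7 days of treatment start, glucose < 200 mg/dL) are advisory: they emit
machine-readable findings and never exclude a pair, because the source
protocol does not state that QC failures removed patients from analysis.

**Agreement.** Cohen's kappa for binary response concordance delegates to
scikit-learn and returns NaN when chance agreement is 1 (both raters
constant on the same label).

## ctDNA

Retention requires coverage strictly above 100, a forward-read fraction in
the inclusive window [0.10, 0.90] (the standard strand-bias convention for
a "10%, 90% forward-reverse ratio"), and a protein-affecting consequence
(missense, nonsense, frameshift, splice); silent and intronic calls are
dropped, and each removal is logged with the first failing rule in that
order. Detection counts variants of unknown significance by default; a
`pathogenic_only` switch restricts to pathogenic calls, since the source
does not state which convention its detection rate used.

The CDR sums mutated copies/ml over *all* retained mutations of a patient
at each timepoint. Mutations undetected at day 14 contribute zero;
mutations first seen at day 14 add to the numerator whenever the baseline
sum is positive (the single-gene original of this ratio has no such case,
so the convention is documented here). CDR is undefined — not zero — when
baseline ctDNA is undetected or the day-14 sample is missing. Median
dichotomisation uses the midpoint-of-middle-two convention with the
inclusive "low ⇔ value ≤ median" labelling. VAF strata default to
{not detected} / {detected, VAF < 20%} / {VAF ≥ 20%}; detected values below
10% — a gap in the printed strata — are assigned to the middle stratum.

Because a variant table cannot distinguish "assayed, nothing detected" from
"no sample", an optional `samples.tsv` manifest carries sample presence;
without it, every listed patient is assumed assayed.

## Combination and predictive value

The reported "NPV" is operationally P(PFS < horizon | test unfavorable)
with a 3-month default horizon — the probability that an unfavorable early
test correctly identifies a patient who will not benefit — rather than the
textbook 2×2 NPV; the full 2×2 table is emitted so sensitivity/specificity
style quantities stay derivable. Patients censored before the horizon
without an event have an undeterminable horizon status and are excluded
from numerator and denominator (exclusion, not imputation — conservative
and logged). Percentages are rounded half-away-from-zero to one decimal.

## Survival and design

Kaplan–Meier, log-rank and Cox estimation are delegated to lifelines:
KM median is the earliest time with Ŝ(t) ≤ 0.5; ties use the Efron
approximation; CIs are Wald on the log hazard ratio. These conventions are
the package's own choices where the source is silent. Cox fits that fail
to converge (including the monotone likelihood of complete separation)
return a *flagged* result with NaN estimates instead of a silently
unstable number; constant covariates are rejected. The forest table runs
one univariate fit per covariate with no multiplicity adjustment, matching
the marginal-analysis presentation it reproduces.

Design: under exponential survival the hazard ratio is the ratio of log
survival fractions at any common horizon (the horizon parameter exists for
interface symmetry only), and the Schoenfeld event count uses
double-precision normal quantiles with a ceiling to whole events. The
42-event reproduction of the 0.37 vs 0.70 design uses an allocation
fraction of 0.59 — the pilot-phase non-response rate — because the source
derives its event count "considering the results of the pilot phase"
without printing the allocation; balanced allocation gives 41 events, so
the 0.59 inference is supporting but not proven, and allocation remains an
explicit parameter.

## Synthetic cohorts

The generator emulates the structure of a ~47-patient early-response
study. A latent per-patient benefit status (default prevalence 0.333,
matching a 66.6% non-response rate) drives everything else:

- **Lesions** (1 + Poisson(2.5), capped at 15): baseline SUVmax lognormal
  (median 6, σ = 0.5); the first lesion is forced above the evaluability
  threshold so every patient is analysable. Day-14 SUVmax = baseline ×
  group effect × lognormal(0, 0.10) noise, with effect 0.74 for benefiting
  patients (a 26% mean SUV decrease, the pilot-phase figure) and 1.0
  otherwise; multiplicative noise keeps uptake positive. New lesions arise
  only in non-benefiting patients (probability 0.25 by default), creating
  class-4 mass without hand-tuning.
- **ctDNA**: baseline detection Bernoulli(0.565); at most two mutations per
  patient (a structural constraint of the emulated cohort), genes weighted
  so ESR1 and PIK3CA dominate; copies/ml lognormal (median 50, σ = 1.2).
  Day-14 copies = baseline × clearance factor: benefiting patients clear
  fully with probability 0.70 (else lognormal factor, median 0.05);
  non-benefiting patients clear with probability 0.10 (median factor 0.8).
  Copies below 0.5/ml read as undetected. The benefit → clearance link is
  the simulator's dependence knob between imaging and plasma; its strength
  is not identifiable from published summaries and is documented as a
  modelling choice.
- **Outcome**: PFS exponential with group medians 6.4 (benefit) and 2.2
  months, independent exponential censoring (median 40 months, ≈ 15%
  censoring in the fast group's follow-up range). Missingness: 2% baseline
  plasma, 9% day-14 plasma, 70% progression samples — the emulated study's
  sample accounting.

The generator reproduces the *generating process*, not real data: it has no
inter-rater variability, no measurement error in SUV beyond lesion noise,
no clonal hematopoiesis or panel-dropout structure in ctDNA, and
biomarkers are conditionally independent of outcome given benefit. Passing
recovery tests therefore show the pipeline is a consistent estimator of
its own generating model — not that the clinical effect sizes generalise.

`recover_parameters` runs the full pipeline over a generated cohort and
reports the Cox hazard ratio on latent benefit and on the Consist
readouts (the readout estimate is attenuated toward 1, as expected of a
noisy surrogate), KM medians per latent group, detection rates against
their configured values, and the median CDR.

## Problem sizes in the test suite

Property and recovery tests run at sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances: the classifier-oracle grid enumerates
all ≤ 3-lesion delta combinations (4,440 cases); cut-off monotonicity uses
a 1,000-patient cohort; KM median recovery uses 2,000 patients split evenly
between groups (sampling SD of the benefit-group median ≈ 0.3 months);
log-rank null uniformity uses 500 replicates of n = 40; Cox bias uses 100
replicates of n = 2,000 (SE of the mean log-HR ≈ 0.005); the baseline
detection-rate calibration uses 100 replicates of the 47-patient default
(SE ≈ 0.7 percentage points). All stochastic tests are seeded.

## Known limitations

- No image- or read-level processing; errors upstream of the tables are
  invisible to the package.
- Only univariate survival analysis; no multivariable Cox, time-dependent
  covariates or interval censoring.
- The Consist class 2/3 load weighting and the class-4 trigger encode
  documented interpretations of an under-specified criterion (above);
  alternative readings would change class assignments for mixed-response
  patients with isolated progressing lesions.
- The printed cohort-specific survival medians of the emulated study are
  not reproducible from summaries alone (patient-level data are not
  deposited); they are covered by parameter recovery on synthetic cohorts
  instead.
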