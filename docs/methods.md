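# Methods

## Scope

The package consumes *called, annotated* somatic variants (a minimal
MAF-style dialect with pre-joined population allele frequencies and a
panel-of-normals flag), a per-draw plasma assay table and a per-patient
clinical table. Alignment, somatic calling, copy-number/rearrangement
analysis and effect annotation are upstream and out of scope; survival
times are accepted in months only (day-unit columns are rejected, not
converted).

## Filtering cascade

A candidate is removed iff any rule fires, tested in the fixed order
dbSNP → ExAC → KRGDB → panel of normals → manual-review blocklist:

| rule | semantics | default |
|---|---|---|
| dbSNP | AF strictly above threshold ("common") | > 0.01 |
| ExAC | AF at or above threshold | ≥ 0.001 |
| KRGDB | AF at or above threshold | ≥ 0.001 |
| PoN | boolean flag | — |
| blocklist | (chrom, pos, ref, alt) membership | empty |

Threshold semantics are asymmetric on purpose: the "common" definition
is strict (> 1%), while a stated "threshold frequency" most plausibly
removes at the threshold, hence ≥ for ExAC. The KRGDB threshold is not
published; reusing the ExAC value is an assumption exposed in
`PipelineConfig.krgdb_max_af`. Absence from a database is evidence of
absence and never removes a candidate. Kept-set membership is
order-independent; only the logged first-fired rule depends on rule
order.

## Biomarkers

- **bTMB** = (count of filtered, whole-exonic synonymous +
  non-synonymous SNVs/InDels) / footprint. The effective footprint is
  not published for this panel; the default **0.26 Mb** is derived from
  the anchor "2 mutations ⇔ 7.7 Mut/Mb" (2/7.7 = 0.2597 Mb) and
  cross-checks against "3 mutations ⇔ 11.5 Mut/Mb" (3/0.2597 = 11.55).
  Every bTMB output scales with this constant
  (`PanelDefinition.footprint_mb`).
- **hVAF** = max VAF × 100 (%); undefined (not zero) for an empty
  variant set.
- **VAFSD** = standard deviation of the VAFs, sample (n−1) denominator
  by default (`vafsd_ddof`; the population form is a config switch since
  the convention is not fixed in the field). Defined only for ≥ 2
  variants. Under the clonal model below, VAFSD grows with the number
  and imbalance of clones, which is what makes it an intratumoral-
  heterogeneity surrogate.
- **Reporting precision**: Mut/Mb and percent to one decimal, VAFSD to
  three decimals; raw values are retained internally and rounding only
  happens at the reporting layer.

Dynamics: ratio = on-treatment / baseline, classed **increased** iff
ratio > 1 (a tie is "no change or decreased", matching the strict
inequality in the two-factor stratification). A missing value or a zero
baseline leaves the class undefined and the patient out of dynamics
analyses; on-treatment draws whose ctDNA is undetectable therefore
*exclude* the patient from variant-marker dynamics rather than imputing
a ratio of zero — the alternative convention would conflate assay
dropout with true clearance.

Profiles nest by construction: VAFSD-evaluable (≥ 2 variants) ⊆
bTMB/hVAF-evaluable (ctDNA-positive) ⊆ cfDNA-evaluable (QC-pass,
evaluable baseline draw).

## Endpoints

DCB = best response CR/PR/SD with no progression or death before 24
weeks; NDB otherwise when observed; patients censored before the
landmark without an event are not evaluable. The landmark is converted
at 30.44 days/month (24 × 7 / 30.44 ≈ 5.52 months) and is
boundary-inclusive — progression exactly at 24 weeks meets the landmark
(the convention is unstated in the field's definitions; inclusivity is
the documented choice here). Rapid progressors (progression and death
before first assessment) are NDB regardless of other fields. ORR and
DCB rate use the full intention-to-treat denominator. Blood indices:
NLR = ANC/lymphocytes, dNLR = ANC/(WBC − ANC), PLR =
platelets/lymphocytes, dichotomized at the cohort median with ties to
the high group.

## Statistics

- **Cutpoints**: low-favorable markers (cfDNA, hVAF, VAFSD) get an
  empirical ROC over midpoint thresholds; AUC is reported after
  orientation (always ≥ 0.5, "high" labelled unfavorable); Youden's J
  picks the cutoff, ties broken toward higher specificity
  (closest-to-(0,1) is a config alternative). bTMB is split at the
  cohort median, value ≥ median → high.
- **Group comparisons**: Mann-Whitney U (exact null when both sides
  ≤ 8 and tie-free, tie-corrected normal approximation otherwise);
  Fisher's exact test for 2×2 tables. Both via scipy.
- **Survival**: Kaplan–Meier with exponential-Greenwood log-log 95%
  bands and Brookmeyer–Crowley median intervals; "not reached" is
  reported as a missing median, never a number. Cox partial likelihood
  with Efron tie handling and Wald intervals (lifelines); a fit with
  zero events is refused with a diagnostic. Multivariate models admit
  covariates with univariate p < 0.05 (`multivariate_entry_p`), an
  explicit configuration because entry rules vary between analysts.
- **Two-factor stratification**: patients are labelled by their count
  of risk factors (0/1/2, e.g. increased bTMB + high baseline cfDNA);
  patients with either factor undefined are excluded.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not any
patient dataset:

- latent benefit class per patient (default prevalence 0.25);
- cfDNA ng/mL lognormal per class (medians 5.5 DCB / 12 NDB), lower in
  the benefit class;
- clonal variant model: 1–6 clones (uniform), Dirichlet clone
  fractions, per-class lognormal tumor fraction (medians 0.05 / 0.15),
  **VAF = clone fraction × tumor fraction / 2** (diploid heterozygous
  somatic variants) plus Gaussian read noise (sd 0.002), floored at a
  0.005 detection limit;
- on-treatment VAFs are baseline VAFs times a per-class shrinkage
  factor (0.4 DCB, 1.5 NDB); variants falling under the detection limit
  drop out (baseline-only keys), and emergent on-treatment-only
  variants arrive at Poisson rates (0.1 / 0.8 per patient) — together
  these produce the benefit group's larger baseline-only share and the
  non-benefit group's emergent share;
- germline/artifact contaminants (Poisson, mean 1 per patient) carry
  annotations strictly on the removal side of one cascade threshold;
- gene assignment is TP53-dominant (weight 0.30, chosen so roughly
  two-thirds of ctDNA-positive patients carry a TP53 variant under the
  uniform 1–6 clone count), with EGFR/KRAS/CDKN2A/ARID1A and friends at
  a few percent and the rest of the 118-gene panel uniform;
- PFS is exponential proportional hazards on boolean truth factors
  (`hazard_ratios`, default: non-benefit class ×15, high baseline cfDNA
  ×1.5 on progression hazard); OS is progression time plus an
  exponential residual with its own multipliers; censoring is
  administrative (uniform 6–24-month follow-up) plus light exponential
  dropout sized from `censoring_rate`;
- QC-failed (11) and non-evaluable (3) baseline draws are assigned by
  count, not rate, so exclusion bookkeeping is exact;
- the best RECIST response is assigned *consistently with the realized
  progression time*: a latent-benefit patient whose progression happens
  to fall before the 24-week landmark is observed as NDB. This keeps
  the survival model strictly proportional-hazards — no post-hoc
  truncation — at the cost of a small gap between latent prevalence and
  the observed DCB rate. The truth table records the latent values.

What the generator does **not** emulate: mutational signatures and
real panel hotspot structure, copy-number/rearrangement events,
sequencing-depth-dependent VAF error, correlated comorbidity covariates,
or non-proportional hazards. Passing tests therefore demonstrate the
pipeline's correctness and the recoverability of planted effects, not
clinical performance on real cohorts.

## Numerical choices and degenerate inputs

All randomness flows from a single `numpy` Generator seeded from
`SimulationConfig.seed`; identical seeds give byte-identical output
tables. Median splits send ties to the high group (so a tied median
makes the high group the larger one). ROC cutoffs are midpoints between
adjacent distinct values, so they are never attained exactly by a
sample value and the </ vs ≤> distinction is moot. Empty variant sets:
hVAF/VAFSD undefined, bTMB = 0 only for a ctDNA-positive draw.
Single-class ROC input, empty comparison groups, zero-event Cox fits
and duplicate patient/sample identifiers all raise validation errors
rather than degrading silently; singular Cox fits inside the full study
model are caught and reported as missing rather than aborting the run.

## Problem sizes

The test and verification suites use 100–200-patient cohorts for
structural checks, 100 random instances for the ROC/Kaplan–Meier oracle
equivalences, 20 seeded cohorts for group-direction checks, and 50
replicates of 2,000 patients for Cox hazard-ratio recovery (log-HR bias
under 10%, ≥ 90% CI coverage at a planted HR of 5) — sizes at which the
binomial/asymptotic tolerances used in the assertions are comfortably
informative.
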