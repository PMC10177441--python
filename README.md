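# plasmabm

Plasma cell-free DNA (cfDNA) biomarker analysis for immunotherapy
response prediction in advanced non-small cell lung cancer, built for
paired baseline / on-treatment liquid-biopsy designs.

Checkpoint-inhibitor monotherapy benefits only a minority of pretreated
NSCLC patients, and tissue biomarkers (PD-L1, tissue TMB) are often
unavailable or unreliable in the second line. Blood-based markers are an
accessible alternative: this package implements a complete analysis
pipeline from annotated somatic variant calls and plasma assay tables to
response and survival associations, plus a seeded synthetic-cohort
generator so every stage is testable without patient data.

## The biomarkers

For each plasma draw (baseline C0; on-treatment C4, or end-of-treatment
EOT when treatment stopped earlier), after a population-frequency /
panel-of-normals filtering cascade over the variant candidates:

- **bTMB** — blood tumor mutational burden: the count of somatic,
  whole-exonic (synonymous and non-synonymous) SNVs and InDels per
  megabase of panel footprint, `bTMB = n / F` (Mut/Mb), with the
  effective footprint `F = 0.26 Mb` by default;
- **cfDNA concentration** — ng/mL, a tumor-burden surrogate;
- **hVAF** — the highest variant allele frequency in the sample (%), a
  proxy for circulating-tumor-DNA content (analogous to MSAF);
- **VAFSD** — the sample standard deviation of the VAFs (fraction
  units, requires ≥ 2 variants), a surrogate for intratumoral
  heterogeneity.

Dynamics are classified from the ratio `r = x_on / x_C0`: **increased**
iff `r > 1`, otherwise **no change or decreased**. Durable clinical
benefit (DCB) is best response CR/PR/SD without progression at 24 weeks;
cutpoints come from ROC curves (Youden's J) for the low-favorable
markers and from the cohort median for bTMB; survival uses Kaplan–Meier
estimates and Cox proportional-hazards models, including a two-factor
risk stratification (increased bTMB + high baseline cfDNA).

## Worked example

```python
import plasmabm as pb

cohort = pb.generate_cohort(pb.SimulationConfig(seed=1))
results = pb.BiomarkerStudy.from_cohort(cohort).fit()
print(results.summary())
```

prints (abridged):

```
Patients (ITT): 100
cfDNA BEP profiles: 86
ORR: 8.0%   DCB rate: 22.0%

Baseline cutoffs (C0):
  btmb     11.538  (median split)
  cfdna     7.725  (ROC AUC 0.845)
  hvaf      1.446  (ROC AUC 0.858)
  vafsd     0.005  (ROC AUC 0.883)

DCB vs NDB comparisons (Mann-Whitney p):
  btmb   C0 p=0.3460   C4/C0 ratio p=0.0001
  cfdna  C0 p=0.0000   C4/C0 ratio p=0.0000
  ...
Univariate Cox (PFS):
  btmb_increased         HR   2.36 (95% CI 1.22-4.56) p=0.0103
  cfdna_high             HR   3.09 (95% CI 1.83-5.21) p=0.0000
  ...
```

Reading this: of 100 simulated patients, 86 baseline draws pass QC and
are evaluable (the cfDNA biomarker-evaluable population). Baseline bTMB
does not separate benefit groups (p = 0.35) but its on-treatment
dynamics do (ratio p = 0.0001), and high baseline cfDNA and rising bTMB
are the dominant progression risk factors — the qualitative structure
the generator encodes. The same pipeline runs from files via
`BiomarkerStudy.from_tables(...)` or the `plasmabm` CLI
(`simulate`, `filter`, `biomarkers`, `analyze`, `profile`).

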