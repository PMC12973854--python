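# mrcausal

One- and two-sample Mendelian randomization (MR) for a binary exposure and
a bounded continuous outcome, built so the complete analysis — instrument
selection, polygenic-score 2SLS, and summary-statistic meta-analysis with
sensitivity checks — runs end to end on synthetic data when the real
individual-level cohort is access-restricted.

It is aimed at genetic epidemiologists who want a transparent, fully
seeded implementation of the standard MR toolbox: the motivating setting
is a migraine → cognitive-impairment analysis, with migraine status as a
liability-threshold binary exposure and an MMSE-like cognition score
(0–30, higher is better) as the outcome.

## What it computes

**Instrument selection.** Exposure GWAS records are filtered at genome-wide
significance (p < 5×10⁻⁸, strict), then pruned by PLINK-style greedy LD
clumping (window 10,000 kb, r² < 0.001, index/secondary p < 10⁻⁵) against
a reference dosage panel, and harmonized against the outcome GWAS
(allele swaps, strand complements, palindromic-SNP policy, full audit
trail).

**Strategy 1 — one-sample PRS/2SLS.** A polygenic risk score
PRS_i = Σⱼ γ̂ⱼ G_ij (G_ij = effect-allele count) is built from the joint
stage-1 regression of the exposure on all instrument dosages; the stage-2
regression of the outcome on the fitted PRS gives the 2SLS causal
estimate. Instrument strength is the F-statistic of the exposure-on-PRS
regression, with F < 10 flagged as weak. Cohort descriptives by PRS
tertile (ANOVA, χ², trend and Cochran–Armitage tests) come alongside.

**Strategies 2–3 — summary MR.** Per-SNP Wald ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ
(outcome association over exposure association) are combined by:

* **IVW** — β = Σwⱼβ̂ⱼ/Σwⱼ with wⱼ = 1/se(β̂ⱼ)²; the headline model is
  multiplicative random-effects (SE scaled by max(1, √(Q/(k−1)))), with
  the fixed-effect model always reported alongside;
* **MR-Egger** — weighted regression of Γ̂ on γ̂ with a free intercept
  (average directional pleiotropy), gated by the I²GX regression-dilution
  diagnostic: estimates with I²GX < 90% are reported but flagged invalid;
* **weighted median** — consistent while valid instruments carry > 50% of
  the weight; SE by seeded parametric bootstrap.

Sensitivity: funnel-plot outliers by the 3×IQR rule (reported
not-applicable below 5 SNPs), an automatic re-run excluding them, and
leave-one-out re-estimation. Estimates are also shown exponentiated
(odds-ratio scale).

**Synthetic cohorts.** A seeded generator produces LD-structured biallelic
dosages (latent equicorrelated Gaussian haplotypes, Hardy–Weinberg per
SNP), a standard-normal liability driven by ~18 small per-allele effects
with the binary exposure thresholded at a chosen prevalence, an outcome
with configurable causal effect, confounding and horizontal pleiotropy
(balanced or directional presets), and independent cohort pairs for
two-sample designs.

## Worked example

```
mr-causal simulate --seed 7 --out sim/ --n 20000          # two-cohort study, true beta 2.4
mr-causal two-sample-mr --exposure sim/exposure_stats.tsv \
    --outcome sim/outcome_stats.tsv --out mr/ --seed 7
```

The log reports the selection funnel (`18 -> 15` SNPs survive p < 5×10⁻⁸
at this sample size) and `mr/report.json` contains:

```
ivw               2.284  (2.078, 2.489)   valid
ivw_fixed         2.284  (2.078, 2.489)   valid
mr_egger          2.090  (1.247, 2.933)   INVALID (I2_GX = 0.833 < 0.90)
weighted_median   2.268  (1.956, 2.579)   valid
```

The generating causal effect was 2.4 outcome units per liability SD: the
IVW and weighted-median CIs cover it, and the Egger estimate is correctly
disqualified by the I²GX gate — with 18 instruments of similar small
effects, the exposure-association spread is not large relative to its
measurement error, which dilutes Egger regression. `estimates.tsv` adds
the odds-ratio scale (e.g. IVW OR 9.81, 95% CI 7.99–12.05), and
`forest.tsv`, `funnel.tsv`, `leave_one_out.tsv` hold the per-SNP tables.

The same library surface is importable directly
(`mrcausal.simulate_two_sample_study`, `mrcausal.harmonize_instruments`,
`mrcausal.mr_report`, ...), and `mr-causal onesample` runs the Strategy-1
PRS/2SLS pipeline from a dosage TSV/VCF plus phenotype CSV.

## Layout

```
src/mrcausal/
  datatypes.py    shared containers (SnpSpec, GenotypeMatrix, InstrumentSet, ...)
  synthetic.py    cohort generator and single-SNP GWAS
  instruments.py  significance filter, LD clumping, harmonization
  onesample.py    PRS, 2SLS, F-statistic, tertile table, Cochran-Armitage
  summary_mr.py   Wald ratios, IVW, MR-Egger + I2_GX, weighted median, sensitivity
  validation.py   replicated operating-characteristic experiments
  io.py           summary-stat TSV, dosage TSV, VCF, phenotype CSV, config
  pipeline.py     strategy orchestration and report writing
  cli.py          mr-causal command line
docs/methods.md   model, assumptions, defaults and design choices
```

See `docs/methods.md` for the generator's assumptions, what the synthetic
data does and does not emulate, and the numerical conventions.
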