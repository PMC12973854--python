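# Methods

## The causal model

The package analyses the effect of a binary, polygenic exposure on a
bounded continuous outcome with genetic variants as instrumental
variables. The generative model mirrors the classic liability-threshold
formulation:

* **Liability.** Each individual carries dosages G_ij ∈ {0,1,2} at m
  biallelic SNPs. The exposure liability is
  `L_i = Σⱼ γⱼ (G_ij − 2 pⱼ) + c_x C_i + ε_i`, with C a normal
  confounder and the residual scaled so the *empirical* variance of L is
  exactly 1. (The theoretical genetic variance has no closed form once
  within-block LD is generated by thresholding correlated Gaussians, so
  the residual scale is set from the realized systematic variance; the
  empirical Var(L) = 1 ± 0.05 property is tested.) The binary exposure
  is `X_i = 1{L_i > Φ⁻¹(1 − K)}` for prevalence K (default 0.15, a
  typical adult migraine prevalence).
* **Outcome.** `Y_i = μ₀ + β L_i + Σⱼ αⱼ G_ij + c_y C_i + noise`, with β
  the causal effect *per liability SD*, αⱼ direct (horizontally
  pleiotropic) SNP effects, and noise SD `noise_sd_y` (default 3.0 —
  large enough that no single source dominates an MMSE-like score, small
  enough that a 0–30 scale with mean ≈ 27 remains plausible). Optional
  clipping to [0, 30] and integer rounding produce realistic scores;
  both default **off** because they break the exact linear identities
  the estimator tests rely on.

Because β acts on the continuous liability, the per-SNP ratio estimand
Γⱼ/γⱼ equals β exactly in the no-pleiotropy limit *when the exposure
GWAS is run on the liability*. That is the two-sample simulator's
default. Running the exposure GWAS on the thresholded binary trait
shrinks every γⱼ by a common liability-to-probability factor
(≈ φ(Φ⁻¹(1−K)) for small effects), so all Wald ratios are inflated by
its inverse; the binary scale is retained because the one-sample
PRS/2SLS strategy regresses the observed binary exposure, and the
attenuation/inflation is a property of that design, not a bug.

## Genotypes and LD

Each genotype is the sum of two independent haplotypes. Within an LD
block a haplotype's alleles come from an equicorrelated standard
Gaussian (pairwise correlation ρ) thresholded at the MAF quantile;
blocks are independent. This preserves Hardy–Weinberg proportions per
SNP while giving tunable pairwise r² — enough structure for LD clumping
to act on, which is all the analysis needs. It does **not** emulate
realistic human LD decay, allele-frequency spectra, imputation
uncertainty, or array-QC artefacts (monomorphic/degenerate records are
flagged instead). Missingness is optional MCAR, default 0.

The `study_like_panel` preset is the study condition used throughout:
18 independent instruments, per-allele liability effects γ ~ U(0.05,
0.15), MAF ~ U(0.1, 0.5), non-palindromic allele pairs. Pleiotropy
presets plant direct effects on a fraction of SNPs: `balanced`
α ~ N(0, 0.01), `directional` α ~ N(0.05, 0.01) on 30% of SNPs.

## Instrument selection

Selection applies the genome-wide filter (p < 5×10⁻⁸, strict inequality)
first and then PLINK-style greedy clumping (window 10,000 kb inclusive,
r² ≥ 0.001 clumps, index/secondary p < 10⁻⁵). Running the 5×10⁻⁸ filter
first makes the 10⁻⁵ index threshold vacuous, but it mirrors the stated
two-step procedure and both thresholds remain configurable. Ties on p
break by position then SNP id, so clumping is order-independent; r² is
computed on user-supplied reference dosages (undefined r² from a
constant column never clumps, and is logged).

Harmonization matches by SNP id and aligns outcome records to the
exposure's coded allele by swap (sign flip + EAF complement), strand
complement, or both. Palindromic SNPs cannot be resolved by strand;
default policy aligns them by allele frequency and drops them when
either EAF lies in [0.42, 0.58] (a conventional ambiguity band — the
original analysis does not state its choice, so the audit table makes
ours explicit). Every input SNP appears in the audit with an action and
reason; retained + dropped = input.

## Estimators and numerical conventions

* **Wald ratios.** βⱼ = Γⱼ/γⱼ. The published formula text reads
  "γ/Γ", but the published estimates carry outcome units per exposure
  unit, which forces the outcome-over-exposure orientation; the report
  states the orientation used. First-order delta SE se(Γⱼ)/|γⱼ| is the
  default (it defines the IVW weights and preserves the textbook
  IVW ≡ weighted-through-origin-regression identity); a second-order
  option adds the exposure-side term.
* **IVW.** The headline model is multiplicative random effects: fixed-
  effect SE scaled by max(1, √(Q/(k−1))). The fixed-effect model is
  always computed alongside. Rationale: when the causal effect is a
  non-trivial share of outcome variance (as in the study preset, where
  β=2.4 on a unit-variance liability is ~40% of Var(Y)), the neglected
  exposure-side uncertainty shows up as genuine overdispersion of the
  ratios; the Q-scaling absorbs it (measured 95–96% CI coverage vs ~86%
  for fixed under the preset), and it is also the default behaviour of
  the standard two-sample MR software. Under a null effect the floor at
  1 makes the test mildly conservative (~3–4% rejection at nominal 5%).
* **MR-Egger.** SNPs are oriented so γⱼ ≥ 0, then Γ is regressed on γ
  with intercept, weights 1/se(Γⱼ)², SEs on the same multiplicative
  scale floored at 1. I²GX — computed from the precision-weighted
  dispersion of |γⱼ|, clamped to [0,1] — gates validity at 90%: diluted
  estimates are still reported, flagged invalid. With 18 instruments of
  similar small effects this gate typically fires (I²GX ≈ 0.83–0.90 at
  n = 20k), matching the motivating analysis, where Egger was declared
  unusable for the same reason.
* **Weighted median.** Interpolated weighted median of the sorted
  ratios (cumulative-midpoint convention); SE from a seeded parametric
  bootstrap redrawing γⱼ* and Γⱼ* from their SEs (1000 replicates by
  default). The original software's SE method is unknown; bootstrap is
  the documented choice here.
* **Funnel outliers.** 3×IQR fences with linear-interpolation sample
  quartiles (NumPy's default convention, fixed here since the rule's
  source names none); not applicable below 5 SNPs.
* **CIs** are 95% normal-based (β ∓ 1.96 se) throughout; p-values are
  two-sided normal, including in the GWAS records (whose beta/se/p are
  kept mutually consistent under the normal approximation).
* **2SLS.** Stage 1 is a linear(-probability) joint regression by
  default — the additive PRS and the 2SLS consistency argument both
  presuppose a linear first stage; logistic weights are available with
  the caveat that the PRS then lives on the log-odds scale. The
  headline SE is the naive stage-2 OLS SE (the manual two-regression
  procedure); the conventional IV sandwich SE is always computed and
  reported in the notes. PRS rounding (e.g. 4 decimals) is supported
  and shown to be benign (< 10⁻² shift on the packaged fixture).
  Exactly collinear dosage columns raise an error naming the SNPs;
  tertile ties are resolved by a stable sort into thirds, which matches
  quantile cuts for distinct scores and keeps group sizes within 1 of
  each other under ties.

## Validation experiments

`mrcausal.validation` re-runs complete studies under known truth:

* **Coverage/bias** (100 replicates): two-sample preset, k=18,
  n=20,000/cohort, β=2.4, no pleiotropy. Headline IVW covers the truth
  in ≈95% of replicates; the small negative mean bias (≈ −0.02 to
  −0.04) is the expected weak-instrument attenuation Σγ²/(Σγ² + k·se²).
* **Type-I error** (500 replicates): β=0, same preset; rejection ≈ 3–5%
  at nominal 5% (the random-effects floor is conservative under the
  null).
* **Directional-pleiotropy robustness** (200 replicates): 30% of SNPs
  invalid with α ~ N(0.05, 0.01), redrawn every replicate so the
  experiment marginalizes over which SNPs are invalid rather than
  inheriting one panel's accidental α–γ correlation. This experiment
  runs at n=400,000/cohort: the median's consistency under <50% invalid
  weight is an asymptotic property, and the cohort size is chosen so the
  planted per-SNP ratio shift (≈0.5) is about four times the per-SNP
  ratio SE — in that contamination-dominated regime the weighted median
  is less biased than IVW in ~95–100% of replicates, while at n=20,000
  sampling noise swamps the planted bias and the comparison is
  uninformative. The mean Egger intercept tracks the planted average
  pleiotropy (≈0.014 per SNP) with a small upward dilution inflation.
* **2SLS recovery** (100 replicates): one-sample cohorts (n=10,000)
  with β=−2.3 on the MMSE-coded outcome, exposure taken on the
  liability scale; mean estimate within 0.1 of truth, CI coverage
  ≥95% (the naive SE is mildly conservative).

Problem sizes are the package's chosen study conditions; they keep every
experiment exactly reproducible from a single seed.

## What passing tests do and do not show

The synthetic data satisfies the MR assumptions by construction
(instruments affect the outcome only through the liability unless
pleiotropy is explicitly planted, and confounding is off by default), so
passing recovery tests demonstrates correctness of the estimators and
pipeline plumbing — not that any real exposure–outcome pair satisfies
those assumptions. Features of real data the generator does not emulate:
realistic LD maps and allele-frequency spectra, population structure and
relatedness, genotyping error, selection into the cohort, non-normal
outcome noise, and case-control ascertainment of the exposure GWAS.

## Known limitations

* Multi-allelic variants are skipped on VCF read; no proxy-SNP lookup.
* The Egger intercept's magnitude is inflated under low I²GX (the gate
  exists precisely because of this); only its sign is a reliable
  direction signal in that regime.
* The odds-ratio conversion `exp(β)` is reproduced as published even
  though its interpretation for a continuous-outcome β is unusual; the
  package converts without endorsing the reading.
* `logistic` stage-1 weights are exploratory; no bias correction is
  applied for the resulting scale change.
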