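# Methods

## Model

The package analyses the two-sample summary-data MR model. For SNP
j = 1..J, the exposure GWAS reports β̂ˣⱼ with SE σₓⱼ (SD units of the
exposure after standardization) and the outcome GWAS reports β̂ʸⱼ with SE
σᵧⱼ (log-odds). Under a linear exposure-outcome relationship with causal
effect θ (log OR per SD) and valid instruments,

    β̂ˣⱼ ~ N(ξⱼ, σ²ₓⱼ),    β̂ʸⱼ ~ N(θ ξⱼ, σ²ᵧⱼ),   independently,

where ξⱼ is the true SNP-exposure effect. The headline estimator maximizes
this bivariate-normal likelihood. Profiling out ξⱼ in closed form leaves a
one-dimensional deviance

    f(θ) = Σⱼ (β̂ʸⱼ − θ β̂ˣⱼ)² / (σ²ᵧⱼ + θ² σ²ₓⱼ),

minimized by bounded scalar search started at the IVW solution (bracket
±10·(1+|start|), tolerance 1e-12, 500-iteration cap; failure raises a
convergence error). The SE comes from the observed information of the
profile likelihood, I(θ̂) = f″(θ̂)/2, with f″ by central differences at
step 1e-5·(1+|θ̂|). Because f is smooth and unimodal in all realistic
configurations, the bracketed search is reliable; the test suite
cross-checks it against a dense grid scan of f.

When σₓⱼ → 0 the deviance reduces to the IVW criterion, so the likelihood
estimate converges to the IVW slope; this limit is tested at σₓ = 1e-8 to
1e-6 agreement.

All confidence intervals are θ̂ ± 1.96·SE on the log-odds scale,
exponentiated for OR-scale reporting; p-values are two-sided normal except
where noted.

## Sensitivity estimators

Horizontal pleiotropy — a SNP affecting the outcome other than through the
exposure — breaks the model above. Four complementary analyses bound the
damage:

* **MR-Egger.** Each SNP is re-signed so β̂ˣⱼ ≥ 0, then y = α + θx is fit
  by WLS with weights 1/σ²ᵧⱼ. α estimates the average directional
  pleiotropy; its two-sided test uses the t distribution on J−2 df with the
  dispersion-estimated SE (the statsmodels WLS default). That choice keeps
  the intercept test near nominal size under balanced pleiotropy, which the
  simulation harness verifies. Instruments with fewer than 3 SNPs are not
  estimable and surface as NA at pipeline level.
* **Weighted median.** Wald ratios are sorted; with weights
  wⱼ = (β̂ˣⱼ/σᵧⱼ)² normalized to sum 1, the estimate interpolates the
  ratio at cumulative mid-weight 0.5. Consistent when ≥ 50% of weight is
  valid. The first-order inverse-variance weights are the originating
  method's default.
* **Mode.** A normal-kernel density over the ratios with the same
  normalized weights and modified-Silverman bandwidth
  h = φ·0.9·min(weighted SD, weighted MAD/0.6745)·J^(−1/5), φ = 1 by
  default; the estimate is the argmax on a 10,000-point grid spanning the
  ratios ± 3h. Identical ratios short-circuit to the common value with SE
  0; a zero MAD with non-identical ratios falls back to the SD-based
  bandwidth. Consistent when the largest homogeneous SNP group is valid.
* **Cochran's Q.** Q = Σ wⱼ(θⱼ − θ_IVW)², wⱼ = (β̂ˣⱼ/σᵧⱼ)², on J−1 df;
  inflation signals pleiotropy of any kind.

SEs for the median and mode use a parametric bootstrap (resample β̂ˣⱼ,
β̂ʸⱼ from their sampling normals, 1000 replicates by default, seeded).
Bootstrap SEs are exchangeable in distribution but not bit-identical under
sign flips of the outcome, hence the equivariance tests allow a loose SE
tolerance for these two estimators only.

## MR-PRESSO

The global test computes the leave-one-out IVW residual sum of squares
RSS = Σⱼ wⱼ(β̂ʸⱼ − θ̂₋ⱼ β̂ˣⱼ)², wⱼ = 1/σ²ᵧⱼ, and compares it with its
parametric null: n_sim simulated datasets drawn as β̂ˣⱼ* ~ N(β̂ˣⱼ, σ²ₓⱼ),
β̂ʸⱼ* ~ N(θ̂₋ⱼ β̂ˣⱼ, σ²ᵧⱼ), each with the leave-one-out slopes recomputed
on the simulated data (the originating method's construction; fully
vectorized). P-values use the add-one convention (1+#exceedances)/(n_sim+1),
so the smallest representable value is 1/(n_sim+1): the default n_sim = 5000
resolves p ≈ 2×10⁻⁴, and regimes like P_global < 1×10⁻⁴ need n_sim ≥ 10⁴
(`--presso-sims` in the CLI, `presso_sims` in study configs). The per-SNP
outlier test compares each SNP's weighted squared residual with its
simulated counterpart, Bonferroni-multiplies by J, and flags below 0.05.
When outliers are flagged, the distortion statistic
D = (θ̂_no-outliers − θ̂_all)/|θ̂_all| is referred two-sidedly to the
distribution of D under random removals of equally many SNPs. Instruments
below 4 SNPs are NA. Simulations show the global test holds its size
(rejection ≈ 0.04–0.05 at α = 0.05 over 500 null instruments) and flags a
10-outcome-SE displaced SNP essentially always.

## Power

For a binary outcome with N = n_cases + n_controls and case fraction p, the
MR z-statistic for log OR b has approximate non-centrality
b·√(N·R²·p(1−p)), giving the minimum detectable OR
exp[(z₁₋α/₂ + z_pow)/√(N R² p(1−p))] and its inverse power curve. Target
power defaults to 0.80, the conventional design value; α defaults to 0.05
two-sided. An alternative of exactly OR = 1 returns power α/2 (the
formula's continuous limit). Subtype power columns require subtype-specific
control counts; the package computes whatever design it is given and makes
no assumption about shared controls.

## Subtype heterogeneity

For one exposure with CD and UC estimates (θ̂_cd, se_cd), (θ̂_uc, se_uc),
the pooled fixed-effect mean is the inverse-variance-weighted average and
Q = Σ(θ̂ᵢ − θ̄)²/se²ᵢ is referred to χ²(1). No random-effects fallback:
with two estimates the fixed-effect model is the only identifiable one.
When either subtype estimate is NA the test is NA. A helper reconstructs
log-scale estimates from printed ORs and 95% CIs (SE = CI log-width/3.92)
to re-test published forest-plot rows.

## Harmonization rules and selection

Instrument selection filters at P < 5×10⁻⁸ (strict inequality) and prunes
greedily by ascending p-value at LD R² < 0.01, ties broken by input order —
the deterministic clumping behaviour. Harmonization keeps matched allele
pairs, flips swapped pairs (negating the outcome beta and complementing the
frequency), resolves strand complements for non-palindromic pairs, and by
default drops palindromic (A/T, C/G) SNPs, since resolving them properly
requires an LD proxy lookup that is out of scope. An opt-in frequency mode
keeps palindromic SNPs when both effect-allele frequencies are informative
(minor-allele frequency < 0.42) and orients by which side of 0.5 they fall
on. Only single-base alleles are accepted; indel rows are rejected with a
logged reason, as are rows with non-positive SEs or out-of-range
frequencies or p-values.

## Synthetic data

The generator emulates the statistical structure the estimators assume: J
independent SNPs with MAF uniform on [0.05, 0.5], true effects γⱼ drawn
half-normal and rescaled so Σ 2·mafⱼ(1−mafⱼ)γⱼ² equals the target R²
exactly, exposure SEs 1/√(2 maf(1−maf)·n_exposure) and outcome SEs from the
case-control effective sample size n_cases·n_controls/N on the log-odds
scale. Effect alleles are coded as the exposure-increasing allele — the
convention of curated instrument tables — which is what makes "directional"
pleiotropy directional in the MR-Egger sense; the outcome table is then
randomly allele-swapped and strand-complemented to exercise harmonization.
Pleiotropy modes: none, balanced N(0, τ²), directional N(μ, τ²), or point
outliers displaced by a fixed multiple of their outcome SE. Default
designs use the IBD consortium outcome (25,042 cases / 34,915 controls) and
an exposure GWAS of 300,000 — typical of the anthropometric-trait GWAS that
supply such instruments.

What the simulations do *not* model: LD between instruments, sample
overlap, allele-frequency differences between the two GWAS, per-SNP
logistic-regression SEs, winner's-curse in instrument selection, and
liability-scale subtleties for binary exposures. Passing calibration tests
therefore demonstrates correctness of the estimators under the assumed
sampling model, not robustness to those real-data complications.

The thirteen preset instrument designs (`simulate_table1_designs`) mirror
the published study: instrument sizes from 2 SNPs (physical activity,
folate — exercising the NA policy for sub-minimum instruments) to 816
(BMI), explained variances from 0.08% to 6.3%. Discovery-GWAS sizes not
printed in the study are set to the approximate published sizes of the
source GWAS (1.2M smoking, 700k anthropometric, 91k accelerometer physical
activity, 46k–80k vitamins, 9k NMR fatty acids).

## Pipeline choices

The likelihood-based estimate is the headline; IVW, Egger, median and mode
are labelled sensitivity analyses. Bonferroni divides α = 0.05 by the
number of *exposures* (13 in the reference study, printing as 0.0038), not
exposure × outcome pairs, and is applied to the headline p-values only.
Per-pair RNG seeds derive deterministically from the study seed, so a rerun
of the same config is byte-identical (verified by manifest checksums).
Stage failures are recorded per pair and the run continues; a failure log
accompanies the report.

## Problem sizes used in validation

Calibration checks use 500 null instruments (J = 30, R² = 0.05, IBD-scale
design) for type-I error of the likelihood estimator and of the MR-PRESSO
global test (n_sim = 1000 per run), 200 replicates at J = 50 for parameter
recovery (mean estimate within ±0.02 of θ = 0.3), and 100 seeded injection
runs for outlier detection. These sizes give binomial Monte-Carlo error
around 1–3 percentage points on the estimated rates.

## Known limitations

Single-outcome, single-exposure univariable MR only: no multivariable MR,
no correlated-instrument GLS, no Steiger filtering, no LD-proxy lookup, no
liftover. The weighted-median and mode variants implemented are the
weighted forms; penalized weights are not provided. MR-PRESSO's distortion
p-value depends on the resampling budget and is reported with the add-one
floor rather than as a closed form.
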