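# Methods

## Design

The package analyses the metabolic consequences of genetic liability to
Alzheimer's disease (AD) across the life course. Liability is the exposure
throughout; metabolites are outcomes. Three arms share one effect scale:

1. **GRS arm.** For each sample, the score `S_i = Σ_j w_j g_ij` sums
   effect-allele dosages weighted by external case-control log odds
   ratios. Each rank-inverse-normalised metabolite is regressed on `S`
   with age and sex adjustment, separately per assessment timepoint. The
   coefficient is in SD units per log-odds of liability.
2. **MR arm.** Within age tertiles, a per-SNP OLS GWAS of each metabolite
   produces SNP→metabolite estimates `Γ_j`; combined with the instrument's
   SNP→liability effects `γ_j`, the Wald ratios `Γ_j/γ_j` are pooled by
   IVW, MR-Egger, weighted median and weighted mode. The four estimators
   fail under different pleiotropy patterns, so their agreement is itself
   evidence.
3. **APOE arm.** rs429358/rs7412 dosages are hard-called and mapped to
   ε-diplotypes; ε4 carriers are contrasted with ε3/ε3 (excluding all ε2
   carriers) and ε2 carriers with ε3/ε3 (excluding all ε4 carriers);
   ε2/ε4 heterozygotes are excluded from both. The contrast is a
   covariate-adjusted mean difference in SD units, not ln2-scaled.

Per-log-odds estimates (GRS slope, all MR slopes) are multiplied by
ln 2 = 0.6931… — estimate, SE and both CI bounds alike — giving SD change
per **doubling** of liability, the conventional reporting scale for binary
exposures. The Egger intercept is an average per-SNP direct effect, not a
liability effect, and is left unscaled.

## Instrument handling

- **Harmonization.** Outcome rows are aligned to the instrument's effect
  alleles: direct matches are kept, swapped rows get `β → −β` and
  `eaf → 1−eaf`, opposite-strand rows are complemented first, and
  irreconcilable rows are dropped with a logged reason. Palindromic (A/T,
  C/G) SNPs are aligned by allele frequency when both tables have an EAF
  further than 0.08 from 0.5, else dropped (configurable: always-drop, or
  assume-same-strand). Harmonization is idempotent.
- **Proxies.** LD proxy *search* is out of scope; a user-supplied map
  (proxy id, r², distance) is consumed, enforcing r² ≥ 0.8 within
  10,000 kb. Weights carry over unchanged.
- **Missing genotypes.** Scores are computed for every sample with at
  least one observed instrument SNP. Default policy rescales the observed
  weighted sum by `Σ_all |w| / Σ_obs |w|`, keeping scores on a common
  scale across missingness patterns; `sum_observed` and
  `mean_dosage_impute` (missing → 2·EAF) are selectable. Which rule a
  given published score used is generally unstated, hence the options.
- **Orientation.** The bundled synthetic instrument codes every effect
  allele as the risk-increasing allele (all weights positive). rs7412 is
  therefore coded by its risk allele C; `apoe_defining_dosages()` recovers
  the ε2-defining T count before diplotype classification.

## Estimators and numerical choices

With weights `w_j = σ_Γj⁻²` and `J` SNPs:

- **IVW** is WLS of `Γ` on `γ` through the origin. Default SE is
  multiplicative random effects: fixed-effects SE × `max(1, √(Q/(J−1)))`
  with Cochran's `Q = Σ w_j (Γ_j − β̂γ_j)²`; the floor at 1 means the SE
  never shrinks below fixed effects (this makes CI coverage mildly
  conservative, ~95.5% in calibration runs). Fixed effects by flag.
  `J = 1` falls back to the Wald ratio with a warning.
- **Wald ratio** SE is first-order `σ_Γ/|γ|`; the optional second-order
  form adds `Γ²σ_γ²/γ⁴`.
- **MR-Egger** orients every pair so `γ_j ≥ 0` (results are invariant to
  per-SNP sign flips), then solves the 2×2 weighted normal equations; SEs
  are inflated by `max(1, √(RSS_w/(J−2)))`. Requires `J ≥ 3` and
  non-constant `γ`.
- **Weighted median** sorts ratios, forms cumulative-weight midpoints
  `p_k = Σ_{i≤k} w′_i − w′_k/2` and interpolates at 0.5. If a single
  instrument carries >50% of normalized weight its ratio is returned
  directly — the estimator's breakdown point — since interpolation
  between neighbours would otherwise dilute a dominant valid instrument.
- **Weighted mode** uses the modified Silverman bandwidth
  `h = φ·0.9·min(SD_w, IQR_w/1.349)·J^{−1/5}` (φ = 1 default) on the
  weighted ratio distribution, evaluates the weighted Gaussian KDE on a
  512-point grid spanning the ratios ± 3h, and refines the argmax by
  bounded scalar minimisation between the flanking grid points (tolerance
  1e-10). Identical ratios (h = 0) return that ratio.
- **Bootstrap SEs** for median and mode: 1000 parametric resamples
  `γ* ~ N(γ̂, σ_γ²)`, `Γ* ~ N(Γ̂, σ_Γ²)` with a fixed seed; reported as
  the resample SD. `n_boot = 0` skips the bootstrap (NaN SE), used in
  Monte-Carlo studies where only point estimates are needed.
- **CIs** use the normal 1.96 quantile throughout (GWAS/MR convention at
  these sample sizes); OLS SEs are classical (`σ̂²(XᵀX)⁻¹`), listwise
  deletion for missing data, no multiple-testing adjustment in primary
  output (CIs are interpreted directly).

## Rank-based inverse normal transformation

Within each timepoint or age stratum (never pooled across ages), observed
values map to `Φ⁻¹((r_i − c)/(n − 2c + 1))` with Blom's offset `c = 3/8`
and average ranks for ties; missing values stay missing. Blom is the
prevailing convention in genetic-epidemiology pipelines; the offset is
configurable since published analyses rarely state it. The transform is
monotone and affine-invariant; outputs are mean ≈ 0, SD ≈ 1.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes:

- Dosages `g_ij ~ Binomial(2, f_j)`, independent across SNPs (linkage
  equilibrium), except rs429358/rs7412 which come from joint haplotype
  draws with frequencies (ε2, ε3, ε4) = (0.08, 0.77, 0.15) — UK-typical —
  so diplotype classification sees realistic joint genotypes.
- Metabolites `M = θ·L + Σ_j α_j g_j + age·slope + sex·diff + ε`,
  `ε ~ N(0, σ²)` with σ = 1 by default; `L = Σ w_j g_j` is the true
  liability. `θ` (default 0.1 SD per log-odds in validation studies) is
  the recovery target; per-allele direct effects `α_j` inject horizontal
  pleiotropy — independent of weights by default (InSIDE satisfied), with
  an option to correlate them with `w_j` for InSIDE-violating stress
  tests.
- Two-sample summary statistics use `se = 1/√(2f(1−f)n)` (the standard
  GWAS variance approximation) and emit outcome alleles on randomized
  strands/orderings so harmonization is exercised on every run.
- Missingness is completely at random at a configurable rate; every
  sample keeps ≥ 1 observed SNP. Timepoints are Gaussian age
  distributions.

What the generator does **not** emulate: LD beyond the APOE pair,
imputation dosage uncertainty, population structure, relatedness,
platform batch effects, non-linear or age-varying effects, and
non-Gaussian metabolite noise beyond what rank-INT absorbs. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to those real-data features.

The bundled 25-SNP instrument is synthetic: familiar AD locus ids with
illustrative weights in the published range (the APOE ε4 SNP dominant at
1.12 log-odds), intended for simulation and examples, not inference about
real data.

## Validation studies (`lifemr.studies`)

All studies derive per-replicate seeds from one integer seed. Problem
sizes were chosen to hold the Monte-Carlo SD of each summary near or
below 1% while completing in seconds on one CPU:

- Estimator recovery: 200 replicates of J = 25 summary pairs at
  n = 2×10⁴ per sample, θ = 0.1; each estimator's mean per-doubling
  estimate is compared with 0.0693 at 2 MC-SE. At this GWAS precision the
  ratio estimators carry ~1% regression-dilution attenuation from noise
  in `γ̂` — a finite-sample property, visible only at ≥500 replicates and
  within the stated tolerance.
- Coverage: IVW CI coverage over 500 replicates; GRS-arm coverage over
  400 replicates of n = 2000 cohorts (larger replicate counts keep the
  binomial SD of the coverage estimate ~1% so the [93%, 97%] band is
  informative).
- Null calibration: 400 replicates at θ = 0 for the GRS-arm test and the
  GRS-confounder check; nominal-5% rejection expected in [3%, 7%].
- Pleiotropy: constant `α_j = 0.02` on every SNP; the Egger intercept
  recovers it (tolerance max(3 MC-SE, 10%) for the dilution above) and
  Egger's slope error beats IVW's in ~100% of replicates (paired sign
  test).
- APOE dominance: direct effects confined to the APOE pair; excluding
  those SNPs attenuates the IVW estimate towards the null in ≥95% of
  replicates.
- Diplotype calibration: simulated carrier-group frequencies against the
  Hardy-Weinberg multinomial, |z| < 4 at n = 2×10⁴.

## Degenerate inputs and edge policies

Constant metabolite vectors are rejected (INT undefined); monomorphic
SNPs in a stratum yield missing GWAS rows with a log entry; samples with
no observed instrument SNP are excluded and reported; APOE dosages are
hard-called only within 0.1 of an integer, otherwise the sample is
unclassifiable; age tertiles are contiguous rank groups with stable tie
breaking, remainder samples going to the youngest groups; a failing
pipeline arm aborts only itself, and a fully empty run raises.

## Known limitations

Classical (non-robust) OLS SEs; no mixed-model GWAS, relatedness or
ancestry correction (eligibility is an input flag); no MR-PRESSO,
contamination-mixture, multivariable MR or Steiger filtering; proxy
discovery and genotype imputation are out of scope; figure rendering is
limited to forest-plot-ready tables.
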