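# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices and the known limitations of mwaskit.

## Quality control

The QC chain assumes a multi-batch untargeted MS study in which abundances
are only relatively quantified, so all corrections are multiplicative
median scalings, never empirical-Bayes adjustments (out of scope by
design). Stage order: run-day normalization → sample exclusion →
metabolite-missingness exclusion → plate masking → batch median
normalization → technical-CV filter → wave-missingness test → kNN
imputation → log2 + winsorization.

* **Sample exclusion** removes samples whose missing fraction exceeds
  mean + 5 SD of the per-sample missing fractions, computed separately in
  the experimental and reference strata so one stratum's outliers cannot
  shift the other's threshold. With zero spread the threshold collapses to
  the mean and nothing is removed. Note that the rule is self-masking in
  tiny strata: a single gross outlier inflates the SD it is judged
  against, so reliable detection needs tens of samples per stratum.
* **Metabolite exclusion** uses strictly-greater-than 30% missingness
  (a 30.0% metabolite is kept).
* **Plate masking** formalizes what is a visual-inspection judgement in
  practice: a (metabolite, plate) group is set to missing when its
  observed median deviates from the batch median by more than 4× in either
  direction, or when over half its values lie beyond 5 SD of the
  metabolite's distribution. Both factors are configurable; masking is
  idempotent.
* **Technical CV** is sample SD / mean (ddof = 1) of the batch-normalized
  reference values, pooled over all reference samples by default; a
  per-batch-then-average variant sits behind `cv_per_batch` because the
  pooling level is a genuinely open choice. The threshold is 0.30.
* **Wave-missingness test**: per metabolite, an exact test on the
  wave × (missing, observed) table. Two waves use the standard 2×2
  minimum-likelihood two-sided Fisher test; for three or more waves no
  exact R×C implementation is available in the scientific Python stack, so
  the R×2 test enumerates the full conditional support when it is small
  (≤ 2×10⁶ tables) and otherwise uses a seeded Monte-Carlo estimate
  (10⁵ draws from the multivariate hypergeometric null, add-one smoothed).
  Flagged metabolites (default α = 0.05/m) are reported; imputation still
  pools waves, as the flag is diagnostic.
* **kNN imputation** (k = 10) works in metabolite space: distances are
  Euclidean over pairwise-complete entries between per-metabolite
  standardized log2 profiles, and a missing cell receives the plain mean
  of its k nearest metabolites' log2 values in that sample (so k identical
  neighbours reproduce their value exactly), transformed back to the
  matrix's scale. Observed values pass through bit-for-bit. Exact-test and
  distance choices are recorded in the run manifest. Imputation quality
  depends entirely on between-metabolite correlation; for uncorrelated
  metabolites the imputed value degrades to a neighbour average unrelated
  to the truth.
* **Winsorization** clips log2 values at mean ± 5 SD with the statistics
  computed once, before clipping (a single pass, not iterated). Clipping
  is monotone, so within-metabolite ranks are preserved.

## Association models

Each metabolite is z-scored on the analysis sample so effects are in SD
units, then fitted with a marginal Gaussian model: depression status as a
3-level factor (controls reference, giving the current-vs-control and
remitted-vs-control contrasts) or the IDS severity score (z-scored), plus
education, sex, age, physical activity (MET-min/week), smoking (ex and
current dummies vs never), alcohol (units/week), chronic-disease count and
shipment batch; BMI joins in a sensitivity model. Rows are complete-case
per model, with `n_used` reported.

Family clustering is handled by GEE with an exchangeable working
correlation and robust sandwich SEs. The solver is written directly in
numpy: for exchangeable clusters the working covariance inverse has the
closed form V⁻¹ ∝ (I − ρ/(1+(m−1)ρ)·J)/(1−ρ), so each iteration reduces
to batched einsums over clusters grouped by size, and a metabolome-wide
scan takes under a second. ρ uses the standard moment estimator with a
degrees-of-freedom correction and is clipped to keep V positive definite.
The solver is validated against statsmodels' GEE in the test suite
(estimates to ~1e-3 absolute, SEs to 1%); with singleton clusters (or the
independence working correlation) it reproduces OLS exactly, which is also
how the follow-up wave is analyzed (`estimator="ols"`, no clusters) since
that wave has no family structure.

The plain sandwich is biased downward in finite samples, which matters at
metabolome-wide significance thresholds: at ~260 clusters the uncorrected
null z-statistics ran 2–3× the nominal rate at p ≈ 2.5e-4, enough to break
FDR control under a global null. Two standard small-sample remedies are
therefore the default: the Mancl–DeRouen bias-corrected meat (per-cluster
residuals inflated by (I − H_g)⁻¹; the classical sandwich remains
available via `cov_correction="none"`) and a t reference with
(n_clusters − n_params) degrees of freedom for Wald p-values. With these,
the null calibration tests hold from the 5% level down to the BH
threshold.

The severity model defaults to metabolite-as-outcome
(`metabolite ~ IDS + covariates`); the reversed direction
(`IDS ~ metabolite + covariates`) is available via
`ModelSpec(reverse_severity=True)` because the outcome role of the two
variables is ambiguous in practice and the sign/significance pattern is
what matters; both directions agree on sign for clear effects.

BH q-values are computed within each contrast family separately (current,
remitted, severity are separate multiplicity families, matching how hit
counts are reported per contrast). `bh_fdr` delegates to statsmodels'
`multipletests` and is checked against a brute-force all-thresholds oracle.

**Antidepressant sensitivity**: the current-MDD contrast is refitted
without AD users; per-class models (SSRI/TCA/SNRI use as exposure, same
covariates, classes with < 10 users skipped) feed the flag rule — a hit
whose absolute class beta exceeds 2× its absolute current-MDD beta is
flagged and removed from the replication candidate set.

**Replication rule**: a candidate replicates iff its follow-up status or
severity association has nominal p < 0.05 and the same sign as the
baseline current-MDD beta; candidates absent from the follow-up tables are
recorded as not assessable (neither success nor failure).

## Pathway enrichment

Hits are intersected with the classified universe (metabolites that carry
a pathway annotation) before testing; each super- and sub-pathway gets a
two-sided Fisher exact test (minimum-likelihood convention, the default of
scipy and of R's `fisher.test`) on the 2×2 hit × membership table, with
directional splits by beta sign. Raw p-values are primary; BH q-values
across pathways within a level are reported alongside. Exact-test
p-values on discrete tables are conservative, never anti-conservative:
uniformity under permutation holds only as super-uniformity, which is what
the tests assert.

## Mendelian randomization

All estimators are implemented from first principles on the harmonized
per-SNP table (bx, sx, by, sy).

* **Instrument selection**: biallelic SNVs only; strand-ambiguous (A/T,
  C/G) variants removed up front, which sidesteps frequency-based
  palindrome inference at harmonization; MAF ≥ 0.01; p < 5×10⁻⁸; greedy
  clumping by ascending p within 10,000 kb at LD r² ≥ 0.001. LD comes
  from a user-supplied pairwise map (the simulator emits one); without a
  map, clumping is distance-only, which is stricter. No reference panel is
  bundled.
* **Harmonization** aligns outcome effects to the exposure's effect
  allele, flipping the sign and frequency where the allele order is
  swapped and dropping irreconcilable variants with a logged reason.
  Harmonization is involutive and invariant to flipping both studies.
* **IVW** is fixed-effect with multiplicative variance inflation
  max(1, Q/(k−1)) — the conventional default of summary-MR software — with
  the uninflated SE also reported. It requires ≥ 2 instruments (the
  single-SNP Wald ratio exists internally for leave-one-out). First-order
  weights ignore sx, giving the textbook O(1/F̄) regression dilution; at
  the default instrument strength (per-SNP r² = 1%, F ≈ 140 at n = 14,000)
  this is ≈ 1% of the estimate and far inside the estimator-consistency
  tolerance.
* **Weighted median**: ratio estimates ordered by value, 50% point of the
  normalized cumulative IVW weights with midpoint linear interpolation; SE
  from a seeded parametric bootstrap (1,000 draws) perturbing bx and by.
* **MR-Egger**: instruments oriented so bx ≥ 0, weighted (1/sy²)
  regression with intercept; multiplicative overdispersion
  max(1, RSS/(k−2)) and a t(k−2) reference, matching standard practice.
  The intercept is the directional-pleiotropy statistic. With finite
  spread in |bx| across instruments, exposure noise leaves a small
  deterministic intercept term ≈ θ·mean(bx)·(1−I²GX); at default settings
  it is well inside the per-fit intercept SE.
* **Cochran's Q** on the Wald ratios with first-order weights bx²/sy²,
  chi-square(k−1).
* **Global outlier test** (≥ 4 instruments): observed RSS of by around
  leave-one-out IVW predictions against a simulated null
  (by\* ~ N(bx·θ̂loo, sy²), θ̂loo re-estimated per replicate), add-one
  smoothed so p ∈ [1/(n_sim+1), 1]. Because the null simulation holds bx
  fixed, the observed residual variance exceeds the simulated one by
  θ²sx²; the p-values are exactly calibrated under the θ = 0 null and
  mildly anti-conservative for strong causal effects (≈ 7% rejection at
  θ = 0.09 with default instruments). Only the global test is implemented;
  outlier removal and distortion assessment are out of scope.
* **Pipeline**: per metabolite passing the ≥ 2-instrument gate, all
  estimators plus diagnostics, minimum per-SNP F = (bx/sx)² against the
  F > 10 adequacy convention, and BH q-values across metabolites on the
  IVW p-values; gated-out metabolites are listed with reasons.

## Synthetic-data generators

`simulate_cohort` defaults describe a desk-scale clinical depression
study: 600 subjects in 260 families (sizes 1–4), 200 metabolites, 2 waves
(80% follow-up retention), 4 batches × 3 run-days × 2 plates, 40 pooled
reference samples, 3% missingness with MNAR weight 0.5, status mix
30/30/40 (control/remitted/current — a clinically enriched design), 20
truly status-associated metabolites at δ = 0.5 SD (remitted effects at
0.7δ, 60% downregulated), one TCA-driven metabolite at 1.5 SD, and
technical CVs log-normal with median 8%.

Mechanics worth knowing:

* Abundance = 2^(log2 signal) × run-day factor × batch factor ×
  multiplicative log-normal technical noise with the metabolite's drawn
  CV. Effects are injected in units of the metabolite's *total* log2 SD
  (biological + technical), so downstream betas on z-scored metabolites
  estimate δ directly up to the variance the effects themselves add
  (≈ 2–4% attenuation, visible as the small negative bias the calibration
  tests bound at 0.02).
* Depression status comes from a probit liability with family random
  effect (intra-family liability correlation 0.3) thresholded at the
  configured proportions; IDS scores are drawn per status (means 8/15/30);
  follow-up status evolves by a fixed transition matrix (so most effects
  persist); BMI tilts mildly with liability; antidepressant use
  concentrates in current MDD (27% SSRI / 10% TCA / 11% SNRI).
* Missingness: cell probability ∝ (1−w) + 2w·(1 − abundance rank), w the
  MNAR weight — w = 0 is MCAR, w = 1 fully low-abundance-driven, and the
  marginal rate equals the configured rate at every w.
* Reference samples share one fixed plasma profile and differ only by
  technical factors and noise.
* `simulate_sumstats` defaults: 20 metabolites (2 causal at θ = 0.09
  log-odds/SD), 20 instruments each at per-SNP r² = 1% (F ≈ 140; strong
  instruments chosen so estimator-recovery properties are not masked by
  the known O(1/F) IVW dilution), exposure GWAS n = 14,000, outcome GWAS
  246,363 cases / 561,190 controls, MAF ~ U(0.05, 0.5), 20% palindromic
  variants (removed at selection), 30 null SNPs per file, 30% of outcome
  rows stored with swapped allele order to exercise harmonization.
  Binary-outcome SEs use 1/sqrt(2·maf·(1−maf)·n_eff·v) with
  n_eff = 4/(1/n_cases + 1/n_controls) and v = 1/4, so the oracle tests
  can reproduce them exactly. Directional pleiotropy is injected aligned
  with the exposure-increasing allele (the orientation MR-Egger fits in);
  allele-frame injection would be re-balanced by the orientation flip and
  undetectable by construction.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: correlated metabolite modules (metabolites
are conditionally independent given the technical factors, so kNN
imputation and pathway-level effect clustering are exercised only by
dedicated fixtures), LD beyond block-diagonal proxy pairs, sample overlap
between the two GWAS, selection/recruitment artifacts, measurement drift
within run-days, and non-log-normal abundance tails.

## Numerical choices and degenerate inputs

Seeds: every stochastic component (generators, bootstrap, outlier-test
null, Monte-Carlo exact tests) takes an explicit seed, recorded in stage
manifests. Ties: weighted-median interpolation uses cumulative-weight
midpoints; clumping breaks p ties by file order (stable sort). Degenerate
inputs fail loudly and specifically: all-missing matrices, metabolites
with no observed values at imputation, non-positive values at log2,
rank-deficient designs (collinear terms are named), < 2 clusters, < 2/3/4
instruments for IVW/median–Egger/outlier tests. A GEE fit with < 30 rows
warns; AD classes with < 10 users are skipped with a warning; an MR run in
which nothing passes the gate returns an empty table and exit code 0.

## Calibration scale

The test suite's calibration loops run at the sizes the package treats as
its reference conditions: 50 replicates of the 200-metabolite global null
and 100 recovery replicates at δ = 0.3 for the association layer; 500
replicates for Egger-intercept recovery and CI coverage, 300 for
outlier-test uniformity. These sizes give Monte-Carlo SEs comfortably
below each asserted tolerance.

## Known limitations

Gaussian GEE only (no GLM links); no random-effects likelihood models; no
longitudinal change-score models — waves are analyzed cross-sectionally.
Enrichment is 2×2 exact tests only (no GSEA-style rank enrichment).
MR: no multivariable MR, Steiger filtering or colocalization; the LD map
must be supplied for r²-aware clumping. The QC plate-masking rule is a
formalization of a human-judgement step and should be re-tuned per
platform.
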