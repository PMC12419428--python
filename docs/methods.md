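# Methods

`mrdietcvd` implements a summary-statistics pipeline for asking whether
dietary habits (binary "never eat X" exposures and a balanced-diet indicator)
causally influence cardiovascular diseases, using two-sample Mendelian
randomization (MR), per-disease meta-analysis, Bayesian colocalization, and
ROC-based candidate-gene evaluation.  This note records the models, the
tunable parameters and their defaults, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was open.

## Two-sample MR

**Model.**  For SNP j, let (β̂ₓⱼ, σₓⱼ) be its estimated effect on the
exposure and (β̂ᵧⱼ, σᵧⱼ) its effect on the outcome (log-odds scale for binary
traits), from non-overlapping samples.  Under the instrumental-variable
assumptions (relevance, independence, exclusion restriction) each Wald ratio
β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect θ.  The ratio SE is first order,
σᵧⱼ/|β̂ₓⱼ|, ignoring exposure-side noise (the conventional default; exact
under the no-measurement-error approximation).

**Estimators.**

- *IVW*: inverse-variance-weighted mean of the ratios, wⱼ = 1/SEⱼ².  Fixed
  SE is √(1/Σw); the multiplicative random-effects SE scales it by
  √max(1, Q/(k−1)).  The `auto` model applies the switching rule used in the
  motivating analysis: random effects when Cochran's Q has p < 0.05,
  otherwise fixed.  IVW-fixed is algebraically identical to zero-intercept
  WLS of β̂ᵧ on β̂ₓ with weights 1/σᵧ² (tested numerically against
  statsmodels).
- *MR-Egger*: WLS of β̂ᵧ on β̂ₓ with an intercept, weights 1/σᵧ², after
  orienting every pair so β̂ₓ > 0 (negating both on a flip — required for
  the estimator's validity; the slope is consistent for θ under InSIDE while
  the intercept estimates mean directional pleiotropy).  Residual dispersion
  is RSS_w/(k−2), not floored at 1; p-values use the t distribution with
  k−2 df.
- *Weighted median*: linear interpolation of the ordered ratios at
  standardized cumulative weight sⱼ = (Σᵢ≤ⱼ wᵢ − wⱼ/2)/Σw = 0.5.  Consistent
  when valid instruments carry a majority of weight.
- *Simple / weighted mode*: argmax over a 512-point grid of a normal-kernel
  density of the ratios with Silverman-type bandwidth
  φ·0.9·min(SD, IQR/1.349)·k^(−1/5), φ = 1 by default; inverse-variance
  weights in the weighted variant.  If all ratios coincide the bandwidth is
  zero and that common value is returned.
- Bootstrap SEs (weighted median, modes) are parametric: ratioⱼ ~
  N(ratioⱼ, SEⱼ²), 1000 draws by default, always seeded so report tables are
  reproducible.

CIs use z = 1.959964 (not scipy's longer constant) so that exponentiated
bounds round-trip against three-decimal rendered tables.

**Instrument processing.**  Selection keeps SNPs with exposure p < 5×10⁻⁶
(the protocol's relaxed threshold for sparse dietary exposures), minus a
user-supplied rsid exclusion list standing in for PhenoScanner confounder
lookups (no network dependency).  LD clumping is greedy on a supplied r²
matrix: visit by ascending p (ties: chromosome, position, rsid — so output
is order-independent), accept iff r² < 0.001 with every accepted SNP within
10,000 kb.  Harmonization aligns outcome records to the exposure's effect
allele, handling swapped and strand-complemented alleles; palindromic (A/T,
C/G) SNPs are kept only when both allele frequencies are outside the
0.42–0.58 ambiguity band (conventional default) and agree in direction.
Missing allele frequencies disable palindromic inference (such SNPs are
dropped) and sdY estimation.

**Sensitivity battery.**  Cochran's Q on the ratios with
I² = max(0, (Q−df)/Q); the Egger intercept test (surfaced from the
estimator, single source of truth); the Steiger directionality check with
per-SNP r² = z²/(z²+n) on both sides (log-odds scale for binary traits —
the observational-scale refinement is out of scope) and a two-sided normal
test on the difference of Fisher-z pooled correlations with variances
1/(n−3); leave-one-out IVW re-fits flagging SNPs whose omission flips the
sign or crosses α = 0.05; and Benjamini–Hochberg FDR applied within
per-outcome-dataset families (the published FDR family is not fully
recoverable from the source tables; the grouping is configurable).

## Meta-analysis

Per disease group, each outcome dataset's IVW odds ratio and 95% CI are
converted back to log-OR and SE = (ln uci − ln lci)/(2·1.959964), then
pooled on the log scale: fixed-effect inverse variance, and
DerSimonian–Laird random effects with τ² = max(0, (Q−(k−1))/C),
C = Σw − Σw²/Σw.  DL is the package's choice of between-study variance
estimator (the motivating analysis names none; the fixed-effect column it
reports is estimator-free).  The report's "sensitivity" column is the
Cochran-Q heterogeneity p of the pooled studies — the best-supported reading
of its role — and is labeled as such.

Reconstructing the published pooled ORs from the published per-study IVW
rows (inputs rounded to 3 decimals) agrees to within ±1 unit in the third
decimal; this is exercised in the test suite and acceptance checks.

## Colocalization

Per SNP and trait, the Wakefield approximate Bayes factor against the null:
with V the variance of the effect estimate, z the association z-score, and
W the prior variance of the causal effect, the shrinkage ratio is
r = W/(V+W) and lABF = 0.5·(log(1−r) + r·z²).  W is 0.2² for case/control
traits and (0.15·sdY)² for quantitative traits, estimating sdY by regressing
2·maf·(1−maf)·n on 1/V through the origin when it is not supplied.

With L1, L2, L12 the logsumexp over SNPs of lABF₁, lABF₂, lABF₁+lABF₂, the
five hypothesis weights are lH0 = 0, lH1 = log p1 + L1, lH2 = log p2 + L2,
lH3 = log p1 + log p2 + logdiff(L1+L2, L12), lH4 = log p12 + L12, softmaxed
into PP.H0–PP.H4; per-SNP SNP.PP.H4 = exp(lABF₁ⱼ+lABF₂ⱼ−L12).  Priors
default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (conventional) and are exposed in
config.  logdiff(a,b) = a + log1p(−exp(b−a)), clamped to −∞ with a warning
if rounding makes b ≥ a; a single-SNP region forces lH3 = −∞.  All sums are
in log space, so lABFs in the thousands are safe.  Regions are the closed
interval ±500 kb around a center position; positions are 1-based and
builds are treated as opaque (positions are only compared within one
dataset).  Both the regional PP.H4 and the per-SNP SNP.PP.H4 are emitted:
summary reports of "PH4" in the motivating analysis conflate the two (its
0.855/0.716 are the SNP-level values), so the output keeps them distinct.
PP.H4 > 0.7 is the support threshold carried into reports.

## ROC evaluation

AUC is the Mann–Whitney statistic (ties half), identical to the trapezoidal
area under the ROC curve; curves place thresholds at unique scores with ties
grouped.  The 95% CI uses the DeLong paired-placement variance by default,
or a stratified percentile bootstrap (2000 seeded resamples) for classes
with fewer than two samples.  AUC > 0.6 sets the high-accuracy flag.  AUCs
below 0.5 are reported as computed with an advisory note — silent direction
flipping would hide label errors.

## Synthetic data

The generators emulate the statistical structure of the real sources so the
whole pipeline is testable offline; they do not reproduce any external
dataset.

- **MR pairs** (`simulate_mr_pair`): summary statistics are generated
  directly, without individual-level genotypes.  Per SNP, maf ~ U(0.05, 0.5);
  the exposure effect is fixed at √(h2_per_snp/(2·maf(1−maf))) on the
  exposure-increasing allele with SE 1/√(2·maf(1−maf)·n) (the standardized-
  trait approximation, reused on the log-odds scale for binary traits);
  the outcome effect is θ·βₓ + α + noise with α ~ N(pleiotropy_mean,
  pleiotropy_sd²) and noise at the outcome SE.  Treating the exposure betas
  as noise-free satisfies the no-measurement-error condition, so IVW
  coverage is nominal by design; regression-dilution effects of noisy
  exposure estimates are deliberately not emulated.  Defaults (K = 30,
  n = 200,000, h2_per_snp = 5×10⁻⁴ giving instrument z ≈ 10) reflect
  biobank-scale dietary GWAS past the 5×10⁻⁶ threshold.
- **Regional LD** (`simulate_coloc_region`): R[i,j] = exp(−ld_decay·|i−j|)
  in index distance (not physical distance) over a uniform position grid
  spanning ±500 kb; per trait z ~ MVN(Rλ, R) with λ placing the scenario's
  non-centrality (default 10, matching the |z| ≈ 10–12 seen at strong lipid
  loci) on the causal index: none (H0), trait 1 or 2 only (H1/H2), distinct
  indices (H3), shared (H4).  Sample sizes default to 100,000 per the
  inclusion rule of the motivating analysis.  Population structure,
  imputation error, and sample overlap are not modeled.
- **Expression** (`simulate_expression`): Normal(shift·group, noise_sd²)
  entries for 111 cases vs 46 controls across six candidate genes; default
  standardized shifts (0.833, 0.571, 0.649 for PSRC1, CELSR2, MYBPHL; 0
  elsewhere) are back-derived from the binormal identity AUC = Φ(d/√2) so
  synthetic AUCs land in the realistic 0.65–0.72 band.  No probe-level or
  batch structure is emulated, so passing tests demonstrate correctness of
  the ROC machinery, not biological reproducibility.

All generators are deterministic given their seed.

## Pipeline

Step 1 (per exposure × outcome): select → clump → harmonize → estimator
battery + sensitivity battery → per-method report rows with grouped FDR.
Step 2: pool IVW rows per disease group.  Step 3: pairs whose fixed-effect
meta p passes BH FDR < 0.1 (the "positive findings" gate; configurable and
logged, since the original gate is ambiguous between meta-p and single-study
FDR) go to colocalization over the ±500 kb window centered on the outcome's
top shared SNP, then optional ROC on a provided expression matrix.  Reports
carry the config hash (analysis parameters, output directory excluded) and
seed on every row; a MANIFEST lists every file with a SHA-256 and the
completion state, and partial outputs survive stage failures.

## Problem sizes in checks

The calibration checks run at the stated study conditions: IVW coverage and
type-I error use 500 replicates of K = 30 instruments at n = 100,000; Egger
intercept recovery uses 200 replicates at K = 100; colocalization power and
specificity use 100 seeded replicates of Q = 100 SNP regions.  These sizes
give Monte-Carlo error comfortably inside the asserted bands (binomial SD
≈ 1 percentage point at 500 replicates).

## Known limitations

- First-order Wald SEs and noise-free simulated exposure effects understate
  weak-instrument effects; no F-statistic filter is applied (none is used in
  the motivating analysis).
- Steiger r² on the log-odds scale is an approximation for binary traits.
- Single-signal colocalization only (no SuSiE/conditional decomposition).
- LD clumping requires a user- or simulator-provided r² matrix; there is no
  reference-panel client.
- The exact family behind the published FDR-P values cannot be recovered
  with certainty; the per-outcome grouping used here is explicit and
  configurable.
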