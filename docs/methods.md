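# Methods

## The causal model

Two-sample MR treats germline variants as instruments for a circulating
exposure X (an adipokine or CRP) and asks whether X causally shifts the risk
of an outcome Y (a breast-cancer endpoint). For SNP *i* with per-allele
SNP-exposure association β_GX,i (estimated in one sample) and SNP-outcome
association β_GY,i (estimated in an independent sample), validity of the
instrument requires relevance (association with X), independence from
confounders, and the exclusion restriction (effects on Y only through X).
Under these assumptions each ratio β_GY,i/β_GX,i estimates the same causal
slope θ, and the estimators here are different ways of pooling the ratios
with different robustness/efficiency trade-offs.

Because the two samples are independent, cov(β̂_GX, β̂_GY) = 0, which is why
the Wald-ratio delta SE carries no covariance term and why exposure and
outcome sampling noise can be simulated independently.

## Estimators and numerical choices

- **Wald ratio** (k = 1): θ̂ = β̂_GY/β̂_GX with first-order two-term delta SE
  √(se²_GY/β²_GX + β²_GY·se²_GX/β⁴_GX). β_GX = 0 is a degenerate instrument
  and is rejected rather than propagated as ±inf.
- **IVW**: weighted regression through the origin, weights w_i = 1/se²_GY,i.
  The fixed-effect SE is (Σ w_i β²_GX,i)^(−1/2). The multiplicative
  random-effects model multiplies it by φ = max(1, √(RSS_w/(k−1))) where
  RSS_w is the weighted residual sum of squares (reported as Cochran's Q).
  The floor at 1 is the underdispersion rule: apparent residual scatter
  below the sampling noise never tightens the interval. φ is reported on
  every estimate and in the run log so the rule is auditable.
- **Correlation-adjusted IVW**: generalized weighting with
  Ω_ij = se_GY,i·se_GY,j·r_ij from a signed-r LD matrix;
  θ̂ = (xᵀΩ⁻¹x)⁻¹xᵀΩ⁻¹y with the same φ floor. If cond(Ω) > 10¹², a ridge of
  1e-8 × mean(diag Ω) is added once; if Ω is still that ill-conditioned the
  fit aborts with a conditioning error. With identity LD this reduces
  exactly to fixed-effect IVW (asserted in the tests).
- **MR-Egger**: SNPs are first oriented so β̂_GX ≥ 0 (the fit is invariant to
  per-SNP sign flips but not to mixed orientations), then a weighted
  regression with free intercept is fitted (via statsmodels WLS; the
  coefficients equal the weighted normal equations, which is how the tests
  check them). P-values use t with k−2 df. The slope SE carries the φ =
  max(1, √(RSS_w/(k−2))) floor, like IVW. The intercept — the
  directional-pleiotropy test — deliberately uses the *unfloored* residual
  scale: with the floor the test statistic is no longer t(k−2) under the
  null and the test becomes conservative (rejection ≈3% at nominal 5%);
  without it the type-I error is exact, which is what a formal test should
  deliver. This is the package's choice for the intercept; the floor
  remains on everything reported as an effect-estimate SE.
- **Weighted median**: ratio estimates sorted ascending with normalised
  inverse-delta-variance weights; with cumulative midpoint weights
  s_i = Σ_{j<i} w_j + w_i/2 the estimate is linearly interpolated where s
  crosses 0.5. The SE is the SD over n_boot (default 1000) parametric
  bootstrap replicates — normal perturbations of β̂_GX and β̂_GY — under an
  explicit seed, so results are reproducible and the study runner derives a
  stable per-pair seed from the study seed.
- **P-values** use the normal reference everywhere except Egger (t, k−2).
  Two-sided p-values are floored at the smallest positive float so extreme
  signals (|z| ≳ 38) keep a representable p in (0, 1]; regional plot data
  recompute −log10 p from the normal log-survival function instead, which
  does not saturate.

## Instrument construction and harmonisation

Significance 5×10⁻⁸, cis window ±1 Mb (closed interval, measured from the
transcription start site supplied in config), clumping thresholds r² < 0.01
(independent) or r² < 0.15 (weakly correlated cis sets). Clumping is greedy
in ascending p with ties broken by (chrom, pos, snp id), so the output is
order-independent.

Harmonisation matches alleles as reported, then as strand complements;
outcome effects reported on the swapped allele get sign-flipped (and eaf
reflected). Palindromic A/T and C/G SNPs cannot be strand-resolved from the
alleles; they are resolved by effect-allele frequency when both frequencies
lie outside the open band (0.42, 0.58) — band edges count as resolvable —
and dropped otherwise, or whenever a frequency is missing. Instruments
absent from the outcome are dropped and flagged; no proxy-SNP search is
attempted. Every SNP's fate (kept / flipped / dropped-and-why) is recorded
in the harmonised set's provenance map and the run log.

## Colocalisation

Per-SNP evidence is the Wakefield approximate Bayes factor
log ABF = ½log(1−r) + z²r/2, r = W/(V+W), with effect-prior SDs W^½ = 0.15
for quantitative and 0.20 for case-control (log-odds) traits — configurable;
the method itself does not fix them. Per-SNP causal priors default to
p1 = p2 = 1×10⁻⁴ and p12 = 1×10⁻⁵, the field-standard values. All hypothesis
sums are accumulated with log-sum-exp; H3's difference term uses a guarded
log-diff that returns −inf when the cross term underflows (e.g. single-SNP
regions). Regions are intersected on SNP id only. The single-causal-variant
assumption is surfaced: any SNP within 2 −log10 p units of the lead but with
r² < 0.1 to it is reported as a secondary peak warning.

The study runner triggers colocalisation per (factor, endpoint) pair at
nominal p < 0.05, over ±100 kb windows (closed) around the exposure's top
instrument SNP.

## The synthetic generator

Summary statistics are drawn from their asymptotic distributions, not from
genotypes: standardized joint effects b are scaled so bᵀΣb equals the
instrument heritability h² (default 0.1), marginal effects are Σb, and
observed effects are multivariate normal with SE 1/√(2f(1−f)n) per allele
(quantitative) or 1/√(2f(1−f)·n·cf(1−cf)) on the log-odds scale
(case-control with case fraction cf). Outcome effects are θ·b plus per-SNP
direct (pleiotropic) effects on the configured invalid fraction — balanced
(zero-mean) or directional. Effect alleles are oriented trait-increasing
(non-negative joint exposure effects), the usual convention when variants
are selected for association with a measured protein; this is what makes
directional pleiotropy direction-consistent relative to the instrument. LD
is AR(1) with ρ = 0.9 per 5 kb grid step by default, or any explicit
matrix. All randomness flows from one seed through counter-based Philox
streams split per operation, so outputs are byte-reproducible.

What the generator does *not* emulate: real allele-frequency spectra and
LD-block structure, sample overlap between cohorts, binary-trait
non-collapsibility (log-odds effects are treated as linear in the score
approximation), winner's-curse selection of instruments, or the true locus
architecture of any real protein. Passing tests therefore demonstrate that
the estimators and the coloc machinery behave as their theory says under
their stated assumptions — not that any particular real-data result is
correct.

### Calibration study conditions

The estimator calibration suite uses 20 independent SNPs, maf 0.3, h² = 0.1,
exposure n = 200,000 ("large n": per-SNP F ≈ 1000, so weak-instrument bias,
of order θ/F, is far below Monte-Carlo resolution), outcome n = 100,000 at
case fraction 0.5. Replicate counts are 2,000 (IVW bias/coverage), 1,000
(Egger intercept type-I), 500 (weighted median vs IVW, 40% invalid SNPs
with directional pleiotropy mean 0.08, about twice a typical causal per-SNP
outcome effect under these conditions). Coloc calibration uses 200-SNP
regions (5 kb grid, ρ = 0.9), causal z = 8, 200 replicates per scenario;
the distinct-variant scenario separates the causal variants by 80 kb so
their r² ≈ 0.034 stays below 0.05.

### The toy study

`make_fixture_tables` writes seven risk factors × three endpoints mirroring
a protein-MR study design: per-factor instrument modes (single-SNP cis for
HGF, leptin receptor and resistin; a weakly correlated 3-variant cis set for
IL-6; 8-, 10- and 3-locus polygenic instruments for adiponectin, CRP and
PAI-1), source-GWAS sample sizes of the corresponding published studies,
and instrument R² values near the published ones — except that the CRP
instrument is scaled down from 45 to 10 independent loci (a problem-size
choice; instrument SNP counts are source-data configuration, not a model
output) and the HGF locus signal is sized (R² = 0.02, expected z ≈ 8) so a
single-SNP instrument clears genome-wide significance reliably across
seeds. Each locus is 41 SNPs on a 5 kb grid (spanning exactly the ±100 kb
coloc window). Two scenarios are planted: PAI-1 → overall risk is truly
causal (θ = 0.6 log-odds per unit, acting through the instrument SNPs, so
the signals share causal variants), and HGF → ER− risk is genomically
confounded (the endpoint's own causal variant sits 30 kb from the HGF index
SNP, r ≈ 0.53): an MR hit whose regional signals do not colocalise. A
random 30% of outcome rows are reported on the opposite effect allele so
harmonisation is genuinely exercised. The full generating truth is written
to `truth.yaml`.

## Known limitations

- No proxy-SNP lookup, no MR-PRESSO/mode-based/multivariable MR, no Steiger
  filtering, no SuSiE-style multi-signal colocalisation or conditional
  analysis, no LD computation from reference genotypes (LD is always
  supplied), no VCF ingestion or liftover.
- R² from summary statistics (Σ 2f(1−f)β²) assumes an SD-scale exposure and
  independent SNPs; for weakly correlated cis sets it overstates the
  variance explained.
- Unit conversion between source GWAS scales is the user's responsibility;
  effects are reported per unit of the exposure on its source scale.
- The coloc posterior is only as meaningful as the single-causal-variant
  assumption; the secondary-peak warning flags violations but does not fix
  them.
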