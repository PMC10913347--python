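# Methods notes

This note documents the models behind `crpfrail`, the choices made where the
design was genuinely open, and what the synthetic-data generators do and do
not emulate.

## Frailty index and cohort models

The deficit-accumulation FI divides the number of deficits present by the
number of items considered (41 by default; the item list is user-supplied).
Boundary conventions are lower-bound inclusive: FI = 0.10 is pre-frailty and
FI = 0.25 is frailty, matching the interval notation health < 0.10,
pre-frail 0.10–0.25, frailty ≥ 0.25. hs-CRP tertile boundaries put 0.90 and
2.00 mg/L in the middle tertile (brackets < 0.90 / 0.90–2.00 / > 2.00);
a data-driven tertile mode is available. Two readings of the grouping rule
coexist in the literature — categorize each wave by its own FI, or both by
the subject's mean FI over the study period — so `frailty_records` exposes a
`grouping` switch; transitions always come from per-wave categories, and
baseline frailty is excluded by the generator's design.

Missing deficit items are imputed by chained equations (statsmodels
`MICEData`, predictive mean matching, which keeps binary items in {0, 1});
default m = 5 imputations, per-subject FI pooled as the mean across completed
datasets. Constant observed items are filled directly (a PMM regression on a
constant outcome is degenerate). Imputation is seeded and reproducible.

Logistic models use maximum likelihood (Newton/IRLS via statsmodels) with
Wald inference; on a single three-level factor the unadjusted ORs equal the
contingency cross-products with Woolf SEs, which is the identity the tests
exploit. Separation is detected from diverging coefficients/SEs and reported
with the offending column. Design choices, each configurable:

* trend tests code tertiles 0/1/2 (tertile-median coding available);
* the spline dose–response uses a hand-rolled restricted cubic (natural)
  spline basis with 4 knots at the 5/35/65/95th percentiles, OR curve
  normalized to OR(1.46 mg/L) = 1, and non-linearity judged by an LRT of the
  nonlinear terms against the linear-in-CRP model;
* stratified models drop the stratifier from the adjustment set by default
  (`drop_stratifier_from_adjustment=False` keeps it); the interaction p is an
  LRT of tertile × stratifier product terms, and a degenerate stratum (no
  cases) flags that stratum and leaves the LRT NaN rather than failing;
* complete-case analysis is the default; imputation is an explicit step.

## Synthetic cohort

Baseline deficit propensity is Beta(2, 14) (mean FI ≈ 0.125, realistic
health/pre-frail split); baseline counts are Binomial(41, q) with frailty
excluded by redraw. The wave-2 *category* is drawn first, from logistic
transition models with common intercepts per baseline category
(pre-frail progression rate 0.074, regression rate 0.339 at the low tertile,
matching the published transition table's margins), and the wave-2 deficit
count is then sampled inside the drawn category's FI band, anchored on the
baseline count. Because the outcome is generated at the category level, the
configured `crp_effect_logodds` (default log 1.66) is the exact conditional
log-OR; the empirical marginal OR is attenuated only by non-collapsibility
over the default covariate effects (~1–2%, verified ≈1.63–1.66 at n = 50 000).
hs-CRP is log-normal(0.29, 0.92), giving tertile boundaries near the fixed
0.90/2.00 mg/L cuts. Covariates carry configurable effects on both the
outcome and log-CRP, so confounding scenarios are one field away.
Missingness is MCAR. Not emulated: item-level correlation structure, MNAR
missingness, attrition between waves, and measurement error in hs-CRP —
tests passing here say nothing about those features of real cohorts.

## Synthetic GWAS pairs

LD is block-diagonal with exchangeable within-block genotype correlation
r_b drawn per block from (0.1, 0.8), so LD scores ℓ = 1 + (B−1)r_b² vary —
variation that is precisely what identifies the LD-score regression slope.
Per-SNP causal effects are bivariate normal scaled to the configured
heritabilities; marginal (LD-aggregated) effects are α_j = β_j + r_b Σ_{k≠j}
β_k, giving E[χ²] = 1 + N h² ℓ/M exactly when all SNPs are causal (the
default; sparse causal sets hold only in expectation over placement).
Sample overlap induces a cross-trait error correlation
ρ·n_overlap/√(n₁n₂), the quantity the pleiotropy scan's Z-correlation step
must detect. When `causal_beta` is nonzero, the outcome effect is
causal_beta·β_exposure plus a direct component carrying the remaining h²;
`rg` then applies to the direct component, so rg = 0 with a causal effect
means valid instruments rather than exactly-canceling correlated pleiotropy.
A share of outcome rows is emitted with swapped alleles (sign and EAF
flipped) or strand complements, and ~10% of SNPs are palindromic (half with
EAF near 0.5), to exercise harmonization; truth tables record everything.

With fully polygenic pairs, per-instrument direct effects dominate the causal
signal, so the MR stage of a default pipeline run shows strong heterogeneity
and a wide random-effects interval — the realistic regime. Clean-recovery
experiments use `generate_instruments`, which draws instrument-level effects
directly (half-normal, i.e. oriented to the exposure-increasing allele, the
convention under which directional pleiotropy is directional).

## LD-score regression

Weights are 1/max(ℓ, 1) in a first pass, updated once with the fitted
conditional variance (for χ²: (1 + Nh²ℓ/M)²; for products: v₁v₂ + mean²).
h² is observed-scale throughout (the frailty GWAS is of a continuous index);
no liability conversion. M and the block count (default 200) are parameters,
with blocks reduced (warning) when SNPs are scarce. r_g inference jackknifes
all three regressions jointly per deleted block. The cross-trait munging
convention drops strand-ambiguous SNPs, whose swap-vs-flip status is
undecidable from alleles. The Bonferroni helper reproduces the 0.05/14
threshold used in the study's correlation screen.

## Pleiotropy scan

Var(z) in the composite-null formula is the empirical variance of each
trait's z after the z² > 80 prefilter — the filter's purpose is exactly to
keep that estimate finite-sample stable. The near-null set for the
Z-correlation estimate keeps |z| < 3.89 (p > 10⁻⁴) on both traits: a tighter
cut (e.g. |z| < 1.96) attenuates a true correlation of 0.5 to ≈0.39 through
double truncation. Decorrelation by the symmetric inverse square root of R
is applied when the estimated |correlation| exceeds 0.05 (threshold ours;
"never"/"always" modes provided, since variance-adjustment-only is an equally
defensible reading).

F(x) is evaluated by the closed form 1 − x(K₀L₋₁ + K₁L₀)(x) (modified Struve
functions) for |x| ≤ 6 — exact and vectorized — and by adaptive quadrature of
the K₀ density beyond, where the closed form loses relative precision to
cancellation; both paths agree to ~10 significant digits on the crossover and
the quadrature path is exposed for cross-checks. Near the origin the
composite-null formula can legitimately exceed 1 (each term is a valid tail
probability); such values are clamped to 1.

## Mendelian randomization

IVW uses first-order ratio weights (βₓ/σᵧ)²; the multiplicative
random-effects SE inflates by max(1, √(Q/(k−1))) and is the primary
estimator. MR-Egger orients exposure effects positive and forces the
residual scale ≥ 1, the convention of the reference implementations; its
constrained-intercept mode collapses to fixed IVW (tested algebraically).
The weighted median interpolates the weighted CDF at 50% with a parametric
bootstrap SE; mode estimators maximize a kernel-smoothed, optionally
weighted ratio density with bandwidth φ·0.9·min(sd, mad)·n^(−1/5), φ = 1 by
default. MR-PRESSO's global statistic is the leave-one-out weighted residual
sum of squares against a parametric-bootstrap null; per-SNP outlier p-values
are Bonferroni-corrected at 0.05/k (the number of simulations bounds the
smallest attainable p at 1/(n_sim+1), so flagging requires n_sim > k/0.05);
the distortion test compares the outlier-corrected shift against random
same-size removals. Maximum likelihood profiles out per-SNP true exposure
effects (residual variance σᵧ² + θ²σₓ²); penalized IVW down-weights SNPs by
min(1, 20·p_j) with p_j from each SNP's χ²₁ heterogeneity contribution;
MR-RAPS adds an additive overdispersion variance τ² and an optional Huber
loss (k = 1.345). Palindrome ambiguity window [0.42, 0.58] on either trait's
EAF, configurable. Clumping without an LD source degrades to distance-only
pruning with a loud warning. Where heterogeneity or a significant Egger
intercept coexists with the IVW primary estimate, the suite surfaces the
tension as a warning instead of silently choosing.

## Numerical and testing notes

All randomness flows through `numpy.random.default_rng` seeds; fixed seeds
give byte-identical outputs. Logistic convergence is Newton with tolerance
1e−8, max 100 iterations. The test suite's simulation sizes (50k-SNP LDSC
runs, 10⁵-pair calibration, 10⁸-draw tail oracle, 1000-replicate coverage)
were chosen so the whole suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted bands. Known limitations:
no real-genotype LD (exchangeable blocks only), no INFO/imputation-quality
modelling, observed-scale h² only, and no multivariable MR.
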