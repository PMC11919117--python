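# Methods

This note documents the statistical content of `mrmediate`: the estimators,
the generative model behind the synthetic test bed, the numerical
conventions, and the places where a genuine design choice had to be made.

## Instrument selection and harmonization

Instruments are variants reaching genome-wide significance (default
p < 5×10⁻⁸) in the exposure GWAS, minus a user-supplied exclusion list of
confounder-associated variants, pruned to approximate linkage independence
by greedy clumping: candidates are visited in order of ascending p-value and
accepted iff their pairwise r² with every already-accepted variant within
the clump window (default 10,000 kb; 1-based, inclusive ends) is at most
`ld_r2_max` (default 0.001). When positions are absent every accepted
variant is compared, which can only prune more, never less. r² values come
from the simulator or a user matrix; the package never computes LD from
genotype panels. Variants missing from the outcome are dropped and logged —
no proxy search is attempted.

Harmonization aligns every trait's effect to the first exposure's effect
allele: swapped alleles flip the effect sign and complement the frequency;
pairs matching only after strand complement (A↔T, C↔G) are complemented
first. Palindromic variants are strand-ambiguous from alleles alone; they
are resolved through allele frequency when it is informative on both sides
(outside 0.5 ± `palindromic_eaf_tol`, default 0.08) and dropped as ambiguous
otherwise. Every dropped variant carries exactly one machine-readable
reason; retained + dropped partitions the candidate list, and harmonizing an
already-harmonized set is a no-op (tested as a property).

Row validation enforces positive SEs, distinct single-nucleotide alleles,
p ∈ (0, 1], and consistency of the stated p-value with the two-sided normal
p of beta/se to 10% relative error (skipped below 1e-280 where the
comparison underflows).

## Univariable estimators

With harmonized per-variant effects (β̂_Xj, β̂_Yj) and outcome SEs σ_Yj:

* **Wald ratio**: β̂_j = β̂_Yj/β̂_Xj, first-order delta SE
  sqrt(σ²_Yj/β̂²_Xj + β̂²_Yj σ²_Xj/β̂⁴_Xj) (optional second-order term).
* **IVW**: weighted least squares of β̂_Y on β̂_X through the origin with
  weights 1/σ²_Yj — algebraically the precision-weighted mean of Wald
  ratios. Cochran's Q on n−1 df measures heterogeneity. The default
  *multiplicative random effects* model scales the fixed-effect SE by
  sqrt(max(Q/df, 1)); fixed effects is available by flag. This default makes
  the test slightly conservative under perfect homogeneity (empirical size
  ~4% at nominal 5%, verified in the suite's null-calibration test), which
  is the standard trade-off in MR practice.
* **MR-Egger**: the same regression with an unconstrained intercept, after
  orienting each variant so the exposure effect is non-negative. The
  intercept estimates average directional pleiotropy in the
  exposure-increasing frame; the slope is a consistent causal estimate under
  InSIDE. Heterogeneity is reported on n−2 df. Egger's intercept relies on
  extrapolating to zero instrument strength; when instrument strengths
  cluster (small coefficient of variation), its power is intrinsically low
  regardless of how strong the pleiotropy is — visible in the generator's
  desk-scale configurations and documented in the test choosing a
  well-instrumented configuration for the detection property.
* **Weighted median**: per-variant ratios sorted ascending, weighted by
  inverse first-order ratio variance (β̂²_Xj/σ²_Yj, the weights of the
  method's original definition), the estimate interpolates the cumulative
  weight midpoints at probability 0.5. Valid while >50% of weight comes from
  valid instruments. The SE is the standard deviation (ddof = 1) of the
  estimate over seeded parametric-bootstrap resamples
  (β̂*_X ~ N(β̂_X, σ_X), β̂*_Y ~ N(β̂_Y, σ_Y); default 1000 draws) — bit-for-bit
  reproducible for a fixed seed.

All p-values use the standard normal reference (the consumed GWASs have
n ≥ 10⁵; t corrections are negligible) and 95% CIs use ±1.96·SE. Binary
outcomes are analyzed on the log-odds scale and reported as OR = exp(β)
with exp-transformed CIs.

## MR-PRESSO

The global test measures the leave-one-out residual sum of squares
RSS = Σ_j w_j (β̂_Yj − β̂_Xj β̂^(−j))², w_j = 1/σ²_Yj, where β̂^(−j) is the IVW
estimate without variant j. Its null distribution is simulated
parametrically (β̂*_Xj ~ N(β̂_Xj, σ_Xj), β̂*_Yj ~ N(β̂_Xj β̂^(−j), σ_Yj),
recomputing the leave-one-out fits per replicate); p-values use the add-one
Monte-Carlo convention, so 1/(n_sim+1) is the smallest attainable value
(default n_sim = 1000, configurable; statistical equivalence with the
reference procedure is the goal, not RNG-stream identity). The outlier test
compares each variant's observed RSS term with its own simulated
distribution, Bonferroni-corrected at α/n_snp (α = 0.05). The distortion
test compares the relative change of the IVW estimate after outlier removal
with the change from removing random subsets of the same size. A single
planted outlier also leaks into the leave-one-out lines of its neighbours,
so occasional secondary flags are expected behaviour of the method, not an
implementation artifact.

## Multivariable MR

MVMR-IVW regresses β̂_Y on the (n_snp × k) exposure-effect matrix without
intercept, weights 1/σ²_Yj, SEs scaled by sqrt(max(Q/(n−k), 1)); k = 1
reduces exactly to univariable IVW. First-order weighting ignores
measurement error in the exposure effects (the NOME approximation standard
in MVMR practice); with weak instruments this attenuates direct effects by
roughly 1/F̄ — one reason the acceptance bound on recovery bias is 5% rather
than zero. Instrument sets are the union of per-exposure selections,
re-harmonized jointly; variants missing from any exposure are dropped with
an explicit reason. MVMR-Egger adds an intercept after orienting on the
first exposure. The conditional F-statistic regresses the target exposure's
instrument effects on the other exposures' (weights 1/σ²_Yj) and scales the
weighted residual sum of squares by the target's instrument variances:
F_cond = Q_x/(n_snp − k + 1), with F > 10 the conventional adequacy rule.
The instrument-validity Q is the weighted residual sum of squares of the
fitted model on n−k df.

## Two-step mediation

Step 1 estimates β₁ (exposure→mediator, per SD) by univariable IVW on the
exposure's instruments; step 2 estimates β₂ (mediator→outcome log-odds,
exposure-adjusted) as the mediator's MVMR direct effect on the union of both
traits' instruments. The indirect effect is β₁β₂ with

* first-order delta SE sqrt(β₂²se₁² + β₁²se₂²), assuming zero covariance
  between the steps (they use non-overlapping samples in a clean two-sample
  design; the real UK-Biobank-based GWASs overlap, an acknowledged
  approximation). At β₁ = β₂ = 0 the first-order variance vanishes; the
  implementation then falls back to the exact product variance
  (+ se₁²se₂²) so inference stays defined.
* an asymmetric 95% CI from the exact distribution of the product of two
  independent normals. The CDF is integrated with a 160-node Gauss–Legendre
  rule on each side of the x = 0 kink (agreeing with adaptive quadrature to
  ~1e-14 away from degenerate corners) and inverted by bisection; a seeded
  Monte-Carlo route is provided and the two agree to three decimals at the
  scales used here. Both converge to the symmetric delta interval as the
  component z-scores grow.
* a two-sided normal p on β₁β₂ / se.

Proportion mediated is reported only when indirect and total effects share a
sign. Classification: *complete mediation* when the direct effect's CI spans
zero while the indirect CI excludes it, *partial* when both exclude zero,
*none* otherwise.

Tabular output rounds effects and SEs to three decimals and formats
p-values with two significant figures; the displayed p is recomputed from
the displayed (rounded) indirect and SE so each printed row is internally
consistent — the convention under which published tables of this kind
round-trip. Full-precision values go to the JSON serialization.

## Synthetic-data generator

The generator is the package's test bed, replacing real GWAS downloads with
a model whose truth is known.

Per variant: minor-allele frequency ~ U(0.05, 0.5), genotypes
Binomial(2, maf), linkage-free by default (optional blocks with declared
within-block r²). Continuous traits are standardized:

    X = Σ γ_j g_j + ε_X                      Var(X) = 1, instruments explain h²_X
    M = β₁ X + Σ δ_j g_j + ε_M               Var(M) = 1, own instruments explain h²_M
    liability = direct·X + β₂ M + Σ α_j g_j
    Y ~ Bernoulli(expit(a + λ·liability))    prevalence fixed (default 5.5%)

Summary statistics are produced exactly as the consumed GWASs produce them:
per-variant simple linear regression for continuous traits and a per-variant
logistic score test (β̂ = U/V, se = V^{-1/2}) for the binary outcome, each in
its own disjoint cohort (default 20,000 per cohort), all randomness flowing
from one integer seed.

Three design choices deserve explanation:

* **Mediator-specific instruments.** A mediator influenced only through the
  exposure makes the MVMR step of two-step mediation unidentifiable (its
  instrument-effect columns are exactly proportional). Real mediators have
  their own GWAS hits, so the generator gives the mediator its own
  instrument set (default 50 SNPs explaining h²_M = 0.20, in line with
  large-biobank mediator GWASs).
* **Two-tier effect sizes.** Half of each trait's instruments carry 90% of
  its heritability. With effects spread equally, every instrument at desk
  scale (50 SNPs, n = 20,000, h² = 0.10) sits just above the genome-wide
  threshold, and p < 5×10⁻⁸ selection then induces several percent of
  winner's-curse attenuation — an artifact of hovering at the threshold that
  the strong tail of a real polygenic architecture does not exhibit. The
  two-tier design reproduces the realistic situation: selected instruments
  are comfortably strong (F ≈ 70), the weak tier stays invisible to
  selection.
* **Marginal-scale calibration.** GWAS effect estimates for a binary trait
  are *marginal* per-allele log-odds; because odds ratios are
  non-collapsible, a conditional liability coefficient of −1.0 would appear
  as roughly −0.91 in the summary statistics no matter how good the MR
  estimator — a property of the estimand, not the method. The generator
  therefore solves λ·κ(λ) = 1, where κ = E[p(1−p)]/(p̄(1−p̄)) is the average
  score-test attenuation factor, by damped fixed-point iteration, so that
  the stated log-odds effects are exactly the marginal estimands the
  logistic score scan measures (to first order in the small per-variant
  effects). When no exact solution exists (extremely dispersed liabilities,
  e.g. very strong pleiotropy) the generator warns and uses the closest
  scale.

Pleiotropy modes: `balanced` draws zero-mean direct variant effects on the
outcome for the exposure's instruments; `directional` shifts the draw three
SDs in the direction of the exposure-increasing allele, so essentially every
direct effect shares a sign — anchoring matters because a positive mean in
an arbitrary allele frame cancels under Egger's orientation and is
undetectable by construction.

A second generator produces k genetically correlated exposures through a
shared genetic factor (defaults: 40 shared SNPs, factor variance 0.15,
loadings 0.9, 20 unique SNPs per exposure explaining 0.06) with only a
subset causal for the outcome (default: the first, −0.46 log-odds per SD).
These defaults were chosen by power analysis so that, at desk scale, the
qualitative two-stage pattern — every correlated exposure "significant"
univariably, only the causal one surviving MVMR — is the expected outcome
rather than a coin flip.

What the generator deliberately does **not** emulate: realistic LD from
reference panels, population stratification, sample overlap between
exposure and mediator cohorts, imputation noise, multi-allelic variants or
indels. Consequently, passing tests demonstrate the correctness and
calibration of the estimators under a clean two-sample design, not
robustness to those real-data complications.

## Problem sizes used in the test suite

Study-scale checks run at the generator defaults (cohorts of 20,000, 50+50
instruments): 200 replicates for parameter recovery and CI coverage, 500 for
null calibration (mediator generation disabled there — it plays no role
under the null), 100 for outlier detection (summary-level fixtures with 21
variants) and for the correlated-exposure pattern. These sizes put 3-SE
Monte-Carlo bands well inside the asserted tolerances while keeping the
suite desk-runnable.

## Known limitations

* First-order MVMR weighting (NOME) biases direct effects by ~1/F̄; the
  conditional F table is the guardrail the package reports.
* The two-sample independence assumption enters the zero-covariance delta
  SE; overlap-aware covariance correction is not implemented.
* The delta-method p-value for a product is a normal approximation; for
  weak components the product-normal CI is the better summary (both are
  always reported).
* No mode-based estimators, MR-RAPS, or Steiger filtering; no
  covariance-aware MVMR with LD-score intercepts.
* Monte-Carlo p-values are bounded below at 1/(n_sim+1); raise `n_sim` when
  smaller resolution is needed.
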