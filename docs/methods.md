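# Methods

## The measurement and its preprocessing

The raw datum per subject is a vector of 24 integrated UHPLC peak areas of
2-AB-labelled IgG N-glycans (GP1–GP24). Peaks are made comparable across
samples by total-area normalisation (each peak divided by the chromatogram
total, ×100), which imposes compositional closure: every row sums to
100%. Because batch effects in this assay act multiplicatively and the
area distributions are right-skewed, downstream correction operates on
natural-log values.

Plate-batch correction uses the parametric empirical-Bayes location–scale
model: per peak g and plate i,

    y_ijg = α_g + X β_g + γ_ig + δ_ig ε_ijg,

with γ shrunk toward a normal prior and δ² toward an inverse-gamma prior,
both moment-estimated across peaks, solved by the standard coupled
posterior iteration (convergence 1e-4 on the relative change of γ*, δ*).
The prior variance of γ uses the population (ddof 0) moment, matching the
widely used `combat.py` lineage; the test suite cross-checks the whole
procedure against the scanpy implementation at 1e-6. The covariate model
X preserves group, age and sex by default: plates are blocked on those
variables by design, so on-design the choice is nearly irrelevant, but
preserving biology is the safer default off-design. A plate perfectly
confounded with a preserved covariate is a hard error; a single plate
yields the identity correction.

GP20 and GP21 (poorly resolved on some plates) are dropped after
correction without renormalising — exclusion is post hoc, the remaining
22 peaks keep their percentage values. Six derived traits are sums of
member peak percentages:

    G0 = GP1+GP2+GP3+GP4+GP6            (agalactosylated)
    G1 = GP7+GP8+GP9+GP10+GP11          (monogalactosylated)
    G2 = GP12+GP13+GP14+GP15            (digalactosylated)
    S  = GP16+GP17+GP18+GP19+GP22+GP23+GP24        (sialylated)
    F  = 14 fucosylated peaks, B = 9 bisecting-GlcNAc peaks.

Traits are computed on the percentage scale, so batch-corrected log values
are exponentiated back first; this keeps the trait formulas dimensionally
meaningful. Whether correction precedes trait computation is a genuinely
open design point; we correct first so that the traits inherit the
cleaned peaks.

For association testing every variable is mapped through the rank-based
inverse-normal transform Φ⁻¹((r−0.5)/n) with average ranks for ties,
giving each variable mean 0 and SD 1 so group effects are comparable
across cohorts of different size. The (r−0.5)/n offset was chosen over
the Blom variant; switching is a one-line change and does not affect any
monotone-invariance property. Samples with any missing peak are dropped
(count logged). All-constant vectors are rejected rather than silently
mapped to zeros.

## Association models

Per cohort, each rank-transformed variable is regressed on a DS indicator
plus age (years, uncentred) and sex (female = 1) by OLS; the DS
coefficient is the standardized effect, with t-based p-values. Cohorts
are pooled by inverse-variance fixed-effects meta-analysis
(w_i = 1/se_i², pooled SE (Σw)^{-1/2}); variables are re-rank-transformed
within each cohort before fitting, which is idempotent with respect to
any earlier pooled ranking. FDR is controlled by Benjamini–Hochberg
across the 28 variables of one contrast (22 peaks + 6 traits); the family
boundary is per contrast, a choice the analysis design leaves open.
Sibling pairs are analysed with a family random-intercept linear mixed
model fitted by REML (statsmodels MixedLM; lbfgs with powell/cg
fallback). At the zero-variance boundary it collapses to OLS; in the
balanced complete-pair case it reproduces the paired t-test exactly,
which the suite asserts.

## The glycan-age shift

Within each cohort and group, the raw-percentage clock traits (G0 and G2
by default) are regressed on age: value = a·age + b. Equality of ageing
rates is tested by the group×age interaction in a single joint model — a
significant interaction would indicate an accelerating divergence
("amplified instability"); parallel slopes indicate a constant offset.
The shift maps the DS expectation onto the control curve:

    Δ(x) = (a_DS·x + b_DS − b_ctrl)/a_ctrl − x,

evaluated on integer ages over the intersection of the two groups'
observed ranges (for parallel lines Δ is grid-independent and equals
(b_DS − b_ctrl)/a_ctrl; mapping control onto DS instead would differ by
O(Δ·|a_DS−a_ctrl|/a_ctrl), negligible near parallelism). A positive Δ
means the DS glycome resembles older controls, for both rising/elevated
traits (G0) and falling/reduced traits (G2). Per-cohort averages are
combined as an unweighted mean; uncertainty comes from a nonparametric
bootstrap resampling subjects within group within cohort (percentile CI,
default B = 500, minimum 200). The control slope sits in the
denominator, so small-cohort shift estimates are heavy-tailed; near-zero
or opposite-sign slopes are a hard error rather than a wild number.

## PCA placement of singletons

PCA uses the correlation matrix (per-variable standardisation) of the
measured peaks; components carry a deterministic sign (largest-magnitude
loading positive). A singleton sample is excluded from the fit, projected
through the stored means/SDs and loadings, and assigned to the nearest
group centroid in the first k = 3 components — matching the practice of
reading cluster membership off PC1–PC2/PC1–PC3 plots. The choice to
exclude the singleton from fitting (rather than refit with it) is
configurable in the library functions.

## Synthetic cohort generator

The generator produces data with exactly the structure the analysis
assumes, so that every estimator can be checked against known truth.

Per subject, latent values of G0, G1 and G2 are drawn around group- and
cohort-specific lines a·age + b with additive Gaussian noise (SD in %
units); S absorbs the compositional remainder after fixed small
fractions for the structurally orphan peaks GP5 (1%), GP20 (0.5%) and
GP21 (0.5%) — G0/G1/G2/S plus those three peaks partition all 24 peaks,
which guarantees exact closure. Trait totals are split over member peaks
by fixed weights (dominant biantennary structures carry most mass); F
and B are emergent, not controlled, because their formulas overlap the
galactosylation groups. Multiplicative lognormal noise is applied per
peak (log-SD 0.03) and per plate (log-SD 0.10, the batch effect), then
rows are renormalised to 100. Draws that break closure or positivity are
redrawn deterministically; configured *mean* lines that break closure
raise an error naming the offending age. Plates are assigned by blocked
randomisation (shuffle within group, deal round-robin across 7 plates).
All randomness flows from one integer seed via named SeedSequence
sub-streams.

Default adult parameterisation: the FRA/ITA/UK cohort designs (sizes
207/110/95 split 109+98, 53+57, 42+53; age ranges 22–67, 22–66, 22–82;
sex ratios and co-morbidity rates per the published cohort tables) and
the six published G0/G2 trend-line pairs per cohort and group. G1 lines
are mild defaults (slope −0.05%/yr, DS 1% lower) — no G1 equations are
published. Trait noise SDs (G0 6.5, G1 3.0, G2 4.0%) were chosen once so
that the default intercept offsets imply standardized effects near the
published values (e.g. FRA G0 offset 4.7% / 6.5% ≈ 0.72 SD). The DS
offset is an intercept shift with equal slopes by default (matching the
parallel-slopes finding); a slope-difference knob exists for power
studies of the interaction test.

For recovery experiments the offset can instead be *calibrated* to a
target standardized effect d: because the rank-INT transform rescales by
the pooled marginal SD, the latent offset solving d is

    offset = d·sqrt((σ² + a²·Var(age)) / (1 − d²/4)),

with Var(age) from the uniform age distribution. The realized pooled
estimate carries a small downward shrinkage from peak-level technical
noise and renormalisation (~0.01–0.02 in practice).

The children cohort (38 DS + 17 euploid, ages 0.5–5.25, single plate)
uses child-range lines: G0 falling from a high infant baseline
(control 25 − 1.0·age), DS offsets +8% (G0) and −3.5% (G2), trait noise
SD 2.0%. These are generator defaults — no child trend equations are
published — anchored to two published features: the clearly separated
DS and euploid clusters in the child PCA (with the segmental-duplication
child inside the DS cluster and outside the euploid range), and a large
rank-INT G0 group effect (the defaults give ≈1.56; the published child
estimate is 1.45 with a wide standard error at n = 38 + 17). The
optional singleton is one extra draw from the DS distribution with a
distinct label. The sibling sub-cohort (35 pairs) adds a family-level
Gaussian random intercept (SD 3%) shared within pairs, recoverable by
the paired model.

What the generator does *not* emulate: non-linear ageing trajectories,
non-Gaussian trait tails, correlated co-morbidity structure, assay
drift within plates, and any realistic absolute peak composition (the
split weights are plumbing, not estimates). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to real-data violations of it.

## Numerical choices and problem sizes

- Closure tolerance 1e-9 on row sums; log transform requires strictly
  positive values (a floor-at-half-minimum policy is available for
  non-positive single peaks, default reject).
- Shift denominator tolerance |a_ctrl| > 1e-6.
- Bootstrap minimum B = 200; percentile (not BCa) intervals.
- Monte-Carlo checks in the suite use sizes chosen for tight-but-fast
  inference: calibration of type-I error at 1000 simulations of n = 60–80
  with a 3σ binomial band; bootstrap coverage at 40 outer replicates of
  n = 200 subjects with B = 200 and a 3σ floor (0.85 for nominal 0.95);
  effect-recovery runs average 20 generator seeds of the full three-cohort
  design (412 subjects per trait per seed).

## Known limitations

- The shift estimator is a ratio; for small cohorts or weak control
  slopes its sampling distribution is heavy-tailed and the percentile CI
  can be wide or asymmetric.
- ComBat assumes the batch model is exchangeable across peaks; with only
  24 peaks the EB priors are estimated from few "genes", so shrinkage is
  coarser than in transcriptome-scale applications.
- The mixed model restricts to a single random intercept (sibling pairs);
  larger pedigrees would need a richer covariance structure.
- Derived traits are computed after back-exponentiating corrected log
  values; when batch effects are large the sum of corrected peaks need
  not equal exactly 100, and no re-closure is applied (matching the
  post-hoc character of the exclusion step).
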