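# Methods

This note documents the statistical model behind the package, the
synthetic-cohort generator and its calibration, the numerical
conventions, and the known limitations.

## Study design being emulated

The analysis shape is a parallel diagnostic-accuracy evaluation: a
cohort of neonatal calves (target ~245 analyzable animals aged 2–6 days
from ~90 herds, 1–6 calves per herd) with a reference serum IgG by
radial immunodiffusion and up to five indirect tests per calf, each test
evaluated against the dichotomized reference (FTPI positive iff
IgG < 10.0 g/L, strict inequality; 8.0 g/L supported as an alternative).
Each test is analysed on its own complete cases, mirroring the per-test
sample sizes that arise in field data.

## Core statistics

- **ROC and AUC.** The empirical curve is computed over the distinct
  observed values of a test plus an all-negative sentinel; under the
  `lower_is_positive` orientation a calf is called positive iff its
  value ≤ cutoff. The AUC is the trapezoidal area, which for this
  construction equals the Mann–Whitney pairwise probability
  P(value⁺ < value⁻) + ½P(tie); the test suite verifies that identity
  exhaustively on small instances. All five tests correlate positively
  with IgG, so `lower_is_positive` is the default everywhere; an AUC
  below 0.5 raises unless explicitly overridden, so an inverted
  orientation can never pass silently.
- **Cutoff selection.** Youden's J = Se + Sp − 1 is maximized over the
  candidate cutoffs; ties are broken by minimal Euclidean distance to
  the ROC corner (0, 1), then by higher sensitivity — deterministic and
  documented because tie handling is a common source of irreproducible
  cutoff tables. Cutoffs are reported on the observed-value scale (not
  inter-value midpoints), matching how such tables are printed in
  practice. Both the corner distance d and its square d² are reported;
  published tables in this field sometimes label the d column "d²", so
  both readings are available.
- **Constrained thresholds.** The rule-in cutoff maximizes Se subject to
  Sp ≥ 95 % (ties resolved toward higher Sp), the rule-out cutoff
  maximizes Sp subject to Se ≥ 95 % (ties toward higher Se); between
  them lies an explicit grey zone in which no confident call is made. An
  infeasible side is reported as undefined rather than silently clamped.
- **Uncertainty and agreement.** Se/Sp intervals are exact
  Clopper–Pearson (binomial-tail inversion via beta quantiles), the
  defining property being coverage ≥ nominal for every true proportion.
  Agreement with the reference is Cohen's unweighted κ at the selected
  cutoff. Paired test-vs-test comparisons use the exact McNemar test
  (two-sided p = min(1, 2·smaller binomial tail) on the discordant
  counts), computed separately within reference-positive calves (Se
  comparison) and reference-negative calves (Sp comparison), on the
  overlap of the two tests' complete cases, each test at its own
  optimal cutoff unless explicit cutoffs are supplied.
- **Design statistics.** Sample size per reference class is
  ⌈z²p(1−p)/d²⌉ with the exact normal quantile (1.959964 at 95 %); the
  total size divides by anticipated prevalence and takes the ceiling.
  At the defaults (p = 0.80, d = 0.10, 95 %, prevalence 0.25) this gives
  62 and 248. Intra-assay CV is per-sample SD/mean over replicates with
  an unweighted min/max/mean summary across samples.
- **Rank comparison of age groups.** The GGT age-group comparison uses a
  two-sided Wilcoxon–Mann–Whitney rank-sum test (exact when both groups
  have ≤ 10 tie-free observations, otherwise the normal approximation
  with midranks, without continuity correction). A signed-rank test is
  sometimes named for this comparison in the applied literature, but the
  two age groups are independent samples, so the rank-sum test is the
  statistically appropriate choice.

## Synthetic cohort generator

The generator's defaults are the study conditions; they are solved in
closed form from the target marginals and correlations — nothing is
tuned by simulation.

- **IgG.** Single log-normal, moment-matched to mean 16.26 / SD 8.91 g/L
  (log-scale σ = √ln(1 + (8.91/16.26)²) ≈ 0.5124, μ ≈ 2.6574). The
  implied FTPI prevalence at 10 g/L is ≈ 0.24 and the implied quartiles
  (≈ 10.1 / 20.1) are tighter than the field-data 8.80 / 22.70 — a
  single log-normal cannot match both moments and quartiles. An optional
  two-component mixture (a low FTPI-prone component and a solved high
  component preserving the overall mean/SD) is provided for closer
  quartile matching; it is off by default because the marginal-moment
  and correlation targets do not need it.
- **Protein measures.** STP_BA, STP_OP and %Brix are linear-Gaussian in
  IgG: slope = r·SD_test/SD_IgG, intercept matching the means,
  noise SD = SD_test·√(1−r²). This hits the marginal moments and the
  Pearson targets (0.87, 0.74, 0.73) exactly in expectation.
- **Albumin and globulin.** ALB = intercept + λ·IgG + γ·e_STP + ε, where
  e_STP is STP_BA's measurement noise. (λ, γ) are solved in closed form
  so that corr(ALB, STP_BA) = 0.60 **and** the derived
  GLOB = STP_BA − ALB has corr(GLOB, IgG) = 0.89. A construction in
  which ALB is independent of IgG given STP_BA would force
  corr(GLOB, IgG) ≈ 0.82, so the small direct IgG loading
  (λ ≈ 0.127) is necessary. One consequence: Var(GLOB) is fully
  determined by the ALB/STP_BA marginals and their correlation, giving
  SD(GLOB) ≈ 7.44 g/L where the field data show 7.84 — those published
  marginals are mutually inconsistent under any joint-Gaussian model
  (SD(GLOB) = 7.84 would require corr(ALB, STP_BA) ≈ 0.49). The
  correlation targets take priority; the recovery tests therefore check
  GLOB via its mean and correlation, not its SD.
- **GGT.** log(GGT) = α_age + β·log(IgG) + ε, i.e. GGT is jointly
  log-normal with IgG, times a multiplicative age factor
  f = 640.46/456.56 ≈ 1.403 for calves ≤ 3 days old. β, the log-noise
  and α are solved from log-normal moment algebra so the age-group
  means (640.46 / 456.56 IU/L), the overall SD (338.90) and the overall
  Pearson correlation (0.67) hold in expectation. A Gaussian link was
  rejected: with these moments it puts ~4 % of mass below zero, and
  flooring at zero biases the recovered mean and SD; the log-normal is
  strictly positive and reproduces GGT's heavy right skew. The
  population overall GGT mean implied by the age composition is
  ≈ 556 IU/L, slightly below the 561.38 target (which arises from a
  younger-skewed measured subsample in field data); the difference is
  within Monte-Carlo error at the validation size n = 10,000.
- **Structure.** Herd sizes are drawn iid from a categorical on {1..6}
  with median 3 (mean ≈ 2.85, so ~90 herds at n = 258); an optional
  additive herd effect on log-IgG (default SD 0) models clustering. Ages
  follow the shares 0–1 d: 1.2 %, 2–3 d: 51.2 %, 4–6 d: 43.8 %,
  > 6 d: 1.2 %, missing: 2.7 % (missing-age calves have a true age in
  2–6 d used for the GGT age effect but no recorded age). Missingness
  is completely at random per test at rates reproducing the per-test
  sample sizes (e.g. 45/245 for %Brix and GGT) — MCAR is an assumption;
  field missingness mechanisms are unknown. One seeded PRNG stream per
  dataset; generation is bit-reproducible given the seed.

### What the generator does and does not emulate

It reproduces marginal means/SDs, pairwise test–IgG and ALB–STP_BA
correlations, prevalence, herd/age structure and missingness rates. It
does **not** model higher-order dependence beyond the stated loadings,
colostrum-management covariates, breed, dam parity, hemolysis or
dehydration effects, inter-operator measurement variation, or
informative missingness. Passing recovery tests therefore demonstrates
that the pipeline estimates the *generating model's* operating points
correctly; it does not certify the field-data cutoffs themselves.

## Numerical conventions

- Quantiles: linear interpolation between order statistics (numpy
  default); sample SD uses the n−1 denominator.
- Missing tokens on input: empty cell, "NA", "NaN" (case-insensitive);
  other non-numeric tokens become missing with a logged warning, while
  structural problems (duplicate herd/calf keys, unreadable files) are
  fatal.
- Age window inclusive [2, 6] days; FTPI threshold strict "<";
  borderline-exclusion interval closed on both ends.
- The borderline sensitivity analysis freezes the main run's optimal
  cutoffs rather than re-optimizing, so its Se/Sp deltas isolate the
  effect of removing hard-to-classify calves.
- Floating-point ties in cutoff selection are compared with a 1e−12
  tolerance; all tie-breaks are deterministic.
- Reported p-values below ~1e−300 underflow to 0 in double precision.

## Validation sizes

Statistical recovery checks run on a cohort of n = 10,000 (correlations
within ±0.02, marginal moments within 3 Monte-Carlo SEs with a
kurtosis-adjusted SE for SDs, operating points at fixed cutoffs within
3 binomial SEs of the analytic values obtained by numerical integration
over the IgG density). The empirical Youden cutoff is checked by *value*
convergence — the generating model's J at the estimated cutoff is within
0.03 of the analytic maximum — because the argmax itself converges at a
cube-root rate and is therefore far noisier than the J value it
achieves. Oracle-equivalence checks are exhaustive on small instances
(all confidence-interval cases with n ≤ 25, all discordant-count pairs
up to 15, ROC instances up to 30 records).

## Known limitations

- The reference (RID) is treated as a perfect gold standard; no
  latent-class correction for reference misclassification is attempted
  (the borderline-exclusion analysis is the provided illustration of
  reference imprecision near the threshold).
- No bootstrap or parametric CI for AUC, no partial AUC, no smoothed
  ROC, and no multiplicity adjustment across tests.
- Herd clustering is ignored in inference (as in the emulated design);
  the generator can produce clustered cohorts for robustness
  experiments, but the estimators remain i.i.d.-based.
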