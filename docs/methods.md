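# Methods

## The classification

An orbit is described by three linear dimensions in millimetres: depth
(D, anteroposterior), height (H, vertical rim-to-rim) and width (W,
mediolateral). Three morphotypes partition the population: A
("Tall & Broad"), B ("Deep & Broad") and C ("Compact"). Two decision
rules assign a type from raw dimensions:

* **Full rule** — `H > 34.35 mm → A`; otherwise `D > 41.65 mm → B`;
  otherwise `C`. The strict `>` in the A and B conditions means exact
  threshold values fall through to C. Width never decides the label;
  when H or D lies within a configurable margin (default 0.5 mm) of its
  threshold, the case is flagged borderline and width is reported as a
  consistency annotation: W > 36.25 mm leans B, W ≤ 34.45 mm leans C,
  no lean in between. The two published width thresholds overlap as
  decision rules (both would claim 34.45–36.25 mm), so this package
  demotes them to mutually exclusive, non-overriding annotations; the
  primary rules already partition the space.
* **Depth-only rule** — `D ≤ d1 → C`, `d1 < D ≤ d2 → A`, `D > d2 → B`
  with d1 = 40.75 and d2 = 41.95 mm. The interval→type mapping follows
  ascending per-type mean depth (C 38.56 < A 40.1 < B 43.52 mm); A
  occupies the narrow middle band, which is why it is recovered least
  reliably from depth alone.

## Synthetic cohort generator

No raw cohort is available, so all distribution-level work runs on
synthetic cohorts from `orbitmorph.synthetic_data`. The generative
model is a three-component mixture:

1. a type label is drawn from the prevalence vector
   (0.335, 0.302, 0.362, renormalized from the printed values, which
   sum to 0.999);
2. each dimension is drawn from `Normal(mean, sd)` restricted to the
   type's `[min, max]` by rejection sampling, with the published
   per-type cells as parameters. Rejection is exact and cheap here: the
   bounds always bracket the mean and the per-pass acceptance rate for
   the default cells is ~95–99 %. Bounds that exclude the mean are
   rejected at construction, so the loop always terminates;
3. dimensions are independent within a type by default. Within-type
   correlations are unpublished; an optional per-type correlation
   matrix (Gaussian proposal, joint rejection) exists for sensitivity
   analyses only;
4. age is `Normal(44.6, 18.1)` years truncated to [8, 88], coupled to
   width by a Gaussian-copula rank coupling. For a bivariate normal the
   Spearman correlation is `rho_s = (6/pi) arcsin(r/2)`, so the latent
   correlation is set in closed form to `r = 2 sin(pi rho_s / 6)` for a
   target `rho_s` (default −0.11); the latent ranks are then matched to
   the observed width ranks, preserving both the age margin and the
   target rank correlation. With the target at 0, age is independent;
5. sex is Bernoulli (male fraction 0.633); optional additive male
   shifts on depth and width default to 0 mm because no per-sex means
   are published. Non-zero shifts are applied after truncation and may
   exceed the per-type range — they are an exploratory knob, not part
   of the default model.

`n` defaults to 499, the published cohort size. (The published per-type
counts sum to 486 and the ANOVA degrees of freedom imply 486 analyzed
orbits; the 13-orbit discrepancy is unexplained in the source, so the
generator targets the printed prevalences and leaves `n` free.)

Because the printed mean/SD are used directly as the *untruncated*
parameters, the moments of the generated values differ slightly from
the printed cells wherever truncation is asymmetric — most visibly
Type C width, whose truncated mean is ≈ 34.09 mm against the printed
34.22. Tests therefore check empirical moments against the
truncated-normal moments computed by numerical quadrature (an
independent oracle), not against the printed cells.

**What passing tests do and do not show.** The generator reproduces the
published marginals, prevalences and the weak age–width rank
correlation. It does not reproduce within-type dimension correlations,
per-sex distributions, scanner (CBCT vs FBCT) effects, left–right
pairing of orbits from the same patient, or measurement error — real
cohorts have all of these. Reproduction tolerances on classifier
accuracies are set wide enough (±2–4 percentage points) to absorb the
independence assumption, which biases rule accuracy slightly low.

## Derivation pipeline

* **Standardization**: per-column z-scores, sd with denominator n−1;
  constants retained for the inverse transform.
* **k-means** (k = 3): Lloyd's algorithm with k-means++ seeding, best of
  10 restarts by within-cluster sum of squares, at most 300 iterations,
  fully seeded. The objective is asserted non-increasing on every
  iteration. An emptied cluster is re-seeded at the point farthest from
  its assigned centroid. Restart count, initialization and iteration cap
  are this package's choices (surfaced as arguments), since no source
  states them.
* **Cluster naming**: greatest mean raw height → A; of the remaining
  two, greater mean raw depth → B; last → C. Exact ties warn and break
  toward the lower cluster index.
* **LDA**: pooled within-class covariance (denominator n−k), priors
  proportional to class sizes (no priors are published), discriminant
  score `delta_k(x) = x'S⁻¹mu_k − mu_k'S⁻¹mu_k/2 + log pi_k`, argmax
  wins. A pooled-covariance condition number above 1e10 is rejected as
  singular. Cross-validation is stratified 5-fold (stratification is
  this package's choice; only "5-fold" is published), seeded, accuracy
  averaged over folds.
* **Threshold extraction**: the stump is constrained to the published
  structure — root on H (A vs {B, C}), child on D (B vs C) — rather
  than grown greedily by impurity, so the derivation yields the same
  *kind* of rule that is published; an unconstrained CART could select
  different variables. Each threshold is an exhaustive search over
  midpoints of consecutive sorted unique values maximizing the accuracy
  of its own split, ties toward the smaller threshold.
* **Depth-only optimization**: exhaustive search over ordered midpoint
  pairs (d1 < d2) maximizing raw accuracy of the C/A/B mapping
  (decomposed into prefix sums, so the scan is O(n log n)); 95 %
  percentile bootstrap over record resamples (B = 1000 by default,
  seeded) for the cut-off CIs. Degenerate resamples (fewer than three
  distinct depths or a missing class) fall back to the point estimate.
  The published optimization criterion is not stated, so the optimized
  cut-off locations themselves are not treated as reproduction targets —
  only the accuracy of the *published* cut-offs is.

## Statistics

η² is SSB/(SSB+SSW); the analytic mixture η² used for checking
simulations is `sum p_k (m_k − m̄)² / (that + sum p_k v_k)`, evaluated
either from tabulated per-type mean/SD as-is or from truncation-adjusted
moments (matching what the generator actually draws; the
`truncation_adjusted` flag selects the form). Kruskal–Wallis uses
midrank tie correction and the χ² approximation — appropriate at these
group sizes; exact small-sample p-values are out of scope. Mann–Whitney
U is computed from midranks; the p-value uses the exact null
distribution when the samples are tie-free and `n_x·n_y ≤ 400`,
otherwise the tie-corrected normal approximation; the rank-biserial
effect size `r_rb = 2U/(n_x n_y) − 1` is positive when the first sample
is stochastically larger. Pairwise post hoc comparisons are Welch t
tests with Bonferroni adjustment (`p_adj = min(1, m·p)`); the
studentized-range (Tukey HSD) distribution is deliberately not
implemented, and published Tukey p-values are not reproduction targets.
Age strata are fixed at 8–30, 31–55 and 56–88 years.

## Numerical conventions

* Indices are computed per orbit at full precision; printed-style
  rounding is half-away-from-zero to 2 decimals (`round_display`).
  Published index means agree with indices of per-type means to 2 dp
  for most cells; the remaining cells differ by one unit in the last
  digit, consistent with mean-of-ratios vs ratio-of-means, and only the
  agreeing cells are used as exact checks.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical inputs give byte-identical cohorts and identical derived
  models.
* Dimension records must be strictly positive; a 15–70 mm plausibility
  window warns without rejecting.

## Problem sizes

Distribution-level checks use one 100,000-orbit cohort (binomial /
Monte-Carlo error on accuracies ≈ 0.15 percentage points). The
cross-validation reproduction uses twenty 499-orbit replicates, matching
the published cohort size. The ANOVA type-I-error calibration uses
10,000 null datasets of 3×10 observations. The whole suite runs in well
under a minute on one CPU.

## Known limitations

* Independence of dimensions within type is an assumption, not a
  published fact; it slightly lowers threshold-rule accuracy relative
  to the published value and slightly alters mixture effect sizes.
* The depth-only cut-off optimizer can legitimately find different
  (d1, d2) than the published pair on re-derived clusters; this is
  expected re-fitting variability, not an error.
* The classifiers are deterministic rules; no posterior probabilities
  under the mixture model are provided.
* Measurement extraction from imaging (segmentation, plane alignment)
  is entirely out of scope; inputs are tabular millimetre measurements.
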