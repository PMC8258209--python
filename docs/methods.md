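# Methods

This note documents the statistical procedures, the generative model
behind the synthetic datasets, and the design choices made where the
field's conventions are ambiguous.

## Specimen filtering

A dissected gut is classified from its prey rows alone: *empty* (no
rows), *unidentifiable-only* (rows, but none identifiable), or
*analyzable* (≥ 1 identifiable item). Analysis retains only analyzable
specimens, and unidentifiable rows inside retained guts are dropped
before any counting, so every percentage downstream is a percentage of
*identifiable* gut contents. The filter summary partitions the input
exhaustively (n_total = n_empty + n_unidentifiable_only +
n_analyzable) and reports percentages of n_total, rendered at one
decimal with half-up rounding (the convention of printed diet tables).
Filtering is idempotent.

## Volume estimation and imputation

Per-item volume uses the ellipsoid (prolate-spheroid) approximation
V = (4π/3)(L/2)(W/2)² with L the maximum length and W the maximum
width in mm. This treats both transverse axes as equal to W; for
elongate soft-bodied taxa (Annelida) no special case is applied — the
same formula is used for all categories.

Fragmented items with a missing dimension are imputed with the mean of
that dimension over *intact, fully measured items of the same category
in the same dataset*; a user-supplied reference table
(category, mean_length_mm, mean_width_mm) supplements or replaces this
when a category has no intact exemplars, and the imputed width is
clamped at the item's measured length. A fragmented item in a category
with neither source of reference dimensions is an error that names the
category — silently guessing a volume would bias %V invisibly.
Identifiable but wholly unmeasured intact items contribute to %N and
%FO but are excluded from both the numerator and denominator of %V,
with a warning (specimen preparation can destroy soft-tissue
measurements without making the item unidentifiable).

## IRI conventions

Two forms of the index of relative importance circulate:

* multiplicative (the original): IRI_j = %FO_j × (%N_j + %V_j)
* additive: IRI_j = %FO_j + (%N_j + %V_j)

Both are implemented; the multiplicative form is the default because
published %IRI values attributed to the index's original source are
typically only consistent with it. The package makes that
arithmetic checkable: under the additive convention the total IRI is
fully determined by the printed %FO values (Σ%FO + 200, since %N and
%V each sum to 100), so a published %IRI share pins its category's %V
exactly; `implied_volume_feasibility` solves the resulting linear
feasibility problem under either convention and reports whether any
non-negative volumetric composition summing to 100 could have produced
the published shares. For the *O. quelchii* composition the additive
reading demands %V values of 68.1 and 101.3 for the two leading
categories — over 169 % of the total volume in two categories — while
the multiplicative reading admits a valid composition; this ships as a
regression test.

## Niche breadth and diversity

Levins B = 1/Σpⱼ² is computed on numerical proportions (%N/100);
feeding the 13-category *O. quelchii* composition through
B_st = (B−1)/(n−1) reproduces the published 0.317, confirming that
convention. The category count n is the length of the supplied
proportion vector, including categories with pⱼ = 0, so B_st is
evenness over the stated category universe; input must sum to 1 within
1e-6 (renormalized exactly inside that tolerance, rejected beyond it).

Shannon–Wiener H′ = −Σ p ln p uses natural logarithms by default: at
richness ≤ 14, published per-group values near 1.7–1.9 are only
attainable in nats. The base is configurable (2, 10). Per-specimen
diversity is computed on each gut's identifiable items; group-level H′
is reported both as the mean of per-specimen H′ and as the H′ of the
pooled category counts, because published group values are ambiguous
between the two conventions. Group *tests* always use per-specimen
values.

## Rank-sum comparisons

`mann_whitney` reports the rank-sum W of the first-named group
(mid-ranks), the equivalent U = W − n_a(n_a+1)/2, and a two-sided
p-value. For n_a + n_b ≤ 20 the p-value is exact: all C(n, n_a)
assignments of the pooled observed values to the groups are
enumerated, and since mid-ranks are a function of the pooled values
this is a full permutation test that handles ties without
approximation (the null distribution of W is symmetric about
n_a(n+1)/2 under exchangeability, which defines the two-sided tail).
Beyond 20 the normal approximation is used with tie-corrected variance
and a 0.5 continuity correction. Tests verify that the enumeration
reproduces the closed-form exact null distribution on tie-free data
and that the approximation tracks the exact p within 0.01 at
n_a = n_b = 10. When grouping by sex, specimens recorded as sex
`unknown` are excluded; a grouping that does not yield exactly two
non-empty groups is an error rather than a silent multi-group test.

## Synthetic data generator

The generator emulates a dissection series: per specimen, sex ~
Bernoulli(sex_ratio); empty with probability p_empty; otherwise
unidentifiable-only with probability p_unidentifiable_only (realized
as 1–3 category-less debris rows, so the discard path is genuinely
exercised); otherwise an analyzable gut.

* **Counts.** Identifiable items per analyzable gut follow a
  zero-truncated count model targeted at a stated mean ± SD. When
  SD² > mean, a negative binomial with size k = mean²/(SD²−mean)
  (moment-matched on the untruncated scale) whose untruncated mean is
  solved numerically so the *truncated* mean hits the target; when
  SD² ≤ mean (as for the 2.5 ± 1.4 preset) a zero-truncated Poisson
  with the rate solved the same way. Sampling is by rejection of
  zeros.
* **Categories.** I.i.d. multinomial draws from the configured
  proportion vector (which must sum to 1 within 1e-9).
* **Sizes.** Per-category lognormal lengths truncated to the
  configured range via a truncated-normal draw on the log scale;
  width = ratio × length with ratio ~ Beta(5, 2) on (0, 1], so W ≤ L
  holds by construction. The per-category log-means are
  order-of-magnitude stand-ins for tepui mesofauna (mites ≈ 0.6 mm,
  beetles ≈ 2 mm, worms ≈ 3 mm), not estimates of real measurement
  distributions.
* **Fragments.** Each item is fragmented with probability
  fragment_prob (default 0.1), realized by withholding the width, so
  the imputation path is exercised.

The two presets mirror the study populations: `quelchii` — 13
categories at the published numerical composition, 111 specimens,
p_empty = 0.054, unidentifiable-only 15/105, counts 2.5 ± 1.4, sizes
0.3–5 mm; `nigra` — 12 categories (the published composition sums to
100.8 due to table rounding and is renormalized), 86 specimens,
p_empty = 0.012, unidentifiable-only 6/85, counts 2.3 ± 1.6, sizes
0.3–3 mm.

Generation is deterministic given a seed. `recovery_experiment` runs
the full pipeline on replicate datasets (replicate r seeds a fresh
generator from the seed-sequence of (seed, r), keeping replicates
independent and the experiment reproducible) and reports bias and RMSE
of empirical %N, B_st and pooled H′ against the generating truth.

What the generator does **not** model: spatial structure across
sampling localities, seasonality, within-specimen category clustering
(items are i.i.d. given the gut), between-sex composition differences,
measurement error or preparation-induced shrinkage, and any
correlation between prey size and category frequency. Passing recovery
and calibration tests therefore demonstrates correctness of the
estimators under these idealized conditions, not robustness to the
messiness of real gut-content data.

## Calibration and problem sizes

The test suite checks, among others: exact reproduction of the
published B_st = 0.317 from the 13-category composition; the empty-gut
percentages 5.4 % (6/111) and 1.2 % (1/86); recovery of the generating
%N (within 3 binomial SE per category) and B_st (mean within 0.02)
over 200 replicate datasets at the quelchii preset; and uniformity of
the sex-comparison p-value under the null (both sexes from one
generator) over 1,000 replicates, by Kolmogorov–Smirnov at α = 0.01.
These replicate counts keep the whole suite at roughly a minute on one
CPU while leaving the Monte-Carlo error of each check well below its
tolerance.

At the study's sample sizes the empirical B_st estimator is slightly
biased downward (≈ −0.015 at ~230 items per dataset): Σp̂² is biased
upward by roughly (1 − Σp²)/N for N items, which is the dominant term.
The recovery tolerance of 0.02 accommodates this known finite-sample
bias; it vanishes as item counts grow.

## Known limitations

* Reference dimensions for fragment imputation come from the same
  dataset's intact items; with very few intact exemplars the imputed
  volumes are noisy, and no uncertainty is propagated into %V.
* %FO confidence intervals and any prey-availability/electivity
  analysis (Ivlev, Chesson) are out of scope, as is multi-group
  testing (Kruskal–Wallis) and niche overlap (Pianka).
* The exact rank-sum enumeration is O(C(n, n_a)) and is capped at
  n_a + n_b = 20 by default; the cap is a parameter, not a hard limit.
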