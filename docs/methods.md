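# Methods

This note documents the models, conventions and numerical choices behind
`croprisk`, and what the synthetic-data generator does and does not
emulate.

## Exposure model

**Buffer.** Exposure is the share of land covered by agricultural polygons
inside a circular buffer of radius *r* (default 1000 m) around the
residence. The circle is approximated by a regular *n*-gon (default
*n* = 128) whose vertex radius is inflated by
`sqrt(2*pi / (n*sin(2*pi/n)))` so the polygon's area equals `pi*r^2`
exactly ("area-true" approximation). An inscribed 128-gon would bias every
index low by ~0.05%; the area-true polygon removes the area bias and
leaves only a boundary-shape error well below Monte-Carlo resolution at
10^5 sample points. Buffer centers must be finite planar metric
coordinates; lon/lat input is rejected rather than silently projected,
because a degree is not a distance and the projection choice (and its
distortions) should be the data owner's explicit decision.

**Index.** For each of the six agricultural classes *c*,
`index_c = 100 * area(buffer ∩ class-c polygons) / (pi*r^2)`; the global
index is their sum. Polygons of class `other` (non-agricultural cover,
including deliberately excluded agricultural types such as non-irrigated
arable land and pastures) contribute nothing. Agricultural polygons must
form a partition: pairwise overlaps beyond tolerance (1e-6 of the buffer
area per buffer, or 1e-3 m² at map level) raise a data-quality error
instead of being double counted, since a land-cover inventory that
overlaps itself is corrupt, not ambiguous. Holes in polygons are respected
(area = exterior − holes). A subject is **exposed** iff the global index
is strictly greater than 0%. A fully covered buffer can accumulate to
100 + O(1e-13)% in floating point; indexes are rescaled onto [0, 100] in
that case.

**Quartile categories.** Per region and per crop type, the zeros are
removed and the 25/50/75 empirical quantiles of the remaining positive
values become cutpoints (q1, q2, q3); every subject is then assigned
category 0 (index = 0), 1 ((0, q1]), 2 ((q1, q2]), 3 ((q2, q3]) or 4
((q3, 100]). Conventions, each configurable:

- *Quantile rule*: linear interpolation between order statistics (the
  default of numpy, R's `quantile` type 7 and most statistical software).
- *Pooling*: quartiles are fitted on exposed cases and controls together,
  so one set of category bounds serves all subjects of a region.
- *Ties*: intervals are right-closed, so an index equal to a cutpoint
  falls in the lower category; with degenerate cutpoints (all positive
  values equal) every exposed subject lands in category 1.
- *Sparsity*: a (region, crop type) with fewer than 4 exposed subjects
  (configurable) gets no scheme; its category column is left missing and
  the categorical analysis for that crop is skipped — this is what
  happens to rice under the default mixture, where almost nobody is
  exposed.

## Estimation

**Plain logistic regression** (single-region analyses) is Newton-scoring
maximum likelihood via statsmodels, with convergence at relative
log-likelihood change < 1e-10 or 100 iterations. Rank-deficient designs,
perfect separation, non-convergence and |coefficient| > 30
(quasi-separation) raise an explicit estimation error; nothing is
penalized or silently dropped. Matching (6:1 on birth year, region, sex)
is deliberately *not* conditioned on — the analysis is unconditional, with
the matching variables available as covariates; the default adjusters are
the two SES scores and the industrial-proximity flag.

**Random-intercept logistic regression** (pooled-region analyses) adds a
per-region intercept deviation `u_g ~ N(0, sigma^2)` and maximizes the
marginal likelihood integrated over `u_g` by adaptive Gauss–Hermite
quadrature: per group, a 1-D Newton search finds the mode of the
integrand, nodes (default 9; 1 node recovers the Laplace approximation)
are centered at the mode and scaled by the local curvature, and the
optimizer (L-BFGS-B over coefficients and log sigma) runs on the summed
log marginal likelihood. Verified against `lme4::glmer` (nAGQ = 9) on a
frozen dataset: coefficients and the variance component agree to ~1e-4.
Numerical conventions:

- A variance estimate at the boundary (sigma below 1e-4, or a marginal
  log-likelihood within 1e-4 of the plain fit's) is reported as exactly
  `random_intercept_sd = 0` with the plain-model coefficients — the ML
  solution in that limit — never hidden.
- Wald covariance of the fixed effects is the inverse observed information
  at the optimum *conditional on the estimated sigma* (the convention of
  lme4 and most mixed-model software); sigma's own uncertainty is not
  propagated.
- A pooled unit whose data subset spans a single region (a rare diagnostic
  group present in one region only) degenerates to the plain fit.

**Odds ratios** are `exp(b)` with Wald intervals `exp(b ± 1.96*SE)`.
Profile-likelihood intervals are out of scope. The **trend test** enters
the 0–4 category (0 = unexposed included) as a numeric score in the
adjusted model and reports the two-sided Wald p-value of its slope; with
few categories and moderate n this is asymptotically equivalent to score
and likelihood-ratio versions, and its null calibration is checked by
simulation. The **eligibility rule** suppresses estimates for any term
with fewer than 3 cases in the exposure category (threshold configurable,
0 disables); suppressed rows keep their counts and a status note, so a
blank is always distinguishable from a failure, and estimation failures
are likewise recorded per row rather than aborting unrelated strata.

## Synthetic worlds

The generator emulates the study design the pipeline targets, not any
real geography. Defaults (all configurable in `SimulationConfig` /
`RegionSpec`):

- **Regions**: five square 30 × 30 km regions, four pooled into a "north"
  analysis unit fitted with the random intercept, one ("madrid") fitted
  alone.
- **Land cover**: 500 m grid cells (25 ha, the minimum mapping unit of
  the CORINE-style inventory being emulated). A Gaussian-smoothed random
  field (smoothing 2 cells) is thresholded so 10% of cells are
  agricultural, forming contiguous farming belts rather than salt-and-
  pepper noise; 30% of the remainder becomes `other`. Agricultural cells
  draw a class from the mixture irrigated .384, heterogeneous .332,
  fruits .156, vineyards .088, olives .031, rice .009 — the relative
  composition of agricultural land in the kind of region the design
  describes. Under these defaults roughly a quarter to a third of
  children have any crops within 1 km, and the exposed have a wide,
  right-skewed index distribution.
- **Population**: locations uniform; birth years uniform on 1996–2011;
  male share 1.28/2.28 (sex ratio 1.28). Census tracts are 1 km grid
  cells: both standardized SES scores (unemployment, socioeconomic
  condition) are drawn once per tract and shared by its residents,
  reproducing the area-level (not individual) nature of census SES.
  Industrial exposure is a binary flag: any of the region's facilities
  (default 25, uniform) within 2.5 km, closed boundary.
- **Outcomes**: `logit P(case) = b0 + log(1.02) * global_index +
  0.10 * (ses_u + ses_c) + 0.18 * industrial + u_region`,
  `u_region ~ N(0, 0.2^2)`. The per-1% odds ratio of 1.02 is the effect
  size the design is meant to detect. The baseline `b0 = -4.2` keeps
  cases rare relative to the control pool so that 6:1 matching never
  plausibly exhausts a (birth year × region × sex) stratum — mirroring a
  registry study, where controls come from the full birth registry —
  while still yielding hundreds of cases at the default population sizes
  (childhood cancer's true ~1/10,000 rarity is scaled up; what matters
  for the methods is the case:pool ratio, not the absolute rate). Cases
  draw a diagnostic group from the 11-group multinomial with weights
  (1062, 92, 245, 711, 398, 139, 212, 57, 114, 200, 120).
- **Matching**: 6 controls per case sharing (birth year, region, sex),
  without replacement within and (by default) across cases; realized by
  shuffling each stratum's pool once and slicing consecutive blocks,
  which is distributionally identical to sequential draws. Exhaustion
  raises an error naming the stratum.
- **Randomness**: one root seed feeds named substreams (landcover,
  population, ses, industry, region_effects, outcomes, matching — keyed
  by CRC of the name and region), so identical configs give byte-identical
  worlds and layers can be regenerated independently.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: real cartography and its digitizing
error, geocoding error in addresses, residential mobility between birth
and diagnosis, spatial correlation of SES with agriculture (SES fields are
independent of the crop field), within-class heterogeneity of pesticide
use, and non-logistic outcome mechanisms. Tests establish that the
*pipeline* is correct and calibrated under its own assumptions, not that
the exposure surrogate is valid epidemiology.

## Problem sizes used in the checks

The replicated experiments fix one exposed population and redraw
outcomes, matched controls and fits per replicate (exposure is fixed by
design in a case–control resampling experiment): parameter recovery uses
one 42,000-child region with `b0 = -3.4`, giving ~2,000 cases and 12,000
matched controls per replicate, 200 replicates in the test suite (100 in
the acceptance script); trend-test null calibration uses 200 independent
fits of n = 800; the geometry oracle compares the overlay result with a
10^5-point Monte-Carlo point-in-polygon estimate on 50 random scenes of
up to 10 polygons; the zero-variance mixed-model check uses four regions
of 5,000 children at a ~10% event rate, where a spuriously positive
variance estimate can no longer move the fixed effects beyond 1e-3.

## Known limitations

- Exact circular-arc clipping is not attempted; the area-true 128-gon is
  the accuracy/simplicity compromise (index error ≲ 0.01 percentage
  points).
- No Firth or other penalized fallback under separation: sparse strata
  fail loudly and are reported as such.
- The mixed model supports a single random intercept (region); no nested
  or crossed effects, no spatial correlation beyond it.
- Quartile schemes are strictly per region; the package never pools
  regions to share category bounds even when their index distributions
  coincide.
- GeoJSON is the only land-cover interchange format (no rasters, no
  shapefiles, no reprojection).
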