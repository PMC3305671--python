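# Methods

## The generative model

The corneal epithelium is modelled, at the level of a sampling circle, as a
ring partitioned into `N` contiguous angular clones. Each clone is
independently β-gal positive with probability `p` (random X-inactivation
makes clone labels exchangeable and independent to first order). Adjacent
same-label clones are indistinguishable after staining and fuse into a
single visible stripe; a circle crossing the stripes therefore sees a
two-state run process. The number of consecutive positive clones in one
positive stripe is geometric with mean `1/(1-p)`, which motivates the
correction

```
w_corr = w_obs * (1 - p_hat),      n_corr = 1 / w_corr,
```

with `w_obs` the observed mean *positive*-stripe width as a fraction of the
circumference and `p_hat` the same eye's circumferential positive fraction.
The expected number of positive stripes on the ring is `N·p·(1-p)` (each
clone starts a positive stripe iff it is positive with a negative
predecessor); the exact expected count of maximal positive runs carries an
extra `p^N` term for the all-positive ring, which has one visible stripe
but no transition. Since the expected total positive width is `p`, the
estimator's plug-in logic is
`n_corr = n_runs / (p_hat·(1-p_hat)) ≈ N`.

`w_obs` is computed over positive stripes only: the `1/(1-p)` factor is the
expected same-class run length *for positive runs*, so applying it to a
width pooled over both colours would mix two different corrections.
Inverting the colours (positive ↔ negative, `p → 1-p`) gives a second,
symmetric estimate of the same `N`; the test-suite checks the two agree in
distribution.

### Estimator bias

`n_corr` is a ratio estimator and is biased upward by `O(1/N)`:
measured by an independent brute-force simulation (20,000 replicate rings
per condition) the mean relative bias is ≈ +5.3% at `N = 20`, ≈ +2.0% at
`N = 50` and ≈ +1.0% at `N = 100`, essentially independent of `p` in
[0.2, 0.8]. These values are frozen in the acceptance tests as the band the
package's estimator must reproduce; for group *comparisons* (the intended
use) the bias is common to all groups and cancels to first order. Rings
that come out entirely one colour have undefined statistics; they propagate
as missing values (NaN) with a warning, never as zeros.

## Circular clonal analysis

- **Circle placement.** The sampling circle is concentric with the corneal
  disc at 80% of the corneal radius by default (configurable), away from
  the ragged limbal margin. Auto-fitting uses the centroid and
  equal-area radius of the non-background mask; manual coordinates pass
  through unchanged, standing in for interactive placement.
- **Sampling.** `n_samples` equally spaced angles (default 720, i.e. 0.5°)
  classified by nearest pixel. Angles are mathematical convention
  (counter-clockwise from +x), radians in [0, 2π); images are row-major
  with (0,0) top-left. Background samples are re-classified from the
  nearest tissue pixel and flagged; more than 5% flagged aborts with a
  quality error rather than guessing.
- **Run extraction.** Wrap-aware run-length encoding; a run spanning the
  0/2π wrap is reported once. Run boundaries sit at the midpoint between
  adjacent samples of differing class, which halves the quantization error
  of boundary estimates. Widths are fractions of the circumference
  (radius-independent) and sum to 1 exactly.
- **Noise filtering.** Runs narrower than `min_run_width` (default
  3 angular samples; 0 disables, which exact oracle tests require) are
  absorbed narrowest-first, ties broken by start angle. Because runs
  alternate in colour, absorbing a run coalesces it with both neighbours,
  so the filter is monotone: larger thresholds never increase run count.
- **RGB inputs.** X-gal blue is detected as blue-dominance: positive when
  `B > (R+G)/2 + margin` (default margin 20/255). There is no published
  threshold; the rule is explicit and configurable.

## Section scoring

Square scoring regions (default five, mirroring the manual liver protocol)
are placed uniformly at random over positions lying fully inside tissue,
non-overlapping by default (overlap would double-count cells), with a
10 × 10 graticule subdivision kept for bookkeeping. Cells are assigned to
regions by centroid, so each cell counts once. The per-animal value is the
pooled proportion positive across regions, which has smaller variance than
the mean of per-region proportions when region sizes are near-equal.
Scoring functions never see genotype metadata — the join happens at the
inference stage — mirroring blinded manual counting.

## Inference

- **Goodness of fit.** Pearson χ² without continuity correction (the
  published statistics 10.46, 26.70 and 0.290 for counts 50/88/81 are
  reproduced only without Yates correction), `df = k − 1`, error below
  expected count 1, warning below 5. The deficiency percentage is
  `100·(1 − observed/reference)`.
- **Two-way ANOVA.** `statsmodels` OLS with sum-to-zero contrasts,
  Type III sums of squares by default (the convention of the commercial
  software typically used for such group comparisons on unbalanced data);
  Types I and II are selectable. Empty design cells raise an error naming
  the cell, since Type III is undefined there. A vectorized batch path
  computes the same Type III decomposition by full-vs-reduced least squares
  for thousands of replicate datasets at once (used for calibration); the
  test-suite asserts the two paths agree, and both are checked against an
  independently coded model-comparison oracle.
- **Post-hocs.** Pairwise cell comparisons use t statistics with the pooled
  residual variance of the full interaction model; p-values are multiplied
  by the number of comparisons actually requested (e.g. genotype within
  each age: 2 for cornea, 3 for liver), capped at 1.

## Synthetic-data generator: what it does and does not emulate

The generators reproduce the *statistical* structure the analysis assumes:
i.i.d. Bernoulli clone labels, contiguous angular clones, a disc-shaped
cornea, ~200-cell scoring fields, Mendelian cross ratios with configurable
heterozygote lethality and complete hemizygote lethality. Clone widths are
equal by default — no width distribution is established for real corneas,
and equal widths make the correction analyzable — with a symmetric
Dirichlet option for width heterogeneity. They do **not** emulate ragged
stripe boundaries, partial-thickness staining, illumination gradients,
age-dependent clone loss dynamics, or spatially correlated X-inactivation
patches; passing tests therefore validate the measurement and inference
machinery, not the biological adequacy of the clone-ring model for any
particular real image.

Defaults used in simulated cohorts: `N = 100` clones, `p = 0.5`
(balanced mosaicism), two eyes per mouse, unbalanced group sizes
8/9/21/22 across the 2 × 2 genotype × age layout — cell sizes in the range
reported for real cohorts (8–22 mice per group).

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give bit-identical outputs, including CSV bytes.
- Run-width conservation is enforced to 1e-9; statistics on runs validate
  that widths sum to 1.
- Large calibrations use the vectorized ring path
  (`calibration.batch_ring_n_corr`), exact for equal-width rings and
  asserted equal to the run-segment pipeline: 10,000-replicate recovery per
  condition and 10,000-replicate null ANOVA calibration run in seconds.
  Enumeration checks of the run-count law go up to `N = 12`
  (4,096 labelings); the render/sample round trip uses a 1024 px image and
  720 angular samples, where pixel quantization (≈ 0.13° at the sampling
  radius) stays well inside one 0.5° sampling step.

## Known limitations

- The corrected stripe number estimates coherent-clone count per
  circumference, not stem-cell number.
- The clone-merging correction assumes independent clone labels; secondary
  cell selection that spatially correlates labels would bias it.
- Auto circle fitting assumes a roughly disc-shaped tissue mask; heavily
  damaged whole-mounts need manual coordinates.
- Real-image segmentation of sections (cell boundaries) is out of scope;
  section scoring operates on label masks with per-cell classes.
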