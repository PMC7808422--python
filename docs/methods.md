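# Methods

## The monitoring problem

When GM maize flowers next to a non-GM field, a fraction of the
recipient's kernels is sired by donor pollen. Regulators cap this
adventitious presence (e.g. the EU's 0.9% labeling threshold), so the
field-average cross-pollination (CP) rate must be estimated — ideally
from a small sample rather than by harvesting every plot. `pollenflow`
evaluates how well common field sampling layouts support that estimate
in smallholder settings, where fields are small and often separated by
unplanted border strips.

The reference measurement is the *full plots survey*: a field divided
into a grid of sampling plots (rows run away from the pollen source),
every plot scored by counting marker-colored kernels. The actual CP
rate of a plot with `n` ears, `Ear_i` marked kernels on ear `i`, and an
average of `AVK` kernels per ear is

    actual_cp = sum_i(Ear_i) / (n * AVK).

## Dispersal model

CP declines with distance from the pollen source and responds to the
unplanted border (isolation) strip of width FB between the fields:

    CP(FB, D) = p0 * 10**(a*FB + b*D),          predictions clamped to [0, 1]

* `D` (m) — distance from the edge of the pollen-source field to the
  near edge of the plot. A plot in grid row `r` of a strip with border
  width FB sits at `D = FB + r * plot_depth`. This convention matters:
  `D` includes the border crossing, so the border coefficient measures
  the *difference* between flight over open ground and flight over a
  maize canopy.
* `b` (per m) — log10 decay per metre of distance; negative.
* `a` (per m) — border effect; positive `a` means an unplanted strip
  attenuates pollen less than the same metres of planted crop
  (`a + b < 0` keeps CP decreasing along any real transect).
* `p0` — CP rate at `FB = D = 0`. The model statement reads `p0` as the
  average CP of the first sampled row; the package computes that
  summary (`p0_first_row`) but by default estimates the intercept
  freely, because when FB varies across the first row the row average
  is `p0 * mean(10**((a+b)*FB))`, which is not `p0`, and pinning the
  intercept there makes exact recovery of `(a, b)` impossible even on
  noise-free data. `p0_mode="fixed"` restores the data-summary reading.

The model is deliberately minimal: no wind anisotropy, no flowering
synchrony, no fat-tailed mixture kernels. It is the standard log-linear
summary used for scheme comparison, not a mechanistic pollen model.

## Synthetic fields

The generator (`pollenflow.field`) emulates the three survey designs:

| preset | grid | plot (m) | border strips | plots |
|---|---|---|---|---|
| 2009-1 | 41 x 40 | 2.5 x 0.75 | none | 1640 |
| 2009-2 | 78 x 40 | 1.25 x 0.75 | 6.75 m behind cols 20-39 | 3120 |
| 2010-1 | 91 x 40 | 1.25 x 0.75 | 7.5 m behind cols 20-39 | 3640 |

Only total plot counts, plot sizes and border widths are fixed by the
survey descriptions; the row-by-column factorizations and the
half-and-half strip split are this package's assumptions (documented in
the preset docstrings, overridable through `FieldGeometry`). The 41-row
factorization gives the 2009-1 field 100 m of depth, so the regime where
CP is effectively zero beyond ~30 m exists on the grid.

Defaults: `a = 0.6261` /m and `b = -0.6784` /m (the coefficients
estimated from the 2009-1 full survey), `avk = 400` kernels,
one first ear per plant (10 plants on a 2.5 m plot, 5 on a 1.25 m plot —
plants sit 25 cm apart along one 75 cm-spaced row per plot, 53,333
plants/ha). `p0 = 0.3` is a package choice: a first-row CP next to a
flowering donor in the tens of percent is typical for adjacent maize
rows, and it leaves the field-average CP well below 1%, matching the
near-zero whole-field means the survey context implies.

Observation noise: each kernel is an independent Bernoulli draw with the
plot's true CP (`binomial`; totals are `Binomial(n_ears*avk, p)`), or an
ear-level Beta random effect with intraclass correlation `rho`
(`beta_binomial`) for overdispersion. `noise_model="none"` returns the
exact rates — used for oracle tests. Draws come from one seeded PCG64
stream in row-major plot order, so a (config, seed) pair reproduces the
field byte-for-byte and every sampling scheme sees the identical field.

What the generator does *not* emulate: wind-direction anisotropy,
day-to-day flowering dynamics, plant loss, spatially correlated noise
beyond the deterministic distance gradient, and measurement error in
kernel counting. Passing tests therefore show that the estimation and
comparison machinery is correct under the stated model, not that the
model describes any particular real field.

## Fitting and the detection limit

A plot can only reveal CP down to one kernel in `n_ears * avk`
(2.5e-4 for 2000 kernels). With `b = -0.6784` /m, CP falls 50-fold per
2.5 m row, so on the default field only rows 0-2 are above detection:
over 90% of plots are left-censored zeros. How those zeros are handled
dominates the statistics, so three fitters are provided:

* `method="log_ols"` (the `fit_dispersal` default): least squares on
  `log10 CP`. `zero_policy="drop"` (default) excludes below-detection
  plots; `zero_policy="floor"` substitutes `1/(2*n_ears*avk)` — half a
  detectable kernel — keeping them in. Dropping zeros leaves a small
  selection bias (a far plot enters only when it got lucky, so its
  log-CP is biased high, pulling `b` toward zero by ~0.06 here);
  flooring is far worse at this decay rate, because the fitted line
  chases the floor plateau and `b` collapses to ~-0.05. Floors are only
  appropriate when the signal stays near detection across the whole
  transect.
* `method="glm"`: Poisson regression of the grain counts with log link
  and `log(n_ears*avk)` offset — the count-scale likelihood. Its
  estimating equations are unbiased at the truth whatever the censoring
  pattern, so this is the method used for parameter-recovery validation
  and the default for the bootstrap pipeline. Numerically, the IRLS
  loop that statsmodels runs by default can stall when most fitted means
  are near zero, so the fit warm-starts from the log-OLS solution and
  uses Newton steps (the log-link Poisson likelihood is concave, so this
  is globally safe); non-finite coefficients or counts confined to a
  single distance raise a fit error instead of returning garbage.
* `method="nls"`: Levenberg-Marquardt least squares on the raw CP scale,
  for sensitivity analysis when the loss should live where RMSE lives.

All methods pin `a = 0` (flagged `a_fixed`) when FB has no variation in
the data, and accept `fix_a` to impose an externally estimated border
coefficient. Degenerate designs (single distance, all-zero CP, FB
collinear with D) raise errors that the pipeline records as failed
replicates rather than numbers.

## Sampling schemes

All nine layouts are parameterized rules on the grid (exact stake-out
coordinates of the original surveys are not available): `T_two`,
`T_four`, `T_six` place k evenly spaced columns sampled at a distance
ladder of (0, 2.5, 5, 7.5, 10, 15, 30) m, densified near the source
where CP changes fastest; `T_cross` adds a lateral centre-row transect
to one longitudinal transect; `T_V` runs two arms from the source-side
corners to the far-side centre; `JM_L` places plots at 0 m and 3 m from
every field edge along four trisecting transects plus the four transect
junctions, and `JM_H` adds the 10 m offsets (so JM_L ⊆ JM_H by
construction); `SYS` is a lattice with seeded random start; `SRS` a
uniform draw without replacement. Metric positions round to the nearest
grid cell with ties to the smaller index, except along V arms where ties
resolve toward the arms' meeting point (this keeps the two arms mirror
images about the centre line). Default parameters reproduce or
approximate the surveys' sample sizes (T_six 42, SYS 42/70/76, SRS
322/355/361).

## Bootstrap pipeline

Per replicate: resample the raw survey, apply every scheme to the same
bootstrap field, fit the model to each sample, predict all plots, and
score against the **raw** survey's actual CP. Resampling modes:

* `within_plot_ears` (default): each plot's total is re-drawn by
  resampling its ears with replacement; ear totals are imputed by an
  equal-probability multinomial split since the plot table stores plot
  totals only. This preserves the spatial CP gradient — an iid resample
  across plots would destroy the very structure the schemes exploit.
* `iid_plots` and `iid_plots_stratified_by_distance`: plot-level
  resampling (whole-field or within distance rows) for sensitivity
  analysis; `none` disables resampling.

SYS/SRS layouts re-randomize per replicate by default (capturing
placement variability); `reseed_per_replicate=False` freezes one
layout, matching the practice of staking plots once. Every random
stream derives deterministically from `root_seed`, so a run is a pure
function of (field, config); re-runs are byte-identical.

Criteria per replicate: RMSE and Pearson r between predicted and
observed CP over all plots; relative error as mean ± SD of
`|pred - obs| / obs` over plots with `obs > 0` (zero-CP plots carry no
denominator and are excluded — the convention is stamped in the
docstrings; alternatives like symmetric errors or floored denominators
belong to the caller); the field-average predicted CP with a
normal-approximation 95% CI (`mean ± 1.96*SD(pred)/sqrt(N)`). Per
scheme: means/SDs across replicates, the 95% percentile bootstrap CI of
RMSE, CI-coverage of the raw-field mean actual CP, and Tukey box-plot
statistics of the replicate mean predicted CP. Percentiles and
quartiles are order statistics at ranks `ceil(q*B)` (1-based, no
interpolation; for B = 1000 the 95% PBCI is the 25th/975th sorted
values), so endpoints are members of the data and results are
bit-reproducible across platforms.

A scheme failing on more than 10% of replicates aborts the run with a
diagnostic; below that, failures are recorded as missing rows and the
effective replicate count is reported, never interpolated.

## Validation problem sizes

The test suite validates at sizes chosen to give clear statistical
verdicts quickly: exact recovery on one noise-free 1640-plot field
(tolerance 1e-9); bias of the count-scale fit over 200 binomial-noise
fields against a 2-Monte-Carlo-SE band; PBCI nominal coverage over 500
simulated Normal-mean datasets with B = 1000 bootstrap draws each
(92.5-97.5% acceptance band); and the scheme comparison at B = 200
replicates, which reproduces the qualitative orderings (full survey
minimal mean RMSE; six transects beat two; SRS has a tighter
predicted-CP IQR than two transects).

## Known limitations

* Under the default (steep) generating coefficients, T_V and SYS
  samples contain at most one distance row above the detection limit,
  so the decay slope is unidentifiable from them and every replicate
  fails — the pipeline's abort rule fires. This is a real property of
  those layouts under a kernel this steep, not a software restriction;
  both schemes fit fine on shallower gradients (e.g. `b = -0.2` /m,
  as in the test suite's small fields). Scheme-comparison runs under
  the defaults therefore omit them.
* The border coefficient is identifiable only when FB varies within one
  survey; the borderless 2009-1 preset pins `a = 0` unless strips are
  added (`with_two_strips`) or `fix_a` is supplied.
* The within-plot bootstrap understates between-plot variance
  components; plot-level modes overstate them by breaking the gradient.
  Neither is a spatial block bootstrap, which is out of scope.
* CI coverage of the field mean is near 100% under the generator's
  benign noise; the sharp coverage differences seen on real surveys
  arise from heterogeneity the generator does not emulate.
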