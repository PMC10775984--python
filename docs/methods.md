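# Methods

`placemaps` benchmarks estimators of the spatial firing-rate map — the
surface r(x, y), in Hz, describing where a spatially tuned neuron (a
hippocampal place cell) fires.  Because the true tuning of a recorded
neuron is unknowable, the package pairs every estimator with a simulation
pipeline that produces sessions with a known ground-truth spike-probability
surface, so that map accuracy can be quantified and mapping parameters
optimized.

## Simulation pipeline

### Arena and sampling

A rectangular open-field arena, default 1.2 m x 1.2 m, with the origin at
the lower-left corner and all distances in mm.  Position is sampled at 50
Hz (f_s = 0.02 s), the standard video-tracking rate.

### Random-walk trajectories

Foraging is simulated as a decision-step walk on a 5 mm pixel grid.  Once
per second of walk time the agent scores every pixel with the sum of five
terms, each scaled to a unit maximum:

* a Gaussian over step distance (mu = 64 px = 320 mm, sigma = 128 px), so
  steps have rat-like speed;
* a von Mises term over the angle to the pixel relative to the current
  heading (kappa = 1), giving heading persistence;
* inverted occupancy over a retrospective 8-minute sliding window
  (min-max normalized), attracting the agent to recently unvisited areas;
* an inverted wall-proximity Gaussian (sigma = 512 px) — weak wall
  repulsion — and a center-proximity Gaussian (sigma = 512 px) — weak
  center attraction.  In the thigmotaxis condition the wall term uses
  sigma = 100 px un-inverted and the center term is disabled; in the
  goal-biased condition a Gaussian around a fixed goal (sigma = 25 px,
  down-weighted by 0.9) is added.

The next position is *sampled* with probability proportional to the
normalized score raised to a concentration exponent (default 16).  A
deterministic argmax — the infinite-concentration limit — degenerates into
straight-line wall-following because nothing breaks the tie between
"straight ahead" pixels; a sharply concentrated stochastic choice keeps
the intended forces dominant while making the walk ergodic.  With the
default concentration, dwell-time maps are near uniform: the coefficient
of variation over interior 100 mm bins of a 64-minute session is about
0.25.

Decision points are joined by straight segments upsampled to 50 Hz,
corrupted with uniform tracking jitter (+-85 mm per coordinate), smoothed
with a second-difference (Whittaker) penalized spline with penalty 128 per
coordinate, and clamped to the arena.  Longer sessions are clipped from
the start to build 4-, 16- and 64-minute variants of the same walk.

### Place cells

A cell's spike-probability surface is the pointwise maximum of one or more
bivariate Gaussian fields on a 1 mm grid.  Field pools come in three size
groups with mean per-axis variances of 4000, 8000 and 16000 mm^2 — 2-SD
radii of 126, 179 and 253 mm — with per-field variation N(0, 1000^2)
clipped at 1000 mm^2, independent x/y variances, and an xy covariance
equal to the mean variance times a N(0, 0.25^2) multiplier clipped to
[-1, 1] (redrawn if the matrix would not be positive definite).  Field
centroids are uniform in the arena.  The number of fields per cell is a
gamma(shape 5.73, scale 0.26) draw clipped above 1 and rounded.

Each field surface is normalized to unit peak and the merged surface is
scaled to a peak of 2 spikes per position sample (a 100 Hz in-field peak
at 50 Hz sampling).  The scale is arbitrary up to the later rate matching:
it is chosen so that the downsampling step below is the binding constraint
for typical target rates, while the accuracy metric (MISE) normalizes it
away entirely.

### Spiking

Per position sample the spike count is Poisson with rate equal to the
surface value at the (jittered) position plus a Poisson background
(lambda = 0.001/sample).  Tracking error and theta-cycle drift are
mimicked by shifting each sample's probability value along the trajectory
by |N(0.01 s, 0.02 s)| with random sign.  Optional overdispersion
multiplies the probability vector by a 1.5 Hz oscillation spanning
0.2–1.8 (unit mean, so expected counts are unchanged).  The raw train is
finally downsampled, uniformly without replacement, to
floor(target x duration) spikes, where the target rate is N(1, 1) Hz
clipped to [0.5, 10]; if the raw train is already smaller, a warning is
issued and the raw train returned.

## Rate-map estimators

All estimators share a grid convention: square bins of side h, the grid
centered on the arena with ceil(extent/h) bins per axis, left-closed
right-open bins, and NaN as the missing-value marker (0 = visited but
silent).

* **Histogram** — spike counts divided by dwell time per bin.  Gaussian
  smoothing (sigma in mm, kernel side 2*ceil(2*sigma/h)+1 bins, unit sum,
  zero padding by default) is applied either to the spike and dwell maps
  before the division (default), to the rate map after the division using
  a missing-value-aware convolution that renormalizes each pixel's kernel
  over its valid neighbours, or not at all.
* **Averaged shifted histogram (ASH)** — spike and dwell histograms on a
  sub-grid of side h/m are smoothed with the separable quartic (biweight)
  kernel weight vector w(i) = m k(i/m) / sum k(j/m), i = 1-m..m-1, which
  conserves counts, then divided.  m = 1 reduces to the unsmoothed
  histogram.
* **Adaptive smoothing** — per bin, a circle grows through 32 linearly
  spaced radii (bin width to 640 mm) until the Skaggs–McNaughton
  criterion r >= alpha / (n_p sqrt(n_s)) holds, with r in bin widths and
  n_p, n_s the enclosed position-sample and spike counts; the bin's rate
  is n_s / (n_p f_s).  Bins never satisfying the criterion are missing.
  The exponents (1, 1/2) are exposed for sensitivity checks.
* **Adaptive binning** — the same search, but the circle stops when it
  encloses at least t seconds of dwell; rate is the enclosed spike/dwell
  ratio.
* Both adaptive methods have two implementations: *pixelwise* (true
  point-to-point distances via a KD-tree) and *convolution* (circular
  unity-gain kernels over pre-binned, zero-padded maps, accelerated by
  reusing one FFT of the map across all radii).  A bin is inside a kernel
  when its center is within the radius.  On simulated sessions the two
  agree with per-bin Pearson r > 0.99.
* **KSDE** — at each query point (bin center), the ratio of Gaussian
  kernel sums over spike positions and over position samples times f_s.
  Data are reflected across the four arena walls before summation (the
  classic reflection boundary correction); query points farther than 50 mm
  from any real position sample are set missing.  Values at a fixed query
  location are independent of the query-grid density, so bin size is pure
  resolution.
* **Temporal KSDE** — the spike train is binned at the position sampling
  interval, convolved with a unit-gain Blackman window (length
  window x 50 rounded to the nearest odd count; 0.125 s -> 7 samples) and
  divided by f_s to give an instantaneous-rate series; each query point
  takes the Gaussian-distance-weighted average of that series (weights
  normalized to unit sum), with the same 50 mm empty rule.  Short windows
  (0.125 s) outperform the 2 s windows used historically.

## Accuracy and objectives

* **MISE** — the rate map is upsampled to the 1 mm truth grid by
  nearest-neighbour interpolation; both surfaces are normalized to unit
  sum over the jointly non-missing support ("unit sum" rather than unit
  peak, since the result is stated in integrated-probability-squared
  units); the score is the Riemann sum of squared differences with
  dx = dy = 1 mm.  It is invariant to rate-map scale.
* **Place-field detection error** — fields are contiguous regions (8-
  connectivity, configurable) larger than 36 cm^2 after thresholding a map
  at 20% of its maximum (missing bins count as sub-threshold); the error
  is the absolute count difference against the 1 mm truth surface.
* **Empty proportion** — fraction of NaN bins (zeros do not count).
* **Computation time** — wall clock around map construction only;
  recorded for the optimization, never asserted against.
* Pearson correlation and Euclidean distance on the same support are
  available as alternative metrics.

## Parameter optimization

A sweep evaluates a full (bin size x smoothing) grid for one method over a
set of simulated cells and averages the four objectives per combination.
Because the search space is a finite evaluated grid, Pareto extraction is
an exhaustive non-dominated sort (a point is dominated if another is <= on
all objectives and < on one) rather than a genetic algorithm; the result
is deterministic and verifiable against a brute-force dominance oracle.
The *balanced* solution min-max normalizes MISE and computation time over
the front and takes the member closest to the utopia point (the front
minima), ties toward smaller MISE.  Bin-size and smoothing selections can
be regressed on field radius r (mm) and duration d (min) with OLS planes,
and published plug-in coefficients for both the minimum-error and balanced
solutions of all six methods ship with the package
(`placemaps.optimization.TABLE1_DEFAULTS`); entries whose optimal bin size
is "smallest available" return the caller's minimum bin size.

## Pre-map heuristics

* **Field size from spike clustering** — Ripley's K over the arena
  rectangle without edge correction, K(r) = mean neighbour count within r
  divided by the point density; L = sqrt(K/pi), H = L - r.  The field
  radius estimate is 0.75 x argmax H over 64 radii from 5 mm to half the
  arena width.  The absent edge correction biases H increasingly negative
  at radii comparable to the arena, which is why the radius grid stops at
  half the width; the 0.75 factor compensates the peak's overshoot for
  non-isolated clusters.
* **Bin-size rules of thumb** — Sturges: ceil(log2 N + 1) bins per axis,
  bin size = width/nbins truncated to whole mm (truncation, not rounding,
  matches the printed reference values).  Freedman–Diaconis: bin width
  2 IQR N^(-1/3) applied per axis (returning the larger width) or to the
  L2 norms of the positions.

## Problem sizes and numerical choices

The full-scale study design (3 durations x 3 field-size groups x 256
cells x dense parameter grids x 6 methods) is a cluster-scale computation.
The package's own benchmark (`scripts/acceptance.py`) runs the same
pipeline at desk scale: 8 random-walk trajectories of 16 minutes, a
96-cell cohort (32 per size group) for field-size recovery, and a 24-cell
cohort with an 8x8 log-spaced adaptive-binning grid for the error-surface
analysis.  The adaptive-binning sweep floors its bin axis at 4 mm rather
than 1 mm: at 1 mm the convolution counting stacks are 1.44M bins x 32
radii per map, and the correlation between the MISE and field-error
surfaces — the quantity of interest — is computed over the same grid
either way.

Other numerical choices: seeded `numpy` Generators everywhere (identical
seeds give bitwise-identical trajectories, cells and spike trains); FFT
disc-convolution results are rounded back to integers when the inputs are
counts; Gaussian kernel sums use the |q|^2 + |x|^2 - 2 q.x expansion in
chunks (BLAS matmul plus one exp per pair), with the KD-tree-truncated
"native" KSDE path cut off at 8 sigma; ties in the balanced selection
break toward smaller MISE; empty Pareto fronts, rank-deficient regression
designs (fewer than 6 points or no independent variation in r and d) and
degenerate inputs (empty trajectories, zero IQR, fewer than two Ripley
points) raise errors rather than guessing.

## What the simulations do and do not show

The generator reproduces the statistical structure of open-field
place-cell recordings: uniform-ish coverage with realistic speeds and
tracking jitter, anisotropic multi-field Gaussian tuning, Poisson spiking
with background activity, rate heterogeneity across cells, and optional
overdispersion and sampling bias.  It does not model alleyway or maze
geometries (no wall-aware smoothing is needed or provided), 3-D flight
trajectories, head-direction or grid-cell tuning, theta-phase coding
beyond a temporal jitter, or non-Poisson interval structure.  Estimator
rankings established here therefore speak to open-field data; maps for
strongly compartmentalized environments raise smoothing-across-walls
issues the package does not address.
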