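# Methods

This note records the models behind `nodeloc`, the defaults and where they
come from, the numerical choices, and what the simulation framework does and
does not capture about real node networks.

## Signal propagation model

RSS is modelled as `RSS(d) = a·exp(−S·d) + K` with `a > 0`, `S > 0` and, for
any realistic receiver, `K < 0`.  This three-parameter exponential was chosen
over the indoor-standard log-distance path-loss family because in cluttered
outdoor environments signal bounce and shadowing make log-distance fits
poor; the exponential-with-asymptote captures the empirically observed rapid
attenuation onto a noise floor.  The packaged default curve,
`a = 47.23, S = 0.005 /m, K = −105.16 dB` (`nodeloc.GUAM_DECAY_MODEL`), was
fitted to a 72-node field network on Guam and serves as the generator for
all simulations when no site-specific calibration is supplied.

Fitting uses `scipy.optimize.curve_fit` (Levenberg–Marquardt) with a
closed-form self-start: `K₀ = min RSS − 1`, `a₀ = max RSS − K₀`, `S₀` from
the slope of `log((RSS − K₀)/a₀)` against distance.  The fit is unweighted
by default; a `weights=` argument accepts per-window detection counts for
users who prefer inverse-variance weighting of window means.  Preconditions:
≥ 4 observations spanning ≥ 2 distinct distances, RSS within the receiver
reporting range [−120, −30] dB.

### Inversion and the asymptote guard

The closed-form inverse `d = −ln((RSS − K)/a)/S` is only informative on
`K < RSS ≤ a + K`.  Readings above `a + K` (stronger than the modelled
zero-distance signal) map to distance 0.  Readings within `eps = 0.5` dB of
the asymptote map to a non-informative sentinel (infinite by default): below
the guard, the derivative `dd/dRSS` exceeds ~400 m/dB for the default curve,
so sub-floor readings carry essentially no distance information.  The
localizer *drops* guarded nodes rather than assigning them a huge range.
Note one consequence: this guard already removes the most pathological far
nodes even from *unfiltered* trilateration, so unfiltered baselines here are
better than a pipeline that feeds every detection into the solver.

## Detection processing

Detection logs are per-pulse rows (tag, node, RSS, UTC timestamp; receiver
clocks are assumed GPS-disciplined, no drift correction).  For stationary
calibration tests the convention is a 5-minute window trimmed by 60 s at
each end (guarding against clock/GPS mismatch at the boundaries) and
arithmetic per-node averaging, which damps multipath outliers.  For
free-moving animals the windowing is configurable; the default is a 60 s
window with a 60 s stride, a convention chosen to match common 1–15 s pulse
intervals (tens of pulses per window) while keeping the stationarity
assumption within a window tolerable.

## Trilateration

The estimate minimizes `f(p) = Σ (‖p − nodeᵢ‖ − dᵢ)²` over p ∈ R², the
standard range-residual multilateration objective.  Implementation:
Gauss–Newton with step-halving line search, seeded at the strongest-signal
node (ties broken to the smallest node id, for determinism under exact RSS
ties).  Convergence is declared when the accepted step is < 1e-6 m; the
iteration also stops when line search cannot reduce the objective or when
the relative objective decrease falls below 1e-10 — the latter matters when
an estimated distance is exactly 0 (RSS above the zero-distance value),
which puts a gradient kink at that node.  The iteration cap is 200: on noisy
few-node instances Gauss–Newton converges linearly (step ratio ~0.7), and a
small percentage of realizations legitimately needs more than 50 iterations
to reach the metre-microscale tolerance.  Exactly collinear node sets are
solved (least-squares fallback) but flagged `ill_conditioned`.  Fewer than
3 usable nodes yields status `too_few_nodes`, never an exception.

The range-residual surface can be multimodal when nodes with conflicting
long ranges surround the start from one side; the filters' anchored
geometry (nodes clustered around the strongest node) keeps the surface
well-posed in practice, and the test suite verifies Gauss–Newton against an
exhaustive 1-m grid search on instances drawn from the actual pipeline.

## Filters

- RSS filter: keep nodes with mean RSS **strictly greater** than the cutoff
  (boundary readings excluded), cutoff in [−120, −30] dB.
- Distance filter: keep nodes within `radius` of the strongest-signal node
  (anchor always retained).  The radius is `multiplier × avg_spacing_m`, or
  an absolute radius when replicating reported configurations whose printed
  radii (e.g. 315 m for a 250 m grid at 1.25×) are not exact multiples.
  `avg_spacing_m` is the nominal grid spacing for uniform layouts and the
  mean distance to the six nearest neighbours for irregular ones.

Stricter cutoffs/radii always retain subsets of looser ones (tested as an
invariant).  Filtering happens before range inversion and never mutates its
input.

## Simulation framework

**Geometry.**  The study square is 1250 m per side.  Uniform grids anchor at
the origin with nodes every `spacing` (13×13 = 169 nodes at 100 m,
8×8 = 64 at 175 m, 6×6 = 36 at 250 m).  The irregular layout jitters each
uniform-grid node uniformly within its grid cell (clipped to the square),
keeping exactly one node per cell.  Test locations are uniform over the
square; an experiment draws one RSS vector per (location, replicate) and
evaluates *every* filter on that same draw, so filter contrasts are paired.
Replication scale is 100 locations × 1000 replicates per configuration;
reduced-replicate runs (×20–×60) give the same means to within a few
percent and are used where ordering, not precision, is being checked.

**Parametric noise (default).**  A detected reading is
`RSS(d) + N(0, σ²)` clipped to [−120, −30] dB with σ = 6 dB, a typical
residual spread for window means in cluttered outdoor sites.  Detection is
Bernoulli with logistic probability in distance,
`p(d) = 1/(1 + exp((d − d50)/s))`, with `d50 = 826.85 m`, `s = 100 m`.
These two numbers are calibrated, not free: `d50` is solved (by quadrature)
so that the mean detecting fraction across the 100 m grid and the study
square equals 112.82/169 ≈ 0.668 — the detecting fraction implied by the
reference field-resampling experiment — and the steepness was selected
against the reported no-filter and RSS-filter node-count columns of that
experiment across all three grids (the distance-filter columns were held
out as validation).  A steep transition is also what window-level detection
physics predicts: a window is detected if *any* of its ~60–100 pulses is
decoded, which sharpens the per-pulse detection curve substantially.  The
defaults leave detection near-certain to ~400 m and rare (p ≈ 0.15) at 1 km.

**Empirical noise.**  Alternatively a measured calibration table of
(distance, RSS) pairs is resampled: observations are binned at 10 m; a query
draws uniformly from the nearest non-empty bin within ±25 m, and an empty
neighbourhood is a non-detection.  This mirrors how one would propagate a
field site's own noise into design simulations; dropout then emerges from
gaps in the table rather than from a parametric curve.

**What the generator does not emulate.**  Draws are independent across
nodes, locations and replicates — no spatially correlated shadowing, no
per-node receiver-sensitivity differences, no temporal autocorrelation, and
Gaussian RSS noise has a lighter upper tail than field residuals (field
data show more nodes exceeding strong-RSS cutoffs than σ = 6 predicts).
Consequently, simulated *error magnitudes* under a given filter track the
reference experiment only approximately; the node-count and loss columns
(pure geometry × dropout) reproduce closely, except that the 4× filter on
the sparse 250 m grid retains ~16 nodes here versus ~19.5 reported — no
logistic-in-distance dropout can simultaneously match the overall detecting
fraction and that degree of spatial concentration, which is a fingerprint
of the (unpublished) empirical noise distribution.  Passing simulation
tests therefore validate the pipeline and its geometry-driven behaviour,
not site-specific error magnitudes.

## Evaluation

Localization error is the Euclidean true-to-estimate distance; attempts with
< 3 retained nodes (or without convergence) are *location loss* and excluded
from error moments.  The 95% CI of the mean error uses a cluster bootstrap
over test locations (2000 resamples, seeded): replicates within a location
share the truth, so replicate-level resampling would understate the CI.
Min/max are taken over all estimable realizations.  Edge effects are
summarized by binned mean error against distance-to-nearest-edge of the
node bounding box (points outside the box have edge distance 0); binning
replaces loess smoothing to keep the profile assumption-free.

## Known limitations

- Planar (2-D) localization; node and tag heights are ignored.
- One decay curve for the whole network; no per-node calibration covariates.
- No movement-model smoothing across windows, RSS fingerprinting, or
  time-difference-of-arrival — the package scope is single-window RSS
  trilateration and its design-time simulation.
- The Gauss–Newton point estimate carries no location uncertainty ellipse;
  `residual_norm` and `n_iterations` are reported as diagnostics only.
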