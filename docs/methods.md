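# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated on, including what those validations do and
do not establish about real recordings.

## Conventions and covariates

Angles are degrees in [0, 360), East = 0, counterclockwise positive. An
egocentric bearing of 0° means the reference point is dead ahead; +90°
means it is to the animal's left. Only the reference direction (East) is
field-standard — the CCW sign for egocentric bearing is this package's
choice, applied consistently everywhere, so flipping it would relabel
preferred angles without changing any statistic.

The time base is the 30 Hz video frame: one GLM bin = one frame, and
spike counts `n_t` are spikes per frame. Covariates per frame: head
direction; bearing and Euclidean distance of the arena centroid; bearing
and distance of the nearest point on each of the two closest walls
(walls = polygon edges, ties broken by the fixed enumeration south,
east, north, west, inserted-1, inserted-2); linear speed by forward
difference (first frame copies the second; an optional 5-frame boxcar is
off by default). Frames outside the arena polygon or within 0.1 cm of
the centroid (bearing undefined) are dropped listwise from all analyses.
Arenas: a 120 × 120 cm square, and the same box with the northeast
60 × 60 cm quadrant walled off (navigable-region centroid (50, 50) cm).

## Classification GLM

`r = exp(Σ_i X_iᵀ β_i)` over HD (30 bins), center bearing (30), center
distance (10) and speed (10); distance/speed bin edges span the observed
range of valid frames. No explicit intercept: the per-variable β absorb
the mean log rate, and the comparison baseline is a mean-rate-only model
with a single free log-rate parameter. β minimizes `P − l` (roughness
penalty S = 20, wraparound adjacency for circular variables, open chain
otherwise) by L-BFGS-B from β = 0 with the analytic gradient
(deterministic; gradient tolerance 1e-6, ≤1000 iterations). A rate floor
of 1e-8 spikes/bin guards the log-likelihood; `ln n_t!` is constant in β
and only added when reporting likelihood values.

Cross-validation uses 10 *contiguous* session blocks — contiguous folds
respect the strong behavioral autocorrelation, so held-out frames are
genuinely out-of-sample in a way random interleaving would not be. Per
fold, only the full four-variable model is fit on the training frames;
every subset's held-out likelihood reuses those β. A subset's linear
predictor keeps the *occupancy-weighted training mean* of each dropped
variable's contribution as a constant. Without that constant the missing
share of the mean log rate would bias every sub-model's predicted rate
downward by orders of magnitude and the full model would always win; with
it, sub-models differ from the full model only by the dropped tuning
structure, and the mean-rate baseline is the natural limit of dropping
everything.

Forward selection: best model of each size by mean fold likelihood, a
larger model is kept only if a one-sided Wilcoxon signed-rank test across
the 10 folds is significant at α = 0.05, and the final model must beat
the mean-rate model by the same test. Ties favor the smaller model.

EB/HD labels add tuning-curve criteria (12° bins, rate = spikes /
occupancy time; MVL and preferred direction from the rate-weighted
resultant over occupied bins): MVL above max(99th percentile of 400
spike-shift shuffles, 0.10) plus a 1 Hz curve peak for EB; MVL above
max(shuffle 99th, 0.15) for HD. The 1 Hz peak requirement is *not*
imposed on HD cells. For the cue experiment, HD cells are excluded if
their preferred direction moves ≥45° between A1 and A2. Shuffles shift
all spike times by a uniform draw from [30 s, T−30 s] with wraparound,
preserving count and inter-spike structure.

## Local vs. global models

Both contest models are unpenalized full-session fits with identical
parameter counts (80), so raw likelihoods are comparable. The two-wall
model shares one bearing curve and one distance curve across both wall
ranks — a wall-generic response evaluated against whichever two walls
are closest — with wall-distance bins spanning [0, 60] cm (the largest
possible nearest-wall distance in these arenas). Likelihood gains over
the mean-rate model are converted to bits/spike as
`(l_model − l_mean)/(ln 2 · n_spikes)` (the standard definition). The
Globality Index is undefined (NaN, with a reason code) when the gains
sum to ≤ 0, i.e. when neither model beats the mean rate.

## Symmetry analysis

All symmetry scoring runs on 1°-resampled circular curves (linear
circular interpolation), because the required lags (45°, 60°, …) are not
multiples of the 12° HD bin. Autocorrelations are Pearson correlations
with the curve's circular shift; a constant curve is an error
(undefined), and an analysis domain that errors marks the aggregate
incomplete rather than silently contributing.

*HD-conditioned maps*: 120 maps (3° steps, ±30° windows) on the 4-cm
grid with the rate-map module's mask-aware smoothing; bins under 100 ms
conditional occupancy are masked and maps with <10 valid bins flagged.
The 120×120 matrix uses pairwise-complete Pearson correlations (≥10
shared bins). Its diagonal autocorrelation correlates the band within
±45° of the main diagonal with the same band of the (s, s)-shifted
matrix, per circular 3° shift — the "central 90°" band reading; the
exact construction is not fully pinned down by its source description,
so this banded-diagonal version is the documented choice.

*Rotation GLM*: `log r_t = f(s_t) + h(hd_t)` with `s_t` the signed
projection of the position (relative to the arena center) onto an axis
rotated by `g(hd-bin)`; f over 30 bins, h over 30 HD bins (both
penalized with S = 20), g a free rotation per HD bin with an MVL penalty
(weight 10) that discourages all rotations collapsing onto one angle.
Two numerical choices matter and are deliberate:

1. **Projection cap.** Projections are clipped at ± the centroid-to-wall
   inradius (60 cm in the square). With the full corner-to-corner range,
   axes pointing at corners command a strictly larger usable range than
   axes pointing at walls, and the fitted rotation function of even a
   pure center-bearing cell warps measurably toward the corners — a
   parameterization artifact that masquerades as four-fold symmetry. The
   cap equalizes the range across directions; radial-only distance was
   considered and rejected because it cannot represent signed (near/far
   wall) structure.
2. **Two-start alternating optimization.** Given g, (f, h) is a convex
   penalized Poisson fit; given (f, h), each g entry is updated by a 3°
   grid search (three outer rounds). The fit runs from two deterministic
   starts — the identity line, and each HD bin's spike-weighted mean
   position direction (identity-like for center-referenced cells,
   snapped for wall cells) — keeping the better penalized objective,
   ties to the identity start. Unvisited HD bins are interpolated
   circularly and flagged.

Detrending subtracts the identity line with a circular-mean offset
(the plain 0°→360° line has an arbitrary phase relative to the bin
grid); deviations are mapped to (−180°, 180°] before autocorrelation.
The aggregate n-fold score sums the three domains and is compared with
the 95th percentile of the same aggregate over spike-shift surrogates
run through the identical pipeline (100 shuffles for analysis; tests and
the acceptance script use 20, which widens the null's sampling error but
changes nothing structurally).

## Directional measures and waveforms

Angle doubling for the bidirectionality index acts on per-frame head
directions before curve construction, not on the binned curve. The index
is reported missing when MVL_doubled + MVL_normal < 0.02 (untuned). Von
Mises fits use trust-region least squares with 12 equally spaced
multistarts for the lobe location, κ bounded to [0.05, 100], amplitudes
sign-constrained by orientation (upright ≥ 0, inverted ≤ 0), and
unweighted R² over valid bins (occupancy weighting was considered;
unweighted matches how the binned curves are used everywhere else).
Bidirectional fits share κ with lobes exactly 180° apart. Modulation
indices are computed from the *fitted* curve's extrema, with the lobe
closest to the A1 preferred direction attributed to cue A. Waveform
width uses a cubic spline at 100× resolution over the 32-sample (1 ms at
32 kHz) template; the trough is the global minimum after the global
maximum, and 200 µs separates narrow from wide.

## Rate maps and grid scores

4 × 4 cm bins over the arena bounding box; bins under 100 ms occupancy
are masked before smoothing; Gaussian smoothing (σ = 1.5 bins = 6 cm) is
mask-aware (kernel renormalized over valid bins), so the unsmoothed map
exactly conserves spike mass and the smoothed map preserves the spatial
mean to within interpolation error. The inserted-wall analysis jointly
range-normalizes the square and L maps over their common valid bins,
inverts center-preferring cells (mean normalized rate within 20 cm of
the centroid exceeding that within 20 cm of any wall, judged on the
average of the two maps so the measure stays antisymmetric under
swapping sessions), and averages the L−square difference within vs.
beyond 20 cm of the inserted segments. Spatial autocorrelograms use
pairwise-complete Pearson correlation per integer-bin shift (≥20
overlapping bins). The grid-score annulus takes the inner radius from
the first local minimum of the radial profile, the outer radius from the
six nearest autocorrelogram peaks plus one field radius (fallback 1.25×
the median peak radius), resamples on a polar grid (bilinear, missing
values as 0), and contrasts rotational correlations at 60°/120° against
30°/90°/150°; scores above 0.4 classify as grid.

## Synthetic sessions

The simulator emulates a foraging rat: heading follows a persistent
random walk (~1 s relaxation), speed an OU process around 15 cm/s
(capped at 45 cm/s), steps reflect off walls with jitter, and sessions
of ≥15 min cover >80% of 4-cm bins. Head direction is the smoothed
heading plus a slow lateral scanning process (OU, sd 25°, τ = 1.5 s) and
fast 5° jitter. The scanning term matters: with head direction rigidly
locked to the path, wall-following and corner turns imprint much
stronger position-by-HD structure than real rats show, and that excess
coupling leaks into any HD-conditioned spatial analysis.

Firing rates are `baseline + (peak − baseline) × Π kernels` — von Mises
for angular tuning, Gaussian for distance/speed, a sum-of-Gaussians
hexagonal lattice for grids; trough HD cells dip from peak toward
baseline at the preferred angle; bidirectional HD cells add a second
lobe 180° away scaled by the modulation fraction. Spikes are Poisson per
frame with uniform placement within the frame. Defaults follow what the
recorded populations look like: EB-type kernels are broad (κ = 2, curve
MVLs ~0.3–0.6, peak 10 Hz over 0.5 Hz baseline), classic HD cells sharp
(κ = 4), grid spacing 40 cm. The cue experiment is simulated by
re-parameterizing HD tuning across sessions (A1 unidirectional; AB
bidirectional at the stated fraction, default 0.5; A2 at a 0.2 residual
of the AB fraction) — the simulator has no visual system, so cue
influence enters only through tuning shape.

What passing tests on this generator establishes: the estimators recover
the quantities they target from data generated by the model family they
assume, at realistic rates and session lengths, and their nulls are
calibrated. What they do not establish: robustness to non-Poisson
firing, electrode drift, theta rhythmicity, tracking noise, or real
rats' behavioral idiosyncrasies — none of which the generator emulates.

## Problem sizes

Validation runs use 10–20 min sessions (18,000–36,000 frames), 20-cell
populations for directional/population contrasts, 20–30 cells for
false-positive calibration, 20 shuffles for symmetry nulls and 100–400
for MVL nulls. These sizes give stable medians and percentile thresholds
for the synthetic effect sizes used; analyses of real data should use
the full 100/400 shuffle counts.
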