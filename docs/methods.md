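# Methods

`fvrf` characterizes visual neurons recorded while the subject looks
wherever it pleases.  Because receptive fields (RFs) live in retinal
coordinates, every analysis operates on a gaze-contingent representation of
the stimulus: the screen stimulus shifted by minus the measured gaze on each
frame.  The package implements the full chain — synthetic sessions, gaze
tracking, gaze-contingent resampling, RF estimation, tuning, motion
selectivity, neural recalibration of the eye tracker, and high-resolution
spike-triggered averages — and validates each stage against ground truth it
generates itself.

## Coordinate and unit conventions

Screen-centered degrees of visual angle (d.v.a.), +x rightward, +y upward;
times in seconds; rates in spikes/s.  Pixel space (row index downward)
appears only in rendering and image I/O.  Spike counts are binned at frame
resolution aligned to frame onsets.

## Synthetic sessions (`fvrf.simulate`)

The simulator defines the study conditions for every estimator test.

* **Eye traces.** Fixational drift is a Brownian walk (default diffusion
  0.05 d.v.a./√s, clamped to the usable screen area) interleaved with
  saccades whose position profile is minimum-jerk with duration
  20 ms + 2 ms per d.v.a. of amplitude.  This yields main-sequence-like
  kinematics: a 1 d.v.a. saccade peaks near 85 deg/s and 1.2×10⁴ deg/s²,
  well above the detector thresholds, while drift stays well below them.
  The generator returns the ground-truth saccade list, including the
  analytic times at which the speed profile crosses 10 deg/s (the
  detector's start/end criterion).  Real eye movements are not Brownian nor
  exactly minimum-jerk; the generator captures only the kinematic contrast
  the detector exploits.
* **Stimuli.** Sparse dots (independent uniform positions, ±1 polarity,
  full contrast); flashed full-field gratings on a polar
  orientation × spatial-frequency grid at 25% contrast with a configurable
  blank fraction (≤ 50%); and sparse motion noise — up to 32 dots of 0.5
  d.v.a. drifting at 15 deg/s in one of 16 uniformly spaced directions with
  a 5-frame lifetime at 100 Hz, replotted at a random position (fresh
  random direction) at expiry or when leaving the screen.  All generators
  replay bit-exactly from their seed.
* **Model neurons.** Linear–nonlinear–Poisson simple cells (Gabor filter,
  half-squaring), energy-model complex cells (quadrature pair), separable
  orientation × SF tuned units (the parametric tuning surface below used
  generatively), and MT-like units (von Mises direction weighting of each
  moving dot inside a Gaussian spatial envelope).  All share a biphasic
  temporal kernel (peak lag 2 frames) and Poisson spiking.  Simulation
  always uses the TRUE eye trace; analyses only ever see the reported
  trace.
* **Tracker noise.** reported = gain·true + warp(true) + N(0, σ²) per
  sample: additive precision noise, multiplicative calibration gain about
  screen center, and an optional smooth warp field.
* **Eye-camera frames.** 8-bit frames with a bright wide Gaussian (first
  Purkinje reflection, peak ≈ 255) and a dim narrow one (fourth reflection),
  displaced by different linear gains so the P1−P4 vector is linear in
  rotation.

## Eye tracking (`fvrf.eyetrack`)

* **Dual-Purkinje localization** is two-stage: on the 4×-downsampled frame,
  P1 is the center of mass of pixels above 200 (8-bit) and the P4 region is
  the peak of the normalized cross-correlation with a small template (P1's
  neighborhood excluded from the correlation map); at full resolution P1 is
  refined by an iterated intensity centroid and P4 by the gradient-based
  radial-symmetry estimator (centroid available as a fallback).  Frames
  with no suprathreshold pixel (blinks) or a correlation peak below 0.4 are
  flagged invalid, never raised.
* **Calibration refinement** matches detected-fixation means to the nearest
  calibration target within 1 d.v.a. and fits a per-axis offset+gain map by
  least squares (≥ 3 non-collinear pairs required).
* **Saccade detection** resamples the trace at 1 kHz, differentiates with a
  Savitzky–Golay filter (11 ms window, order 3 — the differentiator is a
  free choice and is configurable), takes candidates at negative-going zero
  crossings of the acceleration (local speed maxima), merges candidates
  closer than 20 ms (larger peak wins), retains those whose 150 ms
  neighborhood exceeds 8 deg/s in speed and 2000 deg/s² in acceleration,
  and delimits each saccade at the surrounding 10 deg/s speed crossings.
  Candidates whose delimited span lands on an already-claimed saccade are
  duplicates and dropped.
* **Analysis mask**: frames during a saccade and for 50 ms after its end
  (post-saccadic lens wobble) are excluded from all downstream analyses.

## Gaze-contingent stimulus (`fvrf.gazestim`)

Cells are half-open boxes [center − s/2, center + s/2); a dot is assigned by
its center point to the cell containing its retinal position.  The default
coarse grid tiles 28 × 16 d.v.a. at 1 d.v.a. spacing with centers on the
half-integer lattice (448 cells).  (The published description of this grid
gives mutually inconsistent counts and bounds — 405 locations over
−14..14 × −8..8 at unit spacing; extent and spacing are therefore
configurable and the default documents this choice.)  Gaze is paired to
frames by nearest-sample lookup at frame onset.

Velocity decomposition accumulates each surviving dot's per-transition
displacement (split into horizontal and vertical velocity, d.v.a/s) into
the 2 d.v.a. cell containing its retinal position; replotted dots
contribute nothing.

ROI movies re-render the dot stimulus inside a gaze-anchored window
(default 70×70 px at 1.6 arcmin/px; desk-scale analyses use 20×20 px at 3
arcmin/px) by evaluating each dot's Gaussian luminance profile
(SD = dot diameter/2) at the ROI pixel centers — equivalent to cropping a
full-screen rendering with exact sub-pixel alignment.  Off-screen regions
are background gray and flagged.

## Receptive-field regression (`fvrf.rfmap`)

The estimator solves K = (XᵀX + λD)⁻¹XᵀR on the time-embedded
gaze-contingent stimulus with mean-subtracted spike counts, where D is the
combinatorial graph Laplacian (4-neighbor in space, 2-neighbor chain in
lag; the orientation axis wraps when the design is the grating basis).  λ
is selected per unit on a contiguous 20% held-out time block (avoids
temporal leakage) over a log grid 10⁻²…10⁵, by held-out variance explained
relative to the mean-rate predictor; final weights are refit on all frames
at the selected λ.  Designs are kept sparse (dots per frame ≪ cells), so
XᵀX accumulation is cheap and the dense Cholesky solve dominates.

Coarse→fine: the coarse spatial map at the peak lag (argmax of the
per-lag L2 norm) is thresholded at 50% of max; the largest 8-connected
component's centroid and bounding box (ties broken by first occurrence)
define an ROI scaled ×2 about the centroid and re-binned with 20 bins per
axis; the regression is refit.  A 2D Gaussian is then fit by least squares
(Cholesky-parameterized covariance, moment-based start plus 5 seeded
perturbations, best SSE wins); RF area = π·s₁·s₂ with s the square roots of
the covariance eigenvalues (the 1-SD ellipse).

Selection: (a) held-out variance explained beats the mean rate (cv R² > 0)
and (b) Gaussian fit r² > 0.4; units whose fitted mean sits more than 0.25
d.v.a. (units chosen as d.v.a.; configurable) from the thresholded-blob
centroid of the fine map are excluded.

## Orientation / SF tuning (`fvrf.tuning`)

Gratings project onto 8 von Mises orientation functions (period π, centers
π/8 apart, concentration set so neighbors cross at half height) × 4 raised
cosines on the log(1+ω) axis over 1–16 cyc/deg with support of one
inter-center interval (the "stretch" of this axis is a free choice);
each function peaks at 1 and blanks map to zero.  The grating RF uses the
same penalized regression.  The tuning surface

    K(θ, ω) = b + (M − b) · O(θ) · S(ω)
    O(θ) = (exp(κ cos²(θ − θ̂)) − 1)/(exp(κ) − 1)
    S(ω) = exp(−(log(1+ω) − log(1+ω̂))² / 2σ²)

is fit by bounded nonlinear least squares with multi-start over preferred
orientation.  (The printed form of this model in the source literature is
typographically garbled; the form above is the unique reading consistent
with its stated normalization — each factor has maximum 1 and minimum 0 —
and the (e^κ − 1) denominator.)  Bandwidths are full widths at half height:
2·arccos√(log(1+(e^κ−1)/2)/κ) for orientation (→ π/2 as κ → 0) and
(1+ω̂)(e^h − e^{−h}) with h = σ√(2 ln 2) for SF.  Forward correlation
reports the lag-triggered mean rate after onsets of gratings inside the
fitted half-height region, with a blank-onset baseline.

## MT velocity GLMs (`fvrf.mtvel`)

Poisson GLM with exponential inverse link on the time-embedded velocity
stimulus, penalized by the graph Laplacian (per channel) plus an L1 term,
optimized by monotone FISTA with backtracking (the accelerated candidate is
only accepted when the objective decreases) and a subgradient-aware
stopping rule.  Velocity columns are scaled by their root-mean-square
(zeros stay zero, preserving sparsity) and weights are reported in native
units.  Hyperparameters are selected on held-out Poisson likelihood;
the default L1 grid scales with the data as fractions (0.01, 0.1, 1) of the
lasso critical value, and the default Laplacian grid is {30, 100, 300,
1000} — strong spatial smoothing is what suppresses isolated noise vectors
far from the envelope so the amplitude-weighted preferred direction is
stable.

Preferred direction = normalized amplitude-weighted mean of the per-cell
(h, v) weight vectors at the peak lag (argmax of summed amplitude);
temporal projections dot the unnormalized vectors at the max- and
min-amplitude cells onto it.  Direction tuning by forward correlation
counts in-mask (≥ half-max amplitude) dots per direction per frame and
reports the dot-count-normalized lag-triggered rate at the peak lag, with
95% CIs from 500 multinomial bootstrap resamples of the triggering dot
events.  The von Mises curve R = b + A·exp(K(cos(θ − θ̂) − 1)) is fit by
least squares with multi-start.

## Neural eye-tracker calibration (`fvrf.calibnet`)

The encoding model is a four-layer convolutional core (20 channels per
layer, kernels 11/9/7/7, ReLU + batch normalization, kernels multiplied by
a fixed 2D Hamming taper; time enters through 4 input-channel lags), a
factorized per-neuron readout (spatial weights × 20 feature weights →
softplus rate), and a 2-layer shifter (2 → 20 softplus → 2 linear) that
maps measured gaze to a single readout shift shared by all neurons,
pinned to exactly (0,0) at gaze (0,0) by subtracting its own output at the
origin.  The shifter's raw output is squashed through cap·tanh(·/cap)
(default cap 1 d.v.a per component) so the correction saturates smoothly at
a physical bound instead of extrapolating without limit where gaze data are
sparse.  All parameters are trained jointly by Adam on the summed Poisson
negative log-likelihood with minibatches of frames, cosine learning-rate
decay, a contiguous 20% validation block, and early stopping.  Four
stabilizers make short runs reliable: per-unit biases start at the inverse
softplus of the unit's mean count (so initial predicted rates match the
data); spatial readouts are initialized from each unit's stimulus-energy
STA (so the shifter receives informative gradients once enabled); the
shifter is frozen for the first 15% of steps while core and readout settle
(otherwise its early random walk can drag the fit into a shifted local
optimum); and shifter gradients are norm-clipped per step.  A final
shifter-only polish phase (core and readout frozen, no convolutional
backward pass) refines the correction cheaply; its result is kept only if
validation improves.  The network is implemented as a compact reverse-mode
layer library on numpy (`fvrf.nnet`), gradient-checked against finite
differences.

A gaze-independent (constant) calibration error is not identifiable from
neural data: the loss is invariant under moving every readout by c while
shifting the correction by −c, and a constant misalignment does not blur an
STA.  The origin constraint fixes this gauge.  When ground truth is
available (synthetic sessions), `absolute_correction_grid` resolves the
constant from the displacement of the learned readout centroids relative to
the units' true retinal anchors, and `pipeline.refine_gauge_with_sta`
sharpens it by cross-correlating each unit's corrected-movie STA with its
true filter (sub-pixel peak interpolation, SNR-weighted across units).  The
exported calibration grid evaluates the shifter on a −5…5 d.v.a. lattice
(values in arcmin); corrections are applied by bilinear interpolation at
the measured gaze, with out-of-span queries clamped.  The model is used
only to produce this grid — all downstream RF estimates are conventional
STAs on the corrected stimulus.

Desk-scale defaults (20×20 px ROI at 3 arcmin/px, 4 lags, 20 neurons,
5×10⁴ frames, ~1000–1500 Adam steps of batch 32 plus ~500 polish steps)
keep a full calibration run in the ten-minute range on one CPU; the 70×70
ROI configuration remains available.  Batch size, learning rates, stopping
rule and embedding depth are config defaults, not reported values.

## High-resolution STAs (`fvrf.foveal`)

STA(τ) is the spike-count-weighted mean of per-pixel mean-centered frames τ
frames before each spike; a spike contributes at lag τ only when both its
frame and the stimulus frame pass the analysis mask, so masked frames can
never influence the estimate.  Defaults: 12 lags at the movie frame rate.
z-scored copies divide by a per-lag constant (pixel SD/√N by default);
passing one STA's constants to another keeps pre- and post-calibration maps
on the same scale.  Significance uses the maximum absolute raw STA value
against a null built by assigning the unit's spike count uniformly to valid
frames (the behavior of spikes recorded before stimulus onset), 1000
seedable resamples, p with the +1 correction, significant at p < 0.001.
The squared-pixel STA applies the same machinery to centered energy values
and is what detects phase-invariant units.

Simple/complex classification fits two canonical models at the energy-STA
peak lag — a single linear filter (training-fold STA) with half-squaring,
versus the energy of the top two spike-triggered-covariance eigenvectors —
each followed by a two-parameter Poisson output map, and labels the unit by
the higher summed held-out log-likelihood ("unclassified" when neither
beats the intercept-only model).

## What the synthetic tests do and do not show

Passing tests demonstrate that each estimator recovers what it is supposed
to recover under its own generative assumptions (LNP/energy neurons,
Poisson spiking, stationary rates, the stated stimulus statistics, and
tracker errors limited to noise/gain/offset/smooth warps).  They do not
certify behavior under real-data phenomena the simulator omits: natural
image statistics, adaptation and non-Poisson variability, spike-sorting
contamination, eye-tracker dropouts, torsion, or nonstationary calibration
drift within a session.

## Numerical notes and limitations

* Penalized solves use Cholesky with a fall-back to the next larger penalty
  when a system is numerically singular.
* Cell-boundary ties in binning are deterministic (lower edge inclusive).
* The encoding network trains in float32; gradient checks run at
  float32-appropriate tolerances.
* The constant-offset component of calibration recovery relies on
  ground-truth anchors and is therefore a synthetic-session capability; on
  real data the gauge is irrelevant because absolute RF position is defined
  only relative to the tracker's calibration.
* Problem sizes in the test suite (20k frames for retinotopy, 10 min of
  motion noise at 100 Hz, 5×10⁴-frame calibration sessions at 20×20 px) are
  the package's standard desk-scale study conditions.
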