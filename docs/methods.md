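# Methods

This note documents the modelling choices, the synthetic data the package is
validated on, the numerical conventions, and the known limits of what the
tests demonstrate.

## Signal model of the synthetic subject

One simulated subject mimics the structure of the public hybrid-BCI
benchmarks: 3 sessions, 20 balanced binary trials per session, 60 s of rest
before and after the trial block, 30 EEG channels at 200 Hz, 36 fNIRS
channels (HbO and HbR) at 10 Hz, two EOG reference channels.  Sensors sit on
mirror-symmetric rings of the upper unit hemisphere with a vertex sensor;
the exact benchmark montages are not tabulated anywhere usable, and nothing
downstream depends on more than symmetry and upper-hemisphere coverage.

**EEG.** Each channel carries 1/f background noise (default 3.5 µV RMS), an
8-12 Hz rhythm whose amplitude grows with |x| (lateral channels, default
5 µV at the most lateral site), and frontal leakage from blink-like EOG
activity.  During a trial the rhythm is attenuated on one hemisphere
(event-related desynchronization): class 0 attenuates the left channels,
class 1 the right, with relative depth `eeg_effect_size` (default 0.7).

**Neural drive and adaptation.** The task lasts 10 s, but the effect
envelope is a 3 s plateau followed by an exponential decay (τ = 2 s) — an
adaptation profile.  Two considerations fixed this choice.  First, the
module contract requires the noise-free HbO response to peak 5-8 s after
onset; a canonical double-gamma kernel convolved with a flat 10 s boxcar
peaks near 11.7 s, which would break the delay geometry the 11-segment
pairing is built around, whereas the adaptation-weighted drive puts the peak
at 7.7 s.  Second, the same envelope makes the EEG effect strongest in the
first windows, reproducing the early EEG-branch accuracy peak and delayed
fNIRS-branch peak that the published per-window analysis reports — with a
single shared piece of physics rather than two unrelated knobs.

**fNIRS.** The HbO response is the double-gamma kernel (gamma shapes 6 and
16, undershoot ratio 1/6) convolved with the neural drive, normalized to
unit peak and scaled by `fnirs_effect_size` (default 1 µM) times a lateral
gain; class 0 activates left channels, class 1 right.  HbR is -1/3 of HbO.
Noise: a 0.1 Hz Mayer wave (0.4 µM), two slow drift components
(0.004/0.009 Hz, 0.4 µM), and white noise (default 0.9 µM).

Defaults were calibrated once so that the trained single-modality branches
land in the 80-95% accuracy range on the default subject — a learnable,
non-trivial problem — with a logistic read-out of hemispheric band-power
asymmetry as the quick separability oracle.  The generator does **not**
model volume conduction, optode short channels, motion artifacts, or
cross-session nonstationarity; consequently, passing the learning-sanity
tests demonstrates that the pipeline and optimizer work, not that the
architecture would reach any particular accuracy on real recordings.

## Preprocessing

EEG: 6th-order zero-phase Butterworth bandpass 0.5-50 Hz (forward-backward
`sosfiltfilt`, reflective padding of 3x the filter order), common average
reference, then ocular removal.  Ocular removal is least-squares regression
on the demeaned EOG references: deterministic, and it satisfies the
operational contract (residuals uncorrelated with every EOG channel).  An
ICA-based cleaner could sit behind the same interface, but ICA unmixing is
seed- and algorithm-dependent and no component-selection rule is published,
so regression is the default.

fNIRS: modified Beer-Lambert law when raw intensities are supplied (default
DPF 6, source-detector distance 3 cm, 760/850 nm extinction coefficients
from standard tables; the op is bypassed when the generator emits
concentrations directly), bandpass 0.01-0.1 Hz, then per-trial baseline
correction against the -5..-2 s window, in that order.

## Tensorization

Azimuthal equidistant projection (vertex at origin, radius = polar angle),
scaled so the outermost sensor maps to a grid radius of 7.5 cells of the
16 x 16 grid; row 0 is anterior.  Scattered-data interpolation uses the
Clough-Tocher piecewise-cubic interpolant on a Delaunay triangulation — the
natural scattered-data member of the cubic-spline family — with zero fill
outside the convex hull (neutral under convolution).  Windows: 3 s, step
1 s, over -2..10 s, giving 10 EEG windows per trial; fNIRS windows use the
same step so that "current plus 10 subsequent segments" tiles the 13 s
hemodynamic horizon, requiring fNIRS coverage to +20 s.  Insufficient
coverage raises; windows are never silently truncated.

Because adjacent stacks share 10 of their 11 segments, `SampleSet` stores
each trial's 20 distinct fNIRS windows (and the trial's rasterized EEG time
course) once and materializes per-sample tensors on demand.  The stored
pairing remains a bijection between EEG windows and fNIRS stacks.

## Network and numerics

The layer geometry (kernels, strides, channel counts, and all ten
intermediate feature dimensions) follows the published table exactly; a
forward pass records every shape and the test suite asserts all ten.
Adaptive padding is same-style zero padding with output `ceil(n/stride)` and
the asymmetric extra sample at the end of the axis.  Block order is conv →
ELU → batch norm → dropout (rate 0.5, training only); batch-norm statistics
are per-batch in training and running averages (momentum 0.1) in evaluation,
so single-sample inference is well defined.

Gates γ, α (EFGF) are unconstrained scalars initialized to zero — honoring
the published zero initialization, which a sigmoid parameterization cannot
express — and clipped to [0, 1] after every optimizer update.  At exactly
α = 0 the fNIRS attention convolution receives a zero gradient; it wakes up
as soon as α moves into the interior.

CAFE tokens: the 11 post-GAP fNIRS segment features (dim 4·4·32 = 512) with
learnable positional encodings, and the 16 spatial fusion features (dim 32),
both projected to model dimension d.  The published CAFE configuration
defers to an unavailable reference; d = 512 with 4 heads is the default
because it reproduces both published parameter-count directions (full model
≈ 3.35 M parameters vs the printed 3,335,576; the no-CAFE ablation is far
smaller) — with a small d the no-CAFE variant would be *larger* than the
full model, since its fNIRS head consumes the raw 5632-dim flattened
features.  All dims are configurable.

Decision fusion divides the sigmoid-weighted sum of branch scores by 3
("mean of the three weighted scores"); dividing by the weight sum instead is
available via `fuse_mean="weights"`.  The fused score is renormalized to the
simplex (ε-guarded) before entering its cross-entropy, preserving the
argmax while keeping the loss a proper log score.

The printed form of the Pearson-correlation denominator in the source
material omits the squares/square root (as printed it is degenerate); the
standard Pearson formula is implemented.  Per-sample correlations guard the
denominator with an ε inside the square root, which bounds |r| ≤ 1 and sends
constant inputs to 0 without NaNs.  The EFGF regularizer averages per-sample,
per-layer correlations between the temporally/channel-averaged EEG feature
map and the attention map (the only pooling that makes the two operands
share a shape); the CAFE regularizer pools fNIRS tokens over segments and
fusion tokens over positions to a common d before correlating.

**Autodiff core.** The network runs on an in-package tape-based autodiff
over NumPy with numba-compiled im2col/col2im kernels.  Two exact algebraic
optimizations matter on a CPU: (1) the EEG and fusion branches share their
first convolution's input and geometry, so it is evaluated as one
double-width convolution and split; (2) the EFGF attention convolutions are
stride-1 and immediately averaged over time, and `mean_t(conv_t(x))` equals
a k-term contraction of sliding means, so the full-resolution conv is never
materialized (verified to machine precision against the direct computation).
Training forwards deduplicate the shared fNIRS windows of a batch (batches
are trial-grouped); in evaluation mode this path is bitwise-equivalent to
convolving the per-sample stacks, and in training mode it means batch-norm
statistics are computed over the distinct windows — the sensible statistic,
since duplicated segments would otherwise be over-counted.

## Training protocol

Adam (lr 0.001, default moments), batch size 64.  Stage 1: random 4:1 split
at the trial level (windows of one trial never straddle the split, which
would leak overlapping data into validation), early stop after 50 epochs
without a strict validation-accuracy improvement (ties do not reset
patience), cap 300; the best-validation weights are restored and that
epoch's mean training loss recorded.  Stage 2: fresh optimizer, full
training set, stop when the epoch-mean total loss drops below the stage-1
reference, cap 200.  Cross-session hold-out rotates each session out as the
test set; test samples never contribute to any gradient or normalization
statistic of their fold.  Fixing the seed fixes the split, the
initialization, the batch order and the dropout masks, so runs are
reproducible.

## Problem sizes used in the tests

Unit tests run on a two-session, four-trial subject with 8-channel montages
(full tensor geometry, tiny signal lengths).  The learning-sanity checks use
the default subject (seed 7, 3 sessions x 20 trials = 600 windows) with a
reduced-width model (conv widths scaled by 1/8, d = 32) and epoch caps of
30/20 — sizes chosen so the full cross-session hold-out, the label-shuffled
control (one fold) and both ablation variants complete on a single CPU in
tens of minutes while leaving the protocol itself untouched.  The
acceptance script's targets are closed-form kappa arithmetic and run in
milliseconds.

## Known limitations

* The synthetic effects are stationary across sessions, so cross-session
  accuracy here is an upper bound relative to real recordings.
* The ocular-removal contract is linear regression, not ICA.
* The CAFE dimensioning is a declared default, not an inferred one.
* The autodiff core implements exactly the operator set this network needs;
  it is not a general-purpose framework.
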