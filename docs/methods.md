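# Methods

## The calibration model

Post-beamformed RF ultrasound factors, in the frequency domain and at each
axial location, into a machine-dependent system response and a
medium-dependent tissue signal, `I(x, f) = S(x, f) · P(x, f)`.  When one
uniform calibration phantom is imaged on two machines, the tissue factor
is common, so the ratio of the measured spectra isolates the ratio of
system responses — the machine-to-machine transfer-function magnitude

    |Γ_train→test(z, f)| = sqrt( P̄_test(z, f) / P̄_train(z, f) ),

where `P̄_d(z, f)` is the one-sided power spectrum averaged over all
calibration patch columns of axial zone `z` on machine `d`.  The raw gain
is regularized with an SNR-weighted, Wiener-inspired rule

    Γ_W = |Γ|⁻¹ / (|Γ|⁻² + SNR⁻¹) = |Γ| · SNR / (SNR + |Γ|²),

with per-bin SNR `(P̄ − floor) / floor` on each side (the floor is the
minimum of the zone's averaged spectrum, taken to represent noise-only
energy outside the transducer band) combined as the per-bin minimum of
the two sides.  Where the SNR is high the gain is untouched; where it
vanishes the gain is damped to zero, so the transfer behaves as a
denoiser rather than amplifying out-of-band noise.

The regularized gain moves RF patches between domains: train-time
calibration filters the training set into the test domain and trains
there (statistics for patch-level z-score normalization are then taken
from the transformed training set); test-time calibration trains once in
the training domain and filters incoming test patches back into it,
normalized with the training statistics.  Neither procedure touches the
raw test-domain classification data before final scoring.

### Estimation and application choices

- Γ is magnitude-only, estimated from averaged power spectra (average
  first, then ratio).  Speckle phase is not transferable between
  independent acquisitions, so application is zero-phase: per patch
  column, real FFT → multiply by the real zone gain → inverse real FFT.
  A linear-convolution variant with a 129-tap symmetric FIR kernel
  (frequency-sampling design) is available via `mode="fir"`; the two
  agree away from patch edges.
- Spectra use a rectangular window, no zero-padding, `n_fft` equal to the
  patch axial length (200 → 101 bins, 0.2 MHz spacing at 40 MHz).  The
  ratio cancels window bias to first order; leakage skirts matter only
  outside the analysis band, which the Wiener weighting suppresses.
- Depth dependence is tracked over the nine patch axial zones.  Spectral
  ratios guard denominators at 1e-12 of the spectrum maximum; the std
  patch used in z-score normalization is floored at 1e-12 of the mean
  absolute amplitude (population convention, divide by N).
- Both transfer directions are estimated from the same averaged spectra
  (the raw magnitudes are exact reciprocals) and regularized with the
  same combined SNR, so the regularized forward·backward product is ≤ 1
  and approaches 1 only where the SNR is high.

## Patch geometry

Frames are 2080 axial samples × 256 lines (4 cm at 40 MHz, sound speed
1540 m/s).  The first 540 axial samples are skipped; patches are 200×26
with axial stride 100 (half-patch overlap, zones 0–8) and exact lateral
tiling of width 26 from column 0 (the lateral origin is a package
choice; 9·26 = 234 ≤ 256).  A frame yields 81 patches, each tagged with
its axial zone and class label.  Train/validation splits are 4:1,
stratified by (class, zone).

## Rate conversion

Machines digitizing at 50 MHz are brought to the 40 MHz reference grid
by a polyphase FIR resampler (interpolation 4, decimation 5): windowed-
sinc low-pass at the lower Nyquist with `24·max(up, down) + 1` taps and
a Kaiser window (β = 5), group-delay compensated so depth registration
survives.  The vendor routine this mirrors does not publish its
coefficients; exact filter equivalence is not claimed, only unity
passband gain and < 1e-2 round-trip error for signals band-limited to
0.8× the lower Nyquist.

## The classifier harness

The exercised architecture is a compact 4-block conv–BN–ReLU stack on
NumPy (single-channel 200×26 input, strided convolutions, global average
pooling, one logit; ≈1.6·10⁴ parameters — sized for single-CPU training).
Training uses Adam, sigmoid + binary cross-entropy, 50% lateral-mirror
augmentation, and a seeded 4:1 stratified split; runs are reproducible
under a fixed seed.  BN supports three statistic modes:

- `batch_stats`: batch statistics at both training and evaluation, no
  stored running statistics — the mode the calibration algorithms
  prescribe.  Evaluation batches are formed by a seeded shuffle at a
  fixed batch size (default 256) so results are reproducible despite
  being batch-composition-dependent.
- `running_stats`: conventional exponential running statistics; used by
  the no-calibration-family baselines (no-calibration variants,
  fine-tuning pretraining, AUC analysis), which model a conventionally
  trained network.
- `frozen`: statistics track the batches for one warm-up epoch and are
  then pinned for the rest of training and for evaluation (the
  BN-freezing baseline; evaluated with true test statistics, its stated
  requirement).  Freezing at raw initialization instead would leave deep
  normalization mismatched with the weights as they train; the warm-up
  epoch is the from-scratch analogue of freezing statistics that match a
  pretrained network.

Fine-tuning unfreezes only the last conv block and the linear head;
frozen parameters are bit-identical afterwards.  The AUC-analysis
baseline re-selects the score threshold by maximizing Youden's J over
midpoints between adjacent distinct scores (first maximum on ties) —
the selection criterion is a documented package choice.  ImageNet-scale
architectures are accepted in the config enum but are not implemented in
this build.

The full-scale protocol of the original study (learning rate 1e-5 for 50
epochs for calibration runs, 5e-6 for 25 epochs for no-calibration runs,
batch 2048, ten repetitions) is recorded in `workflows.PAPER_PROTOCOL`;
desk-scale runs use Adam at 2e-3, batch 256, five epochs for the
calibration-method models and a shorter (4/5) schedule for the
conventionally normalized no-calibration family — the desk analogue of
that protocol's early-stopped no-calibration training — with three
repetitions, appropriate for a small randomly initialized network.
Repetition `r` uses seed `base + r`; run-to-run variance comes from
initialization and batching.  Aggregates are mean ± population standard
deviation; paired comparisons use the two-sided Wilcoxon signed-rank
test (exact null for n ≤ 25, zeros dropped).

## The synthetic two-machine study

Every scan line is a Poisson stream of point scatterers (default 5.2·10⁴
per metre ≈ one per 40 MHz sample — fully developed speckle) with i.i.d.
Gaussian amplitudes, drawn in continuous depth and binned to the
machine's grid; binned amplitudes are scaled by `Fs / 40 MHz` so machines
digitizing at different rates see the same continuous medium, which makes
stable (clamped-transducer, shared-speckle) acquisitions meaningful
across grids.  The system response is piecewise-stationary over
100-sample depth blocks aligned with the patch half-zones: a
super-Gaussian pulse spectrum, an optional in-band reverberation comb, a
Lorentzian focal-gain depth profile, and round-trip frequency-linear
attenuation owned by the phantom.  White noise is added at the machine's
noise-floor amplitude and frames are quantized to 16 bits.  Because each
axial zone spans two blocks, the analytic transfer magnitude is the RMS
over the zone's two block depths of the machine-response ratio — the
oracle against which the estimator is tested (attenuation and tissue
signature cancel in the ratio).

### What the default study emulates

The virtual pair mirrors the asymmetry of a real two-scanner study: the
training machine has an 8.9 MHz pulse (fractional bandwidth 0.7,
Gaussian edges, high in-band SNR) sampled at 40 MHz; the testing
machine a 5.2 MHz pulse (bandwidth 0.8) sampled at 50 MHz and resampled
4/5, with steep super-Gaussian band edges, a 0.45-deep reverberation
comb (4 MHz period, resolvable at the patch spectral resolution), a 20×
RF gain scale, and a different focal configuration (2.8 cm focus,
narrower depth-gain profile vs 2.0 cm).  The two tissue classes are
bimodal bead-size mixtures whose backscatter bumps place a loud contrast
in the training machine's exclusive band (9.0 vs 10.6 MHz, invisible
behind the test machine's band edge) and a moderate contrast inside the
mutual band (5.7 vs 6.7 MHz); attenuation (0.3 dB/cm/MHz) and power-law
slope are matched so no machine-invariant amplitude cue shortcuts the
task.  The calibration phantom is unimodal and featureless (power-law
1.5, 0.7 dB/cm/MHz).

This composition makes the benchmark reproduce, mechanistically, the
phenomenology a two-scanner study exhibits: a conventionally normalized
network trained on the training machine leans on the loud exclusive-band
cue and inherits the training machine's input scale and depth profile,
so on raw test-machine data its accuracy collapses to ~50% while
correcting only the normalization statistics recovers part of the
performance; both calibration procedures restore ≥95% accuracy because
the mutual-band contrast is exactly recoverable through the transfer
function.  Desk scale is 100 frames per classification phantom per
machine (16 200 patches a side), 50 adaptation frames per phantom, 10
stable calibration views, and up to 500 free-hand calibration frames
(streamed through a bounded-memory spectra accumulator).

### What the simulator does not capture

Speckle is Gaussian (circular statistics), so machine phase responses
are statistically invisible and magnitude-only calibration is exact by
construction — real sparse or structured scatterers break this.  There
is no diffraction, element directivity, beam width (lines are laterally
independent), nonlinear propagation, or motion; bead-size spectra are
qualitative emulations, not fits to any physical phantom.  Passing the
end-to-end benchmark therefore demonstrates the pipeline's correctness
and the calibration's information accounting, not clinical performance.

## Problem sizes

Unit tests run on reduced geometries; the end-to-end suite uses the full
desk study above with a 3-epoch, 3-repetition protocol, 500 calibration
frames for the oracle-recovery and free-hand-equivalence checks, and a
smaller same-machine study (30 frames/phantom) for the identity
calibration check.  `scripts/acceptance.py` recomputes all of these from
scratch from a single seed.
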