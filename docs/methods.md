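# Methods

This note records the models implemented in `hearkit`, the parameters that
matter, and the design choices made where more than one reasonable option
existed.

## Sparse Gammatone coding

**Model.** An audio segment `x` is approximated as a K-term superposition of
Gammatone atoms,

    x(t) = Σ_{k=1..K} a_k · γ_{f_k, t_k}(t) + ε(t),

where each atom is the impulse response of one of M Gammatone filters shifted
to an integer sample offset, and ε is the residual.  Atoms are selected by
plain matching pursuit: at each step the (filter, offset) pair maximising the
absolute inner product with the current residual is chosen, the signed
projection becomes the amplitude, and the scaled atom is subtracted.  Because
the representation stores only (filter index, offset, amplitude) triples plus
two scalar energies, the serialized code contains no raw samples; the
`privacy_report` utility quantifies how much of the original a reconstruction
recovers rather than assuming it.

**Dictionary.** 4th-order Gammatone impulse responses,
`t³·exp(−2π·b·t)·cos(2π·f·t)` with `b = 1.019·ERB(f)` and the Glasberg–Moore
bandwidth `ERB(f) = 24.7·(4.37·f/1000 + 1)` — the de-facto convention in
auditory modelling.  Centre frequencies are uniform on the ERB-rate scale.
Defaults: M = 64 filters, f ∈ [80 Hz, 0.45·fs], fs = 16 kHz, K = 1024 atoms
per 10-s segment.  Impulse responses are truncated where the gamma envelope
falls 60 dB below its peak — the discarded tail carries < 1e-6 of the atom
energy — and normalised to unit Euclidean norm so correlations equal
amplitudes.

**Numerical choices.**

- The offset search covers every integer offset in `[0, len(x))`.  An atom
  whose support would extend past the signal end is truncated there and
  renormalised to unit norm.  This keeps the step-wise energy identity
  `‖x‖² = Σ a_k² + ‖ε‖²` exact for every admissible candidate; the
  reconstruction routine applies the same convention.  Offsets whose
  truncated support is numerically empty are excluded.
- Correlations are FFT-accelerated: one full cross-correlation per filter at
  the start, then incremental updates confined to the support of each
  subtracted atom.  The selected amplitude is recomputed with a direct dot
  product before subtraction, so acceleration affects speed only; the test
  suite asserts exact agreement (to float rounding) with an exhaustive
  direct-inner-product search on small instances.
- Ties break to the lowest filter index, then the smallest offset.
- Encoding stops early when the residual energy falls below 1e-12 of the
  initial energy.
- Multichannel (binaural) input is downmixed to the channel mean before
  encoding.

**Spikegram features.** Codes are rasterized onto an M × T grid: cell (m, t)
accumulates `transform(|a_k|)` over the atoms of filter m falling in time bin
t.  Defaults: 25-ms bins (T = 400 for 10 s) and the `log1p` magnitude
transform, which compresses the amplitude dynamic range in the spirit of
log-spectral features.  Rasterization is a deterministic, order-invariant
function of the atom multiset.

## Synthetic scene corpus

The generator emulates the *structure* of a hearing-device scene corpus: 14
classes in three groups — speech (cocktail party, interfering speakers),
backgrounds (in-vehicle, traffic, wind, rain, music, kitchen clatter) and
speech-in-background mixtures (including a reverberant-environment class).
Sources are parameterised signal models:

- speech: harmonic complex, drifting fundamental (100–220 Hz), formant-like
  band emphasis near 500/1500/2500 Hz, ~4 Hz syllabic amplitude modulation
  with pauses; multi-talker scenes superpose independent talkers;
- backgrounds: Gaussian noise with class-specific spectral tilt, optional
  narrowband hums (engine), slow deep amplitude modulation (wind), tonal
  chord sequences (music), and Poisson event trains (rain droplets, clatter
  transients, traffic swells);
- mixtures: speech + background scaled so the pre-mix component energy ratio
  equals the scene's configured SNR exactly (default 5 dB; the reverberant class convolves
  the speech with a synthetic exponentially decaying tail, T60 = 0.8 s).

Every record is deterministic given (spec, seed), exactly the requested
duration, and peak-normalised to 0.9.  Per-record seeds derive from the
master seed via `SeedSequence`.

**What this does and does not show.** The classes differ in their
time–frequency statistics by construction, so a classifier that learns them
certifies that encoding, rasterization, training and evaluation compose
correctly.  Synthetic scenes are far cleaner than field recordings — no
recording-channel variability, no overlapping scene content, no
device-specific coloration — so accuracies obtained here say nothing about
accuracy on real corpora.

## Scene classifier

Four convolutional blocks (3×3 kernels, stride 1, same padding; filter counts
32, 64, 128, 256; each block is convolution → batch normalisation → ReLU →
2×2 max pooling), then flatten → 280-unit dense → ReLU → 50 % dropout →
linear output with one unit per class (14).  Training uses Adam (learning
rate 1e-3, the conventional default), categorical cross-entropy, mini-batches
of 24, per-epoch shuffling, at most 250 epochs, and early stopping after 10
consecutive epochs without improvement of the monitored loss.  The monitored
loss is the training loss; there is no separate validation split in the
protocol.  "Iterations" are read as epochs — 250 optimiser steps would be
implausibly short against a patience of 10.  Evaluation uses stratified
random 70/30 train/test splits (largest-remainder rounding so the training
share is exactly `round(0.7·n)`), repeated with fresh splits and fresh
initialisation; reports give class-wise accuracies and the element-wise mean
and standard deviation of row-normalised confusion matrices.

The network and its backward passes are implemented directly on numpy
(im2col + GEMM convolutions); every layer is verified against numerical
differentiation.  Features are standardised with training-split statistics
before fitting.  All stochastic elements — initialisation, shuffling,
splitting, dropout — are keyed to explicit seeds, so identical seeds give
identical loss histories.

**Scaled learning check.** The end-to-end check trains one repetition on 14 ×
40 synthetic segments of 2 s at 16 kHz, K = 205 atoms (the 10-s default 1024
scaled by duration), 25-ms raster (input 64 × 80), and at most 25 epochs.
These sizes keep a single repetition tractable on one CPU core while running
every pipeline stage at full fidelity; the pass criterion is held-out
accuracy above five times the 1/14 chance level.

## Audiometry simulation

Listeners are simulated with logistic psychometric functions: response
probability `expit((L_perceived − θ)/s)·(1 − lapse)` with threshold θ per
frequency, spread s (default 2 dB), and lapse rate (default 0.01); slopes
below 1e-6 dB are treated as the deterministic step limit.  Thresholds are
measured with a modified Hughson–Westlake staircase — start 40 dB, down
10 dB after a response, up 5 dB after a miss, threshold = the lowest level
with ≥ 2 responses during ascents (a level refuted in three ascents has its
tally reset) — over the five audiometric frequencies 500, 1000, 2000, 4000
and 6000 Hz on a 5-dB grid.  Levels outside [−10, 120] dB flag the frequency
unmeasurable.

Paradigms differ only in reaction latency.  The latency maps to a level bias
through a configurable sweep rate (default 5 dB/s): a subject reacts to the
level presented `latency` seconds earlier, so the slower paradigm records
thresholds `latency × sweep_rate` dB higher.  The comparison measures each
cohort member three times per paradigm and reports clinical − remote
differences per frequency (median, quartiles, extremes, 1.5-IQR outliers).
With equal latencies the median difference is zero; a remote latency worth
one 5-dB step moves the median to −5 dB.  The sign convention (clinical −
remote; slower remote ⇒ negative median) is a package definition — prose
descriptions of such box plots are notoriously ambiguous — and is documented
at the API.  Cohort thresholds are drawn as normal-hearing listeners,
N(5, 5) dB HL clipped to [−10, 20].

## Known limitations

- Matching pursuit is the plain greedy variant; no orthogonal re-projection.
  Reconstructions therefore use the stored amplitudes, and the residual
  identity is asserted at 1e-6 relative tolerance.
- The synthetic corpus cannot stand in for field recordings (above).
- The CNN runs on a single CPU core; training wall-time, not statistical
  capacity, is what bounds the default problem sizes.
- The audiometry bias model is a deliberate single-mechanism account
  (latency × sweep rate); real paradigm differences include calibration,
  transducer and attention effects that are out of scope.
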