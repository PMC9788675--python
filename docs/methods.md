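# Methods

## Pipeline model

`respviz` treats respiratory-sound classification as an image-classification
problem. The unit of analysis is one pre-segmented audio event (a single
cough or a breathing period) with a class label: wet cough (wC), dry cough
(dC), whooping cough (whC) or restricted breathing (RB). Events are
standardized, converted to time–frequency images, and classified by a CNN;
three tasks are evaluated (C1: 4-way; C2: wC vs dC; C3: cough vs RB).
Assumptions inherited from this framing: events are already segmented (no
onset detection), mono, and essentially noise-free apart from what the
augmentation adds; all discriminative information is assumed to survive in
a 227×227 8-bit rendering of the 0–4 kHz band.

## Synthetic audio

No redistributable corpus of labelled wet/dry/whooping cough and wheeze
recordings exists, so the package generates its own study corpus. The
generator is phenomenological: it reproduces the *visual* structure that
distinguishes the classes in time–frequency images, not cough acoustics.

- **Bursts** (all cough classes): white noise band-limited to 50–4000 Hz
  (order-4 Butterworth bandpass) under a 10 ms linear attack and an
  exponential decay. The decay constant is a fraction of burst length —
  0.8 for wC (sustained response across the event), 0.25 for dC
  (percussive bursts with a silent gap), 0.3 for whC.
- **Whoop** (whC): an 800→1500 Hz linear chirp held for 0.75 s after three
  short bursts.
- **Wheeze** (RB): a 400 Hz tone amplitude-modulated at 0.3 Hz (the
  breathing-cycle rate), spanning the 2 s event.
- A Gaussian noise floor (relative amplitude 0.02, scaled ×0.05) underlies
  every event; peak amplitude is normalized to 0.9 to leave filtering
  headroom. Generation runs at 44.1 kHz so the 20 kHz standardization path
  is always exercised.

Default event durations (wC 0.7 s, dC 0.8 s, whC 1.8 s, RB 2.0 s) and the
corpus composition (27/19/97/25 events) reflect the study conditions the
pipeline was designed for; per-event jitter (±20 % onsets, ±10 % lengths
and frequencies) is drawn from the corpus seed. What passing tests on this
corpus shows: the pipeline's bookkeeping, transforms and training protocol
behave as specified, and the classifier can exploit genuine time–frequency
differences. What it does **not** show: performance on real recordings,
whose within-class variability (recording chain, subject, background noise)
the generator deliberately does not model.

## Preprocessing

Polyphase rational resampling to 20 kHz (anti-aliased), then an order-8
Butterworth lowpass at f_c = 4 kHz applied forward–backward
(`sosfiltfilt`), i.e. zero phase, so spectrogram features are attenuated in
place rather than smeared. The filter family and order are configuration
options (`cheby2` and `ellip` alternatives provided) because only the
cutoff is a fixed design point; Butterworth was chosen for its ripple-free
passband, which makes the energy-non-increase and idempotence contracts
clean. Events too short for filtfilt's edge padding fall back to a single
forward pass.

## Time–frequency transforms

- **STFT**: 25 ms Hamming window (500 samples at 20 kHz), FFT length 512,
  overlap 0.90 (hop = 50 samples); 0.50 overlap supported for the cheaper
  variant (columns in ratio ≈ 5:1). Normalization is pinned: an entry is
  `|DFT(window·frame)|²` one-sided with no further scaling, so Parseval's
  identity reads `Σ_k |X_k|² = N·Σ_n |w_n x_n|²` over the full spectrum.
- **Log spectrogram**: per-column linear interpolation of STFT power onto
  64 geometrically spaced frequencies, 20 Hz–4 kHz.
- **Mel**: 64 triangular filters, HTK mel scale, 20 Hz–4 kHz, no area
  normalization. At 64 bands the lowest triangles are narrower than the
  39 Hz FFT bin spacing; a filter that would capture no bin receives unit
  weight at its nearest bin so every band stays positive.
- **CWT**: analytic Morlet (`cmor1.5-1.0`), 12 voices/octave, 20 Hz–4 kHz
  (92 scales), FFT-based convolution; rows ordered by ascending
  pseudo-frequency.

Window, FFT, band and voice counts are conventional values consistent with
how such visualizations usually look; all are exposed in configuration
rather than hard-coded.

## Rendering

Power → dB, clipped to [max − 80 dB, max] (explicit bounds available for
comparative rendering), normalized, bilinearly resized to 227×227 without
preserving aspect ratio, mapped through a colormap, frequency pointing up.
The default colormap is the identity gray ramp: the classifier input is
triplicated grayscale anyway, and an identity ramp makes rendering exactly
monotone in input power (a tested invariant). Any matplotlib colormap may
be substituted for figures. An all-zero matrix renders at the floor, by
definition rather than as an error. Grayscale conversion uses the broadcast
luma weights (0.299, 0.587, 0.114) everywhere.

The **aggregate image** stacks grayscale renderings as channels in the
fixed order red = linear spectrogram, green = Mel-spectrogram, blue =
wavelet scalogram. Composition requires all three inputs to share an event
id; mixing events would fabricate an observation. Channel extraction
recovers the three inputs exactly (tested round-trip).

## Dataset construction

Order matters and is fixed: (1) hold out 8 events per class (≈10 % of the
largest class) *before* augmentation — test images are never duplicates and
no image derived from a test event can reach training (a mandatory leakage
test enforces this); (2) oversample each class's training images to the
largest class (89) by duplicating uniformly chosen originals with an
additive Gaussian pixel-noise overlay, σ = 5 on the 8-bit scale, clipped to
[0, 255] — mild enough to keep visual structure, sufficient that every
duplicate differs from its source; (3) relabel for the task (C2 drops
whC/RB; C3 merges coughs); (4) stratified 70/30 train/validation split of
the augmented pool. Undersampling to the smallest class is available as a
configuration alternative but is not the default.

Note an accounting quirk: under this procedure the oversampled C3 pool is
267 cough + 89 RB images (3×89 and 89). Published descriptions of this
protocol have quoted 262/97 for the same construction; those totals are not
reconstructible from the stated steps, so the implementation follows the
steps and documents the difference here.

## Classifier and training

Default backbone is a small from-scratch CNN in numpy: Conv(3→8, 7×7,
stride 4) → ReLU → maxpool 2×2 → Conv(8→16, 3×3) → ReLU → maxpool →
dense head, softmax output, cross-entropy loss. Training: SGD with momentum
0.9, mini-batch 15, ≤ 10 epochs, base learning rate 1e-4, reshuffled every
epoch; the dense head uses a learning-rate multiplier of 20 (faster
learning for the new layers) while the convolutional layers use a
configurable multiplier — 1.0 by default for the from-scratch backbone
(nothing is transferred, so there is nothing to protect) and intended to be
< 1 (e.g. 0.1) for the pretrained path, where preserving transferred
features is the point. A gradient-isolation test pins the mechanism: one
step with head multiplier 20 vs backbone 0.1 moves head weights far more.

The pretrained AlexNet-compatible backbone is feature-flagged behind an
optional torch/torchvision dependency and raises a clear ImportError when
that dependency is absent; the from-scratch path keeps the package fully
self-contained. He-normal initialization, argmax ties break to the lowest
class index, and everything is deterministic given the seed (single
generator drives initialization and shuffling).

## Evaluation

Confusion matrix → accuracy (trace/total), per-class precision/recall,
F1 = 2PR/(P+R) with F1 := 0 when P+R = 0, support-weighted by default
(macro switchable — the weighted variant is used throughout for
consistency across the three tasks), and Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products; κ is
reported as missing (None) when p_e = 1, where it is undefined. The
implementation is direct formula evaluation; tests cross-check it against
scikit-learn's independent implementations on arbitrary label sequences.

## Problem sizes and numerical choices

The end-to-end experiment used by the test suite and the acceptance script
runs the full 168-event synthetic corpus (27/19/97/25), task C3 on
aggregate images, ≈ 350 training images, 10 epochs — about 1.5 minutes on
one CPU, dominated by the 92-scale CWT. The tiny bookkeeping tests use 4
events per class with 1 held out. Tolerances: STFT-vs-brute-DFT agreement
at 1e-8 absolute; mel projection at 1e-12 relative; CWT ridge within one
voice (2^(1/12)); stopband attenuation within a factor 2 of the designed
|H|²; the end-to-end accuracy contract (≥ 0.85 on the separable synthetic
C3 task) is an engineering threshold, not an empirical claim about real
data.

## Known limitations

- The synthetic classes are far more separable than clinical recordings;
  end-to-end accuracies near 1.0 on them say nothing about clinical
  performance.
- The whoop and wheeze have fixed spectral prototypes per class; there is
  no subject-level variation model.
- The pretrained transfer-learning path is untestable without the optional
  dependency and pretrained weights.
- No audio-domain augmentation (time-stretch, pitch-shift) — augmentation
  is image-domain only, matching the pipeline's design.
- Wavelet scalograms are computed on the full sample grid and then resized;
  for very long events this is memory-hungry (≈ 30 MB per 2 s event at
  float64) though not limiting at this corpus scale.
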