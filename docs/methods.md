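# Methods

## Problem setting

The package classifies passive driver fatigue from short multi-channel
EEG windows. Five ordinal classes (0 = normal … 4 = full fatigue) are
evaluated in four nested cases: I = {normal, full fatigue},
II = I ∪ {fatigue}, III = II ∪ {semi-fatigue}, IV = all five. Only four
channels are used — P4, C3, O1, O2 — parietal/central/occipital sites
where theta- and alpha-band fatigue correlates are strongest.

## Synthetic cohort generator

No public recordings exist for this task, so all experiments run on
synthetic cohorts with the statistical structure the classifier assumes.

Each window is a sum over the four canonical bands (delta 0.5–4 Hz,
theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz) of five random-frequency,
random-phase sinusoids whose total variance equals the class's relative
band power, plus Gaussian sensor noise. A filtered-noise band generator
(4th-order Butterworth bandpassed white noise) is available behind
`mode="filtered_noise"`. Channels blend a band process shared across
channels with an independent one at weight 0.5 each (in variance), so
expected inter-channel correlation is ≈ 0.5 — enough structure for the
connectivity graph without making channels redundant.

Default class profiles (relative band powers):

| class | delta | theta | alpha | beta |
|---|---|---|---|---|
| 0 normal | 0.8 | 0.4 | 0.8 | 1.4 |
| 1 alert-for-fatigue | 0.8 | 0.7 | 0.9 | 1.2 |
| 2 semi-fatigue | 0.8 | 1.0 | 1.0 | 1.0 |
| 3 fatigue | 0.8 | 1.4 | 1.1 | 0.7 |
| 4 full fatigue | 0.8 | 1.9 | 1.2 | 0.4 |

Theta rises and beta falls monotonically with fatigue, alpha drifts
upward — the gradient the EEG fatigue literature motivates. Noise floor
2 µV per channel; an overall 10 µV amplitude scale puts raw windows
around ±50 µV (cosmetic realism only). Sampling rate 250 Hz, 5-s windows
(1,250 samples). Mains contamination (50 Hz sinusoid, random phase per
channel) and white noise at an exact empirical SNR are separate, seeded
corruptions.

What the generator does **not** emulate: 1/f background spectra,
non-stationarity within a window, eye-blink/EMG artifacts, volume
conduction geometry, inter-subject variability. Passing tests therefore
demonstrate that the pipeline recovers the band-power class structure it
is built for — not performance on real recordings.

## Preprocessing

Channel selection (case-insensitive 10–20 match, reordered to
P4/C3/O1/O2), then a second-order IIR notch at 50 Hz, then a
second-order Butterworth bandpass 0.02–50 Hz, then the terminal 5 s of
the recording, then per-channel min–max normalization to [0, 1].

- All filters are applied forward–backward (zero phase): no group delay
  on 5-s windows; the effective magnitude response is the squared
  single-pass response.
- Notch quality factor Q = 30 (configurable): ~1.7 Hz stopband width,
  passband within 0.001 dB at 10 Hz.
- Filtering happens on the full recording *before* terminal-window
  extraction. The 0.02 Hz highpass edge has a ~8 s time constant; on
  recordings shorter than a minute it is effectively inert and its edge
  transient dominates broadband measurements — steady-state gains should
  be read off the frequency response, not signal RMS.
- Min–max normalization is per channel per window (the per-recording
  alternative is a flag-level change); constant channels map to zeros
  with a `RuntimeWarning`. Normalization happens after splitting and
  before augmentation, so synthetic windows are generated directly in
  the normalized [0, 1] convention.

## Channel graph

Edges are |Pearson r| between channels pooled over training windows only;
the adjacency is frozen before validation/test data are seen. Absolute
value: negative coupling counts as connectivity. Default sparsification
threshold 0.5 on |r| (weights retained; `binarize` flag available);
a disconnected result warns rather than fails. Desk-scale experiments in
the tests use 0.3 because the generator's design correlation is ≈ 0.5,
and filtering leaves edge weights hovering at the default cutoff.

The symmetric normalized Laplacian L = I − D^(−1/2) A D^(−1/2) assigns
isolated nodes identity rows (keeping L PSD with spectrum in [0, 2]);
λ_max = 0 (null graph) is an error. Rescaling to L̃ = (2/λ_max) L − I
uses the exact largest eigenvalue by default (n = 4 makes this free);
`mode="approx"` fixes λ_max = 2 for parity with common implementations.

## Classifier

Five Chebyshev graph-conv layers (orders C₁…C₅ = 1 at the published
optimum, configurable), each followed by Leaky-ReLU (slope 0.01) and
batch normalization (statistics pooled over batch and nodes), then
dropout 0.3, flattening, and a fully connected softmax head. Node count
stays 4 throughout; per-node feature widths shrink along the chain.
The full-scale replica keeps the published chain
2920→2920→1460→730→365→180 (flatten 720); its per-layer trainable-array
counts are what `count_parameters` reproduces analytically. The head
width equals the active case's class count (4 in the replica's printed
table; 5 for case IV).

**Spectral front end.** Desk-scale models prepend a fixed, non-trainable
transform: per-node Welch log-power (1-s Hann segments, 50 % overlap,
126 bins for 250 Hz). Random-phase band-limited signals have zero mean
at every sample — their class information lives entirely in the spectrum
— so raw-sample inputs give chance-level generalization at desk-scale
sample sizes regardless of optimizer (verified against an independent
MLP baseline), while the log-periodogram restores the separability the
band-power structure guarantees. The front end adds no parameters and is
disabled (`front_end="none"`) in the full-scale replica used for
parameter accounting.

**Training.** Adamax (the infinity-norm Adam variant), cross-entropy,
weight decay 4×10⁻⁴ (classic L2 added to gradients), batch size 16.
Full-scale defaults: learning rate 10⁻⁴, 150 epochs. Desk-scale smoke
runs use 3×10⁻³ for 30 epochs — a 30-epoch budget needs a larger step
size; all other settings unchanged. Model selection keeps the weights of
the best validation accuracy, ties broken by lower validation loss, then
earlier epoch. Splits are stratified 70/20/10 per class
(floor-then-distribute-remainder); the shuffle key is the window id, so
partitions are insensitive to input order.

## GAN augmentation

One generator/discriminator pair per class, trained on that class's
normalized training windows with the non-saturating BCE loss and Adam
(lr 10⁻³, batch 10, β₁ = 0.5). The generator projects a 100-d latent
vector to a 1-D convolutional stack whose temporal lengths grow
128→256→512→window length (linear-interpolation upsampling between conv
stages, kernel 5); a sigmoid output keeps samples in [0, 1] like
normalized real windows. The discriminator is four fully connected
layers (512, 256, 128, 1) with dropout 0.3 after the first. Real windows
are normalized first, then augmented; every synthetic window carries an
`is_augmented` provenance flag and the pipeline refuses configurations
that would fit the GAN on anything but the training split.

## Metrics

Confusion matrices are rows-true/columns-predicted. Binary cases use the
standard TP/TN/FP/FN substitutions with class index 1 (the more fatigued
class) as positive; multiclass scalars are macro averages of one-vs-rest
values, with zero-denominator classes flagged NaN and excluded (with a
warning). Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the marginals;
when p_e = 1 (both raters constant) κ is defined as 1 for perfect
agreement and 0 otherwise. ROC curves are one-vs-rest with trapezoidal
AUC (scikit-learn provides the sweep).

## Robustness sweep

Test windows are corrupted with Gaussian white noise at each requested
SNR (the realization is rescaled so the empirical SNR is exact), then
re-normalized per channel before inference, since the model consumes
min–max-normalized windows; a clean reference accuracy is always
reported. On the default 2-class cohort, accuracy holds near the clean
value through 10 dB and collapses to chance around 0 dB.

## Problem sizes and numerics

Desk-scale experiments use 100 windows per class, 30 training epochs and
the 64/32/16/8/8 feature chain; GAN property checks run on 1-s windows
with a proportionally scaled generator. Chebyshev recursion agrees with
eigendecomposition-based filtering to ~1e−12 (tolerance 1e−8 in tests);
filter responses match closed forms (including bilinear prewarping) to
~1e−12 (tolerance 1e−4); all layer gradients are verified against
central finite differences at tolerance 1e−7. Seeds: every stochastic
component (generator, splits, initialization, dropout, GAN sampling,
noise injection) is an explicit function of a user-supplied seed;
spawned `SeedSequence` children keep windows independent.

## Known limitations

- Synthetic-only validation; headline accuracies on the original private
  cohort are not reproducible and are not claimed.
- The GAN is judged only by mean-periodogram proximity, not by
  distributional realism.
- The 5-class case is markedly harder than the binary case at desk-scale
  sample sizes (≈ 0.7 test accuracy); this matches the expected
  difficulty ordering but absolute values depend on the synthetic effect
  sizes.
- Batch-norm statistics are pooled across nodes; a per-node variant is a
  plausible alternative the published description does not disambiguate.
- EDF reading is supported (via MNE); EDF writing is not — synthetic
  cohorts are stored as CSV directories with a manifest.
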