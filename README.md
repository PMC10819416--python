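# fatiguegcn

Multi-class detection of passive driver fatigue from EEG, built around two
components: per-class GAN augmentation of short EEG windows, and a
Chebyshev graph-convolutional classifier operating on a
functional-connectivity graph of four channels (P4, C3, O1, O2 in the
10–20 system). Five ordinal fatigue classes — normal, alert-for-fatigue,
semi-fatigue, fatigue, full fatigue — are evaluated in four nested cases:
case I (normal vs full fatigue, 2 classes) through case IV (all 5).

The human recordings behind this task were never deposited, so the package
ships a first-class **synthetic cohort generator** that emulates the
physiologically motivated structure the classifier relies on: theta
(4–8 Hz) power rises and beta (13–30 Hz) power falls with deepening
fatigue, channels share a latent band process (non-degenerate
inter-channel correlation), and windows can carry 50 Hz mains
contamination and SNR-controlled white noise.

## Model

For each trial, four channel time series become graph nodes. Edge weights
are |Pearson r| between channels pooled over the *training* windows,
thresholded to sparsity. With degree matrix D and adjacency A, the
symmetric normalized Laplacian

&nbsp;&nbsp;&nbsp;&nbsp;L = I − D^(−1/2) A D^(−1/2),&nbsp;&nbsp;
L̃ = (2 / λ_max) L − I

has spectrum in [−1, 1], on which spectral filters are expanded in
Chebyshev polynomials T₀ = I, T₁ = L̃, T_k = 2 L̃ T_{k−1} − T_{k−2}.
One graph-conv layer maps per-node features X to

&nbsp;&nbsp;&nbsp;&nbsp;Y = Σ_{k<C} T_k(L̃) X W_k + b,

followed by Leaky-ReLU and batch normalization. The classifier stacks
five such layers (feature chain 2920→2920→1460→730→365→180 in the
full-scale replica; 126→64→32→16→8→8 at desk scale), then dropout,
flattening (4 × 180 = 720 full scale) and a softmax head. Desk-scale
models prepend a fixed, non-trainable spectral front end (per-node Welch
log-power over 1-s Hann segments), since band-limited signals with random
oscillation phases carry class information only in second-order
statistics. Training: Adamax, cross-entropy, weight decay 4×10⁻⁴, batch
16, best-validation weights retained.

Augmentation trains one GAN per class on normalized windows — a 1-D
convolutional generator (temporal lengths 128→256→512→window length,
sigmoid output) against a four-layer fully connected discriminator
(512/256/128/1, dropout 0.3 after the first layer) with the
non-saturating BCE loss and Adam — then samples synthetic windows until
each class reaches the target count (e.g. 1,250 real → 2,920 total).
Synthetic windows never enter validation or test splits; a pipeline guard
enforces this.

All networks run on a small in-package numpy layer library with explicit
forward/backward passes (verified against finite differences in the test
suite).

## Worked example

```python
import fatiguegcn as fg

# 2-class cohort: normal (0) vs full fatigue (4), 100 windows per class
specs = fg.default_class_specs()
cohort = fg.CohortSpec(classes=[specs[0], specs[4]], n_windows_per_class=100, seed=0)
ds = fg.normalize_dataset(fg.select_case(fg.generate_cohort(cohort), "I"))

train_ds, val_ds, test_ds = fg.split_dataset(ds, seed=0)          # 70/20/10
graph = fg.build_channel_graph(train_ds, threshold=0.3)           # training split only
model = fg.build_model(fg.reduced_architecture(n_classes=2), graph, seed=0)
trained = fg.train(model, train_ds, val_ds,
                   fg.TrainConfig(learning_rate=3e-3, epochs=30, seed=0))

labels, probs = fg.predict(trained, test_ds)
report = fg.evaluate_predictions(test_ds.y, labels, probs, n_classes=2)
print(f"best validation accuracy: {max(trained.history['val_acc']):.3f}")
print(f"test accuracy: {report.accuracy:.3f}  kappa: {report.kappa:.3f}  "
      f"AUC: {report.roc['auc_macro']:.3f}")
```

prints

```
best validation accuracy: 1.000
test accuracy: 1.000  kappa: 1.000  AUC: 1.000
```

i.e. the binary normal/full-fatigue case is cleanly separable on the
default synthetic cohort; the 5-class case IV is substantially harder
(test accuracy ≈ 0.7 under the same budget), mirroring the accuracy
ladder expected as fatigue stages are added.

The same flow is available from the shell:

```bash
fatiguegcn simulate --class-ids 0,4 --windows-per-class 100 --seed 0 --out cohort/
fatiguegcn train --data cohort/ --case I --epochs 30 --lr 3e-3 --out run/
fatiguegcn robustness --data cohort/ --checkpoint run/model --case I --snrs 20,10,0,-10
fatiguegcn run --config config.yaml --out artifacts/   # full pipeline from YAML
```

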