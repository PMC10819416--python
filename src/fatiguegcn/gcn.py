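"""Five-layer Chebyshev graph-convolution classifier over the channel graph.

Each graph-conv layer maps per-node feature vectors through a Chebyshev
spectral filter of order C_k on the scaled Laplacian, followed by
Leaky-ReLU and batch normalization; node count stays fixed (the four EEG
channels) while per-node feature widths shrink along the layer chain.
After the fifth layer: dropout, flattening, one fully connected layer and
softmax over the active case's classes.

The full-scale replica keeps the published layer chain
2920 -> 2920 -> 1460 -> 730 -> 365 -> 180 (flatten 4 x 180 = 720), whose
per-order weight counts are reproduced exactly by
:func:`count_parameters`.  A reduced chain over 1,250-sample windows
(5 s x 250 Hz) is the default for runnable desk-scale experiments.

For desk-scale runs the model's first stage is a fixed (non-trainable)
spectral front end: per-node Welch log-power over 1-s Hann segments.
Band-limited EEG surrogates carry their class information purely in
second-order temporal statistics (random oscillation phases leave no
time-locked template), so a phase-discarding spectral representation is
what makes small-sample training generalize; the graph-conv stack then
learns on per-node spectra.  The front end adds no parameters and is
disabled in the full-scale replica used for parameter accounting.

Training follows the published recipe: Adamax, cross-entropy, weight
decay 4e-4, batch size 16; the best-validation-accuracy weights are
retained (ties: lower validation loss, then earlier epoch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import WindowedDataset
from .graph import ChannelGraph, chebyshev_matrices
from .nn import (
    Adam,
    Adamax,
    BatchNorm1d,
    ChebGraphConv,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    Sequential,
    cross_entropy,
    softmax,
)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "GCNModel",
    "full_scale_architecture",
    "reduced_architecture",
    "count_parameters",
    "build_model",
    "split_dataset",
    "train",
    "predict",
    "evaluate_accuracy",
]


@dataclass(frozen=True)
class LayerSpec:
    """One graph-convolution layer: Chebyshev order and per-node feature widths."""

    cheb_order: int
    in_features: int
    out_features: int
    negative_slope: float = 0.01
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.cheb_order < 1:
            raise ValueError("cheb_order must be >= 1")
        if self.in_features < 1 or self.out_features < 1:
            raise ValueError("feature widths must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer chain + head. ``flatten_dim`` = n_nodes x last layer width.

    ``front_end="welch"`` inserts a fixed log-power spectral transform before
    the first graph-conv layer; layer 1's ``in_features`` must then equal the
    number of spectral bins (nperseg // 2 + 1).
    """

    layers: tuple[LayerSpec, ...]
    n_nodes: int = 4
    dropout_rate: float = 0.3
    n_classes: int = 4
    front_end: str = "none"
    front_end_nperseg: int = 250

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_classes < 2:
            raise ValueError("need n_nodes >= 1 and n_classes >= 2")
        if self.front_end not in ("none", "welch"):
            raise ValueError(f"unknown front end {self.front_end!r}")
        if self.front_end == "welch" and self.layers:
            bins = self.front_end_nperseg // 2 + 1
            if self.layers[0].in_features != bins:
                raise ValueError(
                    f"welch front end yields {bins} bins but layer 1 expects "
                    f"{self.layers[0].in_features} features"
                )
        for prev, cur in zip(self.layers, self.layers[1:]):
            if cur.in_features != prev.out_features:
                raise ValueError(
                    f"layer chain broken: {prev.out_features} -> {cur.in_features}"
                )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def in_features(self) -> int:
        return self.layers[0].in_features if self.layers else 0

    @property
    def flatten_dim(self) -> int:
        return self.n_nodes * self.layers[-1].out_features if self.layers else 0


def full_scale_architecture(n_classes: int = 4, cheb: Sequence[int] = (1, 1, 1, 1, 1),
                        node_feature_len: int = 2920) -> ArchitectureSpec:
    """The published full-scale replica: 2920->2920->1460->730->365->180, FC 720->classes."""
    widths = (2920, 1460, 730, 365, 180)
    chain = (node_feature_len,) + widths
    layers = tuple(
        LayerSpec(cheb_order=c, in_features=chain[i], out_features=chain[i + 1])
        for i, c in enumerate(cheb)
    )
    return ArchitectureSpec(layers=layers, n_nodes=4, dropout_rate=0.3, n_classes=n_classes)


def reduced_architecture(widths: Sequence[int] = (64, 32, 16, 8, 8),
                         n_classes: int = 2, cheb: Sequence[int] = (1, 1, 1, 1, 1),
                         n_nodes: int = 4, front_end: str = "welch",
                         nperseg: int = 250, in_features: int | None = None) -> ArchitectureSpec:
    """Desk-scale chain over 5-s windows, with the Welch spectral front end by default.

    With ``front_end="welch"`` the first layer consumes nperseg//2 + 1 spectral
    bins per node; with ``front_end="none"`` pass the raw per-node window length
    as ``in_features``.
    """
    if len(widths) != len(cheb):
        raise ValueError("one Chebyshev order per layer required")
    if front_end == "welch":
        first = nperseg // 2 + 1
    elif in_features is None:
        raise ValueError("in_features required without a spectral front end")
    else:
        first = in_features
    chain = (first,) + tuple(widths)
    layers = tuple(
        LayerSpec(cheb_order=c, in_features=chain[i], out_features=chain[i + 1])
        for i, c in enumerate(cheb)
    )
    return ArchitectureSpec(layers=layers, n_nodes=n_nodes, dropout_rate=0.3,
                            n_classes=n_classes, front_end=front_end,
                            front_end_nperseg=nperseg)


def count_parameters(spec: ArchitectureSpec) -> dict:
    """Analytic per-layer trainable-parameter table.

    Graph-conv layer: C_k x in x out weights + out bias (+ 2 x out batch-norm);
    head: flatten_dim x n_classes weights + n_classes bias.  Matches a
    brute-force enumeration of the instantiated arrays.
    """
    rows = []
    total = 0
    for i, layer in enumerate(spec.layers, start=1):
        per_order = layer.in_features * layer.out_features
        weights = layer.cheb_order * per_order
        bn = 2 * layer.out_features if layer.batch_norm else 0
        row = {
            "layer": f"conv{i}",
            "cheb_order": layer.cheb_order,
            "in_features": layer.in_features,
            "out_features": layer.out_features,
            "weights_per_order": per_order,
            "weights": weights,
            "bias": layer.out_features,
            "batch_norm": bn,
            "total": weights + layer.out_features + bn,
        }
        rows.append(row)
        total += row["total"]
    if spec.layers:
        fc_w = spec.flatten_dim * spec.n_classes
        rows.append({
            "layer": "fc",
            "in_features": spec.flatten_dim,
            "out_features": spec.n_classes,
            "weights": fc_w,
            "bias": spec.n_classes,
            "total": fc_w + spec.n_classes,
        })
        total += fc_w + spec.n_classes
    return {"layers": rows, "total": total}


class WelchFrontEnd:
    """Fixed per-node log-power spectrum: (batch, nodes, L) -> (batch, nodes, bins).

    Welch's method over Hann segments of ``nperseg`` samples (50% overlap),
    log1p-compressed.  No trainable parameters; gradients are not propagated
    to the raw inputs (it is always the first stage).
    """

    def __init__(self, nperseg: int) -> None:
        self.nperseg = nperseg

    @property
    def n_bins(self) -> int:
        return self.nperseg // 2 + 1

    def __call__(self, X: np.ndarray) -> np.ndarray:
        from scipy.signal import welch

        if X.shape[-1] < self.nperseg:
            raise ValueError(
                f"window length {X.shape[-1]} shorter than Welch segment {self.nperseg}"
            )
        _, p = welch(X, fs=1.0, nperseg=self.nperseg, axis=-1)
        return np.log1p(p)


class GCNModel:
    """Instantiated classifier: [spectral front end] + graph-conv stack +
    dropout + flatten + FC head."""

    def __init__(self, spec: ArchitectureSpec, graph: ChannelGraph, seed: int = 0) -> None:
        if graph.n_nodes != spec.n_nodes:
            raise ValueError(
                f"graph has {graph.n_nodes} nodes but the architecture expects {spec.n_nodes}"
            )
        self.spec = spec
        self.graph = graph
        self.front_end = (
            WelchFrontEnd(spec.front_end_nperseg) if spec.front_end == "welch" else None
        )
        rng = np.random.default_rng(seed)
        modules = []
        for i, layer in enumerate(spec.layers, start=1):
            T = chebyshev_matrices(graph.laplacian_scaled, layer.cheb_order)
            modules.append(ChebGraphConv(T, layer.in_features, layer.out_features, rng,
                                         name=f"conv{i}"))
            modules.append(LeakyReLU(layer.negative_slope))
            if layer.batch_norm:
                modules.append(BatchNorm1d(layer.out_features, name=f"bn{i}"))
        modules.append(Dropout(spec.dropout_rate, np.random.default_rng(seed + 1)))
        modules.append(Flatten())
        modules.append(Dense(spec.flatten_dim, spec.n_classes, rng,
                             init_scale=np.sqrt(1.0 / spec.flatten_dim), name="fc"))
        self.net = Sequential(*modules)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Logits for a (batch, nodes, features) input (raw windows if a
        spectral front end is configured)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (batch, nodes, features)")
        if self.front_end is not None:
            X = self.front_end(X)
        return self.net.forward(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax of logits), dropout disabled."""
        was_training = self.net.training
        self.net.eval()
        try:
            p = softmax(self.forward(X))
        finally:
            self.net.train(was_training)
        return p

    def parameters(self):
        return self.net.parameters()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


def build_model(spec: ArchitectureSpec, graph: ChannelGraph, seed: int = 0) -> GCNModel:
    return GCNModel(spec, graph, seed)


@dataclass
class TrainConfig:
    optimizer: str = "adamax"
    learning_rate: float = 0.0001
    weight_decay: float = 4e-4
    batch_size: int = 16
    epochs: int = 150
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.weight_decay, 0) < 0 or self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive, weight_decay non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy training is supported")


@dataclass
class TrainedModel:
    model: GCNModel
    architecture: ArchitectureSpec
    graph: ChannelGraph
    history: dict[str, list[float]]
    best_epoch: int
    config: TrainConfig


def split_dataset(ds: WindowedDataset, fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Stratified train/validation/test split.

    Per class: floor the fractional counts, then hand the remainder to the
    splits with the largest fractional parts (earlier split on ties).  The
    shuffle key is the window id, so the partition is insensitive to input
    order and reproducible from ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("need three non-negative fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    parts: list[list[int]] = [[], [], []]
    for class_id in sorted(set(ds.y.tolist())):
        idx = [i for i in range(len(ds)) if ds.y[i] == class_id]
        if len(idx) < 3:
            raise ValueError(f"class {class_id} has {len(idx)} windows; need >= 3 to split")
        idx.sort(key=lambda i: ds.ids[i])
        rng = np.random.default_rng([seed, class_id])
        order = rng.permutation(len(idx))
        idx = [idx[j] for j in order]
        n = len(idx)
        exact = [f * n for f in fractions]
        counts = [int(np.floor(e)) for e in exact]
        rem = n - sum(counts)
        by_frac = sorted(range(3), key=lambda j: (-(exact[j] - counts[j]), j))
        for j in by_frac[:rem]:
            counts[j] += 1
        start = 0
        for j in range(3):
            parts[j].extend(idx[start : start + counts[j]])
            start += counts[j]
    return tuple(ds.subset(sorted(p, key=lambda i: ds.ids[i])) for p in parts)


def _batched_eval(model: GCNModel, ds: WindowedDataset, batch: int = 256) -> tuple[float, float]:
    """(accuracy, mean cross-entropy loss) in inference mode."""
    model.net.eval()
    losses, correct = [], 0
    for start in range(0, len(ds), batch):
        Xb = ds.X[start : start + batch]
        yb = ds.y[start : start + batch]
        logits = model.forward(Xb)
        loss, _ = cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return correct / len(ds), float(np.sum(losses) / len(ds))


def train(model: GCNModel, train_ds: WindowedDataset, val_ds: WindowedDataset,
          config: TrainConfig) -> TrainedModel:
    """Mini-batch training; retains the best-validation-accuracy weights."""
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty train or validation split")
    if set(train_ds.ids) & set(val_ds.ids):
        raise ValueError("train and validation splits overlap")
    k = model.spec.n_classes
    present = set(train_ds.y.tolist())
    if present != set(range(k)):
        raise ValueError(
            f"training labels {sorted(present)} do not cover the {k} model classes"
        )
    if val_ds.y.max() >= k or val_ds.y.min() < 0:
        raise ValueError("validation labels out of range")

    opt_cls = {"adamax": Adamax, "adam": Adam}.get(config.optimizer.lower())
    if opt_cls is None:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    opt = opt_cls(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best = None  # (val_acc, -val_loss, -epoch, state)
    for epoch in range(config.epochs):
        model.net.train(True)
        order = rng.permutation(len(train_ds))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            model.net.zero_grad()
            logits = model.forward(train_ds.X[idx])
            loss, grad = cross_entropy(logits, train_ds.y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            model.net.backward(grad)
            opt.step()
        tr_acc, tr_loss = _batched_eval(model, train_ds)
        va_acc, va_loss = _batched_eval(model, val_ds)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        key = (va_acc, -va_loss, -epoch)
        if best is None or key > best[0]:
            best = (key, model.net.state())
    model.net.load_state(best[1])
    model.net.eval()
    return TrainedModel(model=model, architecture=model.spec, graph=model.graph,
                        history=history, best_epoch=-best[0][2], config=config)


def predict(model: GCNModel | TrainedModel, windows) -> tuple[np.ndarray, np.ndarray]:
    """(labels, class probabilities); deterministic (dropout off)."""
    if isinstance(model, TrainedModel):
        model = model.model
    X = windows.X if isinstance(windows, WindowedDataset) else np.asarray(windows, dtype=float)
    probs = model.predict_proba(X)
    return probs.argmax(axis=1), probs


def evaluate_accuracy(model: GCNModel | TrainedModel, ds: WindowedDataset) -> float:
    labels, _ = predict(model, ds)
    return float((labels == ds.y).mean())
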