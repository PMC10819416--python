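"""Classification losses with analytic gradients."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "cross_entropy", "bce_with_logits"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. logits."""
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValueError("labels out of range for logit width")
    p = softmax(logits)
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable mean binary cross-entropy on raw logits."""
    z = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return loss, (sig - t) / z.size
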