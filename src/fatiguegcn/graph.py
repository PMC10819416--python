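"""Functional-connectivity channel graph and its Chebyshev spectral machinery.

The classifier treats the selected EEG channels as graph nodes.  Edge
weights are absolute Pearson correlations between channel time series
pooled over the *training* windows only (the adjacency is frozen before
validation/test data are seen), sparsified by a threshold.  From the
adjacency we form the symmetric normalized Laplacian
L = I - D^{-1/2} A D^{-1/2} (eigenvalues in [0, 2]) and rescale it to
L~ = (2/lambda_max) L - I so its spectrum lies in [-1, 1], the domain on
which Chebyshev polynomials T_k form a stable recursion:

    T_0(x) = 1,  T_1(x) = x,  T_k(x) = 2 x T_{k-1}(x) - T_{k-2}(x).

Spectral graph filters of order K are then sums over T_k(L~) X, computed
without any eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import WindowedDataset

__all__ = [
    "ChannelGraph",
    "correlation_adjacency",
    "sparsify",
    "normalized_laplacian",
    "scaled_laplacian",
    "chebyshev_basis",
    "chebyshev_matrices",
    "build_channel_graph",
]

_SYM_TOL = 1e-10


def _pool_channels(windows) -> tuple[np.ndarray, list[str]]:
    """Stack windows into one (channels, total_samples) matrix."""
    if isinstance(windows, WindowedDataset):
        X = windows.X
        labels = [f"ch{i}" for i in range(X.shape[1])]
        return np.concatenate(list(X), axis=1), labels
    arr = np.asarray(windows, dtype=float)
    if arr.ndim == 2:
        return arr, [f"ch{i}" for i in range(arr.shape[0])]
    if arr.ndim == 3:
        return np.concatenate(list(arr), axis=1), [f"ch{i}" for i in range(arr.shape[1])]
    raise ValueError("expected a WindowedDataset, (channels, samples) or (n, channels, samples)")


def correlation_adjacency(windows) -> np.ndarray:
    """|Pearson r| between channels pooled over windows; zero diagonal, symmetric."""
    data, labels = _pool_channels(windows)
    n_ch = data.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    stds = data.std(axis=1)
    for i, s in enumerate(stds):
        if s == 0:
            raise ValueError(f"channel {labels[i]!r} is constant; correlation undefined")
    A = np.abs(np.corrcoef(data))
    np.fill_diagonal(A, 0.0)
    return (A + A.T) / 2.0


def sparsify(A: np.ndarray, threshold: float) -> np.ndarray:
    """Zero entries below ``threshold``; retained weights are kept as-is."""
    A = np.asarray(A, dtype=float)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not np.allclose(A, A.T, atol=_SYM_TOL):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -_SYM_TOL or A.max() > 1 + 1e-9:
        raise ValueError("adjacency entries must lie in [0, 1]")
    out = A.copy()
    out[out < threshold] = 0.0
    return (out + out.T) / 2.0


def normalized_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian I - D^{-1/2} A D^{-1/2}.

    Isolated (degree-0) nodes get identity rows, keeping L PSD with
    eigenvalues in [0, 2].
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=_SYM_TOL):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -_SYM_TOL:
        raise ValueError("adjacency entries must be non-negative")
    if np.abs(np.diag(A)).max(initial=0.0) > _SYM_TOL:
        raise ValueError("adjacency must have zero diagonal")
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = np.eye(A.shape[0]) - dinv[:, None] * A * dinv[None, :]
    # isolated nodes: row already equals the identity row since A row is 0
    return (L + L.T) / 2.0


def scaled_laplacian(L: np.ndarray, mode: str = "exact") -> tuple[np.ndarray, float]:
    """Map the Laplacian spectrum into [-1, 1]: L~ = (2/lambda_max) L - I.

    ``mode="exact"`` uses the true largest eigenvalue; ``mode="approx"``
    uses the upper bound lambda_max = 2 common in ChebNet implementations.
    """
    L = np.asarray(L, dtype=float)
    if not np.allclose(L, L.T, atol=1e-8):
        raise ValueError("Laplacian must be symmetric")
    if mode == "exact":
        lam = float(np.linalg.eigvalsh(L)[-1])
    elif mode == "approx":
        lam = 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if lam <= 1e-12:
        raise ValueError("lambda_max is zero (null graph); rescaling undefined")
    Lt = (2.0 / lam) * L - np.eye(L.shape[0])
    return (Lt + Lt.T) / 2.0, lam


def chebyshev_basis(Lt: np.ndarray, X: np.ndarray, K: int) -> list[np.ndarray]:
    """[T_0(L~)X, ..., T_{K-1}(L~)X] via the three-term recursion."""
    if K < 1:
        raise ValueError("K must be >= 1")
    Lt = np.asarray(Lt, dtype=float)
    X = np.asarray(X, dtype=float)
    if Lt.ndim != 2 or Lt.shape[0] != Lt.shape[1]:
        raise ValueError("L~ must be square")
    if X.shape[0] != Lt.shape[0]:
        raise ValueError("X must have one row per node")
    out = [X.copy()]
    if K >= 2:
        out.append(Lt @ X)
    for _ in range(2, K):
        out.append(2.0 * (Lt @ out[-1]) - out[-2])
    return out


def chebyshev_matrices(Lt: np.ndarray, K: int) -> np.ndarray:
    """Stack of dense polynomial matrices T_k(L~), shape (K, n, n)."""
    n = Lt.shape[0]
    return np.stack(chebyshev_basis(Lt, np.eye(n), K))


def _connected(A: np.ndarray) -> bool:
    from scipy.sparse import csgraph, csr_matrix

    n_comp, _ = csgraph.connected_components(csr_matrix(A != 0), directed=False)
    return n_comp == 1


@dataclass
class ChannelGraph:
    """Frozen channel graph: adjacency plus derived spectral operators."""

    adjacency: np.ndarray
    threshold: float
    lambda_max: float
    laplacian_norm: np.ndarray
    laplacian_scaled: np.ndarray
    channel_labels: Sequence[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))


def build_channel_graph(
    windows,
    threshold: float = 0.5,
    binarize: bool = False,
    mode: str = "exact",
    channel_labels: Sequence[str] = (),
) -> ChannelGraph:
    """Adjacency from training windows -> sparsify -> Laplacians, in one step.

    Warns (does not fail) if thresholding disconnects the channel graph.
    """
    A = sparsify(correlation_adjacency(windows), threshold)
    if binarize:
        A = (A > 0).astype(float)
    if not _connected(A):
        warnings.warn(
            f"channel graph is disconnected at threshold {threshold}", RuntimeWarning
        )
    L = normalized_laplacian(A)
    Lt, lam = scaled_laplacian(L, mode=mode)
    return ChannelGraph(A, threshold, lam, L, Lt, list(channel_labels))
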