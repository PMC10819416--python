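"""Readers and writers: EDF recordings, CSV channel matrices, cohort
directories, window archives, graph edge lists and model checkpoints.

Cohorts are stored as a flat directory of per-window CSV files
(rows = channels, cols = samples) plus a ``labels.csv`` manifest
(window_id, class_id, seed, is_augmented) and a ``cohort.json`` header
(sampling rate, channel labels).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EEGRecording, WindowedDataset
from .graph import ChannelGraph

__all__ = [
    "read_raw_edf",
    "read_csv_matrix",
    "write_csv_matrix",
    "write_cohort_csv",
    "read_cohort_csv",
    "save_window_archive",
    "load_window_archive",
    "export_graph",
    "import_graph",
    "save_checkpoint",
    "load_checkpoint",
]


def read_raw_edf(path, recording_id: str | None = None) -> EEGRecording:
    """Load an EDF/EDF+ recording (data returned in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, list(raw.ch_names), float(raw.info["sfreq"]),
                        recording_id or Path(path).stem)


def read_csv_matrix(path, fs: float, channel_labels: Sequence[str] | None = None,
                    recording_id: str | None = None) -> EEGRecording:
    """Plain channels x samples CSV; labels from a `<path>.labels` sidecar if present."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if channel_labels is None:
        sidecar = path.with_suffix(path.suffix + ".labels")
        if sidecar.exists():
            channel_labels = [s.strip() for s in sidecar.read_text().split(",") if s.strip()]
        else:
            channel_labels = [f"ch{i}" for i in range(data.shape[0])]
    return EEGRecording(data, channel_labels, fs, recording_id or path.stem)


def write_csv_matrix(path, data: np.ndarray) -> None:
    np.savetxt(path, np.asarray(data), delimiter=",", fmt="%.8g")


def write_cohort_csv(ds: WindowedDataset, out_dir, fs: float,
                     channel_labels: Sequence[str] = ()) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, wid in enumerate(ds.ids):
        fname = f"{wid}.csv"
        write_csv_matrix(out / fname, ds.X[i])
        p = ds.provenance[i]
        rows.append({
            "window_id": wid,
            "class_id": int(ds.y[i]),
            "seed": int(p.get("seed", -1)),
            "is_augmented": bool(p.get("is_augmented", False)),
            "file": fname,
        })
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    (out / "cohort.json").write_text(json.dumps({
        "fs": fs,
        "channel_labels": list(channel_labels),
        "n_windows": len(ds),
        "n_channels": ds.n_channels,
        "n_samples": ds.n_samples,
    }, indent=2))
    return out


def read_cohort_csv(in_dir) -> tuple[WindowedDataset, dict]:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "cohort.json").read_text())
    manifest = pd.read_csv(in_dir / "labels.csv")
    X, y, ids, prov = [], [], [], []
    for row in manifest.itertuples(index=False):
        X.append(np.loadtxt(in_dir / row.file, delimiter=",", ndmin=2))
        y.append(int(row.class_id))
        ids.append(str(row.window_id))
        prov.append({"class_id": int(row.class_id), "seed": int(row.seed),
                     "is_augmented": bool(row.is_augmented)})
    return WindowedDataset(np.stack(X), np.array(y), ids, prov), meta


def save_window_archive(path, arrays: dict[str, np.ndarray], meta: dict) -> None:
    """Compressed array archive with a JSON header (portable, not bit-exact)."""
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_window_archive(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return arrays, meta


def export_graph(graph: ChannelGraph, csv_path, json_path=None) -> None:
    """Edge list (i, j, weight) for i < j, plus a JSON header."""
    csv_path = Path(csv_path)
    n = graph.n_nodes
    rows = [
        {"i": i, "j": j, "weight": graph.adjacency[i, j]}
        for i in range(n) for j in range(i + 1, n) if graph.adjacency[i, j] != 0
    ]
    pd.DataFrame(rows, columns=["i", "j", "weight"]).to_csv(csv_path, index=False)
    header = {
        "n_nodes": n,
        "threshold": graph.threshold,
        "lambda_max": graph.lambda_max,
        "channel_labels": list(graph.channel_labels),
    }
    jpath = Path(json_path) if json_path else csv_path.with_suffix(".json")
    jpath.write_text(json.dumps(header, indent=2))


def import_graph(csv_path, json_path=None) -> ChannelGraph:
    from .graph import normalized_laplacian, scaled_laplacian

    csv_path = Path(csv_path)
    jpath = Path(json_path) if json_path else csv_path.with_suffix(".json")
    header = json.loads(jpath.read_text())
    n = int(header["n_nodes"])
    A = np.zeros((n, n))
    edges = pd.read_csv(csv_path)
    for row in edges.itertuples(index=False):
        A[int(row.i), int(row.j)] = A[int(row.j), int(row.i)] = float(row.weight)
    L = normalized_laplacian(A)
    Lt, lam = scaled_laplacian(L)
    return ChannelGraph(A, float(header["threshold"]), lam, L, Lt,
                        header.get("channel_labels", []))


def save_checkpoint(trained, prefix) -> None:
    """Weights (npz) + JSON architecture/graph sidecar."""
    from dataclasses import asdict

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    weights = {f"p{i:04d}": p.value for i, p in enumerate(trained.model.parameters())}
    # batch-norm running statistics are state, not parameters
    buffers = {}
    for j, m in enumerate(trained.model.net.modules):
        if hasattr(m, "running_mean"):
            buffers[f"rm{j:04d}"] = m.running_mean
            buffers[f"rv{j:04d}"] = m.running_var
    np.savez_compressed(str(prefix) + ".npz", **weights, **buffers,
                        adjacency=trained.graph.adjacency)
    spec = trained.architecture
    meta = {
        "architecture": {
            "n_nodes": spec.n_nodes,
            "dropout_rate": spec.dropout_rate,
            "n_classes": spec.n_classes,
            "front_end": spec.front_end,
            "front_end_nperseg": spec.front_end_nperseg,
            "layers": [asdict(l) for l in spec.layers],
        },
        "graph": {
            "threshold": trained.graph.threshold,
            "lambda_max": trained.graph.lambda_max,
            "channel_labels": list(trained.graph.channel_labels),
        },
        "best_epoch": trained.best_epoch,
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(prefix):
    from .gcn import ArchitectureSpec, GCNModel, LayerSpec
    from .graph import normalized_laplacian, scaled_laplacian

    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    with np.load(str(prefix) + ".npz") as z:
        A = z["adjacency"]
        weights = [z[k] for k in sorted(k for k in z.files if k.startswith("p"))]
        buffers = {k: z[k] for k in z.files if k.startswith(("rm", "rv"))}
    L = normalized_laplacian(A)
    Lt, lam = scaled_laplacian(L)
    g = ChannelGraph(A, meta["graph"]["threshold"], lam, L, Lt,
                     meta["graph"].get("channel_labels", []))
    arch = meta["architecture"]
    spec = ArchitectureSpec(
        layers=tuple(LayerSpec(**l) for l in arch["layers"]),
        n_nodes=arch["n_nodes"],
        dropout_rate=arch["dropout_rate"],
        n_classes=arch["n_classes"],
        front_end=arch.get("front_end", "none"),
        front_end_nperseg=arch.get("front_end_nperseg", 250),
    )
    model = GCNModel(spec, g, seed=0)
    model.net.load_state(weights)
    for j, m in enumerate(model.net.modules):
        if hasattr(m, "running_mean") and f"rm{j:04d}" in buffers:
            m.running_mean = buffers[f"rm{j:04d}"]
            m.running_var = buffers[f"rv{j:04d}"]
    model.net.eval()
    return model, g
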