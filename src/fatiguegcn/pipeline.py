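"""End-to-end orchestration: simulate -> preprocess -> split -> augment ->
graph -> train -> evaluate, from a single YAML/dict configuration.

Every stage failure is re-raised with a stage tag.  A leakage guard
refuses configurations that would fit the GAN or the channel graph on
anything but the training split, and asserts post hoc that no synthetic
window entered validation/test.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cases import define_case
from .containers import EEGRecording, WindowedDataset
from .gan import DiscriminatorSpec, GANConfig, GeneratorSpec, augment_to_count
from .gcn import TrainConfig, build_model, predict, reduced_architecture, split_dataset, train
from .graph import build_channel_graph
from .io import export_graph, save_checkpoint
from .metrics import evaluate_predictions
from .preprocess import DEFAULT_CHANNEL_ORDER, normalize_dataset, preprocess_recording
from .robustness import snr_robustness_sweep
from .synthetic import CohortSpec, default_class_specs, generate_cohort

__all__ = ["PipelineError", "DEFAULT_CONFIG", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "case": "I",
    "simulate": {
        "windows_per_class": 40,
        "fs": 250.0,
        "window_s": 5.0,
        "record_s": 10.0,  # simulated recordings; terminal window_s is kept
        "mains_amplitude": 10.0,
    },
    "preprocess": {"notch_hz": 50.0, "band": [0.02, 50.0], "notch_q": 30.0},
    "split": {"fractions": [0.7, 0.2, 0.1]},
    "augment": {
        "enabled": False,
        "target_per_class": None,
        "iterations": 100,
        "learning_rate": 0.001,
        "batch_size": 10,
        "fit_on": "train",
    },
    "graph": {"threshold": 0.5, "binarize": False},
    "model": {
        "widths": [64, 32, 16, 8, 8],
        "cheb": [1, 1, 1, 1, 1],
        "dropout": 0.3,
        "front_end": "welch",
        "nperseg": 250,
    },
    "train": {
        "epochs": 30,
        "batch_size": 16,
        "learning_rate": 0.003,
        "weight_decay": 4e-4,
        "optimizer": "adamax",
    },
    "evaluate": {"snr_sweep": []},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: dict | str | Path, out_dir) -> dict[str, Any]:
    """Run the full pipeline; returns the metrics dict and writes artifacts to ``out_dir``."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"start {time.strftime('%Y-%m-%dT%H:%M:%S')}", f"seed {cfg['seed']}"]
    seed = int(cfg["seed"])
    case = define_case(cfg["case"])

    # leakage guard: the GAN and the graph may only ever see training windows
    if cfg["augment"].get("fit_on", "train") != "train":
        raise PipelineError(
            "[augment] refusing to fit augmentation on split "
            f"{cfg['augment']['fit_on']!r}: GAN training must use the training split only"
        )

    with _stage("simulate"):
        sim = cfg["simulate"]
        specs = [default_class_specs()[c] for c in case.class_subset]
        cohort = CohortSpec(
            classes=specs,
            n_windows_per_class=int(sim["windows_per_class"]),
            fs=float(sim["fs"]),
            window_s=float(sim["record_s"]),
            mains_amplitude=float(sim["mains_amplitude"]),
            seed=seed,
        )
        raw = generate_cohort(cohort)
        log_lines.append(f"simulate: {len(raw)} recordings, classes {case.class_subset}")

    with _stage("preprocess"):
        pp = cfg["preprocess"]
        X, y, ids, prov = [], [], [], []
        label_map = {c: i for i, c in enumerate(case.class_subset)}
        for i in range(len(raw)):
            rec = EEGRecording(raw.X[i], list(DEFAULT_CHANNEL_ORDER), cohort.fs, raw.ids[i])
            w = preprocess_recording(
                rec, DEFAULT_CHANNEL_ORDER, pp["notch_hz"],
                tuple(pp["band"]), float(sim["window_s"]), pp["notch_q"],
            )
            X.append(w.data)
            y.append(label_map[int(raw.y[i])])
            ids.append(raw.ids[i])
            prov.append(dict(raw.provenance[i], original_class=int(raw.y[i])))
        ds = WindowedDataset(np.stack(X), np.array(y), ids, prov)
        log_lines.append(f"preprocess: windows {ds.X.shape}")

    with _stage("split"):
        train_ds, val_ds, test_ds = split_dataset(
            ds, tuple(cfg["split"]["fractions"]), seed=seed + 1
        )
        train_ds, val_ds, test_ds = (
            normalize_dataset(train_ds), normalize_dataset(val_ds), normalize_dataset(test_ds)
        )
        log_lines.append(
            f"split: train {len(train_ds)} / val {len(val_ds)} / test {len(test_ds)}"
        )

    with _stage("augment"):
        aug = cfg["augment"]
        if aug["enabled"]:
            target = aug["target_per_class"]
            if target is None:
                raise ValueError("augment.target_per_class required when augmentation is on")
            parts = []
            for k, c in enumerate(sorted(set(train_ds.y.tolist()))):
                cls = train_ds.subset(np.flatnonzero(train_ds.y == c))
                gcfg = GANConfig(
                    learning_rate=float(aug["learning_rate"]),
                    iterations=int(aug["iterations"]),
                    batch_size=int(aug["batch_size"]),
                    seed=seed + 100 + k,
                )
                gspec = GeneratorSpec(layer_widths=(128, 256, 512, train_ds.n_samples))
                parts.append(augment_to_count(cls, int(target), gcfg, gspec,
                                              DiscriminatorSpec()))
            train_ds = WindowedDataset.concat(parts)
            log_lines.append(f"augment: train grown to {len(train_ds)}")
        # post hoc leakage assertion: no synthetic window outside training
        for split_name, split in (("val", val_ds), ("test", test_ds)):
            if any(p.get("is_augmented") for p in split.provenance):
                raise RuntimeError(f"synthetic window leaked into {split_name} split")

    with _stage("graph"):
        g = build_channel_graph(
            train_ds, threshold=float(cfg["graph"]["threshold"]),
            binarize=bool(cfg["graph"]["binarize"]),
            channel_labels=DEFAULT_CHANNEL_ORDER,
        )
        export_graph(g, out / "graph_edges.csv")
        log_lines.append(f"graph: lambda_max {g.lambda_max:.4f}")

    with _stage("train"):
        mcfg, tcfg = cfg["model"], cfg["train"]
        spec = reduced_architecture(
            widths=tuple(mcfg["widths"]), n_classes=case.n_classes,
            cheb=tuple(mcfg["cheb"]), front_end=mcfg["front_end"],
            nperseg=int(mcfg["nperseg"]),
            in_features=None if mcfg["front_end"] == "welch" else train_ds.n_samples,
        )
        model = build_model(spec, g, seed=seed + 2)
        config_t = TrainConfig(
            optimizer=tcfg["optimizer"], learning_rate=float(tcfg["learning_rate"]),
            weight_decay=float(tcfg["weight_decay"]), batch_size=int(tcfg["batch_size"]),
            epochs=int(tcfg["epochs"]), seed=seed + 3,
        )
        trained = train(model, train_ds, val_ds, config_t)
        pd.DataFrame(trained.history).to_csv(out / "history.csv", index=False)
        save_checkpoint(trained, out / "model")
        log_lines.append(f"train: best epoch {trained.best_epoch}, "
                         f"val acc {max(trained.history['val_acc']):.4f}")

    with _stage("evaluate"):
        labels, probs = predict(trained, test_ds)
        report = evaluate_predictions(test_ds.y, labels, probs, n_classes=case.n_classes)
        metrics = {"case": case.case_id, **report.as_dict()}
        snrs = cfg["evaluate"]["snr_sweep"]
        if snrs:
            metrics["snr_sweep"] = snr_robustness_sweep(trained, test_ds, snrs, seed=seed + 4)
        pd.DataFrame(report.confusion).to_csv(out / "confusion.csv")
        if report.roc is not None:
            roc_rows = [
                {"class": c, "fpr": f, "tpr": t}
                for c, d in report.roc["per_class"].items()
                for f, t in zip(d["fpr"], d["tpr"])
            ]
            pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        log_lines.append(f"evaluate: test accuracy {report.accuracy:.4f}")

    (out / "config_echo.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return metrics
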