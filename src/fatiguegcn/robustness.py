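"""Noise-robustness evaluation: accuracy under additive white Gaussian noise.

Test windows are corrupted at a list of SNRs (dB), re-normalized per
channel (the model consumes min-max normalized windows), and scored.  A
clean reference point is always included.
"""

from __future__ import annotations

import numpy as np

from .containers import WindowedDataset
from .gcn import GCNModel, TrainedModel, evaluate_accuracy
from .preprocess import minmax_normalize
from .synthetic import add_white_noise_snr

__all__ = ["snr_robustness_sweep"]


def snr_robustness_sweep(
    model: GCNModel | TrainedModel,
    test_ds: WindowedDataset,
    snr_list_db,
    seed: int = 0,
) -> dict[str, float]:
    """Accuracy per SNR, keys "snr_<db>dB" plus a "clean" reference."""
    snr_list = list(snr_list_db)
    if not snr_list:
        raise ValueError("empty SNR list")
    if len(test_ds) == 0:
        raise ValueError("empty test set")
    results = {"clean": evaluate_accuracy(model, test_ds)}
    ss = np.random.SeedSequence(seed)
    for snr, child in zip(snr_list, ss.spawn(len(snr_list))):
        wseeds = child.generate_state(len(test_ds)) % (2**31)
        noisy = np.stack([
            minmax_normalize(add_white_noise_snr(w, snr, int(s)))
            for w, s in zip(test_ds.X, wseeds)
        ])
        corrupted = WindowedDataset(noisy, test_ds.y, test_ds.ids, test_ds.provenance)
        results[f"snr_{snr:g}dB"] = evaluate_accuracy(model, corrupted)
    return results
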