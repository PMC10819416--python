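"""Signal-conditioning chain for the fatigue classifier.

Order of operations on a raw recording: select the four informative
channels (P4, C3, O1, O2 — parietal/central/occipital sites where the
theta/alpha fatigue correlates are strongest), remove 50 Hz mains with a
second-order IIR notch, band-limit with a second-order Butterworth
bandpass (0.02-50 Hz), keep only the terminal 5 s of the recording, and
min-max normalize each channel to [0, 1].

All offline filters are applied forward-backward (zero phase), so the
effective magnitude response is the squared single-pass response and no
latency distortion is introduced on short windows.  Filtering happens on
the full recording before the terminal window is cut; on recordings
shorter than ~1 minute the 0.02 Hz highpass edge is effectively inert.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import EEGRecording, Window

__all__ = [
    "DEFAULT_CHANNEL_ORDER",
    "select_channels",
    "notch_filter",
    "notch_frequency_response",
    "bandpass_butterworth",
    "bandpass_frequency_response",
    "extract_terminal_window",
    "minmax_normalize",
    "normalize_dataset",
    "preprocess_recording",
]

DEFAULT_CHANNEL_ORDER = ("P4", "C3", "O1", "O2")

DEFAULT_NOTCH_Q = 30.0


def select_channels(
    rec: EEGRecording, names: Sequence[str] = DEFAULT_CHANNEL_ORDER
) -> EEGRecording:
    """Reduce and reorder channels (case-insensitive 10-20 label match)."""
    lookup = {lab.lower(): i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    for name in names:
        i = lookup.get(name.lower())
        if i is None:
            raise KeyError(f"channel {name!r} not present in recording {rec.recording_id!r}")
        rows.append(i)
    return EEGRecording(
        rec.data[rows].copy(), [rec.channel_labels[i] for i in rows], rec.fs, rec.recording_id
    )


def _notch_ba(fs: float, f0: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    if not 0 < f0 < fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    return signal.iirnotch(f0, q, fs=fs)


def notch_filter(
    x: np.ndarray, fs: float, f0: float = 50.0, q: float = DEFAULT_NOTCH_Q
) -> np.ndarray:
    """Zero-phase second-order IIR bandstop centered at ``f0`` (quality factor ``q``)."""
    b, a = _notch_ba(fs, f0, q)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def notch_frequency_response(
    freqs: np.ndarray, fs: float, f0: float = 50.0, q: float = DEFAULT_NOTCH_Q
) -> np.ndarray:
    """Single-pass magnitude response of the designed notch at ``freqs`` (Hz)."""
    b, a = _notch_ba(fs, f0, q)
    _, h = signal.freqz(b, a, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)


def _bandpass_sos(fs: float, lo: float, hi: float, order: int) -> np.ndarray:
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if not hi < fs / 2:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({fs / 2} Hz)")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_butterworth(
    x: np.ndarray, fs: float, lo: float = 0.02, hi: float = 50.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (second-order sections for numerical stability)."""
    sos = _bandpass_sos(fs, lo, hi, order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass_frequency_response(
    freqs: np.ndarray, fs: float, lo: float = 0.02, hi: float = 50.0, order: int = 2
) -> np.ndarray:
    """Single-pass magnitude response of the designed digital bandpass at ``freqs`` (Hz)."""
    sos = _bandpass_sos(fs, lo, hi, order)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)


def extract_terminal_window(rec: EEGRecording, window_s: float = 5.0) -> Window:
    """The final ``window_s`` seconds of a recording, interval recorded as [N-L, N)."""
    length = int(round(window_s * rec.fs))
    n = rec.n_samples
    if n < length:
        raise ValueError(
            f"recording {rec.recording_id!r} has {n} samples; need >= {length} "
            f"for a {window_s} s window at {rec.fs} Hz"
        )
    return Window(
        rec.data[:, n - length : n].copy(),
        provenance={"recording_id": rec.recording_id, "interval": (n - length, n)},
    )


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Per-channel affine rescale to [0, 1]; constant channels map to zeros with a warning."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    mins = x.min(axis=-1, keepdims=True)
    maxs = x.max(axis=-1, keepdims=True)
    span = maxs - mins
    flat = span[..., 0] == 0
    if np.any(flat):
        warnings.warn(
            "constant channel(s) in min-max normalization mapped to zeros", RuntimeWarning
        )
    out = np.zeros_like(x)
    safe = ~flat
    out[safe] = (x[safe] - mins[safe]) / span[safe]
    return out[0] if squeeze else out


def normalize_dataset(ds):
    """Per-window, per-channel min-max normalization of a WindowedDataset."""
    from .containers import WindowedDataset

    Xn = np.stack([minmax_normalize(w) for w in ds.X])
    return WindowedDataset(Xn, ds.y, ds.ids, ds.provenance)


def preprocess_recording(
    rec: EEGRecording,
    channels: Sequence[str] = DEFAULT_CHANNEL_ORDER,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.02, 50.0),
    window_s: float = 5.0,
    notch_q: float = DEFAULT_NOTCH_Q,
) -> Window:
    """Full conditioning chain: select -> notch -> bandpass -> terminal window.

    Min-max normalization is applied separately, after augmentation.
    """
    rec = select_channels(rec, channels)
    data = notch_filter(rec.data, rec.fs, notch_hz, notch_q)
    data = bandpass_butterworth(data, rec.fs, band[0], band[1])
    filtered = EEGRecording(data, rec.channel_labels, rec.fs, rec.recording_id)
    return extract_terminal_window(filtered, window_s)
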