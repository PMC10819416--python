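"""Synthetic labeled EEG cohorts for the fatigue classifier.

No public recordings back the fatigue-detection task this package targets,
so the cohort generator produces multi-channel windows whose band-power
structure carries the fatigue gradient the physiology motivates: as
drowsiness deepens, theta (4-8 Hz) power rises and beta (13-30 Hz) power
falls, with alpha (8-13 Hz) drifting upward.  Five ordinal classes span
normal (0) to full fatigue (4).

Each channel is a mixture of random-phase sinusoids per frequency band
(variance set by the class's relative band power) blended with a latent
band process shared across channels — so inter-channel correlation is
non-degenerate and the functional-connectivity graph has structure — plus
white sensor noise.  A filtered-noise band generator is available behind
``mode="filtered_noise"``.  Mains contamination and SNR-controlled white
noise are separate, explicitly seeded corruptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .containers import WindowedDataset

__all__ = [
    "BANDS",
    "CLASS_NAMES",
    "FatigueClassSpec",
    "CohortSpec",
    "default_class_specs",
    "generate_window",
    "generate_cohort",
    "inject_mains",
    "add_white_noise_snr",
]

#: Canonical EEG frequency bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

CLASS_NAMES = ("normal", "alert_for_fatigue", "semi_fatigue", "fatigue", "full_fatigue")

DEFAULT_CHANNELS = ("P4", "C3", "O1", "O2")

_SINUSOIDS_PER_BAND = 5
_AMPLITUDE_SCALE_UV = 10.0  # scales relative band powers to ~ +/-50 uV raw range
_SHARED_WEIGHT = 0.5  # latent band process shared across channels


@dataclass(frozen=True)
class FatigueClassSpec:
    """Spectral profile of one ordinal fatigue class.

    ``band_powers`` are relative (dimensionless, >= 0) variances per band;
    ``noise_floor`` is the white sensor-noise standard deviation in uV.
    """

    class_id: int
    band_powers: Mapping[str, float]
    noise_floor: float = 2.0
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.class_id <= 4:
            raise ValueError("class_id must be in 0..4")
        for band, p in self.band_powers.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if p < 0:
                raise ValueError(f"band power for {band!r} must be non-negative")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")


def default_class_specs() -> tuple[FatigueClassSpec, ...]:
    """The five default class profiles: theta rises and beta falls with class_id."""
    theta = (0.4, 0.7, 1.0, 1.4, 1.9)
    beta = (1.4, 1.2, 1.0, 0.7, 0.4)
    alpha = (0.8, 0.9, 1.0, 1.1, 1.2)
    return tuple(
        FatigueClassSpec(
            class_id=c,
            band_powers={"delta": 0.8, "theta": theta[c], "alpha": alpha[c], "beta": beta[c]},
            noise_floor=2.0,
            name=CLASS_NAMES[c],
        )
        for c in range(5)
    )


@dataclass
class CohortSpec:
    """Recipe for a balanced labeled cohort of analysis windows."""

    classes: Sequence[FatigueClassSpec] = field(default_factory=default_class_specs)
    n_windows_per_class: int = 100
    n_channels: int = 4
    fs: float = 250.0
    window_s: float = 5.0
    mains_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a cohort needs at least 2 classes")
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class_ids in cohort spec")
        if self.n_windows_per_class < 1:
            raise ValueError("n_windows_per_class must be >= 1")
        highest_edge = max(hi for _, hi in BANDS.values())
        if not self.fs > 2 * highest_edge:
            raise ValueError(f"fs must exceed twice the highest band edge ({2 * highest_edge} Hz)")
        n = self.window_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_s x fs must be an integer number of samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_s * self.fs))


def _band_sinusoids(rng: np.random.Generator, lo: float, hi: float, variance: float,
                    t: np.ndarray, fs: float) -> np.ndarray:
    """Sum of random-frequency, random-phase sinusoids with total variance ``variance``."""
    hi = min(hi, 0.95 * fs / 2)
    freqs = rng.uniform(lo, hi, size=_SINUSOIDS_PER_BAND)
    phases = rng.uniform(0.0, 2 * np.pi, size=_SINUSOIDS_PER_BAND)
    amp = np.sqrt(2.0 * variance / _SINUSOIDS_PER_BAND)
    return (amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)


def _band_filtered_noise(rng: np.random.Generator, lo: float, hi: float, variance: float,
                         n: np.ndarray, fs: float) -> np.ndarray:
    hi = min(hi, 0.95 * fs / 2)
    x = rng.standard_normal(len(n) if hasattr(n, "__len__") else n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    s = y.std()
    return y * (np.sqrt(variance) / s) if s > 0 else y


def generate_window(
    spec: FatigueClassSpec,
    n_channels: int,
    n_samples: int,
    fs: float,
    seed: int,
    shared_weight: float = _SHARED_WEIGHT,
    amplitude_scale: float = _AMPLITUDE_SCALE_UV,
    mode: str = "sinusoid",
) -> np.ndarray:
    """One (n_channels, n_samples) window drawn from a class spectral profile.

    Channels mix a band process shared across channels (weight ``shared_weight``
    of the band variance) with an independent one, so expected inter-channel
    correlation is strictly between 0 and 1. Pure function of ``seed``.
    """
    if n_channels < 1 or n_samples < 2:
        raise ValueError("need n_channels >= 1 and n_samples >= 2")
    if not fs > 0:
        raise ValueError("fs must be positive")
    if mode not in ("sinusoid", "filtered_noise"):
        raise ValueError(f"unknown generator mode {mode!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    out = np.zeros((n_channels, n_samples))
    for band, (lo, hi) in BANDS.items():
        p = float(spec.band_powers.get(band, 0.0))
        if p == 0.0:
            continue
        if mode == "sinusoid":
            common = _band_sinusoids(rng, lo, hi, p, t, fs)
            indep = [_band_sinusoids(rng, lo, hi, p, t, fs) for _ in range(n_channels)]
        else:
            common = _band_filtered_noise(rng, lo, hi, p, t, fs)
            indep = [_band_filtered_noise(rng, lo, hi, p, t, fs) for _ in range(n_channels)]
        w_c, w_i = np.sqrt(shared_weight), np.sqrt(1.0 - shared_weight)
        for ch in range(n_channels):
            out[ch] += w_c * common + w_i * indep[ch]
    out *= amplitude_scale
    if spec.noise_floor > 0:
        out += rng.normal(0.0, spec.noise_floor, size=out.shape)
    return out


def generate_cohort(cohort: CohortSpec, mode: str = "sinusoid") -> WindowedDataset:
    """Balanced labeled dataset: n_classes x n_windows_per_class windows.

    Window seeds derive from ``cohort.seed`` via a SeedSequence, so the cohort
    is reproducible and windows are mutually independent.
    """
    ss = np.random.SeedSequence(cohort.seed)
    n = cohort.n_samples
    X, y, ids, prov = [], [], [], []
    classes = sorted(cohort.classes, key=lambda c: c.class_id)
    children = ss.spawn(len(classes) * cohort.n_windows_per_class)
    k = 0
    for spec in classes:
        for j in range(cohort.n_windows_per_class):
            wseed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            w = generate_window(spec, cohort.n_channels, n, cohort.fs, wseed, mode=mode)
            if cohort.mains_amplitude > 0:
                w = inject_mains(w, cohort.fs, amplitude=cohort.mains_amplitude, seed=wseed + 1)
            X.append(w)
            y.append(spec.class_id)
            ids.append(f"c{spec.class_id}w{j:05d}")
            prov.append(
                {"class_id": spec.class_id, "seed": wseed, "is_augmented": False,
                 "source": "synthetic"}
            )
    return WindowedDataset(np.stack(X), np.array(y), ids, prov)


def inject_mains(
    window: np.ndarray,
    fs: float,
    f0: float = 50.0,
    amplitude: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Add mains contamination: amplitude * sin(2 pi f0 t + phi), phi random per channel."""
    window = np.asarray(window, dtype=float)
    if not 0 < f0 < fs / 2:
        raise ValueError(f"mains frequency {f0} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    if amplitude == 0:
        return window.copy()
    rng = np.random.default_rng(seed)
    n_ch, n = window.shape
    t = np.arange(n) / fs
    phases = rng.uniform(0.0, 2 * np.pi, size=n_ch)
    return window + amplitude * np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None])


def add_white_noise_snr(window: np.ndarray, snr_db: float, seed: int = 0) -> np.ndarray:
    """Add Gaussian white noise at an exact empirical SNR (dB) relative to the window.

    The noise realization is rescaled so that 10*log10(P_signal/P_noise)
    equals ``snr_db`` to within floating-point error.
    """
    window = np.asarray(window, dtype=float)
    p_signal = float(np.mean(window**2))
    if p_signal == 0.0:
        raise ValueError("all-zero window: SNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(window.shape)
    p_target = p_signal / 10 ** (snr_db / 10.0)
    p_noise = float(np.mean(noise**2))
    if p_noise == 0.0:  # pragma: no cover - degenerate RNG draw
        raise RuntimeError("degenerate noise draw")
    noise *= np.sqrt(p_target / p_noise)
    return window + noise
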