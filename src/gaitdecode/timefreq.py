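"""Morlet-wavelet time–frequency decomposition, spectral perturbation (ERSP)
and event-related desynchronisation (ERD) summaries.

Each epoch is analysed in short windows of 107 samples whose centres are
evenly spaced over the valid positions; at every window a complex Morlet
inner product is taken at 20 log-spaced frequencies between 8 and 40 Hz,
with the cycle count growing linearly from 3 at the lowest to 7.5 at the
highest bin.  Squared magnitudes are floored and converted to dB
(10·log10).  For an 8 s epoch at 256 Hz this yields the canonical
20 × 50 grid spanning −3.789 … +3.789 s around the epoch centre; for 2 s
sliding epochs a 20 × 14 grid spanning ±0.79 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU_BAND = (8.0, 15.0)
BETA_BAND = (16.0, 31.0)


@dataclass(frozen=True)
class TFConfig:
    freqs: np.ndarray = field(
        default_factory=lambda: np.geomspace(8.0, 40.0, 20))
    n_windows: int = 50
    window_len: int = 107
    cycles: np.ndarray = field(
        default_factory=lambda: np.linspace(3.0, 7.5, 20))
    power_floor: float = 1e-20

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        c = np.asarray(self.cycles, float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "cycles", c)
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.diff(c) < 0):
            raise ValueError("cycle counts must be non-decreasing")
        if len(f) != len(c):
            raise ValueError("freqs and cycles must align")

    @classmethod
    def batch(cls) -> "TFConfig":
        return cls(n_windows=50)

    @classmethod
    def sliding(cls) -> "TFConfig":
        return cls(n_windows=14)

    def window_centers(self, n_samples: int) -> np.ndarray:
        """0-based sample indices of the window centres."""
        half = self.window_len // 2
        if n_samples < self.window_len:
            raise ValueError("epoch shorter than the analysis window")
        first, last = half + 1, n_samples - half - 1
        return np.round(np.linspace(first, last, self.n_windows)).astype(int)

    def times(self, n_samples: int, fs: float) -> np.ndarray:
        """Window-centre times (s) relative to the epoch centre."""
        return (self.window_centers(n_samples) - n_samples / 2) / fs

    def wavelet_bank(self, fs: float) -> np.ndarray:
        """(window_len, n_freqs) complex Morlet bank, unit L2 norm each."""
        half = self.window_len // 2
        t = (np.arange(self.window_len) - half) / fs
        bank = np.empty((self.window_len, len(self.freqs)), complex)
        for j, (f, c) in enumerate(zip(self.freqs, self.cycles)):
            sigma = c / (2.0 * np.pi * f)
            w = np.exp(2j * np.pi * f * t) * np.exp(-t ** 2 / (2 * sigma ** 2))
            bank[:, j] = w / np.linalg.norm(w)
        return bank


@dataclass
class TFTensor:
    """Log-power values (dB) on the trials × components × freqs × times grid."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    config: TFConfig

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be (trials, components, freqs, windows)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-power must be finite (power floor applied)")

    @property
    def linear_power(self) -> np.ndarray:
        return 10.0 ** (self.values / 10.0)


@dataclass(frozen=True)
class ErdSummary:
    A: float            # mean linear band power in the region of interest
    R: float            # mean linear band power in the reference period
    erd_percent: float  # (A − R)/R × 100

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("reference power must be positive")


def wavelet_tf(data: np.ndarray, config: TFConfig, fs: float) -> np.ndarray:
    """Windowed Morlet log-power of epochs.

    ``data`` may be 1-D (samples), 2-D (epochs × samples) or 3-D
    (epochs × components × samples); the output appends (n_freqs, n_windows)
    in place of the sample axis.
    """
    x = np.asarray(data, float)
    lead = x.shape[:-1]
    n = x.shape[-1]
    centers = config.window_centers(n)
    half = config.window_len // 2
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    frames = x[..., idx]                       # (..., n_windows, window_len)
    bank = config.wavelet_bank(fs)             # (window_len, n_freqs)
    coef = frames @ bank                       # (..., n_windows, n_freqs)
    power = np.maximum(np.abs(coef) ** 2, config.power_floor)
    out = 10.0 * np.log10(power)
    return np.moveaxis(out, -1, len(lead))     # (..., n_freqs, n_windows)


def make_tf_tensor(component_epochs, config: TFConfig, fs: float) -> TFTensor:
    """TF decomposition of a component-space :class:`~gaitdecode.epochs.EpochSet`."""
    vals = wavelet_tf(component_epochs.data, config, fs)
    times = config.times(component_epochs.data.shape[-1], fs)
    return TFTensor(values=vals, freqs=config.freqs, times=times, config=config)


def constant_baseline(tf: TFTensor, labels: np.ndarray,
                      constant_label: str = "constant") -> np.ndarray:
    """Mean log spectrum of constant-speed epochs: (components, freqs)."""
    mask = np.asarray(labels) == constant_label
    if not mask.any():
        raise ValueError("no constant-speed epochs for the baseline")
    return tf.values[mask].mean(axis=(0, 3))


def ersp(tf: TFTensor, labels: np.ndarray, baseline: np.ndarray | str = "constant",
         pre_window: tuple[float, float] = (-3.789, -1.007)) -> dict[str, np.ndarray]:
    """Per-class trial-average spectral perturbation (dB vs baseline).

    ``baseline='constant'`` subtracts the mean log spectrum of the
    constant-speed class over the whole epoch (the feature-visualisation
    convention); ``baseline='pre_onset'`` subtracts each class's own mean log
    spectrum over ``pre_window`` (the artifact-comparison convention).  A
    precomputed (components × freqs) array can be passed directly.
    """
    labels = np.asarray(labels)
    out = {}
    for cls in np.unique(labels):
        mean_tf = tf.values[labels == cls].mean(axis=0)  # (comp, freq, time)
        if isinstance(baseline, str) and baseline == "constant":
            base = constant_baseline(tf, labels)
        elif isinstance(baseline, str) and baseline == "pre_onset":
            tmask = (tf.times >= pre_window[0]) & (tf.times <= pre_window[1])
            if not tmask.any():
                raise ValueError("pre-onset window is empty on this time grid")
            base = mean_tf[:, :, tmask].mean(axis=2)
        else:
            base = np.asarray(baseline, float)
        out[str(cls)] = mean_tf - base[:, :, None]
    return out


def erd_percent(tf_values: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                band: tuple[float, float], roi: tuple[float, float],
                reference: tuple[float, float]) -> ErdSummary:
    """ERD(%) = (A − R)/R × 100 on linear power.

    ``A`` is the mean linear band power in the time region of interest, ``R``
    in the reference period.  ``tf_values`` is any dB array whose last two
    axes are (freqs, times); leading axes are averaged.
    """
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    rmask = (times >= roi[0]) & (times <= roi[1])
    bmask = (times >= reference[0]) & (times <= reference[1])
    if not (fmask.any() and rmask.any() and bmask.any()):
        raise ValueError("band/roi/reference do not intersect the TF grid")
    lin = 10.0 ** (np.asarray(tf_values, float) / 10.0)
    A = float(lin[..., fmask, :][..., rmask].mean())
    R = float(lin[..., fmask, :][..., bmask].mean())
    if R == 0:
        raise ValueError("reference power is zero")
    return ErdSummary(A=A, R=R, erd_percent=(A - R) / R * 100.0)
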