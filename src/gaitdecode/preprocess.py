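"""FIR band-pass design with automatic order selection, zero-phase filtering
and anti-aliased resampling.

The design heuristic mirrors the automatic-order rule used by common EEG
toolboxes: each passband edge proposes a transition bandwidth of 25 % of the
edge frequency (at least 2 Hz), limited by the distance to 0 Hz or Nyquist;
the overall transition bandwidth is the minimum over the two edges.  The
estimated even order is ``ceil(3.3 · fs / tb)`` and the filter length is one
more tap.  The −6 dB cutoffs sit half a transition bandwidth outside the
passband edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    passband_edges: tuple[float, float]
    transition_bandwidth: float
    n_taps: int
    cutoff_minus6dB: tuple[float, float]
    coefficients: np.ndarray
    design_fs: float

    def __post_init__(self) -> None:
        if self.n_taps % 2 != 1:
            raise ValueError("linear-phase design requires an odd tap count")
        h = np.asarray(self.coefficients, float)
        if not np.allclose(h, h[::-1], rtol=0, atol=1e-12 * np.abs(h).max()):
            raise ValueError("coefficients must be symmetric (linear phase)")

    def response_at(self, freq: float) -> float:
        """Magnitude of the frequency response at ``freq`` (Hz)."""
        w, h = signal.freqz(self.coefficients, worN=[freq], fs=self.design_fs)
        return float(np.abs(h[0]))


def design_fir(passband: tuple[float, float], fs: float) -> FilterSpec:
    """Hamming-window band-pass FIR with automatically selected order."""
    low, high = map(float, passband)
    nyq = fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"invalid passband {passband!r} for fs={fs}")
    tbs = [min(max(0.25 * low, 2.0), low),
           min(max(0.25 * high, 2.0), nyq - high)]
    tb = min(tbs)
    order = int(np.ceil(3.3 * fs / tb))
    order += order % 2  # round up to even
    n_taps = order + 1
    cutoffs = (low - tb / 2.0, high + tb / 2.0)
    h = signal.firwin(n_taps, cutoffs, window="hamming", pass_zero=False, fs=fs)
    return FilterSpec(passband_edges=(low, high), transition_bandwidth=tb,
                      n_taps=n_taps, cutoff_minus6dB=cutoffs,
                      coefficients=h, design_fs=fs)


def apply_zero_phase(data: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase filtering by single-pass convolution with delay removal.

    Edges are padded by reflection over half the filter length, and the
    symmetric-filter group delay ``(n_taps − 1) / 2`` is removed so the output
    aligns sample-for-sample with the input.  Works on 1-D signals or
    (channels × samples) arrays.
    """
    x = np.asarray(data, float)
    one_d = x.ndim == 1
    if one_d:
        x = x[None, :]
    n = x.shape[-1]
    if n <= spec.n_taps:
        raise ValueError(
            f"signal length {n} must exceed the filter length {spec.n_taps}")
    half = (spec.n_taps - 1) // 2
    pad = min(half, n - 1)
    xp = np.concatenate([x[:, pad:0:-1], x, x[:, -2:-pad - 2:-1]], axis=1)
    y = signal.fftconvolve(xp, spec.coefficients[None, :], mode="same", axes=1)
    y = y[:, pad:pad + n]
    return y[0] if one_d else y


def resample(data: np.ndarray, fs: float, target_fs: float = 256.0,
             events_samples: np.ndarray | None = None):
    """Polyphase anti-aliased downsampling; optionally rescales event indices.

    Event sample indices are mapped by the rate ratio and rounded half away
    from zero.  Upsampling is refused.
    """
    if target_fs > fs:
        raise ValueError("upsampling is not supported")
    x = np.asarray(data, float)
    if target_fs == fs:
        y = x.copy()
    else:
        frac = Fraction(target_fs / fs).limit_denominator(1000)
        y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    if events_samples is None:
        return y
    ratio = target_fs / fs
    ev = np.floor(np.abs(np.asarray(events_samples)) * ratio + 0.5)
    ev = (ev * np.sign(events_samples)).astype(int)
    return y, ev
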