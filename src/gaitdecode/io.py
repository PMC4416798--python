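"""Recording container and on-disk formats.

Recordings travel through the pipeline as plain arrays wrapped in a small
dataclass.  For interchange we write BioSemi BDF (the 24-bit EDF variant the
original amplifier produces); reading goes through :func:`mne.io.read_raw_bdf`
so the writer is cross-checked against an independent parser.  Event tables
and speed profiles are TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .headmodel import Montage

_BDF_DIG_MIN, _BDF_DIG_MAX = -8388608, 8388607


@dataclass
class Recording:
    """Multichannel EEG with sampling rate, montage, events and metadata.

    ``signal`` is channels × samples in µV.  ``events`` is a DataFrame with
    columns ``onset_s``, ``onset_sample``, ``from_kmh``, ``to_kmh`` (speed
    change onsets as detected by the treadmill encoder).
    """

    signal: np.ndarray
    fs: float
    montage: Montage
    events: pd.DataFrame
    condition: str = "cued"          # cued | uncued
    session_id: int = 0
    subject_id: str = "S0"
    profile: "pd.DataFrame | None" = None   # columns time_s, belt_speed_ms

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.montage.labels):
            raise ValueError("signal must be (n_channels, n_samples) matching "
                             "the montage")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, signal: np.ndarray, fs: float | None = None,
                  events: pd.DataFrame | None = None) -> "Recording":
        return Recording(signal=signal, fs=self.fs if fs is None else fs,
                         montage=self.montage,
                         events=self.events.copy() if events is None else events,
                         condition=self.condition, session_id=self.session_id,
                         subject_id=self.subject_id, profile=self.profile)


def quantize_bdf(signal: np.ndarray, phys_range: tuple[float, float]):
    """Digital 24-bit codes and the exact physical values they decode to."""
    pmin, pmax = phys_range
    gain = (pmax - pmin) / (_BDF_DIG_MAX - _BDF_DIG_MIN)
    codes = np.round((signal - pmin) / gain) + _BDF_DIG_MIN
    codes = np.clip(codes, _BDF_DIG_MIN, _BDF_DIG_MAX).astype(np.int32)
    decoded = (codes - _BDF_DIG_MIN) * gain + pmin
    return codes, decoded


def write_bdf(rec: Recording, path) -> None:
    """Write a 24-bit BDF file (one 1-second data record per second).

    The trailing partial second, if any, is zero-padded in the last record;
    readers see the padded duration.
    """
    path = Path(path)
    n_ch = rec.signal.shape[0]
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("BDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, :rec.n_samples] = rec.signal
    amax = float(np.abs(data).max())
    lim = max(amax, 1e-6)
    phys = (-lim, lim)
    codes, _ = quantize_bdf(data, phys)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    with open(path, "wb") as fh:
        fh.write(b"\xffBIOSEMI")
        fh.write(pad(f"sub {rec.subject_id}", 80))
        fh.write(pad(f"session {rec.session_id} {rec.condition}", 80))
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (n_ch + 1)), 8))
        fh.write(pad("24BIT", 44))
        fh.write(pad(str(n_rec), 8))
        fh.write(pad("1", 8))       # record duration, seconds
        fh.write(pad(str(n_ch), 4))
        for lbl in rec.montage.labels:
            fh.write(pad(lbl, 16))
        for _ in range(n_ch):
            fh.write(pad("Active electrode", 80))
        for _ in range(n_ch):
            fh.write(pad("uV", 8))
        for val in (phys[0], phys[1]):
            for _ in range(n_ch):
                fh.write(pad(f"{val:.6g}", 8))
        for val in (_BDF_DIG_MIN, _BDF_DIG_MAX):
            for _ in range(n_ch):
                fh.write(pad(str(val), 8))
        for _ in range(n_ch):
            fh.write(pad("", 80))
        for _ in range(n_ch):
            fh.write(pad(str(fs), 8))
        for _ in range(n_ch):
            fh.write(pad("", 32))
        # 24-bit little-endian samples, channel-blocked per record
        u = (codes.astype(np.int64) & 0xFFFFFF).astype(np.uint32)
        for r in range(n_rec):
            block = u[:, r * fs:(r + 1) * fs]  # (n_ch, fs)
            raw = np.empty((n_ch, fs, 3), np.uint8)
            raw[..., 0] = block & 0xFF
            raw[..., 1] = (block >> 8) & 0xFF
            raw[..., 2] = (block >> 16) & 0xFF
            fh.write(raw.tobytes())


def read_bdf(path, montage: Montage | None = None) -> Recording:
    """Read a BDF file via MNE into a :class:`Recording` (µV)."""
    import mne

    raw = mne.io.read_raw_bdf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    if montage is None:
        montage = Montage.default()
    if list(raw.ch_names) != list(montage.labels):
        raise ValueError("channel order in file does not match the montage")
    events = pd.DataFrame(columns=["onset_s", "onset_sample", "from_kmh", "to_kmh"])
    return Recording(signal=data, fs=float(raw.info["sfreq"]), montage=montage,
                     events=events)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)
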