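"""Epoch extraction around speed-change onsets.

Batch epochs: per onset one change-speed epoch over [−4, 4) s and one
constant-speed epoch over [−12, −4) s, so classes stay balanced.  Sliding
(2 s) epochs support the pseudo-online decoder: four jittered training
windows per class per trial, and nine consecutive test windows per trial.
Onset/constant pairs whose preceding steady-speed stretch is shorter than
12 s are dropped (self-paced sessions), which keeps constant-speed epochs
clear of the previous ramp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording

logger = logging.getLogger(__name__)

CHANGE, CONSTANT = "change", "constant"

BATCH_CHANGE_WINDOW = (-4.0, 4.0)
BATCH_CONSTANT_WINDOW = (-12.0, -4.0)
MIN_PRECEDING_STEADY = 12.0

TRAIN_CENTERS_CHANGE = (0.0, 0.5, 1.0, 1.5)
TRAIN_CENTERS_CONSTANT = (-10.0, -9.0, -8.0, -7.0)
TEST_CENTERS_CHANGE = tuple(np.arange(-1.0, 3.0 + 1e-9, 0.5))
TEST_CENTERS_CONSTANT = tuple(np.arange(-9.0, -5.0 + 1e-9, 0.5))
SLIDING_HALF = 1.0  # s


@dataclass
class EpochSet:
    """Trials × channels-or-components × samples with labels and bookkeeping.

    ``index`` columns: trial (parent trial id), label, subclass, session,
    center_s (window centre relative to onset; NaN for batch epochs where the
    window itself defines the timing).
    """

    data: np.ndarray
    index: pd.DataFrame
    window: tuple[float, float]
    fs: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.index) != self.data.shape[0]:
            raise ValueError("index length must match trial count")

    @property
    def labels(self) -> np.ndarray:
        return self.index["label"].to_numpy()

    @property
    def subclasses(self) -> np.ndarray:
        return self.index["subclass"].to_numpy()

    def subset(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.index[mask].reset_index(drop=True),
                        self.window, self.fs)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "epochs.npy", self.data)
        meta = self.index.copy()
        meta.to_csv(path / "index.tsv", sep="\t", index=False)
        pd.DataFrame({"key": ["window_start", "window_end", "fs"],
                      "value": [self.window[0], self.window[1], self.fs]}
                     ).to_csv(path / "meta.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "EpochSet":
        path = Path(path)
        data = np.load(path / "epochs.npy")
        index = pd.read_csv(path / "index.tsv", sep="\t")
        meta = pd.read_csv(path / "meta.tsv", sep="\t").set_index("key")["value"]
        return cls(data, index,
                   (float(meta["window_start"]), float(meta["window_end"])),
                   float(meta["fs"]))


ONSET_THRESHOLD_MS = 0.12  # m/s, encoder detection threshold
KMH_TO_MS = 1.0 / 3.6


def _ramp_window(ev) -> tuple[float, float]:
    """True (start, end) of the speed ramp an onset event belongs to.

    The encoder fires once the speed deviates by the detection threshold, so
    the detected onset lags the ramp start by threshold/slope; the ramp
    geometry (1 km/h per 4 s up, per 8 s down) recovers both endpoints from
    the event alone.
    """
    up = ev["to_kmh"] > ev["from_kmh"]
    ramp = 4.0 if up else 8.0
    slope = abs(ev["to_kmh"] - ev["from_kmh"]) * KMH_TO_MS / ramp
    delay = ONSET_THRESHOLD_MS / slope if slope > 0 else 0.0
    start = ev["onset_s"] - min(delay, ramp)
    return start, start + ramp


def _usable_onsets(rec: Recording) -> list[dict]:
    """Onsets with at least 12 s of preceding steady speed, in session range."""
    evs = rec.events.sort_values("onset_s").reset_index(drop=True)
    out = []
    prev_ramp_end = 0.0
    for _, ev in evs.iterrows():
        steady = ev["onset_s"] - prev_ramp_end
        if steady < MIN_PRECEDING_STEADY:
            logger.info("session %s: onset at %.1f s dropped "
                        "(only %.1f s of steady speed before it)",
                        rec.session_id, ev["onset_s"], steady)
        else:
            out.append(dict(ev))
        prev_ramp_end = _ramp_window(ev)[1]
    return out


def _slice(rec: Recording, t0: float, t1: float) -> np.ndarray | None:
    i0 = int(round(t0 * rec.fs))
    i1 = i0 + int(round((t1 - t0) * rec.fs))
    if i0 < 0 or i1 > rec.n_samples:
        return None
    return rec.signal[:, i0:i1]


def _subclass(ev) -> tuple[str, str]:
    change = f"{int(ev['from_kmh'])}->{int(ev['to_kmh'])}"
    constant = str(int(ev["from_kmh"]))
    return change, constant


def extract_batch(rec: Recording) -> EpochSet:
    """One balanced pair of 8 s epochs per usable onset."""
    rows, chunks = [], []
    for trial, ev in enumerate(_usable_onsets(rec)):
        on = float(ev["onset_s"])
        ch = _slice(rec, on + BATCH_CHANGE_WINDOW[0], on + BATCH_CHANGE_WINDOW[1])
        co = _slice(rec, on + BATCH_CONSTANT_WINDOW[0], on + BATCH_CONSTANT_WINDOW[1])
        if ch is None or co is None:
            logger.info("session %s: onset at %.1f s dropped (window out of range)",
                        rec.session_id, on)
            continue
        sub_ch, sub_co = _subclass(ev)
        chunks += [ch, co]
        rows += [
            {"trial": trial, "label": CHANGE, "subclass": sub_ch,
             "session": rec.session_id, "condition": rec.condition,
             "center_s": np.nan},
            {"trial": trial, "label": CONSTANT, "subclass": sub_co,
             "session": rec.session_id, "condition": rec.condition,
             "center_s": np.nan},
        ]
    if not chunks:
        raise ValueError(f"session {rec.session_id}: no usable trials")
    n = min(c.shape[1] for c in chunks)
    data = np.stack([c[:, :n] for c in chunks])
    return EpochSet(data, pd.DataFrame(rows), BATCH_CHANGE_WINDOW, rec.fs)


def extract_sliding(rec: Recording, mode: str) -> EpochSet:
    """2 s epochs at class-specific window centres relative to each onset.

    ``mode='train'`` uses the jittered-training centres (4 per class per
    trial); ``mode='test'`` the pseudo-online sweep (9 per trial per class).
    """
    if mode == "train":
        centers = {CHANGE: TRAIN_CENTERS_CHANGE, CONSTANT: TRAIN_CENTERS_CONSTANT}
    elif mode == "test":
        centers = {CHANGE: TEST_CENTERS_CHANGE, CONSTANT: TEST_CENTERS_CONSTANT}
    else:
        raise ValueError("mode must be 'train' or 'test'")
    rows, chunks = [], []
    for trial, ev in enumerate(_usable_onsets(rec)):
        on = float(ev["onset_s"])
        sub = dict(zip((CHANGE, CONSTANT), _subclass(ev)))
        for label, cs in centers.items():
            for c in cs:
                seg = _slice(rec, on + c - SLIDING_HALF, on + c + SLIDING_HALF)
                if seg is None:
                    logger.info("session %s: %.1f s window at onset %.1f dropped",
                                rec.session_id, c, on)
                    continue
                chunks.append(seg)
                rows.append({"trial": trial, "label": label, "subclass": sub[label],
                             "session": rec.session_id, "condition": rec.condition,
                             "center_s": c})
    if not chunks:
        raise ValueError(f"session {rec.session_id}: no usable trials")
    n = min(c.shape[1] for c in chunks)
    data = np.stack([c[:, :n] for c in chunks])
    return EpochSet(data, pd.DataFrame(rows), (-SLIDING_HALF, SLIDING_HALF), rec.fs)


def concatenate(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets from several sessions (same geometry)."""
    if not sets:
        raise ValueError("nothing to concatenate")
    fs = sets[0].fs
    win = sets[0].window
    if any(s.fs != fs or s.window != win for s in sets):
        raise ValueError("epoch sets have inconsistent geometry")
    n = min(s.data.shape[2] for s in sets)
    data = np.concatenate([s.data[:, :, :n] for s in sets])
    index = pd.concat([s.index for s in sets], ignore_index=True)
    return EpochSet(data, index, win, fs)
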