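"""Two-pass ICA spatial-filter identification with probability-based segment
rejection.

The decomposition is learned from the training sessions of each
cross-validation fold only.  The signal (1–45 Hz, 256 Hz) is cut into 0.5 s
segments; a segment is discarded when its joint log-probability under
per-channel histogram densities deviates from the mean segment score by more
than 5 SD.  ICA is then run twice: once on the cleaned broadband data, after
which the same probability criterion is applied to the component activations;
the surviving segments are band-passed 8–40 Hz and ICA is run a second time
to yield the final unmixing matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .epochs import EpochSet
from .preprocess import apply_zero_phase, design_fir


@dataclass
class SpatialModel:
    """ICA unmixing/mixing pair with per-component bookkeeping.

    ``unmixing`` maps channels to component activations (n_comp × n_ch);
    ``mixing`` is its pseudo-inverse, whose columns are the component scalp
    maps.  ``retained`` starts all-True; downstream rejection stages flip
    entries and record their reason.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    retained: np.ndarray = field(default=None)
    rejection_reasons: dict[int, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.unmixing.shape[0], bool)
        ident = self.unmixing @ self.mixing
        if np.linalg.norm(ident - np.eye(self.n_components)) > 1e-6 * self.n_components:
            raise ValueError("unmixing · mixing must be the identity on the "
                             "component subspace")

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def scalp_maps(self) -> np.ndarray:
        """(n_channels, n_components); column j is component j's scalp map."""
        return self.mixing

    def reject(self, idx: int, reason: str) -> None:
        self.retained[idx] = False
        self.rejection_reasons.setdefault(idx, []).append(reason)


def segment_bounds(n_samples: int, fs: float, seg_len: float = 0.5) -> np.ndarray:
    seg = int(round(seg_len * fs))
    n_seg = n_samples // seg
    return np.arange(n_seg + 1) * seg


def reject_segments(signal: np.ndarray, fs: float, seg_len: float = 0.5,
                    z: float = 5.0, n_bins: int = 50) -> np.ndarray:
    """Keep-mask over 0.5 s segments by joint log-probability score.

    Densities are per-channel histograms estimated from the whole signal; a
    segment's score is the mean log-density of its samples across channels.
    Segments deviating more than ``z`` SD from the mean score are dropped.
    """
    x = np.atleast_2d(np.asarray(signal, float))
    bounds = segment_bounds(x.shape[1], fs, seg_len)
    n_seg = len(bounds) - 1
    if n_seg < 20:
        raise ValueError(f"need at least 20 segments, got {n_seg}")
    logpdf = np.empty_like(x)
    for ch in range(x.shape[0]):
        counts, edges = np.histogram(x[ch], bins=n_bins)
        width = edges[1] - edges[0]
        dens = counts / (counts.sum() * max(width, 1e-30))
        idx = np.clip(np.searchsorted(edges, x[ch], side="right") - 1, 0, n_bins - 1)
        logpdf[ch] = np.log(np.maximum(dens[idx], 1e-12))
    scores = np.array([logpdf[:, bounds[i]:bounds[i + 1]].mean()
                       for i in range(n_seg)])
    sd = scores.std()
    if sd == 0:
        return np.ones(n_seg, bool)
    return np.abs(scores - scores.mean()) <= z * sd


def _segments_to_samples(keep: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    mask = np.zeros(bounds[-1], bool)
    for i, k in enumerate(keep):
        if k:
            mask[bounds[i]:bounds[i + 1]] = True
    return mask


def _run_ica(data: np.ndarray, n_components: int, seed,
             max_iter: int = 150) -> np.ndarray:
    """FastICA on (n_ch, n_samples); returns the channels→components matrix.

    Whitening is done explicitly through the covariance eigendecomposition
    (cheaper than a data-matrix SVD at these sample counts); FastICA then
    runs on the pre-whitened, dimension-reduced data.
    """
    X = np.asarray(data, float)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    K = evecs.T / np.sqrt(np.maximum(evals, 1e-18))[:, None]
    ica = FastICA(whiten=False, random_state=np.random.RandomState(seed),
                  max_iter=max_iter, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit((K @ Xc).T)
    return ica.components_ @ K


@dataclass
class PreparedSession:
    """Per-session, fold-independent inputs to the two-pass ICA."""
    broad: np.ndarray      # 1–45 Hz signal
    narrow: np.ndarray     # 8–40 Hz signal
    bounds: np.ndarray     # segment boundaries (samples)
    keep: np.ndarray       # first-pass segment keep-mask
    sample_mask: np.ndarray


def prepare_sessions(session_signals: list[np.ndarray], fs: float,
                     seg_len: float = 0.5, z: float = 5.0) -> list[PreparedSession]:
    """First segment rejection and 8–40 Hz filtering, once per session."""
    spec_8_40 = design_fir((8.0, 40.0), fs)
    out = []
    for sig in session_signals:
        keep = reject_segments(sig, fs, seg_len, z)
        bounds = segment_bounds(sig.shape[1], fs, seg_len)
        mask = _segments_to_samples(keep, bounds)
        out.append(PreparedSession(broad=sig,
                                   narrow=apply_zero_phase(sig, spec_8_40),
                                   bounds=bounds, keep=keep, sample_mask=mask))
    return out


def fit_ica_two_pass(sessions: "list[np.ndarray] | list[PreparedSession]",
                     fs: float, seed: int = 0, n_components: int | None = None,
                     seg_len: float = 0.5, z: float = 5.0,
                     decim: int = 1,
                     provenance: dict | None = None) -> SpatialModel:
    """Learn the spatial model from the training sessions of a fold.

    ``sessions`` are the 1–45 Hz, 256 Hz continuous signals of the training
    sessions (or :class:`PreparedSession` objects if the per-session work was
    hoisted out of a cross-validation loop).  ``decim`` uniformly decimates
    the clean samples fed to the ICA solver (an estimation-cost control; the
    model is applied to full-rate data downstream).
    """
    if not isinstance(sessions[0], PreparedSession):
        sessions = prepare_sessions(sessions, fs, seg_len, z)
    n_ch = sessions[0].broad.shape[0]

    broad = np.concatenate([s.broad[:, s.sample_mask] for s in sessions], axis=1)
    rank = np.linalg.matrix_rank(broad @ broad.T / broad.shape[1])
    n_comp = min(n_components or n_ch, rank, n_ch)

    W1 = _run_ica(broad[:, ::decim], n_comp, seed)

    # second rejection: probability score of the component activations
    final_segments = []
    for s in sessions:
        kept_idx = np.nonzero(s.keep)[0]
        acts = W1 @ np.concatenate(
            [s.narrow[:, s.bounds[i]:s.bounds[i + 1]] for i in kept_idx], axis=1)
        if kept_idx.size < 20:
            sel = kept_idx
        else:
            keep2 = reject_segments(acts, fs, seg_len, z)
            sel = kept_idx[keep2]
        final_segments += [s.narrow[:, s.bounds[i]:s.bounds[i + 1]] for i in sel]

    narrow_cat = np.concatenate(final_segments, axis=1)
    W2 = _run_ica(narrow_cat[:, ::decim], n_comp, seed)
    mixing = np.linalg.pinv(W2)

    prov = dict(provenance or {})
    prov.update({"seed": seed, "n_components": n_comp, "rank": int(rank),
                 "segment_keep_fraction": float(np.mean([s.keep.mean()
                                                         for s in sessions])),
                 "decim": decim})
    return SpatialModel(unmixing=W2, mixing=mixing, provenance=prov)


def apply_unmixing(epochs: EpochSet, model: SpatialModel,
                   retained_only: bool = False) -> EpochSet:
    """Project an epoch set from channel space to component space."""
    W = model.unmixing
    if retained_only:
        W = W[model.retained]
    if epochs.data.shape[1] != W.shape[1]:
        raise ValueError(
            f"epochs have {epochs.data.shape[1]} channels, unmixing expects "
            f"{W.shape[1]}")
    data = np.einsum("ck,tks->tcs", W, epochs.data)
    return EpochSet(data, epochs.index.copy(), epochs.window, epochs.fs)


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Amari permutation-invariant separation error of unmixing W vs mixing A.

    0 for a perfect separation (up to permutation/scale); used as the
    recovery oracle for ICA on known mixtures.
    """
    P = np.abs(W @ A)
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * n * (n - 1)))
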