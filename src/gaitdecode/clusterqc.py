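"""Cross-subject clustering of retained independent components and the two
artifact quality-control analyses.

Clustering: every retained component (subject × fold) is represented by its
dipole coordinates plus the principal components (90 % variance) of its
sign-aligned scalp map; blocks are z-scored and clustered with k-means
(k = 4), members further than 5 SD from their centroid are dropped and the
centroids refit once.  A subject contributing fewer than 40 % of their folds
to a cluster is removed from it; clusters with fewer than two subjects are
discarded.  Cluster centroids can be projected dorsally onto the 'cortex'
sphere (58 % of the scalp radius) for display.

QC 1 — channel correlation: squared per-trial Pearson correlation matrices of
the 1–45 Hz channels, averaged per condition (standing-still / constant /
change), compared pairwise by mean absolute difference of the off-diagonal
entries.

QC 2 — retained-vs-rejected pairing: among rejected components that are far
outside the head (radial fraction > 0.90) yet have clean scalp maps
(residual variance < 0.10) and posterior dipoles (x < 0), find the one whose
change-speed spectral perturbation correlates best with any retained
component's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

CORTEX_FRACTION = 0.58


@dataclass
class ClusterMember:
    subject: str
    fold: int
    component: int
    dipole_xyz: np.ndarray
    scalp_map: np.ndarray


@dataclass
class ClusterSet:
    members: list[ClusterMember]
    assignments: np.ndarray          # cluster id per member, −1 = outlier
    centroids_xyz: dict[int, np.ndarray]
    mean_scalp_maps: dict[int, np.ndarray]
    surviving: list[int]             # cluster ids passing the membership rules
    outliers: np.ndarray             # member indices flagged by the SD rule


def _sign_align(maps: np.ndarray) -> np.ndarray:
    """Force the largest-|weight| channel of each map positive (ICA sign is
    arbitrary)."""
    out = maps.copy()
    for i, m in enumerate(out):
        j = int(np.argmax(np.abs(m)))
        if m[j] < 0:
            out[i] = -m
    return out


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def cluster_components(members: list[ClusterMember], k: int = 4,
                       outlier_sd: float = 5.0, seed: int = 0,
                       map_variance: float = 0.90,
                       min_fold_fraction: float = 0.40,
                       min_subjects: int = 2,
                       folds_per_subject: int = 10) -> ClusterSet:
    if len(members) < k:
        raise ValueError(f"need at least k={k} members, got {len(members)}")
    xyz = np.array([m.dipole_xyz for m in members], float)
    maps = _sign_align(np.array([m.scalp_map for m in members], float))
    n_pc = min(len(members) - 1, maps.shape[1])
    pca = PCA(n_components=min(map_variance, 0.999) if len(members) > 2 else n_pc,
              svd_solver="full")
    map_pcs = pca.fit_transform(maps)
    feats = np.column_stack([_zscore(xyz), _zscore(map_pcs)])

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)

    # robustness step: drop members far from their centroid, refit once.
    # The SD is taken leave-one-out so a single extreme member cannot
    # inflate its own rejection threshold.
    dists = np.linalg.norm(feats - km.cluster_centers_[labels], axis=1)
    outliers = np.zeros(len(members), bool)
    for c in range(k):
        sel = np.nonzero(labels == c)[0]
        if sel.size < 4:
            continue
        for i in sel:
            others = dists[sel[sel != i]]
            sd = others.std()
            if sd > 0 and dists[i] > others.mean() + outlier_sd * sd:
                outliers[i] = True
    assignments = np.where(outliers, -1, labels)

    centroids_xyz, mean_maps, surviving = {}, {}, []
    subjects = np.array([m.subject for m in members])
    for c in range(k):
        sel = assignments == c
        if not sel.any():
            continue
        # membership rule: a subject must contribute >= 40 % of their folds
        for s in np.unique(subjects[sel]):
            n_s = int(((subjects == s) & sel).sum())
            if n_s / folds_per_subject < min_fold_fraction:
                assignments[(subjects == s) & sel] = -1
                logger.info("subject %s removed from cluster %d (%d/%d folds)",
                            s, c, n_s, folds_per_subject)
        sel = assignments == c
        if not sel.any() or len(np.unique(subjects[sel])) < min_subjects:
            assignments[sel] = -1
            continue
        surviving.append(c)
        centroids_xyz[c] = xyz[sel].mean(axis=0)
        mean_maps[c] = maps[sel].mean(axis=0)
    return ClusterSet(members=members, assignments=assignments,
                      centroids_xyz=centroids_xyz, mean_scalp_maps=mean_maps,
                      surviving=surviving, outliers=np.nonzero(outliers)[0])


def project_centroid_dorsal(xyz: np.ndarray, radius: float = 85.0,
                            cortex_fraction: float = CORTEX_FRACTION) -> np.ndarray:
    """Shift a centroid dorsally (+z) onto the cortex sphere for display."""
    xyz = np.asarray(xyz, float)
    rc = cortex_fraction * radius
    rho2 = xyz[0] ** 2 + xyz[1] ** 2
    if rho2 > rc ** 2:
        logger.warning("centroid lies outside the cortex cylinder; left in place")
        return xyz.copy()
    if xyz @ xyz >= rc ** 2:
        return xyz.copy()
    out = xyz.copy()
    out[2] = np.sqrt(rc ** 2 - rho2)
    return out


# ---------------------------------------------------------------------------
# artifact QC


@dataclass
class QcMatrices:
    mean_r2: dict[str, np.ndarray]
    differences: dict[tuple[str, str], np.ndarray]
    mad: dict[tuple[str, str], float]


def channel_correlation_qc(epochs_by_condition: dict[str, np.ndarray]) -> QcMatrices:
    """Mean squared channel-correlation matrices per condition and their
    pairwise differences.

    Input: condition → (trials, channels, samples) arrays of 1–45 Hz data.
    The mean absolute difference (m.a.d.) is taken over off-diagonal entries.
    """
    mean_r2 = {}
    for cond, data in epochs_by_condition.items():
        if data.shape[0] == 0:
            raise ValueError(f"condition {cond!r} has no trials")
        acc = np.zeros((data.shape[1], data.shape[1]))
        for trial in data:
            r = np.corrcoef(trial)
            r = np.nan_to_num(r, nan=0.0)
            acc += r ** 2
        mean_r2[cond] = acc / data.shape[0]
    diffs, mads = {}, {}
    off = ~np.eye(next(iter(mean_r2.values())).shape[0], dtype=bool)
    for a, b in combinations(sorted(mean_r2), 2):
        d = mean_r2[a] - mean_r2[b]
        diffs[(a, b)] = d
        mads[(a, b)] = float(np.abs(d[off]).mean())
    return QcMatrices(mean_r2=mean_r2, differences=diffs, mad=mads)


@dataclass
class ErspPair:
    rejected_id: int
    retained_id: int
    correlation: float


def retained_rejected_pairing(retained_ersps: dict[int, np.ndarray],
                              rejected: list[tuple[int, object, np.ndarray]],
                              radial_min: float = 0.90, rv_max: float = 0.10
                              ) -> ErspPair | None:
    """Best-correlated rejected/retained ERSP pair for one subject.

    ``rejected`` holds (component id, DipoleFit, change-speed ERSP) tuples;
    only far-out (radial fraction > ``radial_min``), well-fitting
    (r.v. < ``rv_max``), posterior (x < 0) rejected components are eligible.
    Returns None when no rejected component qualifies.
    """
    pool = [(cid, e) for cid, fit, e in rejected
            if fit.radial_fraction > radial_min
            and fit.residual_variance < rv_max
            and fit.dipole.location[0] < 0]
    if not pool or not retained_ersps:
        logger.info("no eligible retained/rejected ERSP pair")
        return None
    best = None
    for rid, rej_e in pool:
        for kid, ret_e in retained_ersps.items():
            r = float(np.corrcoef(rej_e.ravel(), ret_e.ravel())[0, 1])
            if best is None or r > best.correlation:
                best = ErspPair(rejected_id=rid, retained_id=kid, correlation=r)
    return best
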