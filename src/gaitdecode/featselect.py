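"""Selection of task-relevant ('neural') components and artifactual-epoch
rejection in the time–frequency domain.

Component selection: one sparse (L1) logistic model is fitted on the
concatenated time–frequency features of all candidate components; the number
of features the model selects per component ranks the components, and the
scree-test acceleration factor (discrete second difference of the sorted
counts) locates the elbow.  Components ranked strictly before the elbow are
retained, never fewer than one.

Epoch rejection: an epoch is discarded when its 20–40 Hz power perturbation
relative to the training constant-speed baseline exceeds +25 dB or falls
below −100 dB in any analysis window of any retained component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

ARTIFACT_BAND = (20.0, 40.0)
ARTIFACT_DB_HIGH = 25.0
ARTIFACT_DB_LOW = -100.0


@dataclass
class SelectionReport:
    counts: np.ndarray            # selected-feature count per component
    order: np.ndarray             # component ids sorted by descending count
    sorted_counts: np.ndarray
    acceleration: np.ndarray      # second difference at interior ranks
    elbow_rank: int | None        # rank index in the sorted order, None if flat
    retained_ids: np.ndarray      # component ids kept

    def __post_init__(self) -> None:
        if self.retained_ids.size == 0:
            raise ValueError("selection must retain at least one component")


def scree_elbow(sorted_counts: np.ndarray) -> tuple[np.ndarray, int | None]:
    """Acceleration factor and elbow rank of a descending count profile.

    a_i = c_{i+1} − 2 c_i + c_{i−1} at interior ranks; the elbow is the rank
    with maximal acceleration.  A flat profile has no elbow.
    """
    c = np.asarray(sorted_counts, float)
    if c.size < 3:
        return np.array([]), None
    a = c[2:] - 2.0 * c[1:-1] + c[:-2]
    if np.all(a == a[0]) and np.all(c == c[0]):
        return a, None
    return a, int(np.argmax(a)) + 1


def select_components_by_slr(tf_features: np.ndarray, labels: np.ndarray,
                             seed: int = 0,
                             c_grid=(0.05, 0.5)) -> SelectionReport:
    """Rank components by how many of their features sparse logistic
    regression selects, and keep those before the scree elbow.

    ``tf_features`` is (trials, components, features-per-component);
    ``labels`` is binary.  Regularisation strength is chosen by a small
    internal stratified CV; equal counts are broken by ascending component id
    (stable sort of the negated counts).
    """
    X3 = np.asarray(tf_features, float)
    if X3.ndim != 3:
        raise ValueError("tf_features must be (trials, components, features)")
    n_trials, n_comp, n_feat = X3.shape
    if n_comp < 2:
        raise ValueError("need at least two candidate components")
    y = _encode_labels(labels)
    X = StandardScaler().fit_transform(X3.reshape(n_trials, -1))

    def l1_fit(C, Xf, yf):
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 random_state=seed, max_iter=2000)
        return clf.fit(Xf, yf)

    best_c, best_acc = c_grid[0], -np.inf
    if len(c_grid) > 1:
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for C in c_grid:
            accs = [l1_fit(C, X[tr], y[tr]).score(X[te], y[te])
                    for tr, te in cv.split(X, y)]
            if np.mean(accs) > best_acc:
                best_acc, best_c = np.mean(accs), C
    clf = l1_fit(best_c, X, y)
    counts = (clf.coef_.ravel().reshape(n_comp, n_feat) != 0).sum(axis=1)
    if counts.sum() == 0:
        # fully regularised away: fall back to the weakest penalty
        clf = l1_fit(max(c_grid), X, y)
        counts = (clf.coef_.ravel().reshape(n_comp, n_feat) != 0).sum(axis=1)
    if counts.sum() == 0:
        raise ValueError("sparse model selected no features at all")

    order = np.argsort(-counts, kind="stable")
    sorted_counts = counts[order]
    accel, elbow = scree_elbow(sorted_counts)
    if elbow is None:
        retained = order
    else:
        retained = order[:max(elbow, 1)]
    return SelectionReport(counts=counts, order=order,
                           sorted_counts=sorted_counts,
                           acceleration=accel, elbow_rank=elbow,
                           retained_ids=np.sort(retained))


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iufb":
        y = labels.astype(int)
    else:
        y = (labels == "change").astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return y


def reject_artifactual_epochs(tf_values: np.ndarray, freqs: np.ndarray,
                              baseline: np.ndarray,
                              db_high: float = ARTIFACT_DB_HIGH,
                              db_low: float = ARTIFACT_DB_LOW) -> np.ndarray:
    """Keep-mask over epochs by 20–40 Hz perturbation against the baseline.

    ``tf_values`` is (trials, components, freqs, windows) restricted to the
    retained components; ``baseline`` is the training constant-speed mean log
    spectrum (components × freqs).  An epoch is rejected when the band-mean
    perturbation of any window of any component leaves [db_low, db_high].
    """
    band = (freqs >= ARTIFACT_BAND[0]) & (freqs <= ARTIFACT_BAND[1])
    pert = tf_values - np.asarray(baseline)[None, :, :, None]
    band_pert = pert[:, :, band, :].mean(axis=2)   # (trials, comp, windows)
    bad = (band_pert > db_high) | (band_pert < db_low)
    return ~bad.any(axis=(1, 2))


def build_feature_vectors(tf_values: np.ndarray, retained_ids: np.ndarray,
                          window_mask: np.ndarray | None = None) -> np.ndarray:
    """Concatenate (freq × time) features of retained components per trial.

    ``window_mask`` optionally restricts the time windows (e.g. to the
    pre-onset part of the grid); components are concatenated in ascending id
    order so the layout is stable across folds.
    """
    vals = np.asarray(tf_values, float)
    ids = np.sort(np.asarray(retained_ids, int))
    sub = vals[:, ids]
    if window_mask is not None:
        sub = sub[..., np.asarray(window_mask, bool)]
    return sub.reshape(vals.shape[0], -1)
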