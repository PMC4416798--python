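"""Cross-validated evaluation of the gait speed-change decoder.

Implements leave-one-session-out cross-validation (ICA → dipole/eye
rejection → wavelet features → sparse-selection → PCA → sparse logistic
regression, all fitted on the training sessions of each fold), pooling of
fold confusion matrices, Cohen's kappa with the corrected adjusted-Wald
lower confidence bound, cued/uncued and subclass splits, and the
pseudo-online all-or-nothing trial scoring with ROC/AUC.

Kappa machinery, with ``p`` the observed agreement, ``p0`` the chance
agreement from the confusion-matrix marginals, ``N`` trials of which ``C``
correct::

    k   = (p − p0) / (1 − p0)
    p̂   = (C + 2) / (N + 4)
    k̂   = (p̂ − p0) / (1 − p0)
    k_l = k̂ − z · sqrt( p̂ (1 − p̂) / ((N + 4) (1 − p0)²) )

The decoder is significantly above chance (α = 0.05, two-sided z = 1.96)
when k_l > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from . import classify, featselect, spatial, timefreq
from .epochs import (CHANGE, CONSTANT, concatenate, extract_batch,
                     extract_sliding)
from .headmodel import (HeadModel, Montage, detect_eye_components,
                        fit_single_dipole, reject_components_by_dipole)
from .io import Recording
from .preprocess import apply_zero_phase, design_fir

logger = logging.getLogger(__name__)

SUBCLASSES = ("0->1", "1->2", "2->1", "1->0")


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class KappaResult:
    k: float
    p: float
    p0: float
    k_hat: float
    p_hat: float
    k_lower: float
    z: float
    N: int
    C: int
    significant: bool


def confusion_matrix(true01: np.ndarray, pred01: np.ndarray) -> np.ndarray:
    """2×2 counts, rows = true class (0 constant, 1 change), columns = predicted."""
    cm = np.zeros((2, 2), int)
    for t, p in zip(np.asarray(true01, int), np.asarray(pred01, int)):
        cm[t, p] += 1
    return cm


def classwise_accuracy(cm: np.ndarray) -> tuple[float, float]:
    """Mean ± SD (percent) of the class-wise normalised diagonal."""
    cm = np.asarray(cm, float)
    rows = cm.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("both classes need at least one trial")
    diag = np.diag(cm) / rows
    return float(diag.mean() * 100.0), float(diag.std(ddof=1) * 100.0)


def kappa(cm: np.ndarray, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa of a pooled confusion matrix with the adjusted-Wald
    lower bound (square root over the N+4 term)."""
    cm = np.asarray(cm, float)
    N = cm.sum()
    if N <= 0:
        raise ValueError("empty confusion matrix")
    p = np.trace(cm) / N
    p0 = float((cm.sum(axis=1) * cm.sum(axis=0)).sum() / N ** 2)
    if p0 >= 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    C = int(round(np.trace(cm)))
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    k = (p - p0) / (1.0 - p0)
    p_hat = (C + 2.0) / (N + 4.0)
    k_hat = (p_hat - p0) / (1.0 - p0)
    k_lower = k_hat - z * np.sqrt(p_hat * (1.0 - p_hat) /
                                  ((N + 4.0) * (1.0 - p0) ** 2))
    return KappaResult(k=float(k), p=float(p), p0=p0, k_hat=float(k_hat),
                       p_hat=float(p_hat), k_lower=float(k_lower), z=z,
                       N=int(N), C=C, significant=bool(k_lower > 0))


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclass
class FoldResult:
    fold: int
    test_session: int
    condition: str
    trials: pd.DataFrame          # trial, label, subclass, session, condition, proba, pred
    cm: np.ndarray
    candidate_ids: np.ndarray     # components surviving dipole/eye rejection
    retained_ids: np.ndarray      # components kept by the sparse-count selection
    spatial_model: spatial.SpatialModel
    dipole_fits: list
    selection: featselect.SelectionReport
    n_rejected_epochs: int
    pre_onset_trials: pd.DataFrame | None = None

    @property
    def pre_onset_cm(self) -> np.ndarray | None:
        if self.pre_onset_trials is None:
            return None
        return confusion_matrix((self.pre_onset_trials["label"] == CHANGE).astype(int),
                                self.pre_onset_trials["pred"])


def _trials_cm(df: pd.DataFrame) -> np.ndarray:
    return confusion_matrix((df["label"] == CHANGE).astype(int), df["pred"])


def _fit_fold_classifier(train_X, train_y, seed):
    pca = classify.fit_pca(train_X)
    Xr = classify.project(train_X, pca)
    slr = classify.fit_slr(Xr, train_y, seed=seed)
    return pca, slr


def crossvalidate(sessions: list[Recording], seed: int = 0,
                  n_components: int = 16, n_restarts: int = 4,
                  ica_decim: int = 4,
                  montage: Montage | None = None,
                  model: HeadModel | None = None,
                  compute_pre_onset: bool = False) -> list[FoldResult]:
    """Leave-one-session-out evaluation of one subject.

    ``sessions`` are preprocessed recordings (1–45 Hz band-passed, 256 Hz).
    Each fold learns the spatial model, component rejection, feature
    selection, PCA and classifier on the other sessions only.
    """
    montage = montage or Montage.default()
    model = model or HeadModel()
    fs = sessions[0].fs
    n_folds = len(sessions)
    if n_folds < 10:
        logger.warning("only %d sessions; fold count adjusts accordingly", n_folds)

    # fold-independent stages: segment scoring, 8–40 Hz filtering, epochs
    prepared = spatial.prepare_sessions([r.signal for r in sessions], fs)
    batch_epochs = [extract_batch(rec.copy_with(prep.narrow))
                    for rec, prep in zip(sessions, prepared)]
    tf_cfg = timefreq.TFConfig.batch()

    results = []
    for fold in range(n_folds):
        train_ids = [i for i in range(n_folds) if i != fold]
        sm = spatial.fit_ica_two_pass(
            [prepared[i] for i in train_ids], fs,
            seed=seed, n_components=n_components, decim=ica_decim,
            provenance={"training_sessions": train_ids, "test_session": fold})
        assert fold not in sm.provenance["training_sessions"]

        fits = [fit_single_dipole(sm.scalp_maps[:, j], montage, model,
                                  n_restarts=n_restarts, seed=seed + j)
                for j in range(sm.n_components)]
        keep, reasons = reject_components_by_dipole(fits)
        for j in np.nonzero(~keep)[0]:
            sm.reject(j, "dipole:" + "+".join(reasons[j]))

        # eye detection on broadband activations of the training sessions
        acts = sm.unmixing @ np.concatenate(
            [sessions[i].signal[:, ::4] for i in train_ids], axis=1)
        eye = detect_eye_components(sm.scalp_maps.T, acts, montage, fs / 4.0)
        for j in np.nonzero(eye & sm.retained)[0]:
            sm.reject(j, "eye")
        candidates = np.nonzero(sm.retained)[0]
        if candidates.size < 2:
            candidates = np.argsort([f.residual_variance for f in fits])[:2]
            logger.warning("fold %d: fewer than 2 components survived "
                           "rejection; keeping best-fitting two", fold)

        train_ep = concatenate([batch_epochs[i] for i in train_ids])
        test_ep = batch_epochs[fold]
        Wc = sm.unmixing[candidates]
        train_tf = timefreq.wavelet_tf(
            np.einsum("ck,tks->tcs", Wc, train_ep.data), tf_cfg, fs)
        test_tf = timefreq.wavelet_tf(
            np.einsum("ck,tks->tcs", Wc, test_ep.data), tf_cfg, fs)

        sel = featselect.select_components_by_slr(
            train_tf.reshape(train_tf.shape[0], len(candidates), -1),
            train_ep.labels, seed=seed)
        local_keep = sel.retained_ids                 # indices into candidates
        retained = candidates[local_keep]

        base = train_tf[train_ep.labels == CONSTANT][:, local_keep].mean(axis=(0, 3))
        keep_tr = featselect.reject_artifactual_epochs(
            train_tf[:, local_keep], tf_cfg.freqs, base)
        keep_te = featselect.reject_artifactual_epochs(
            test_tf[:, local_keep], tf_cfg.freqs, base)
        n_rej = int((~keep_tr).sum() + (~keep_te).sum())

        tr_X = featselect.build_feature_vectors(train_tf[keep_tr], local_keep)
        te_X = featselect.build_feature_vectors(test_tf[keep_te], local_keep)
        tr_y = train_ep.labels[keep_tr]
        pca, slr = _fit_fold_classifier(tr_X, tr_y, seed)
        proba = classify.predict_proba(slr, classify.project(te_X, pca))

        trials = test_ep.index[keep_te].reset_index(drop=True).copy()
        trials["proba"] = proba
        trials["pred"] = (proba > 0.5).astype(int)

        pre_df = None
        if compute_pre_onset:
            half = tf_cfg.window_len / 2.0
            times = tf_cfg.times(train_ep.data.shape[-1], fs)
            wmask = times <= -half / fs + 1e-9
            trp = featselect.build_feature_vectors(train_tf[keep_tr], local_keep, wmask)
            tep = featselect.build_feature_vectors(test_tf[keep_te], local_keep, wmask)
            pca_p, slr_p = _fit_fold_classifier(trp, tr_y, seed)
            proba_p = classify.predict_proba(slr_p, classify.project(tep, pca_p))
            pre_df = test_ep.index[keep_te].reset_index(drop=True).copy()
            pre_df["proba"] = proba_p
            pre_df["pred"] = (proba_p > 0.5).astype(int)

        results.append(FoldResult(
            fold=fold, test_session=sessions[fold].session_id,
            condition=sessions[fold].condition, trials=trials,
            cm=_trials_cm(trials), candidate_ids=candidates,
            retained_ids=retained, spatial_model=sm, dipole_fits=fits,
            selection=sel, n_rejected_epochs=n_rej, pre_onset_trials=pre_df))
    return results


def pooled_cm(folds: list[FoldResult], condition: str | None = None,
              pre_onset: bool = False) -> np.ndarray:
    cm = np.zeros((2, 2), int)
    for f in folds:
        if condition is not None and f.condition != condition:
            continue
        c = f.pre_onset_cm if pre_onset else f.cm
        if c is not None:
            cm += c
    return cm


def split_condition_kappa(per_subject_folds: list[list[FoldResult]],
                          alpha: float = 0.05) -> dict:
    """Cued vs uncued kappas per subject plus the paired t-test across subjects."""
    cued, uncued = [], []
    for folds in per_subject_folds:
        cued.append(kappa(pooled_cm(folds, "cued")).k)
        uncued.append(kappa(pooled_cm(folds, "uncued")).k)
    cued, uncued = np.array(cued), np.array(uncued)
    diff = cued - uncued
    if np.allclose(diff.std(ddof=0), 0.0):
        pval = 1.0
    else:
        pval = float(stats.ttest_rel(cued, uncued).pvalue)
    return {"k_cued": cued, "k_uncued": uncued, "p_value": pval,
            "significant": pval < alpha}


def subclass_kappa(folds: list[FoldResult], subclass: str) -> KappaResult | None:
    """Kappa restricted to one speed change vs its preceding constant speed."""
    if subclass not in SUBCLASSES:
        raise ValueError(f"unknown subclass {subclass!r}")
    preceding = subclass.split("->")[0]
    parts = []
    for f in folds:
        df = f.trials
        sel = ((df["label"] == CHANGE) & (df["subclass"] == subclass)) | \
              ((df["label"] == CONSTANT) & (df["subclass"].astype(str) == preceding))
        parts.append(df[sel])
    pooled = pd.concat(parts, ignore_index=True)
    if (pooled["label"] == CHANGE).sum() == 0 or (pooled["label"] == CONSTANT).sum() == 0:
        logger.warning("subclass %s has no trials in one class; omitted", subclass)
        return None
    return kappa(_trials_cm(pooled))


# ---------------------------------------------------------------------------
# pseudo-online evaluation


@dataclass
class OnlineFoldResult:
    fold: int
    condition: str
    epochs: pd.DataFrame    # trial, label, subclass, center_s, proba


def crossvalidate_online(sessions: list[Recording],
                         batch_folds: list[FoldResult],
                         seed: int = 0) -> list[OnlineFoldResult]:
    """Sliding-window decoding reusing each batch fold's spatial model.

    Per fold: 2 s jittered training epochs and the 9-epoch test sweep are
    extracted, projected with the fold's (not recomputed) unmixing restricted
    to the fold's retained components, and a fresh PCA+classifier is fitted
    on the sliding training features.
    """
    fs = sessions[0].fs
    spec_8_40 = design_fir((8.0, 40.0), fs)
    narrow = [rec.copy_with(apply_zero_phase(rec.signal, spec_8_40))
              for rec in sessions]
    cfg = timefreq.TFConfig.sliding()
    out = []
    for fr in batch_folds:
        fold = fr.fold
        train_ids = [i for i in range(len(sessions)) if i != fold]
        W = fr.spatial_model.unmixing[fr.retained_ids]
        tr_ep = concatenate([extract_sliding(narrow[i], "train") for i in train_ids])
        te_ep = extract_sliding(narrow[fold], "test")
        tr_tf = timefreq.wavelet_tf(np.einsum("ck,tks->tcs", W, tr_ep.data), cfg, fs)
        te_tf = timefreq.wavelet_tf(np.einsum("ck,tks->tcs", W, te_ep.data), cfg, fs)
        tr_X = tr_tf.reshape(tr_tf.shape[0], -1)
        te_X = te_tf.reshape(te_tf.shape[0], -1)
        pca, slr = _fit_fold_classifier(tr_X, tr_ep.labels, seed)
        proba = classify.predict_proba(slr, classify.project(te_X, pca))
        df = te_ep.index.copy()
        df["proba"] = proba
        out.append(OnlineFoldResult(fold=fold, condition=sessions[fold].condition,
                                    epochs=df))
    return out


def allornothing_scores(probas: np.ndarray, m: int = 1) -> float:
    """All-or-nothing trial score: maximum of the m-epoch moving average."""
    p = np.asarray(probas, float)
    if m < 1 or m > p.size:
        raise ValueError("averaging order must be between 1 and the epoch count")
    avg = np.convolve(p, np.ones(m) / m, mode="valid")
    return float(avg.max())


@dataclass
class ROCResult:
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    m: int


def roc_auc(scores: np.ndarray, labels01: np.ndarray, m: int = 1) -> ROCResult:
    y = np.asarray(labels01, int)
    s = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(scores=s, labels=y, fpr=fpr, tpr=tpr,
                     auc=float(sk_auc(fpr, tpr)), m=m)


def trial_scores(online_folds: list[OnlineFoldResult], m: int = 1):
    """All-or-nothing score and label per trial across folds."""
    scores, labels = [], []
    for fr in online_folds:
        for (_, label), grp in fr.epochs.groupby(["trial", "label"]):
            grp = grp.sort_values("center_s")
            scores.append(allornothing_scores(grp["proba"].to_numpy(), m))
            labels.append(int(label == CHANGE))
    return np.array(scores), np.array(labels)


def output_timecourse(online_folds: list[OnlineFoldResult]) -> pd.DataFrame:
    """Median and quartiles of the decoder output per class and time bin."""
    df = pd.concat([f.epochs for f in online_folds], ignore_index=True)
    rows = []
    for (label, c), grp in df.groupby(["label", "center_s"]):
        q25, med, q75 = np.percentile(grp["proba"], [25, 50, 75])
        rows.append({"label": label, "center_s": c, "median": med,
                     "q25": q25, "q75": q75, "n": len(grp)})
    return pd.DataFrame(rows).sort_values(["label", "center_s"]).reset_index(drop=True)
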