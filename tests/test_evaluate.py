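"""Kappa machinery, pooling, all-or-nothing scoring and output summaries."""

import numpy as np
import pandas as pd
import pytest

from gaitdecode.evaluate import (allornothing_scores, classwise_accuracy,
                                 confusion_matrix, kappa, output_timecourse,
                                 roc_auc, OnlineFoldResult)


class TestClasswiseAccuracy:
    @pytest.mark.parametrize("cm,mean,sd", [
        ([[18, 0], [0, 18]], 100.0, 0.0),
        ([[9, 9], [9, 9]], 50.0, 0.0),
        ([[12, 6], [3, 15]], 75.0, 11.785113),
    ])
    def test_examples(self, cm, mean, sd):
        m, s = classwise_accuracy(np.array(cm))
        assert m == pytest.approx(mean, abs=1e-4)
        assert s == pytest.approx(sd, abs=1e-4)

    def test_empty_row_error(self):
        with pytest.raises(ValueError):
            classwise_accuracy(np.array([[0, 0], [3, 5]]))


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa(np.array([[10, 0], [0, 10]])).k == pytest.approx(1.0)

    def test_chance_agreement(self):
        r = kappa(np.array([[5, 5], [5, 5]]))
        assert r.k == pytest.approx(0.0)
        assert not r.significant

    def test_hand_worked_adjusted_wald_example(self):
        # N = 16, C = 12, symmetric marginals: p0 = 0.5, p_hat = 0.7,
        # k_hat = 0.4, k_l = 0.4 - 1.96*sqrt(0.21/(20*0.25)) = -0.00168
        cm = np.array([[6, 2], [2, 6]])
        r = kappa(cm)
        assert r.N == 16 and r.C == 12
        assert r.p0 == pytest.approx(0.5)
        assert r.p_hat == pytest.approx(0.7)
        assert r.k_hat == pytest.approx(0.4)
        assert r.k_lower == pytest.approx(-0.00168, abs=5e-5)
        assert not r.significant

    def test_kappa_equals_2acc_minus_1_for_symmetric_matrices(self, rng):
        """For balanced 2x2 matrices with symmetric marginals p0 = 1/2 and
        kappa reduces to 2·accuracy − 1."""
        for _ in range(50):
            a, b = rng.integers(1, 60, size=2)
            cm = np.array([[a, b], [b, a]])
            r = kappa(cm)
            acc = np.trace(cm) / cm.sum()
            assert r.k == pytest.approx(2 * acc - 1, abs=1e-12)

    def test_degenerate_marginals_error(self):
        with pytest.raises(ValueError):
            kappa(np.array([[10, 0], [0, 0]]))


class TestAllOrNothing:
    def test_constant_probabilities(self):
        for m in (1, 2, 3):
            assert allornothing_scores(np.full(9, 0.2), m) == pytest.approx(0.2)

    def test_two_epoch_average(self):
        assert allornothing_scores([0.1, 0.9, 0.1], 2) == pytest.approx(0.5)

    def test_single_epoch_score_dominates_averages(self, rng):
        # the best single epoch bounds every moving-average score (an average
        # never exceeds its largest element); note the m=2 vs m=3 ordering is
        # NOT a theorem ([1,0,1] scores 0.5 at m=2 but 2/3 at m=3)
        for _ in range(200):
            p = rng.uniform(size=9)
            s1 = allornothing_scores(p, 1)
            assert s1 >= allornothing_scores(p, 2) - 1e-12
            assert s1 >= allornothing_scores(p, 3) - 1e-12
        assert allornothing_scores([1.0, 0.0, 1.0], 3) > \
            allornothing_scores([1.0, 0.0, 1.0], 2)

    def test_order_out_of_range(self):
        with pytest.raises(ValueError):
            allornothing_scores(np.full(9, 0.5), 10)


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert r.auc == pytest.approx(1.0)

    def test_identical_scores(self):
        r = roc_auc(np.full(10, 0.4), np.repeat([0, 1], 5))
        assert r.auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self, rng):
        """Trapezoid AUC equals the pairwise win fraction (ties count half)."""
        for _ in range(30):
            scores = np.round(rng.uniform(size=24), 1)  # induce ties
            labels = rng.integers(0, 2, 24)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum() \
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            oracle = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_curve_monotone(self, rng):
        r = roc_auc(rng.uniform(size=40), rng.integers(0, 2, 40))
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


def _online(probs_by_bin, label):
    rows = []
    for trial, probs in enumerate(probs_by_bin):
        for c, p in zip(np.arange(-1, 3.5, 0.5), probs):
            rows.append({"trial": trial, "label": label, "subclass": "1->2",
                         "session": 0, "condition": "cued",
                         "center_s": c, "proba": p})
    return OnlineFoldResult(fold=0, condition="cued", epochs=pd.DataFrame(rows))


class TestTimecourse:
    def test_constant_probability(self):
        tc = output_timecourse([_online([np.full(9, 0.3)] * 4, "constant")])
        assert (tc["median"] == pytest.approx(0.3)) if len(tc) == 1 else \
            np.allclose(tc["median"], 0.3)
        assert np.allclose(tc["q75"] - tc["q25"], 0.0)

    def test_median_definition(self):
        tc = output_timecourse([_online([[0.1] * 9, [0.2] * 9, [0.9] * 9],
                                        "change")])
        assert np.allclose(tc["median"], 0.2)


class TestConfusionPartition:
    def test_subclass_counts_partition_totals(self):
        true = np.array([0, 0, 1, 1, 0, 1])
        pred = np.array([0, 1, 1, 0, 0, 1])
        cm = confusion_matrix(true, pred)
        assert cm.sum() == 6
        assert np.array_equal(cm, [[2, 1], [1, 2]])
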