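"""Cross-subject component clustering, dorsal projection and artifact QC."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from gaitdecode.clusterqc import (ClusterMember, ErspPair,
                                  channel_correlation_qc, cluster_components,
                                  project_centroid_dorsal,
                                  retained_rejected_pairing)
from gaitdecode.headmodel import Dipole, DipoleFit


def _member(subject, fold, xyz, map_seed, flip=1.0):
    rng = np.random.default_rng(map_seed)
    base = rng.normal(size=64)
    return ClusterMember(subject=subject, fold=fold, component=0,
                         dipole_xyz=np.asarray(xyz, float),
                         scalp_map=flip * base)


def _two_groups(n_folds=10, jitter=2.0):
    """Parietal and frontal member groups, two subjects each."""
    rng = np.random.default_rng(0)
    members = []
    for subj in ("S1", "S2"):
        for fold in range(n_folds):
            members.append(_member(subj, fold,
                                   [-35, 8, 42] + rng.normal(0, jitter, 3), 1))
            members.append(_member(subj, fold,
                                   [45, -5, 20] + rng.normal(0, jitter, 3), 2))
    return members


class TestClustering:
    def test_separable_groups_perfectly_assigned(self):
        members = _two_groups()
        cs = cluster_components(members, k=2, seed=0, folds_per_subject=10)
        posterior = [cs.assignments[i] for i, m in enumerate(members)
                     if m.dipole_xyz[0] < 0]
        anterior = [cs.assignments[i] for i, m in enumerate(members)
                    if m.dipole_xyz[0] > 0]
        assert len(set(posterior)) == 1 and len(set(anterior)) == 1
        assert set(posterior) != set(anterior)
        assert len(cs.surviving) == 2

    def test_silhouette_of_separable_case(self):
        members = _two_groups()
        cs = cluster_components(members, k=2, seed=0, folds_per_subject=10)
        X = np.array([np.concatenate([m.dipole_xyz]) for m in members])
        assert silhouette_score(X, cs.assignments) > 0.8

    def test_far_outlier_flagged(self):
        members = _two_groups(jitter=0.5)
        members.append(_member("S1", 0, [-35 + 300, 8, 42], 1))
        cs = cluster_components(members, k=2, seed=0, folds_per_subject=10)
        assert len(members) - 1 in cs.outliers.tolist()

    def test_low_fold_fraction_subject_removed(self):
        members = _two_groups()
        # S3 contributes the posterior cluster in only 3 of 10 folds
        for fold in range(3):
            members.append(_member("S3", fold, [-35, 8, 42], 1))
        cs = cluster_components(members, k=2, seed=0, folds_per_subject=10)
        s3 = [cs.assignments[i] for i, m in enumerate(members)
              if m.subject == "S3"]
        assert all(a == -1 for a in s3)

    def test_needs_at_least_k_members(self):
        with pytest.raises(ValueError):
            cluster_components(_two_groups()[:2], k=4)

    def test_deterministic(self):
        members = _two_groups()
        a = cluster_components(members, k=2, seed=3, folds_per_subject=10)
        b = cluster_components(members, k=2, seed=3, folds_per_subject=10)
        assert np.array_equal(a.assignments, b.assignments)


class TestDorsalProjection:
    def test_interior_point_lifted_to_cortex_sphere(self):
        out = project_centroid_dorsal(np.array([0.0, 0.0, 10.0]), radius=85.0)
        assert out == pytest.approx([0.0, 0.0, 49.3])

    def test_point_on_sphere_unchanged(self):
        p = np.array([0.0, 0.0, 49.3])
        assert project_centroid_dorsal(p, radius=85.0) == pytest.approx(p)

    def test_projected_radius_is_cortex_radius(self, rng):
        for _ in range(20):
            p = rng.normal(size=3) * 10
            out = project_centroid_dorsal(p, radius=85.0)
            if not np.allclose(out, p):
                assert np.linalg.norm(out) == pytest.approx(0.58 * 85.0, abs=1e-9)

    def test_outside_cylinder_left_in_place(self):
        p = np.array([60.0, 0.0, 5.0])
        assert project_centroid_dorsal(p, radius=85.0) == pytest.approx(p)


class TestChannelCorrelationQc:
    def test_identical_conditions_have_zero_difference(self, rng):
        data = rng.normal(size=(6, 8, 300))
        qc = channel_correlation_qc({"a": data, "b": data.copy()})
        assert np.allclose(qc.differences[("a", "b")], 0.0)
        assert qc.mad[("a", "b")] == 0.0

    def test_shared_source_gives_unit_r2(self, rng):
        src = rng.normal(size=(4, 1, 200))
        data = np.concatenate([src, 2.0 * src], axis=1)  # two copies
        qc = channel_correlation_qc({"a": data})
        assert qc.mean_r2["a"][0, 1] == pytest.approx(1.0)

    def test_matrices_symmetric_with_unit_diagonal(self, rng):
        data = rng.normal(size=(5, 6, 400))
        qc = channel_correlation_qc({"a": data})
        M = qc.mean_r2["a"]
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)

    def test_empty_condition_error(self, rng):
        with pytest.raises(ValueError):
            channel_correlation_qc({"a": np.empty((0, 4, 100))})


def _dfit(radial, rv, x):
    return DipoleFit(dipole=Dipole([x, 0.0, 10.0], [0, 0, 1.0]),
                     residual_variance=rv, radial_fraction=radial,
                     converged=True)


class TestPairing:
    def test_self_pair_has_unit_correlation(self, rng):
        e = rng.normal(size=(20, 50))
        best = retained_rejected_pairing({1: e}, [(9, _dfit(0.95, 0.05, -40), e)])
        assert best.correlation == pytest.approx(1.0)
        assert (best.rejected_id, best.retained_id) == (9, 1)

    def test_negated_pair_has_minus_one(self, rng):
        e = rng.normal(size=(20, 50))
        best = retained_rejected_pairing({1: e}, [(9, _dfit(0.95, 0.05, -40), -e)])
        assert best.correlation == pytest.approx(-1.0)

    def test_pool_filters(self, rng):
        e = rng.normal(size=(20, 50))
        rejected = [
            (1, _dfit(0.80, 0.05, -40), e),   # too central
            (2, _dfit(0.95, 0.20, -40), e),   # poor fit
            (3, _dfit(0.95, 0.05, +40), e),   # anterior
        ]
        assert retained_rejected_pairing({0: e}, rejected) is None
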