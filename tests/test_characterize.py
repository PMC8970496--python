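"""Dataset and cluster-structure characterization."""

import numpy as np
import pytest

import clusterselect as cs
from clusterselect.kb import Characteristic as C


def _matrix(n, p, seed=0):
    rng = np.random.default_rng(seed)
    return cs.DatasetMatrix(rng.standard_normal((n, p)))


@pytest.mark.parametrize(
    "n,p,small,high",
    [
        (150, 4, True, False),   # iris-shaped
        (801, 20531, True, True),  # expression-shaped
        (5000, 10, False, False),
    ],
)
def test_size_and_dimensionality_flags(n, p, small, high):
    # broadcast view: full 801x20531 shape without allocating it
    m = cs.DatasetMatrix(np.broadcast_to(0.0, (n, p)))
    dc = cs.characterize_dataset(m)
    assert dc.small_dataset is small
    assert dc.high_dimensional is high
    assert (dc.n_samples, dc.n_features) == (n, p)


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        cs.characterize_dataset(cs.DatasetMatrix(np.zeros((0, 3), dtype=float)))


class TestPCA:
    def test_rank_one_matrix_has_all_variance_on_first_axis(self):
        u = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
        res = cs.project_pca(cs.DatasetMatrix(u), q=1)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_constant_feature_contributes_nothing(self):
        m = _matrix(30, 3, seed=1)
        vals = np.column_stack([m.values, np.full(30, 7.0)])
        full = cs.project_pca(cs.DatasetMatrix(vals), q=4)
        assert full.explained_fraction[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_svd_oracle(self):
        """Scores and fractions equal an independent SVD computation."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 6)) @ np.diag([5.0, 3.0, 1.0, 1.0, 0.5, 0.1])
        res = cs.project_pca(cs.DatasetMatrix(X), q=3)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle_scores = U[:, :3] * S[:3]
        oracle_frac = S[:3] ** 2 / np.sum(S**2)
        # principal axes are sign-indeterminate
        for j in range(3):
            assert np.allclose(res.scores[:, j], oracle_scores[:, j], atol=1e-8) or (
                np.allclose(res.scores[:, j], -oracle_scores[:, j], atol=1e-8)
            )
        assert np.allclose(res.explained_fraction, oracle_frac, atol=1e-8)

    def test_explained_fractions_sum_to_one_at_full_rank(self):
        m = _matrix(20, 4, seed=2)
        res = cs.project_pca(m, q=4)
        assert res.explained_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_oversized_q_rejected(self):
        with pytest.raises(ValueError):
            cs.project_pca(_matrix(10, 3), q=5)


class TestClusterStructure:
    def test_two_equal_separated_blobs_are_featureless(self):
        spec = cs.ClusterSpec(
            sizes=[40, 40],
            means=[np.zeros(2), np.full(2, 20.0)],
            covariances=[1.0, 1.0],
            seed=11,
        )
        st = cs.characterize_clusters(cs.make_clusters(spec))
        assert st.balance_ratio == 1.0
        assert not any(st.flags.values())

    def test_singleton_class_detected(self, blobs3):
        labels = blobs3.labels.copy()
        labels[0] = 99  # carve out a single-point class
        st = cs.characterize_clusters(blobs3, labels)
        assert st.has_single_point_cluster
        assert st.flags[C.SINGLE_POINT_CLUSTER]
        assert st.flags[C.UNEVEN_CLUSTER_SIZE]

    def test_anisotropic_cluster_elongation_matches_generating_covariance(self):
        spec = cs.ClusterSpec(
            sizes=[150], means=[np.zeros(2)], covariances=[np.diag([100.0, 1.0])], seed=3
        )
        st = cs.characterize_clusters(cs.make_clusters(spec))
        assert st.max_elongation == pytest.approx(10.0, rel=0.2)
        assert st.flags[C.NON_SPHERICAL_SHAPE]

    def test_density_scale_recovered(self):
        spec = cs.ClusterSpec(
            sizes=[40, 40],
            means=[np.zeros(3), np.full(3, 50.0)],
            covariances=[1.0, 1.0],
            density_scales=[1.0, 5.0],
            seed=2,
        )
        st = cs.characterize_clusters(cs.make_clusters(spec))
        assert st.density_variation_ratio == pytest.approx(5.0, rel=0.2)
        assert st.flags[C.VARIABLE_CLUSTER_DENSITY]

    def test_sample_permutation_invariance(self, blobs3):
        rng = np.random.default_rng(5)
        perm = rng.permutation(blobs3.n_samples)
        shuffled = cs.DatasetMatrix(blobs3.values[perm], labels=blobs3.labels[perm])
        a = cs.characterize_clusters(blobs3)
        b = cs.characterize_clusters(shuffled)
        assert a.balance_ratio == b.balance_ratio
        assert a.density_variation_ratio == pytest.approx(b.density_variation_ratio)
        assert a.max_elongation == pytest.approx(b.max_elongation)
        assert a.flags == b.flags

    def test_label_relabelling_invariance(self, blobs3):
        relabelled = (blobs3.labels + 5) * 3  # injective remap
        a = cs.characterize_clusters(blobs3)
        b = cs.characterize_clusters(blobs3, relabelled)
        assert sorted(a.sizes) == sorted(b.sizes)
        assert a.flags == b.flags


class TestUnlabelledEstimation:
    def test_separated_clusters_recover_labelled_flags(self, blobs3):
        unlabelled = blobs3.replace(labels=None)
        est = cs.estimate_structure_unlabelled(unlabelled, k=3)
        truth = cs.characterize_clusters(blobs3)
        assert est.estimated
        assert est.flags == truth.flags
        assert sorted(est.sizes) == sorted(truth.sizes)

    def test_k_one_gives_single_balanced_cluster(self, blobs3):
        est = cs.estimate_structure_unlabelled(blobs3.replace(labels=None), k=1)
        assert est.n_clusters == 1 and est.balance_ratio == 1.0

    def test_k_equals_n_gives_all_singletons(self):
        m = _matrix(8, 2, seed=9)
        est = cs.estimate_structure_unlabelled(m, k=8)
        assert est.has_single_point_cluster and est.n_clusters == 8

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            cs.estimate_structure_unlabelled(_matrix(5, 2), k=6)


def test_requirement_profile_from_measurements(blobs3):
    dc = cs.characterize_dataset(blobs3)
    st = cs.characterize_clusters(blobs3)
    profile = cs.derive_requirement_profile(dc, st)
    assert profile[C.SMALL_DATASETS] is True
    assert profile[C.HIGH_DIMENSIONS] is False
    assert not any(profile[c] for c in (
        C.NON_SPHERICAL_SHAPE, C.VARIABLE_CLUSTER_DENSITY,
        C.SINGLE_POINT_CLUSTER, C.UNEVEN_CLUSTER_SIZE,
    ))
    # algorithm-side characteristics are the user's call, not the data's
    assert C.MULTIMODAL_HIERARCHICAL not in profile
    assert C.EFFICIENCY not in profile
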