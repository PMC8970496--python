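"""External (V-measure) and internal cluster validity indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clusterselect as cs
from clusterselect.evaluate import resolve_noise


# ------------------------------------------------------- brute-force oracle


def oracle_hcv(true_labels, pred_labels, beta=1.0):
    """Independent entropy computation by direct enumeration of label pairs."""
    t = list(true_labels)
    p = list(pred_labels)
    n = len(t)

    def entropy(assignment):
        out = 0.0
        for v in set(assignment):
            q = assignment.count(v) / n
            out -= q * np.log(q)
        return out

    def cond_entropy(rows, cols):
        out = 0.0
        for cv in set(cols):
            idx = [i for i in range(n) if cols[i] == cv]
            for rv in set(rows[i] for i in idx):
                joint = sum(rows[i] == rv for i in idx) / n
                out -= joint * np.log(joint / (len(idx) / n))
        return out

    ht, hp = entropy(t), entropy(p)
    h = 1.0 if ht == 0 else 1.0 - cond_entropy(t, p) / ht
    c = 1.0 if hp == 0 else 1.0 - cond_entropy(p, t) / hp
    v = (1 + beta) * h * c / (beta * h + c) if beta * h + c > 0 else 0.0
    return h, c, v


class TestContingency:
    def test_direct_count(self):
        table = cs.contingency([0, 0, 1, 1], [0, 0, 1, 2])
        assert table.tolist() == [[2, 0, 0], [0, 1, 1]]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.contingency([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.contingency([0, 1], [0])

    def test_point_permutation_invariance(self):
        t, p = [0, 1, 0, 2, 1], [1, 1, 0, 2, 0]
        perm = [3, 1, 4, 0, 2]
        a = cs.contingency(t, p)
        b = cs.contingency([t[i] for i in perm], [p[i] for i in perm])
        assert np.array_equal(a, b)


class TestVMeasure:
    def test_identity_labelling_scores_exactly_one(self):
        labels = [0] * 10 + [1] * 10 + [2] * 10
        assert cs.v_measure(labels, labels).v == 1.0

    def test_bijective_relabelling_scores_exactly_one(self):
        t = [0, 0, 1, 1, 2, 2]
        assert cs.v_measure(t, [5, 5, 3, 3, 9, 9]).v == 1.0

    def test_single_cluster_on_two_classes_scores_exactly_zero(self):
        t = [0] * 10 + [1] * 10
        res = cs.v_measure(t, [0] * 20)
        assert res.h == 0.0 and res.c == 1.0 and res.v == 0.0

    def test_hand_computed_homogeneity(self):
        # one mixed cluster of 3: h = 1 - (3/4)H(1/3,2/3)/H(1/2,1/2)
        expected = 1 - (0.75 * (-(1 / 3) * np.log(1 / 3) - (2 / 3) * np.log(2 / 3))) / np.log(2)
        assert cs.homogeneity([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(expected)
        assert expected == pytest.approx(0.3113, abs=1e-4)

    def test_hand_computed_completeness_all_singletons(self):
        # 2 equal classes of 2, each point its own cluster: c = 1 - 1/2
        assert cs.completeness([0, 0, 1, 1], [0, 1, 2, 3]) == pytest.approx(0.5)

    def test_hand_computed_split_cluster(self):
        res = cs.v_measure([0, 0, 1, 1], [0, 0, 1, 2])
        assert res.h == pytest.approx(1.0)
        assert res.c == pytest.approx(2 / 3)
        assert res.v == pytest.approx(0.8)

    def test_pure_clusters_have_unit_homogeneity(self):
        assert cs.homogeneity([0, 0, 1, 1], [0, 1, 2, 3]) == 1.0

    def test_completeness_is_homogeneity_with_roles_swapped(self):
        t, p = [0, 0, 1, 2, 2, 1], [1, 1, 0, 0, 2, 2]
        assert cs.completeness(t, p) == pytest.approx(cs.homogeneity(p, t))

    def test_oracle_equivalence_500_random_instances(self):
        """h, c, v match brute-force enumeration within 1e-12."""
        rng = np.random.default_rng(123)
        for _ in range(500):
            n = rng.integers(2, 31)
            t = rng.integers(0, rng.integers(1, 6), size=n)
            p = rng.integers(0, rng.integers(1, 6), size=n)
            res = cs.v_measure(t, p)
            oh, oc, ov = oracle_hcv(t, p)
            assert abs(res.h - oh) < 1e-12
            assert abs(res.c - oc) < 1e-12
            assert abs(res.v - ov) < 1e-12

    def test_matches_scikit_learn(self):
        """Cross-check against the independent library implementation."""
        from sklearn.metrics import homogeneity_completeness_v_measure

        rng = np.random.default_rng(7)
        for _ in range(50):
            t = rng.integers(0, 4, size=25)
            p = rng.integers(0, 4, size=25)
            res = cs.v_measure(t, p)
            sh, sc, sv = homogeneity_completeness_v_measure(t, p)
            assert res.h == pytest.approx(sh, abs=1e-10)
            assert res.c == pytest.approx(sc, abs=1e-10)
            assert res.v == pytest.approx(sv, abs=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        labels=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=30
        )
    )
    def test_symmetry_and_bounds(self, labels):
        t, p = zip(*labels)
        res = cs.v_measure(t, p)
        swapped = cs.v_measure(p, t)
        assert res.v == pytest.approx(swapped.v, abs=1e-12)  # beta=1 symmetry
        assert 0.0 <= res.v <= 1.0
        assert res.v <= max(res.h, res.c) + 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        labels=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=20
        ),
        shift=st.integers(1, 5),
    )
    def test_label_permutation_invariance(self, labels, shift):
        t, p = zip(*labels)
        remapped = [x + shift for x in p]  # injective relabelling
        assert cs.v_measure(t, p).v == pytest.approx(
            cs.v_measure(t, remapped).v, abs=1e-12
        )

    def test_beta_weighting(self):
        t, p = [0, 0, 1, 1], [0, 0, 1, 2]
        res = cs.v_measure(t, p, beta=2.0)
        assert res.v == pytest.approx(3 * res.h * res.c / (2 * res.h + res.c))
        with pytest.raises(ValueError):
            cs.v_measure(t, p, beta=0)


class TestNoiseConvention:
    def test_noise_as_one_extra_cluster(self):
        labels = np.array([0, 0, 1, -1, -1])
        out = resolve_noise(labels, "cluster")
        assert out.tolist() == [0, 0, 1, 2, 2]

    def test_noise_as_singletons(self):
        labels = np.array([0, 0, 1, -1, -1])
        out = resolve_noise(labels, "singletons")
        assert out.tolist() == [0, 0, 1, 2, 3]

    def test_noise_free_labels_untouched(self):
        labels = np.array([0, 1, 2])
        assert resolve_noise(labels).tolist() == [0, 1, 2]


class TestInternalIndices:
    def setup_method(self):
        self.line = cs.DatasetMatrix(np.array([[0.0], [1.0], [10.0], [11.0]]))
        self.labels = [0, 0, 1, 1]

    def test_silhouette_hand_value(self):
        # per point: (10.5-1)/10.5, (9.5-1)/9.5, (9.5-1)/9.5, (10.5-1)/10.5
        expected = (2 * 9.5 / 10.5 + 2 * 8.5 / 9.5) / 4
        assert cs.silhouette(self.line, self.labels) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.8997, abs=1e-4)

    def test_silhouette_tight_far_blobs_near_one(self):
        spec = cs.ClusterSpec(
            sizes=[25, 25], means=[np.zeros(2), np.full(2, 50.0)],
            covariances=[1.0, 1.0], seed=8,
        )
        data = cs.make_clusters(spec)
        assert cs.silhouette(data, data.labels) > 0.9

    def test_silhouette_random_labels_near_zero(self):
        """Permutation oracle: random labels on one blob average ~0."""
        rng = np.random.default_rng(11)
        m = cs.DatasetMatrix(rng.standard_normal((60, 2)))
        vals = []
        for _ in range(100):
            labels = rng.permutation([0] * 30 + [1] * 30)
            vals.append(cs.silhouette(m, labels))
        assert abs(np.mean(vals)) < 0.05

    def test_silhouette_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cs.silhouette(self.line, [0, 0, 0, 0])

    def test_davies_bouldin_hand_value(self):
        m = cs.DatasetMatrix(np.array([[0.0], [2.0], [10.0], [12.0]]))
        assert cs.davies_bouldin(m, [0, 0, 1, 1]) == pytest.approx(0.2)

    def test_davies_bouldin_point_duplication_invariance(self):
        m = cs.DatasetMatrix(np.array([[0.0], [2.0], [10.0], [12.0]]))
        doubled = cs.DatasetMatrix(np.repeat(m.values, 2, axis=0))
        assert cs.davies_bouldin(doubled, [0, 0, 0, 0, 1, 1, 1, 1]) == pytest.approx(
            cs.davies_bouldin(m, [0, 0, 1, 1])
        )

    def test_davies_bouldin_shrinks_to_zero_with_tight_clusters(self):
        m = cs.DatasetMatrix(np.array([[0.0], [1e-9], [10.0], [10.0 + 1e-9]]))
        assert cs.davies_bouldin(m, [0, 0, 1, 1]) < 1e-8

    def test_davies_bouldin_coincident_centroids_rejected(self):
        m = cs.DatasetMatrix(np.array([[0.0], [2.0], [0.0], [2.0]]))
        with pytest.raises(ValueError, match="oincident"):
            cs.davies_bouldin(m, [0, 0, 1, 1])

    def test_dunn_hand_value(self):
        assert cs.dunn(self.line, self.labels) == pytest.approx(9.0)

    def test_dunn_touching_clusters_zero(self):
        m = cs.DatasetMatrix(np.array([[0.0], [1.0], [1.0], [2.0]]))
        assert cs.dunn(m, [0, 0, 1, 1]) == 0.0

    def test_dunn_scale_invariance(self, blobs3):
        scaled = cs.DatasetMatrix(blobs3.values * 3.7, labels=blobs3.labels)
        assert cs.dunn(scaled, scaled.labels) == pytest.approx(
            cs.dunn(blobs3, blobs3.labels)
        )

    def test_dunn_all_singletons_rejected(self):
        m = cs.DatasetMatrix(np.array([[0.0], [5.0], [9.0]]))
        with pytest.raises(ValueError):
            cs.dunn(m, [0, 1, 2])


class TestEvaluationGrid:
    def test_capable_algorithms_score_one_on_separated_blobs(self, blobs3):
        specs = [
            cs.AlgorithmSpec(name)
            for name in ["Hierarchical (Ward's)", "k-means", "Gaussian Mixture Model"]
        ]
        table = cs.evaluate_grid(specs, [blobs3], groups={"g": [blobs3.name]})
        assert np.allclose(table.scores.to_numpy(), 1.0)

    def test_group_totals_equal_row_sums(self, blobs3):
        other = blobs3.replace(name="second")
        specs = [cs.AlgorithmSpec("Hierarchical (Ward's)"), cs.AlgorithmSpec("k-means")]
        table = cs.evaluate_grid(
            specs, [blobs3, other], groups={"pair": [blobs3.name, "second"]}
        )
        assert np.allclose(
            table.group_totals["pair"].to_numpy(),
            table.scores.sum(axis=1).to_numpy(),
        )

    def test_repeat_invocations_identical(self, blobs3):
        specs = [cs.AlgorithmSpec("k-means", seed=3), cs.AlgorithmSpec("PAM", seed=3)]
        a = cs.evaluate_grid(specs, [blobs3])
        b = cs.evaluate_grid(specs, [blobs3])
        assert a.scores.equals(b.scores)

    def test_per_cell_failure_becomes_annotation(self, blobs3):
        # DBSCAN with absurd eps leaves everything as noise -> annotation
        specs = [cs.AlgorithmSpec("DBSCAN", {"eps": 1e-6, "min_samples": 3})]
        table = cs.evaluate_grid(specs, [blobs3])
        msgs = table.annotations[("DBSCAN", blobs3.name)]
        assert any("noise" in m for m in msgs)
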