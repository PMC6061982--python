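import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from semindex.dbm import sigmoid
from semindex.hierarchy import (
    CoarsePartition,
    HierarchyWeights,
    cluster_labels,
    coarse_loss,
    coarse_targets,
    dbc_predict,
    fine_loss,
    predict_labels,
)
from semindex.synthetic import SyntheticSpec, generate_label_space


def logit(p):
    return np.log(p / (1 - p))


class TestClusterLabels:
    def test_single_cluster(self):
        emb = {f"l{i}": np.random.default_rng(i).standard_normal(4)
               for i in range(5)}
        part = cluster_labels(emb, 1, seed=0)
        assert set(part.assignment.values()) == {0}

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[10.0, 0.0], [-10.0, 0.0]])
        emb, truth = {}, []
        for i in range(20):
            c = i % 2
            emb[f"l{i:02d}"] = centers[c] + 0.1 * rng.standard_normal(2)
            truth.append(c)
        part = cluster_labels(emb, 2, seed=1)
        got = [part.assignment[f"l{i:02d}"] for i in range(20)]
        assert adjusted_rand_score(truth, got) == 1.0

    def test_deterministic(self):
        emb = {f"l{i}": np.random.default_rng(i).standard_normal(3)
               for i in range(8)}
        a = cluster_labels(emb, 3, seed=5)
        b = cluster_labels(emb, 3, seed=5)
        assert a.assignment == b.assignment

    def test_too_many_clusters_errors(self):
        emb = {"a": np.zeros(2), "b": np.ones(2)}
        with pytest.raises(ValueError):
            cluster_labels(emb, 3, seed=0)


class TestCoarseLoss:
    def test_perfect_outputs_zero_loss(self):
        # w chosen so sigmoid saturates to the targets within float precision
        x = np.array([[1.0]])
        w = np.array([[800.0], [-800.0]])
        y = np.array([[1.0, 0.0]])
        loss, dw = coarse_loss(x, w, y)
        assert loss == 0.0
        np.testing.assert_array_equal(dw, 0.0)

    def test_hand_derived_value_one(self):
        # N=1, C=2, f=(1,0), y=(0,1) -> E = (1/2)(1+1) = 1
        x = np.array([[1.0]])
        w = np.array([[800.0], [-800.0]])
        y = np.array([[0.0, 1.0]])
        loss, _ = coarse_loss(x, w, y)
        assert loss == pytest.approx(1.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 3))
        w = rng.standard_normal((2, 3))
        y = (rng.random((5, 2)) < 0.5).astype(float)
        _, dw = coarse_loss(x, w, y)
        eps = 1e-6
        for i in range(2):
            for j in range(3):
                wp = w.copy(); wp[i, j] += eps
                wm = w.copy(); wm[i, j] -= eps
                num = (coarse_loss(x, wp, y)[0] - coarse_loss(x, wm, y)[0]) / (2 * eps)
                assert abs(num - dw[i, j]) / max(abs(num), 1e-8) < 1e-4

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError):
            coarse_loss(np.zeros((0, 2)), np.zeros((1, 2)), np.zeros((0, 1)))


class TestFineLoss:
    def test_perfect_outputs_zero(self):
        x = np.array([[1.0]])
        w = np.array([[800.0], [-800.0]])
        y = np.array([[1.0, 0.0]])
        loss, _ = fine_loss(x, w, y)
        assert loss == 0.0

    def test_hand_derived_half(self):
        # n_k=2 labels, f=(1,1), y=(1,0) -> J = 1/2
        x = np.array([[1.0]])
        w = np.array([[800.0], [800.0]])
        y = np.array([[1.0, 0.0]])
        loss, _ = fine_loss(x, w, y)
        assert loss == pytest.approx(0.5)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 3))
        w = rng.standard_normal((3, 3))
        y = (rng.random((4, 3)) < 0.5).astype(float)
        _, dw = fine_loss(x, w, y)
        eps = 1e-6
        for i in range(3):
            for j in range(3):
                wp = w.copy(); wp[i, j] += eps
                wm = w.copy(); wm[i, j] -= eps
                num = (fine_loss(x, wp, y)[0] - fine_loss(x, wm, y)[0]) / (2 * eps)
                assert abs(num - dw[i, j]) / max(abs(num), 1e-8) < 1e-4

    def test_losses_nonnegative_random(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal((3, 2))
            w = rng.standard_normal((2, 2))
            y = (rng.random((3, 2)) < 0.5).astype(float)
            assert coarse_loss(x, w, y)[0] >= 0
            assert fine_loss(x, w, y)[0] >= 0


def two_cluster_weights(x_dim=1):
    """Partition {a0,a1} | {b0,b1} with hand-constructed weights on x=[1]."""
    partition = CoarsePartition(
        n_clusters=2,
        assignment={"a0": 0, "a1": 0, "b0": 1, "b1": 1},
        centers=np.zeros((2, x_dim)),
    )
    return partition


class TestPredictLabels:
    def test_global_argmax_fallback(self):
        partition = two_cluster_weights()
        weights = HierarchyWeights(
            coarse=np.array([[logit(0.2)], [logit(0.3)]]),
            fine={0: np.array([[logit(0.1)], [logit(0.35)]]),
                  1: np.array([[logit(0.4)], [logit(0.2)]])},
            fine_labels={0: ["a0", "a1"], 1: ["b0", "b1"]},
        )
        # no coarse passes -> argmax cluster 1; no fine passes -> best fine
        assert predict_labels(np.array([1.0]), partition, weights) == {"b0"}

    def test_engineered_two_labels_from_one_cluster(self):
        partition = two_cluster_weights()
        weights = HierarchyWeights(
            coarse=np.array([[logit(0.1)], [logit(0.9)]]),
            fine={0: np.array([[logit(0.99)], [logit(0.99)]]),
                  1: np.array([[logit(0.8)], [logit(0.7)]])},
            fine_labels={0: ["a0", "a1"], 1: ["b0", "b1"]},
        )
        assert predict_labels(np.array([1.0]), partition, weights) == {"b0", "b1"}

    def test_high_fine_score_in_unselected_cluster_excluded(self):
        partition = two_cluster_weights()
        weights = HierarchyWeights(
            coarse=np.array([[logit(0.9)], [logit(0.1)]]),
            fine={0: np.array([[logit(0.8)], [logit(0.1)]]),
                  1: np.array([[logit(0.99)], [logit(0.99)]])},
            fine_labels={0: ["a0", "a1"], 1: ["b0", "b1"]},
        )
        got = predict_labels(np.array([1.0]), partition, weights)
        assert got == {"a0"}
        assert not got & {"b0", "b1"}

    def test_gating_invariant_random(self):
        rng = np.random.default_rng(3)
        partition = two_cluster_weights(x_dim=4)
        for _ in range(50):
            weights = HierarchyWeights(
                coarse=rng.standard_normal((2, 4)),
                fine={0: rng.standard_normal((2, 4)),
                      1: rng.standard_normal((2, 4))},
                fine_labels={0: ["a0", "a1"], 1: ["b0", "b1"]},
            )
            x = rng.standard_normal(4)
            selected = np.flatnonzero(
                sigmoid(weights.coarse @ x) >= weights.tau_coarse)
            if selected.size == 0:
                selected = [int(np.argmax(sigmoid(weights.coarse @ x)))]
            allowed = {lab for c in selected for lab in weights.fine_labels[int(c)]}
            got = predict_labels(x, partition, weights)
            assert got <= allowed
            assert len(got) >= 1


class TestDBCPredict:
    def test_member_wins(self):
        w = np.zeros((1, 2, 1))
        w[0, 0, 0] = logit(0.9)
        w[0, 1, 0] = logit(0.1)
        assert dbc_predict(np.array([1.0]), w, ["L"]) == {"L"}

    def test_non_member_wins(self):
        w = np.zeros((1, 2, 1))
        w[0, 0, 0] = logit(0.1)
        w[0, 1, 0] = logit(0.9)
        assert dbc_predict(np.array([1.0]), w, ["L"]) == set()

    def test_tie_excluded(self):
        w = np.zeros((1, 2, 1))
        assert dbc_predict(np.array([1.0]), w, ["L"]) == set()


class TestCoarseTargets:
    def test_union_of_clusters(self):
        partition = two_cluster_weights()
        t = coarse_targets([{"a0"}, {"a1", "b0"}, {"b1"}], partition)
        np.testing.assert_array_equal(
            t, [[1, 0], [1, 1], [0, 1]])


class TestSyntheticLabelRecovery:
    def test_generated_label_space_recoverable(self):
        spec = SyntheticSpec(n_clusters=2, labels_per_cluster=5,
                            separation=10.0, label_noise=1.0, seed=4)
        labels, emb, planted = generate_label_space(spec)
        part = cluster_labels(emb, 2, seed=0)
        truth = [planted[l] for l in labels]
        got = [part.assignment[l] for l in labels]
        assert adjusted_rand_score(truth, got) == 1.0
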