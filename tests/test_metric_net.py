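import math

import numpy as np
import pytest

from mtsc.errors import BatchConstructionError, DimensionError
from mtsc.metric_net import (
    NPairBatch,
    embed,
    init_network,
    npair_loss,
    npair_loss_and_grad,
    multitask_loss_and_grad,
    sample_npair_batch,
)

from conftest import make_dataset, passthrough_net


def brute_force_npair_loss(net, batch):
    """Independent scalar-loop evaluation of the printed loss formula."""
    F = embed(net, batch.anchors)
    Fp = embed(net, batch.positives)
    n = batch.n_classes
    total = 0.0
    for i in range(n):
        inner = 0.0
        for j in range(n):
            if j != i:
                inner += math.exp(
                    float(F[i] @ Fp[j]) - float(F[i] @ Fp[i])
                )
        total += math.log(1.0 + inner)
    return total / n


def embedding_batch(F, Fp):
    """Batch whose embeddings under a pass-through net are F, Fp."""
    F = np.asarray(F, dtype=float)
    return NPairBatch(anchors=F, positives=np.asarray(Fp, dtype=float),
                      labels=[f"t{i}" for i in range(F.shape[0])])


class TestInitNetwork:
    def test_seed_reproducibility(self):
        a = init_network(10, 8, 4, seed=0)
        b = init_network(10, 8, 4, seed=0)
        for k in a.parameters():
            np.testing.assert_array_equal(a.parameters()[k], b.parameters()[k])

    def test_different_seeds_differ(self):
        a = init_network(10, 8, 4, seed=0)
        b = init_network(10, 8, 4, seed=1)
        assert any(
            not np.array_equal(a.parameters()[k], b.parameters()[k])
            for k in a.parameters()
        )

    def test_zero_vector_embeds_finitely(self):
        net = init_network(10, 8, 4, seed=0)
        assert np.all(np.isfinite(embed(net, np.zeros((1, 10)))))


class TestEmbed:
    def test_row_independence(self):
        net = init_network(30, 16, 5, seed=2)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 30))
        single = embed(net, X[:1])
        batch = embed(net, X)
        np.testing.assert_allclose(single[0], batch[0], atol=1e-6)

    def test_output_shape_default_dims(self):
        net = init_network(50, 500, 20, seed=0)
        assert embed(net, np.zeros((7, 50))).shape == (7, 20)

    def test_identical_rows_identical_embeddings(self):
        net = init_network(12, 8, 4, seed=1)
        x = np.random.default_rng(3).normal(size=12)
        out = embed(net, np.vstack([x, x]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_dimension_mismatch(self):
        net = init_network(12, 8, 4, seed=1)
        with pytest.raises(DimensionError):
            embed(net, np.zeros((2, 13)))


class TestSampleNPairBatch:
    def _ds(self, type_sizes):
        labels = [t for t, n in type_sizes.items() for _ in range(n)]
        rng = np.random.default_rng(0)
        return make_dataset(rng.integers(0, 5, size=(len(labels), 4)), labels=labels)

    def test_one_pair_per_type(self):
        ds = self._ds({"A": 4, "B": 3, "C": 5})
        batch = sample_npair_batch(ds, np.random.default_rng(1))
        assert batch.n_classes == 3
        assert sorted(batch.labels) == ["A", "B", "C"]
        # anchor and positive of each type are distinct cells
        stacked = np.vstack([batch.anchors, batch.positives])
        assert stacked.shape == (6, 4)

    def test_anchor_positive_distinct_cells(self):
        # two cells per type with distinguishable rows
        ds = make_dataset(np.arange(8).reshape(4, 2), labels=["A", "A", "B", "B"])
        batch = sample_npair_batch(ds, np.random.default_rng(0))
        for i in range(2):
            assert not np.array_equal(batch.anchors[i], batch.positives[i])

    def test_single_type_errors(self):
        ds = self._ds({"A": 5})
        with pytest.raises(BatchConstructionError):
            sample_npair_batch(ds, np.random.default_rng(0))

    def test_type_with_one_cell_errors(self):
        ds = self._ds({"A": 4, "B": 1})
        with pytest.raises(BatchConstructionError, match="'B'"):
            sample_npair_batch(ds, np.random.default_rng(0))

    def test_seed_determinism(self):
        ds = self._ds({"A": 6, "B": 6})
        b1 = sample_npair_batch(ds, np.random.default_rng(9))
        b2 = sample_npair_batch(ds, np.random.default_rng(9))
        np.testing.assert_array_equal(b1.anchors, b2.anchors)
        np.testing.assert_array_equal(b1.positives, b2.positives)


class TestNPairLoss:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_identical_embeddings_give_log_n(self, n):
        net = passthrough_net(3)
        F = np.tile([1.0, 2.0, 0.5], (n, 1))
        loss = npair_loss(net, embedding_batch(F, F))
        assert loss == pytest.approx(math.log(n), rel=1e-12)

    def test_orthogonal_pairs_hand_value(self):
        # f1 = f1+ = (1,0), f2 = f2+ = (0,1) -> loss = ln(1 + e^-1)
        net = passthrough_net(2)
        F = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = npair_loss(net, embedding_batch(F, F))
        assert loss == pytest.approx(math.log(1 + math.exp(-1)), rel=1e-12)

    def test_loss_vanishes_as_positives_dominate(self):
        net = passthrough_net(4)
        losses = []
        for t in (1.0, 3.0, 10.0):
            F = t * np.eye(4)
            losses.append(npair_loss(net, embedding_batch(F, F)))
        assert losses == sorted(losses, reverse=True)
        assert losses[-1] < 1e-40
        assert all(v >= 0 for v in losses)

    def test_numerically_stable_for_huge_inner_products(self):
        net = passthrough_net(2)
        F = np.array([[1e4, 0.0], [0.0, 1e4]])
        Fp = np.array([[0.0, 1e4], [1e4, 0.0]])  # negatives dominate
        loss = npair_loss(net, embedding_batch(F, Fp))
        assert np.isfinite(loss) and loss == pytest.approx(1e8, rel=1e-6)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            d = int(rng.integers(2, 21))
            net = init_network(d, 8, d, seed=int(rng.integers(1000)))
            batch = NPairBatch(
                anchors=rng.normal(size=(n, d)),
                positives=rng.normal(size=(n, d)),
                labels=[f"t{i}" for i in range(n)],
            )
            assert npair_loss(net, batch) == pytest.approx(
                brute_force_npair_loss(net, batch), abs=1e-9
            )

    def test_invariant_under_pair_permutation(self):
        rng = np.random.default_rng(5)
        F, Fp = rng.normal(size=(2, 4, 6))
        net = init_network(6, 8, 5, seed=1)
        batch = NPairBatch(anchors=F, positives=Fp,
                           labels=["a", "b", "c", "d"])
        base = npair_loss(net, batch)
        for _ in range(5):
            perm = rng.permutation(4)
            shuffled = NPairBatch(anchors=F[perm], positives=Fp[perm],
                                  labels=[batch.labels[i] for i in perm])
            assert npair_loss(net, shuffled) == pytest.approx(base, rel=1e-12)

    def test_monotone_in_positive_similarity(self):
        # raising f_i . f_i+ with everything else fixed lowers the loss
        net = passthrough_net(2)
        Fp = np.array([[1.0, 0.0], [0.0, 1.0]])
        prev = np.inf
        for scale in (0.5, 1.0, 2.0, 4.0):
            F = scale * Fp
            loss = npair_loss(net, embedding_batch(F, Fp))
            assert loss < prev
            prev = loss


class TestGradients:
    def test_summed_gradient_is_sum_of_task_gradients(self):
        rng = np.random.default_rng(2)
        net = init_network(5, 4, 3, seed=2)
        batches = [
            NPairBatch(anchors=rng.normal(size=(n, 5)),
                       positives=rng.normal(size=(n, 5)),
                       labels=[f"t{i}" for i in range(n)])
            for n in (2, 3)
        ]
        loss, grads = multitask_loss_and_grad(net, batches)
        parts = [npair_loss_and_grad(net, b) for b in batches]
        assert loss == pytest.approx(sum(p[0] for p in parts), rel=1e-12)
        for k in grads:
            np.testing.assert_allclose(
                grads[k], parts[0][1][k] + parts[1][1][k], atol=1e-12
            )

    def test_gradient_descends(self):
        rng = np.random.default_rng(4)
        net = init_network(6, 5, 3, seed=4)
        batch = NPairBatch(anchors=rng.normal(size=(3, 6)),
                           positives=rng.normal(size=(3, 6)),
                           labels=["a", "b", "c"])
        loss, grads = npair_loss_and_grad(net, batch)
        for k, p in net.parameters().items():
            p -= 1e-3 * grads[k]
        assert npair_loss(net, batch) < loss
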