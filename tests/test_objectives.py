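"""The losses: MSE, OGT-anchored dual loss, and Rank-N-Contrast."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tmelt
from tmelt.model import DualPrediction
from tmelt.objectives import (
    ContrastiveBatch,
    SpeciesAnchor,
    dual_loss,
    gaussian_augment,
    mse_loss,
    rank_set,
    rnc_loss,
    rnc_loss_and_grad,
    train_rnc_representation,
)


def test_mse_loss(rng):
    assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mse_loss([58.0], [60.0]) == 4.0
    a, b = rng.standard_normal(10), rng.standard_normal(10)
    assert mse_loss(a, b) == pytest.approx(sum((x - y) ** 2 for x, y in zip(a, b)) / 10, abs=1e-12)
    with pytest.raises(ValueError):
        mse_loss([], [])


class TestDualLoss:
    anchor = SpeciesAnchor({"ecoli": 54.0})

    def test_exact_fit_is_zero(self):
        preds = [DualPrediction(54.0, 6.0)]
        assert dual_loss(preds, [60.0], ["ecoli"], self.anchor) == 0.0

    def test_hand_computed_decomposition(self):
        # y_ogt=55, y_bias=3 -> phi=58; y=60, mu=54: (58-60)^2 + (55-54)^2 = 5
        preds = [DualPrediction(55.0, 3.0)]
        assert dual_loss(preds, [60.0], ["ecoli"], self.anchor) == pytest.approx(5.0)

    def test_bias_error_only_enters_prediction_term(self):
        base = dual_loss([DualPrediction(54.0, 4.0)], [60.0], ["ecoli"], self.anchor)
        worse = dual_loss([DualPrediction(54.0, 2.0)], [60.0], ["ecoli"], self.anchor)
        # the species term stays 0, only MSE(phi, y) grows: 4 -> 16
        assert base == pytest.approx(4.0) and worse == pytest.approx(16.0)

    def test_decomposes_into_two_mses(self, rng):
        preds = [DualPrediction(*p) for p in rng.standard_normal((6, 2)) * 5 + 50]
        y = rng.normal(55, 5, 6)
        loss = dual_loss(preds, y, ["ecoli"] * 6, self.anchor)
        phi = np.array([p.phi_tm for p in preds])
        ogt = np.array([p.y_ogt for p in preds])
        assert loss == pytest.approx(mse_loss(phi, y) + mse_loss(ogt, [54.0] * 6), abs=1e-12)

    def test_missing_anchor_names_species(self):
        with pytest.raises(KeyError, match="yeast"):
            dual_loss([DualPrediction(50.0, 0.0)], [50.0], ["yeast"], self.anchor)


def test_gaussian_augmentation(rng):
    x = rng.standard_normal((5, 4))
    np.testing.assert_array_equal(gaussian_augment(x, 0.0, np.random.default_rng(0)), x)
    a = gaussian_augment(x, 0.5, np.random.default_rng(7))
    b = gaussian_augment(x, 0.5, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)
    big = rng.standard_normal((500, 200))
    noise = gaussian_augment(big, 0.3, np.random.default_rng(1)) - big
    assert abs(noise.std() - 0.3) < 0.02 * 0.3


class TestRankSet:
    def test_worked_example(self):
        # labels (10, 12, 15, 30), anchor 0, candidate 1 (distance 2):
        # distances (-, 2, 5, 20) -> everything at least as far as 2
        assert list(rank_set(0, 1, [10.0, 12.0, 15.0, 30.0])) == [1, 2, 3]

    def test_farthest_candidate_leaves_singleton(self):
        labels = [10.0, 12.0, 15.0, 30.0]
        assert list(rank_set(0, 3, labels)) == [3]

    def test_anchor_equals_candidate_rejected(self):
        with pytest.raises(ValueError):
            rank_set(2, 2, [1.0, 2.0, 3.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12), st.data())
    def test_matches_brute_force(self, labels, data):
        i = data.draw(st.integers(0, len(labels) - 1))
        j = data.draw(st.integers(0, len(labels) - 1).filter(lambda x: x != i))
        got = set(rank_set(i, j, labels))
        expected = {
            k
            for k in range(len(labels))
            if k != i and abs(labels[i] - labels[k]) >= abs(labels[i] - labels[j])
        }
        assert got == expected and j in got

    def test_monotonicity_in_candidate_rank(self, rng):
        labels = rng.normal(50, 10, 10)
        i = 0
        order = sorted(range(1, 10), key=lambda k: abs(labels[i] - labels[k]))
        sizes = [len(rank_set(i, j, labels)) for j in order]
        assert sizes == sorted(sizes, reverse=True)


def _brute_force_rnc(reps, labels, tau):
    m = len(labels)
    total = 0.0
    for i in range(m):
        li = 0.0
        for j in range(m):
            if j == i:
                continue
            s_ij = -np.linalg.norm(reps[i] - reps[j])
            den = 0.0
            for k in range(m):
                if k != i and abs(labels[i] - labels[k]) >= abs(labels[i] - labels[j]):
                    den += math.exp(-np.linalg.norm(reps[i] - reps[k]) / tau)
            li += -math.log(math.exp(s_ij / tau) / den)
        total += li / (m - 1)
    return total / m


class TestRncLoss:
    def test_single_pair_is_zero(self, rng):
        batch = ContrastiveBatch(rng.standard_normal((2, 3)), np.array([5.0, 5.0]), tau=2.0)
        assert rnc_loss(batch) == pytest.approx(0.0, abs=1e-12)

    def test_loss_is_nonnegative(self, rng):
        for _ in range(10):
            reps = rng.standard_normal((6, 4))
            labels = np.tile(rng.normal(50, 10, 3), 2)
            assert rnc_loss(ContrastiveBatch(reps, labels)) >= 0.0

    def test_matches_brute_force_triple_loop(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 5))
            reps = rng.standard_normal((2 * n, 3))
            labels = np.tile(rng.normal(50, 10, n), 2)
            batch = ContrastiveBatch(reps, labels, tau=2.0)
            assert rnc_loss(batch) == pytest.approx(_brute_force_rnc(reps, labels, 2.0), abs=1e-10)

    def test_invariant_under_rotation(self, rng):
        reps = rng.standard_normal((8, 4))
        labels = np.tile(rng.normal(50, 10, 4), 2)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        l1 = rnc_loss(ContrastiveBatch(reps, labels))
        l2 = rnc_loss(ContrastiveBatch(reps @ q, labels))
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_custom_similarity_matches_default(self, rng):
        reps = rng.standard_normal((6, 3))
        labels = np.tile(rng.normal(50, 10, 3), 2)
        batch = ContrastiveBatch(reps, labels)
        l_custom = rnc_loss(batch, sim=lambda a, b: -float(np.linalg.norm(a - b)))
        assert rnc_loss(batch) == pytest.approx(l_custom, abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        reps = rng.standard_normal((6, 3))
        labels = np.tile(rng.normal(50, 10, 3), 2)
        _, dv = rnc_loss_and_grad(reps, labels, tau=2.0)
        eps = 1e-6
        for a in range(6):
            for b in range(3):
                reps[a, b] += eps
                lp, _ = rnc_loss_and_grad(reps, labels, 2.0)
                reps[a, b] -= 2 * eps
                lm, _ = rnc_loss_and_grad(reps, labels, 2.0)
                reps[a, b] += eps
                assert (lp - lm) / (2 * eps) == pytest.approx(dv[a, b], abs=1e-6)

    def test_label_ordered_representations_score_lower(self, rng):
        """Representations whose distances mirror |dTm| beat a random
        permutation of the same vectors on the same labels."""
        labels = np.tile(np.sort(rng.normal(50, 10, 8)), 2)
        reps = labels[:, None] * np.eye(3)[0]  # distance proportional to |dTm|
        ordered = rnc_loss(ContrastiveBatch(reps, labels))
        perm = rng.permutation(16)
        shuffled = rnc_loss(ContrastiveBatch(reps[perm], labels))
        assert ordered < shuffled

    def test_rejects_malformed_batches(self, rng):
        with pytest.raises(ValueError, match="label"):
            ContrastiveBatch(rng.standard_normal((4, 2)), np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="tau"):
            ContrastiveBatch(rng.standard_normal((2, 2)), np.array([1.0, 1.0]), tau=0.0)
        with pytest.raises(ValueError, match="finite"):
            rnc_loss(ContrastiveBatch(np.full((2, 2), np.nan), np.array([1.0, 1.0])))


class TestRncTraining:
    def test_reproducible_given_seed(self, tiny_dataset):
        _, p1, h1 = train_rnc_representation(tiny_dataset, max_epochs=3, patience=3, seed=5)
        _, p2, h2 = train_rnc_representation(tiny_dataset, max_epochs=3, patience=3, seed=5)
        assert h1 == h2
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])

    def test_encoder_orders_distances_by_label_gap(self):
        """After contrastive training on strong within-species signal, encoder
        distances on held-out proteins correlate with |dTm|."""
        from scipy.stats import spearmanr

        cfg = tmelt.SyntheticConfig(
            n_species=5, proteins_per_species=60, embedding_dim=8,
            length_range=(10, 20), kappa=1.0, seed=9,
        )
        ds = tmelt.generate_dataset(cfg)
        enc, params, _ = train_rnc_representation(ds, lr=1e-3, max_epochs=60, patience=10, seed=3)
        test = ds.split_proteins("test")
        reps = np.array(
            [
                enc.mean_representation(
                    params, p.embedding[None].astype(float), np.ones((1, p.length), bool)
                )[0][0]
                for p in test
            ]
        )
        tms = np.array([p.tm for p in test])
        iu, ju = np.triu_indices(len(test), k=1)
        dists = np.linalg.norm(reps[iu] - reps[ju], axis=1)
        rho, _ = spearmanr(dists, np.abs(tms[iu] - tms[ju]))
        assert rho > 0.5
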