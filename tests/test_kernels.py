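"""Kernel forward passes, the clamped-BCE objective and the training loop."""

import numpy as np
import pytest

from circrbp import kernels as K
from circrbp import synthetic
from circrbp.kernels import PairScores, TrainConfig

from util import fd_gradients, relative_grad_error


class TestInit:
    def test_tower_shapes_at_study_scale(self):
        m = K.init_model("mfnn", N_r=673, N_c=94, layer_sizes=(64,), seed=7)
        assert m.params["Wr0"].shape == (94, 64)
        assert m.params["Wc0"].shape == (673, 64)
        assert m.latent_dim == 64

    def test_seed_determinism(self):
        a = K.init_model("gmf", 10, 8, (16,), seed=7)
        b = K.init_model("gmf", 10, 8, (16,), seed=7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_init_std_degenerate_cosine_guarded(self):
        m = K.init_model("mfnn", 6, 5, (4,), seed=0, init_std=0.0)
        Y = np.ones((6, 5))
        s = K.score_pair(m, 0, 0, Y)
        # zero latent vectors: epsilon-guarded cosine is 0, clamped up to eps
        assert s == pytest.approx(m.clamp_eps)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            K.init_model("svd", 5, 5, (4,))


class TestLatentTowers:
    def test_one_layer_matches_hand_matrix_product(self):
        m = K.init_model("mfnn", N_r=2, N_c=3, layer_sizes=(2,), seed=5)
        x = np.array([1.0, 0.0, 1.0])
        expected = np.maximum(x @ m.params["Wr0"] + m.params["br0"], 0.0)
        np.testing.assert_allclose(K.latent_rbp(m, x), expected)
        xc = np.array([1.0, 1.0])
        expected_c = np.maximum(xc @ m.params["Wc0"] + m.params["bc0"], 0.0)
        np.testing.assert_allclose(K.latent_circ(m, xc), expected_c)

    def test_zero_profile_zero_bias_gives_zero_latent(self):
        m = K.init_model("mfnn", 4, 6, (3,), seed=1)
        m.params["br0"][:] = 0.0
        np.testing.assert_array_equal(K.latent_rbp(m, np.zeros(6)), np.zeros(3))

    def test_single_layer_preactivation_linearity(self):
        m = K.init_model("mfnn", 4, 6, (3,), seed=2)
        m.params["br0"][:] = 0.0
        x = np.abs(np.random.default_rng(0).normal(size=6))
        np.testing.assert_allclose(K.latent_rbp(m, 2 * x), 2 * K.latent_rbp(m, x))

    def test_profile_length_mismatch_fatal(self):
        m = K.init_model("mfnn", 4, 6, (3,), seed=2)
        with pytest.raises(ValueError):
            K.latent_rbp(m, np.zeros(5))


class TestCosineScore:
    def test_identical_vectors_clamp_to_upper(self):
        p = np.array([[1.0, 2.0, 3.0]])
        cos, _ = K._cosine_rows(p, p)
        assert cos[0] == pytest.approx(1.0, abs=1e-9)
        assert K._clamp(cos, 1e-6)[0] == 1.0 - 1e-6

    def test_opposite_vectors_clamp_to_eps(self):
        p = np.array([[1.0, -2.0, 0.5]])
        cos, _ = K._cosine_rows(p, -p)
        assert cos[0] == pytest.approx(-1.0, abs=1e-9)
        assert K._clamp(cos, 1e-6)[0] == 1e-6

    def test_matches_brute_force_cosine(self, rng):
        p = rng.normal(size=(20, 5))
        q = rng.normal(size=(20, 5))
        cos, _ = K._cosine_rows(p, q)
        for r in range(20):
            expected = p[r] @ q[r] / (np.linalg.norm(p[r]) * np.linalg.norm(q[r]))
            assert cos[r] == pytest.approx(expected, rel=1e-9)

    def test_scale_invariance(self, rng):
        p = rng.normal(size=(10, 4))
        q = rng.normal(size=(10, 4))
        cos1, _ = K._cosine_rows(p, q)
        cos2, _ = K._cosine_rows(3.7 * p, 3.7 * q)
        np.testing.assert_allclose(cos1, cos2, rtol=1e-9)


class TestBCELoss:
    def test_near_perfect_positive(self):
        s = PairScores(pairs=[(0, 0)], scores=[1 - 1e-6], labels=[1.0])
        assert K.bce_loss(s) == pytest.approx(1e-6, rel=1e-3)

    def test_closed_form_two_pairs(self):
        s = PairScores(pairs=[(0, 0), (0, 1)], scores=[0.5, 0.5], labels=[0.0, 1.0])
        assert K.bce_loss(s) == pytest.approx(2 * np.log(2))

    def test_matches_term_by_term_summation(self, rng):
        f = rng.uniform(1e-6, 1 - 1e-6, size=20)
        y = (rng.random(20) < 0.5).astype(float)
        s = PairScores(pairs=[(0, i) for i in range(20)], scores=f, labels=y)
        expected = -sum(
            yi * np.log(fi) + (1 - yi) * np.log(1 - fi) for yi, fi in zip(y, f)
        )
        assert K.bce_loss(s) == pytest.approx(expected, rel=1e-12)

    def test_unclamped_score_is_contract_violation(self):
        s = PairScores(pairs=[(0, 0)], scores=[1.0], labels=[1.0])
        with pytest.raises(ValueError):
            K.bce_loss(s)


class TestScorePairs:
    def test_empty(self):
        m = K.init_model("gmf", 5, 5, (4,), seed=0)
        assert len(K.score_pairs(m, [], None)) == 0

    @pytest.mark.parametrize("kind,Yneeded", [
        ("mfnn", True), ("gmf", False), ("mlp", False), ("neumf", False),
    ])
    def test_matches_per_pair_loop(self, kind, Yneeded, rng):
        Y = (rng.random((7, 6)) < 0.4).astype(float)
        sizes = (4,) if kind in ("mfnn", "gmf") else (4, 5)
        m = K.init_model(kind, 7, 6, sizes, seed=3, init_std=0.3)
        pairs = [(int(i), int(j)) for i in range(7) for j in range(6)]
        pairs = [pairs[k] for k in rng.choice(len(pairs), 25, replace=False)]
        vec = K.score_pairs(m, pairs, Y)
        for idx, (i, j) in enumerate(pairs):
            assert vec.scores[idx] == pytest.approx(K.score_pair(m, i, j, Y), rel=1e-12)

    def test_scores_respect_clamp_range(self, rng):
        Y = (rng.random((9, 8)) < 0.4).astype(float)
        m = K.init_model("mfnn", 9, 8, (5,), seed=1)
        sc = K.score_pairs(m, [(i, j) for i in range(9) for j in range(8)], Y)
        assert np.all(sc.scores >= m.clamp_eps)
        assert np.all(sc.scores <= 1 - m.clamp_eps)
        assert np.all(sc.raw >= -1 - 1e-12) and np.all(sc.raw <= 1 + 1e-12)


@pytest.mark.parametrize("kind,sizes", [
    ("mfnn", (3,)),
    ("mfnn", (5, 3)),
    ("gmf", (4,)),
    ("mlp", (4, 6)),
    ("neumf", (4, 6)),
])
def test_analytic_gradients_match_finite_differences(kind, sizes):
    """Backprop agrees with central finite differences to 1e-4 relative."""
    rng = np.random.default_rng(42)
    N_r, N_c, B = 6, 5, 8
    Y = (rng.random((N_r, N_c)) < 0.5).astype(float)
    m = K.init_model(kind, N_r, N_c, sizes, seed=11, init_std=0.3)
    bi = rng.integers(0, N_r, size=B)
    bj = rng.integers(0, N_c, size=B)
    y = (rng.random(B) < 0.5).astype(float)
    _, analytic = K.loss_and_grads(m, bi, bj, y, Y)
    numeric = fd_gradients(m, bi, bj, y, Y)
    assert relative_grad_error(analytic, numeric) < 1e-4


class TestTrain:
    def _labeled(self, Y, rng, n_neg=None):
        pos = np.argwhere(Y == 1.0)
        neg = np.argwhere(Y == 0.0)
        neg = neg[rng.choice(len(neg), size=n_neg or len(pos), replace=False)]
        pairs = np.vstack([pos, neg])
        labels = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        return PairScores(
            pairs=[tuple(ij) for ij in pairs], scores=np.zeros(len(pairs)), labels=labels
        )

    def test_loss_decreases_on_separable_matrix(self, rng):
        Y = np.zeros((10, 8))
        Y[:5, :4] = 1.0  # block-structured, trivially separable
        sample = self._labeled(Y, rng)
        m = K.init_model("mfnn", 10, 8, (4,), seed=0)
        cfg = TrainConfig(epochs=200, batch_size=16, learning_rate=1e-3,
                          patience=200, seed=0, val_fraction=0.0)
        m, trace = K.train(m, sample, Y, cfg)
        assert trace[-1][1] < trace[0][1]

    def test_training_is_bit_reproducible(self, rng):
        Y = (rng.random((12, 9)) < 0.3).astype(float)
        sample = self._labeled(Y, np.random.default_rng(5))
        runs = []
        for _ in range(2):
            m = K.init_model("gmf", 12, 9, (4,), seed=3)
            m, trace = K.train(m, sample, Y, TrainConfig(epochs=10, batch_size=8, seed=3))
            runs.append(({k: v.copy() for k, v in m.params.items()}, trace))
        assert runs[0][1] == runs[1][1]
        for k in runs[0][0]:
            np.testing.assert_array_equal(runs[0][0][k], runs[1][0][k])

    def test_early_stopping_respects_patience(self, rng):
        Y = (rng.random((12, 9)) < 0.3).astype(float)
        sample = self._labeled(Y, np.random.default_rng(5))
        m = K.init_model("mlp", 12, 9, (4, 4), seed=3)
        cfg = TrainConfig(epochs=500, batch_size=16, patience=3, seed=3)
        m, trace = K.train(m, sample, Y, cfg)
        assert len(trace) < 500

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = K.init_model("neumf", 6, 5, (4, 6), seed=9)
        K.save_checkpoint(m, tmp_path / "ckpt", TrainConfig())
        back = K.load_checkpoint(tmp_path / "ckpt")
        assert back.kind == "neumf" and back.layer_sizes == (4, 6)
        for k in m.params:
            np.testing.assert_array_equal(m.params[k], back.params[k])


def test_trained_mfnn_recovers_hidden_positives(separable_world):
    """A 1-layer profile-tower kernel ranks hidden positives above true
    negatives on the strongly separable planted world (AUC >= 0.85)."""
    from circrbp.evaluation import auc
    from circrbp.model import InteractionModel

    w = separable_world
    model = InteractionModel(w.Y_observed, kernel="mfnn", layer_sizes=(64,))
    res = model.fit(TrainConfig(epochs=200, batch_size=64, learning_rate=1e-3,
                                patience=30, seed=100))
    hidden = sorted(w.hidden_positives)
    negs = w.true_negatives()
    scores = np.r_[res.predict(hidden), res.predict(negs)]
    labels = np.r_[np.ones(len(hidden)), np.zeros(len(negs))]
    assert auc(scores, labels) >= 0.85
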