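"""GloVe objective, gradients, training and similarity."""

import numpy as np
import pytest
import scipy.sparse as sp

from pixseq.glove import (EmbeddingTable, GloveConfig, glove_grads, glove_loss,
                          load_embedding, save_embedding, similarity,
                          train_glove, weight_fn)
from pixseq.vocab import CooccurrenceMatrix, build_cooccurrence


def matrix_from_dense(X):
    X = np.asarray(X, dtype=float)
    return CooccurrenceMatrix(counts=sp.csr_matrix(X), context_window=1,
                              m=X.shape[0])


def random_table(m, dim, seed=0, scale=0.3):
    rng = np.random.default_rng(seed)
    return EmbeddingTable(w=rng.normal(0, scale, (m, dim)),
                          w_ctx=rng.normal(0, scale, (m, dim)),
                          b=rng.normal(0, scale, m),
                          b_ctx=rng.normal(0, scale, m))


class TestWeightFn:
    def test_saturation_and_zero(self):
        assert weight_fn(100.0) == 1.0
        assert weight_fn(250.0) == 1.0
        assert weight_fn(0.0) == 0.0

    def test_halfway_closed_form(self):
        assert weight_fn(50.0, x_max=100, alpha=0.75) == pytest.approx(0.5 ** 0.75)
        assert 0.5 ** 0.75 == pytest.approx(0.59460, abs=1e-5)

    def test_nondecreasing(self):
        xs = np.linspace(0, 200, 400)
        fx = weight_fn(xs)
        assert (np.diff(fx) >= -1e-15).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weight_fn(-1.0)


class TestGloveLoss:
    def test_exact_fit_is_zero(self):
        X = np.full((3, 3), np.e)
        emb = EmbeddingTable(w=np.zeros((3, 2)), w_ctx=np.zeros((3, 2)),
                             b=np.full(3, 0.5), b_ctx=np.full(3, 0.5))
        assert glove_loss(emb, matrix_from_dense(X), GloveConfig(dim=2)) == pytest.approx(0.0)

    def test_single_pair_hand_value(self):
        delta = 0.3
        X = np.array([[np.e]])
        emb = EmbeddingTable(w=np.zeros((1, 1)), w_ctx=np.zeros((1, 1)),
                             b=np.array([1.0 + delta]), b_ctx=np.zeros(1))
        cfg = GloveConfig(dim=1)
        expected = weight_fn(np.e, cfg.x_max, cfg.alpha) * delta ** 2
        assert glove_loss(emb, matrix_from_dense(X), cfg) == pytest.approx(float(expected))

    def test_nonnegative_and_zero_pairs_skipped(self):
        X = np.array([[0.0, 4.0], [2.0, 0.0]])
        emb = random_table(2, 3, seed=1)
        cfg = GloveConfig(dim=3)
        J = glove_loss(emb, matrix_from_dense(X), cfg)
        assert J >= 0
        # naive reference skipping zero counts
        ref = 0.0
        for i in range(2):
            for j in range(2):
                if X[i, j] > 0:
                    fit = emb.w[i] @ emb.w_ctx[j] + emb.b[i] + emb.b_ctx[j]
                    ref += float(weight_fn(X[i, j], cfg.x_max, cfg.alpha)) * (fit - np.log(X[i, j])) ** 2
        assert J == pytest.approx(ref, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        m = 9
        X = np.round(rng.uniform(0, 30, (m, m)))
        emb = random_table(m, 4, seed=2)
        cfg = GloveConfig(dim=4)
        ref = 0.0
        for i in range(m):
            for j in range(m):
                if X[i, j] > 0:
                    fit = emb.w[i] @ emb.w_ctx[j] + emb.b[i] + emb.b_ctx[j]
                    ref += float(weight_fn(X[i, j], cfg.x_max, cfg.alpha)) * (fit - np.log(X[i, j])) ** 2
        assert glove_loss(emb, matrix_from_dense(X), cfg) == pytest.approx(ref, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            glove_loss(random_table(3, 2), matrix_from_dense(np.ones((4, 4))),
                       GloveConfig(dim=2))


def test_gradients_match_finite_differences():
    """Analytic gradient of the objective vs central differences, 4 tokens."""
    rng = np.random.default_rng(11)
    X = np.round(rng.uniform(0, 20, (4, 4)))
    C = matrix_from_dense(X)
    cfg = GloveConfig(dim=3)
    emb = random_table(4, 3, seed=3)
    grads = glove_grads(emb, C, cfg)
    eps = 1e-6
    for arr, g in zip((emb.w, emb.w_ctx, emb.b, emb.b_ctx), grads):
        flat, gflat = arr.ravel(), g.ravel()
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            jp = glove_loss(emb, C, cfg)
            flat[k] = orig - eps
            jm = glove_loss(emb, C, cfg)
            flat[k] = orig
            fd = (jp - jm) / (2 * eps)
            assert gflat[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestTraining:
    def test_deterministic_under_seed(self):
        C = build_cooccurrence([np.array([0, 1, 2, 0, 1, 2, 1, 0])], context_window=3)
        cfg = GloveConfig(dim=4, epochs=10, seed=5)
        a, b = train_glove(C, cfg), train_glove(C, cfg)
        np.testing.assert_array_equal(a.w, b.w)
        assert a.loss_trace == b.loss_trace

    def test_loss_decreases_median_over_seeds(self):
        rng = np.random.default_rng(0)
        X = np.round(rng.uniform(1, 40, (8, 8)))
        C = matrix_from_dense(X)
        drops = []
        for seed in range(5):
            emb = train_glove(C, GloveConfig(dim=4, epochs=30, seed=seed))
            t = np.array(emb.loss_trace)
            drops.append(float(np.median(np.diff(t))))
        assert np.median(drops) <= 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            train_glove(matrix_from_dense(np.zeros((3, 3))), GloveConfig(dim=2))

    def test_planted_model_recovered(self):
        rng = np.random.default_rng(0)
        m, d = 20, 5
        W, Wc = rng.normal(0, 0.7, (m, d)), rng.normal(0, 0.7, (m, d))
        b, bc = rng.normal(1.5, 0.3, m), rng.normal(1.5, 0.3, m)
        logx = W @ Wc.T + b[:, None] + bc[None, :]
        C = matrix_from_dense(np.exp(logx))
        # noiseless instance: train to convergence, expect near-exact recovery
        cfg = GloveConfig(dim=d, epochs=20000, seed=1, learning_rate=0.1,
                          batch_size=512)
        emb = train_glove(C, cfg)
        assert glove_loss(emb, C, cfg) <= 1e-2 * emb.loss_trace[0]
        fit = emb.w @ emb.w_ctx.T + emb.b[:, None] + emb.b_ctx[None, :]
        assert np.corrcoef(fit.ravel(), logx.ravel())[0, 1] >= 0.99


class TestSimilarity:
    def test_self_orthogonal_and_hand_value(self):
        emb = EmbeddingTable(w=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
                             w_ctx=np.zeros((3, 2)), b=np.zeros(3), b_ctx=np.zeros(3))
        assert similarity(emb, 0, 0) == pytest.approx(1.0)
        assert similarity(emb, 0, 1) == pytest.approx(0.0)
        assert similarity(emb, 0, 2) == pytest.approx(1 / np.sqrt(2))
        assert 1 / np.sqrt(2) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_vector_rejected(self):
        emb = EmbeddingTable(w=np.zeros((2, 2)), w_ctx=np.zeros((2, 2)),
                             b=np.zeros(2), b_ctx=np.zeros(2))
        with pytest.raises(ValueError):
            similarity(emb, 0, 1)


def test_word2vec_text_roundtrip(tmp_path):
    emb = random_table(5, 3, seed=4)
    path = tmp_path / "vectors.txt"
    save_embedding(path, emb)
    assert path.read_text().splitlines()[0] == "5 3"
    back = load_embedding(path)
    np.testing.assert_allclose(back, emb.vectors("sum"), rtol=1e-6)
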