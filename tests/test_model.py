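"""Encoder/decoder composition, training loop and raster prediction."""

import numpy as np
import pytest

from pixseq.labels import LabeledSequence, MASKED
from pixseq.model import (ModelConfig, SeqTaggerModel, load_model,
                          predict_labels, save_model, split_dataset,
                          train_model)
from pixseq.vocab import tokenize


def embed_inputs(model, tokens):
    return model._embed_tokens(np.asarray(tokens))


class TestEncoder:
    def test_empty_sequence_rejected(self, toy_model):
        with pytest.raises(ValueError):
            toy_model.encode([])

    def test_length_one_sequence(self, toy_model):
        out = toy_model.encode(embed_inputs(toy_model, [[3]]))
        assert len(out) == 1
        assert out[0].shape == (1, 2 * toy_model.config.encoder_units)

    def test_zero_parameters_zero_states(self, toy_dictionary, toy_config):
        rng = np.random.default_rng(0)
        model = SeqTaggerModel(toy_config, toy_dictionary,
                               rng.normal(size=(toy_dictionary.m, 8)))
        for fwd, bwd in model.encoder:
            for p in fwd.params() + bwd.params():
                p.data[:] = 0
        out = model.encode(embed_inputs(model, [[1, 2, 3]]))
        for h in out:
            np.testing.assert_allclose(h.data, 0.0)

    def test_reversal_swaps_directions(self, toy_dictionary):
        # with tied forward/backward parameters, reversing the input sequence
        # exchanges the forward and backward hidden trajectories
        cfg = ModelConfig(encoder_units=6, n_encoder_layers=1, dtype="float64",
                          seed=1)
        rng = np.random.default_rng(0)
        model = SeqTaggerModel(cfg, toy_dictionary,
                               rng.normal(size=(toy_dictionary.m, 8)))
        fwd, bwd = model.encoder[0]
        for pf, pb in zip(fwd.params(), bwd.params()):
            pb.data = pf.data.copy()
        toks = [[1, 5, 9]]
        out = model.encode(embed_inputs(model, toks))
        out_rev = model.encode(embed_inputs(model, [toks[0][::-1]]))
        U = cfg.encoder_units
        for t in range(3):
            np.testing.assert_allclose(out[t].data[:, :U],
                                       out_rev[2 - t].data[:, U:], atol=1e-12)


class TestDecoder:
    def test_sos_embedding_changes_first_prediction(self, toy_model):
        toks = np.array([[1, 2, 3]])
        gold = np.array([[0, 1, 2]])
        base = toy_model.forward_teacher(toks, gold).data.copy()
        toy_model.label_embeddings.data[3] += 1.0  # SOS row
        bumped = toy_model.forward_teacher(toks, gold).data
        assert not np.allclose(base[:, 0], bumped[:, 0])

    def test_zeroed_stack_gives_zero_scores(self, toy_dictionary, toy_config):
        rng = np.random.default_rng(0)
        model = SeqTaggerModel(toy_config, toy_dictionary,
                               rng.normal(size=(toy_dictionary.m, 8)))
        for p in model.params():
            p.data[:] = 0
        logits = model.forward_teacher(np.array([[1, 2]]), np.array([[0, 1]]))
        np.testing.assert_allclose(logits.data, 0.0)

    def test_teacher_forcing_matches_inference_when_predictions_equal_gold(self, toy_model):
        toks = np.array([[1, 2, 3, 4]])
        pred, _ = toy_model.forward_greedy(toks)
        logits_tf = toy_model.forward_teacher(toks, pred)
        import pixseq.autodiff as ad
        probs_tf = ad.softmax(logits_tf.data)
        assert (np.argmax(probs_tf, axis=-1) == pred).all()


class TestTraining:
    def test_chance_level_initial_loss(self, toy_model, toy_dataset):
        toks = np.stack([s.tokens for s in toy_dataset])
        labs = np.stack([s.labels for s in toy_dataset])
        assert toy_model.loss_on(toks, labs) == pytest.approx(np.log(3), abs=0.1)

    def test_masking_leaves_loss_unchanged(self, toy_model, toy_dataset):
        toks = np.stack([s.tokens for s in toy_dataset])
        labs = np.stack([s.labels for s in toy_dataset])
        base = toy_model.loss_on(toks, labs)
        pad = toy_model.dictionary.pad_id
        toks2 = np.vstack([toks, np.full((2, 10), pad)])
        labs2 = np.vstack([labs, np.full((2, 10), MASKED)])
        assert abs(toy_model.loss_on(toks2, labs2) - base) < 1e-10

    def test_deterministic_final_loss(self, toy_dictionary, toy_config, toy_dataset):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(toy_dictionary.m, 8))
        a = train_model(toy_dataset, toy_config, toy_dictionary, emb)
        b = train_model(toy_dataset, toy_config, toy_dictionary, emb)
        assert a.loss_trace == b.loss_trace

    def test_learns_separable_token_rule(self, toy_dictionary, toy_config):
        # token t < 4 -> h, 4 <= t < 8 -> c, else o: linearly separable
        rng = np.random.default_rng(9)
        emb = np.eye(12, 8) + 0.01 * rng.normal(size=(12, 8))
        seqs = []
        for i in range(32):
            toks = rng.integers(0, 12, 10)
            labs = np.digitize(toks, [4, 8])
            seqs.append(LabeledSequence(tokens=toks, labels=labs, row=i, col=0, axis="row"))
        import dataclasses
        cfg = dataclasses.replace(toy_config, epochs=60, dtype="float32",
                                  learning_rate=0.003, encoder_dropout=0.0,
                                  decoder_lstm_dropout=0.0, indrnn_dropout=0.0)
        model = train_model(seqs, cfg, toy_dictionary, emb)
        assert model.loss_trace[-1] < 0.5 * np.log(3)

    def test_no_labels_rejected(self, toy_dictionary, toy_config):
        seqs = [LabeledSequence(tokens=np.zeros(10, dtype=int),
                                labels=np.full(10, MASKED), row=0, col=0, axis="row")]
        with pytest.raises(ValueError):
            train_model(seqs, toy_config, toy_dictionary, np.ones((12, 8)))


class TestVariantMatrix:
    @pytest.mark.parametrize("fwd,bwd", [("IndRNN", "IndRNN"), ("IndRNN", "LSTM"),
                                         ("RNN", "RNN"), ("RNN", "LSTM"),
                                         ("IndRNN", "RNN")])
    def test_encoder_cells_from_config_only(self, toy_dictionary, fwd, bwd):
        cfg = ModelConfig(encoder_units=6, decoder_lstm_units=6, indrnn_units=4,
                          label_embedding_dim=4, encoder_cell_forward=fwd,
                          encoder_cell_backward=bwd, dtype="float64", seed=0)
        rng = np.random.default_rng(0)
        model = SeqTaggerModel(cfg, toy_dictionary, rng.normal(size=(12, 8)))
        pred, probs = model.forward_greedy(np.array([[0, 1, 2]]))
        assert pred.shape == (1, 3)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_double_width_decoder_variant(self, toy_dictionary):
        cfg = ModelConfig(encoder_units=6, decoder_units_double_encoder=True,
                          indrnn_units=4, label_embedding_dim=4, dtype="float64")
        model = SeqTaggerModel(cfg, toy_dictionary,
                               np.random.default_rng(0).normal(size=(12, 8)))
        assert model.decoder_lstm[0].n_hidden == 12


class TestPrediction:
    def test_raster_shape_and_probabilities(self, toy_model):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (6, 14))
        grid = tokenize(img, toy_model.dictionary)
        pred, prob = predict_labels(toy_model, grid)
        assert pred.shape == (6, 14)
        assert prob.shape == (6, 14, 3)
        np.testing.assert_allclose(prob.sum(axis=-1), 1.0, atol=1e-6)
        assert np.isin(pred, (0, 1, 2)).all()

    def test_unseen_tokens_map_to_unk(self, toy_model):
        img = np.linspace(5.0, 9.0, 12).reshape(3, 4)  # outside [0, 1] fit range
        pred, prob = toy_model.predict_image(img)
        assert pred.shape == (3, 4)
        np.testing.assert_allclose(prob.sum(axis=-1), 1.0, atol=1e-6)


def test_split_dataset_seeded(toy_dataset):
    tr1, te1 = split_dataset(toy_dataset, 0.75, seed=4)
    tr2, te2 = split_dataset(toy_dataset, 0.75, seed=4)
    assert len(tr1) == 12 and len(te1) == 4
    assert [id(s) for s in tr1] == [id(s) for s in tr2]


def test_checkpoint_roundtrip(tmp_path, toy_dictionary, toy_config, toy_dataset):
    rng = np.random.default_rng(3)
    emb = rng.normal(size=(toy_dictionary.m, 8))
    model = train_model(toy_dataset, toy_config, toy_dictionary, emb)
    toks = np.stack([s.tokens for s in toy_dataset])
    pred, prob = model.forward_greedy(toks)
    path = tmp_path / "model.npz"
    save_model(path, model)
    back = load_model(path)
    pred2, prob2 = back.forward_greedy(toks)
    np.testing.assert_array_equal(pred, pred2)
    np.testing.assert_allclose(prob, prob2, atol=1e-7)
    assert back.dictionary.token_of == toy_dictionary.token_of
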