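"""End-to-end pixel-sequence tagger: Bi-LSTM encoder, LSTM + IndRNN decoder.

Architecture (per input window of 10 pixel tokens):

* an embedding layer maps each pixel token to its pretrained GloVe vector
  (frozen) and each label to a small learned embedding;
* a stacked bidirectional encoder — forward and backward recurrent passes
  concatenated per position; the per-direction cell is configurable (LSTM,
  IndRNN or plain RNN) so encoder-substitution experiments are pure
  configuration;
* a decoder that, at each position ``t``, consumes the encoder state ``h_t``
  concatenated with the embedding of the previous label ``T_{t-1}`` (gold
  label under teacher forcing at train time, the model's own argmax at
  inference; a learned start-of-sequence embedding at ``t = 0``), runs it
  through stacked LSTM layers and then stacked IndRNN layers — both
  recurrent over the sequence;
* a softmax classifier over the three classes.

Training minimizes the masked negative log-likelihood with RMSprop
(learning rate 0.001 by default); PAD and nodata positions never contribute
to the loss.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, dropout_mask, embedding_lookup, softmax
from .cells import IndRnnParams, LstmParams, cell_step, make_cell
from .labels import LabeledSequence, MASKED, reassemble_labels
from .vocab import PixelDictionary, TokenGrid, extract_sequences, tokenize

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "SeqTaggerModel", "train_model", "predict_labels",
           "split_dataset", "save_model", "load_model"]

N_CLASSES = 3
SOS = 3      # start-of-sequence row in the label embedding
PREV_PAD = 4  # previous-label row used at masked positions


@dataclass
class ModelConfig:
    """Hyperparameters of the tagger (defaults = best published setting)."""

    encoder_units: int = 150
    encoder_dropout: float = 0.5
    decoder_lstm_units: int = 200
    decoder_lstm_dropout: float = 0.25
    indrnn_units: int = 32
    indrnn_dropout: float = 0.25
    indrnn_recurrent_dropout: float = 0.0
    n_encoder_layers: int = 2
    n_decoder_lstm_layers: int = 2
    n_indrnn_layers: int = 2
    encoder_cell_forward: str = "LSTM"
    encoder_cell_backward: str = "LSTM"
    learning_rate: float = 0.001
    optimizer: str = "rmsprop"
    label_embedding_dim: int = 32
    batch_size: int = 64
    epochs: int = 30
    peephole_output_current: bool = False
    # prose variant: first decoder LSTM width = 2 x encoder units instead of 200
    decoder_units_double_encoder: bool = False
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        for name in ("encoder_units", "decoder_lstm_units", "indrnn_units",
                     "n_encoder_layers", "n_decoder_lstm_layers", "n_indrnn_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("encoder_dropout", "decoder_lstm_dropout", "indrnn_dropout",
                     "indrnn_recurrent_dropout"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in [0, 1)")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class SeqTaggerModel:
    """Parameter bundle + forward passes.  Build via :func:`train_model` or
    construct untrained with :meth:`initialize`."""

    schema_version = 1

    def __init__(self, config: ModelConfig, dictionary: PixelDictionary,
                 pixel_embeddings: np.ndarray):
        self.config = config
        self.dictionary = dictionary
        dt = config.np_dtype
        m, dim = pixel_embeddings.shape
        if m != dictionary.m:
            raise ValueError("pixel embedding rows must equal dictionary size m")
        # frozen pixel features; PAD row = 0, UNK row = vocabulary mean
        table = np.zeros((m + 2, dim), dtype=dt)
        table[:m] = pixel_embeddings
        table[dictionary.unk_id] = pixel_embeddings.mean(axis=0)
        self.pixel_embeddings = table
        self.embedding_dim = dim
        self.loss_trace: list[float] = []
        self._build(np.random.default_rng(config.seed))

    # -- construction ---------------------------------------------------------
    def _build(self, rng):
        cfg = self.config
        dt = cfg.np_dtype
        self.label_embeddings = ad.parameter(
            rng.uniform(-0.1, 0.1, size=(N_CLASSES + 2, cfg.label_embedding_dim)), dt)

        self.encoder = []
        n_in = self.embedding_dim
        for _ in range(cfg.n_encoder_layers):
            fwd = make_cell(cfg.encoder_cell_forward, n_in, cfg.encoder_units, rng,
                            dtype=dt, **({"peephole_output_current": cfg.peephole_output_current}
                                         if cfg.encoder_cell_forward == "LSTM" else {}))
            bwd = make_cell(cfg.encoder_cell_backward, n_in, cfg.encoder_units, rng,
                            dtype=dt, **({"peephole_output_current": cfg.peephole_output_current}
                                         if cfg.encoder_cell_backward == "LSTM" else {}))
            self.encoder.append((fwd, bwd))
            n_in = 2 * cfg.encoder_units

        first_units = (2 * cfg.encoder_units if cfg.decoder_units_double_encoder
                       else cfg.decoder_lstm_units)
        self.decoder_lstm = []
        dec_in = 2 * cfg.encoder_units + cfg.label_embedding_dim
        units = first_units
        for _ in range(cfg.n_decoder_lstm_layers):
            self.decoder_lstm.append(
                LstmParams(dec_in, units, rng, dtype=dt,
                           peephole_output_current=cfg.peephole_output_current))
            dec_in = units
            units = cfg.decoder_lstm_units
        self.decoder_indrnn = []
        for _ in range(cfg.n_indrnn_layers):
            self.decoder_indrnn.append(IndRnnParams(dec_in, cfg.indrnn_units, rng, dtype=dt))
            dec_in = cfg.indrnn_units
        lim = np.sqrt(6.0 / (dec_in + N_CLASSES))
        self.clf_W = ad.parameter(rng.uniform(-lim, lim, size=(dec_in, N_CLASSES)), dt)
        self.clf_b = ad.parameter(np.zeros(N_CLASSES), dt)

    def params(self) -> list[Tensor]:
        out = [self.label_embeddings]
        for fwd, bwd in self.encoder:
            out += fwd.params() + bwd.params()
        for cell in self.decoder_lstm + self.decoder_indrnn:
            out += cell.params()
        out += [self.clf_W, self.clf_b]
        return out

    # -- forward passes -------------------------------------------------------
    def _embed_tokens(self, tokens: np.ndarray) -> list[Tensor]:
        """Frozen pixel features per position: list over t of (B, dim)."""
        feats = self.pixel_embeddings[tokens]  # (B, T, dim)
        return [Tensor(feats[:, t]) for t in range(tokens.shape[1])]

    def encode(self, inputs: list[Tensor], drop_rng=None) -> list[Tensor]:
        """Stacked bidirectional pass; returns per-position (B, 2*units)."""
        if not inputs:
            raise ValueError("cannot encode an empty sequence")
        cfg = self.config
        batch = inputs[0].shape[0]
        seq = inputs
        for li, (fwd, bwd) in enumerate(self.encoder):
            state = fwd.zero_state(batch)
            hs_f = []
            for x in seq:
                h, state = cell_step(fwd, x, *state)
                hs_f.append(h)
            state = bwd.zero_state(batch)
            hs_b = []
            for x in reversed(seq):
                h, state = cell_step(bwd, x, *state)
                hs_b.append(h)
            hs_b.reverse()
            seq = [concat([hf, hb], axis=-1) for hf, hb in zip(hs_f, hs_b)]
            if drop_rng is not None and cfg.encoder_dropout > 0:
                seq = [h * dropout_mask(h.shape, cfg.encoder_dropout, drop_rng,
                                        dtype=h.data.dtype) for h in seq]
        return seq

    def decode_step(self, h_enc: Tensor, prev_emb: Tensor, states: list,
                    drop_rng=None):
        """One decoder position; mutates ``states`` in place, returns logits."""
        cfg = self.config
        x = concat([h_enc, prev_emb], axis=-1)
        for i, cell in enumerate(self.decoder_lstm):
            x, states[i] = cell_step(cell, x, *states[i])
            if drop_rng is not None and cfg.decoder_lstm_dropout > 0:
                x = x * dropout_mask(x.shape, cfg.decoder_lstm_dropout, drop_rng,
                                     dtype=x.data.dtype)
        off = len(self.decoder_lstm)
        for i, cell in enumerate(self.decoder_indrnn):
            x, states[off + i] = cell_step(cell, x, *states[off + i])
            if drop_rng is not None and cfg.indrnn_dropout > 0:
                x = x * dropout_mask(x.shape, cfg.indrnn_dropout, drop_rng,
                                     dtype=x.data.dtype)
        return x @ self.clf_W + self.clf_b

    def _init_decoder_states(self, batch: int) -> list:
        return [cell.zero_state(batch) for cell in self.decoder_lstm + self.decoder_indrnn]

    def forward_teacher(self, tokens: np.ndarray, gold: np.ndarray,
                        drop_rng=None) -> Tensor:
        """Teacher-forced logits (B, T, 3); gold previous labels shifted right."""
        batch, T = tokens.shape
        enc = self.encode(self._embed_tokens(tokens), drop_rng)
        prev = np.full((batch,), SOS, dtype=np.int64)
        states = self._init_decoder_states(batch)
        logit_list = []
        for t in range(T):
            prev_emb = embedding_lookup(self.label_embeddings, prev)
            logit_list.append(self.decode_step(enc[t], prev_emb, states, drop_rng))
            prev = np.where(gold[:, t] == MASKED, PREV_PAD, gold[:, t]).astype(np.int64)
        return ad.stack(logit_list, axis=1)

    def forward_greedy(self, tokens: np.ndarray):
        """Inference: greedy argmax feedback.  Returns (labels, probs)."""
        batch, T = tokens.shape
        with ad.no_grad():
            enc = self.encode(self._embed_tokens(tokens))
            prev = np.full((batch,), SOS, dtype=np.int64)
            states = self._init_decoder_states(batch)
            labels = np.zeros((batch, T), dtype=np.int64)
            probs = np.zeros((batch, T, N_CLASSES))
            for t in range(T):
                prev_emb = embedding_lookup(self.label_embeddings, prev)
                logits = self.decode_step(enc[t], prev_emb, states)
                p = softmax(logits.data)
                probs[:, t] = p
                labels[:, t] = np.argmax(p, axis=-1)  # ties -> lowest index
                prev = labels[:, t]
        return labels, probs

    def loss_on(self, tokens: np.ndarray, gold: np.ndarray) -> float:
        """Masked NLL without dropout (deterministic evaluation loss)."""
        mask = (gold != MASKED).astype(self.config.np_dtype)
        tgt = np.where(gold == MASKED, 0, gold)
        with ad.no_grad():
            logits = self.forward_teacher(tokens, gold)
            return float(ad.softmax_cross_entropy(Tensor(logits.data), tgt, mask).data)

    # -- raster-level prediction ---------------------------------------------
    def predict_image(self, image: np.ndarray, axis: str = "row",
                      valid: np.ndarray | None = None):
        """Tokenize with the training dictionary (unseen -> UNK) and predict."""
        grid = tokenize(image, self.dictionary, valid=valid)
        return predict_labels(self, grid, axis=axis)


def _as_batches(dataset: list[LabeledSequence]):
    tokens = np.stack([s.tokens for s in dataset]).astype(np.int64)
    gold = np.stack([s.labels for s in dataset]).astype(np.int64)
    return tokens, gold


def split_dataset(dataset: list[LabeledSequence], train_frac: float = 0.8,
                  seed: int = 0):
    """Seeded train/test split over sequences (80/20 by default)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(train_frac * len(dataset)))
    return ([dataset[i] for i in order[:n_train]],
            [dataset[i] for i in order[n_train:]])


class _RmsProp:
    def __init__(self, params, lr, rho=0.9, eps=1e-8):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.s = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, s in zip(self.params, self.s):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1.0 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)
            p.grad = None


def train_model(dataset: list[LabeledSequence], config: ModelConfig,
                dictionary: PixelDictionary, pixel_embeddings: np.ndarray,
                ) -> SeqTaggerModel:
    """Fit the tagger by teacher-forced RMSprop; returns model with loss trace."""
    tokens, gold = _as_batches(dataset)
    if not (gold != MASKED).any():
        raise ValueError("dataset has no unmasked labeled positions")
    if config.optimizer.lower() != "rmsprop":
        raise ValueError("only the RMSprop optimizer is implemented")
    model = SeqTaggerModel(config, dictionary,
                           np.asarray(pixel_embeddings, dtype=config.np_dtype))
    opt = _RmsProp(model.params(), config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    n = tokens.shape[0]
    dt = config.np_dtype
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, weight = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            tb, gb = tokens[sel], gold[sel]
            mask = (gb != MASKED).astype(dt)
            if mask.sum() == 0:
                continue
            tgt = np.where(gb == MASKED, 0, gb)
            logits = model.forward_teacher(tb, gb, drop_rng)
            loss = ad.softmax_cross_entropy(logits, tgt, mask)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total += float(loss.data) * float(mask.sum())
            weight += float(mask.sum())
        model.loss_trace.append(total / weight)
        logger.info("epoch %d/%d: train loss %.6f", epoch + 1, config.epochs,
                    model.loss_trace[-1])
    return model


def predict_labels(model: SeqTaggerModel, grid: TokenGrid, axis: str = "row",
                   window_len: int = 10, batch_size: int = 256):
    """Greedy per-position tagging of a raster.

    Returns ``(label_raster, prob_raster)``: (H, W) int labels (MASKED at
    nodata) and (H, W, 3) class probabilities.  PAD positions are dropped on
    reassembly via sequence provenance.
    """
    seqs = extract_sequences(grid, axis=axis, window_len=window_len)
    pad = grid.dictionary.pad_id
    tokens = np.stack([s.tokens for s in seqs]).astype(np.int64)
    T = tokens.shape[1]
    labels = np.zeros_like(tokens)
    probs = np.zeros((tokens.shape[0], T, N_CLASSES))
    for start in range(0, tokens.shape[0], batch_size):
        lb, pb = model.forward_greedy(tokens[start:start + batch_size])
        labels[start:start + batch_size] = lb
        probs[start:start + batch_size] = pb
    h, w = grid.tokens.shape
    labelled = []
    prob_raster = np.zeros((h, w, N_CLASSES))
    for i, s in enumerate(seqs):
        lab = np.where(s.tokens == pad, MASKED, labels[i])
        labelled.append(LabeledSequence(tokens=s.tokens, labels=lab,
                                        row=s.row, col=s.col, axis=s.axis))
        for t in range(T):
            if s.tokens[t] == pad:
                continue
            r, c = (s.row, s.col + t) if s.axis == "row" else (s.row + t, s.col)
            prob_raster[r, c] = probs[i, t]
    raster = reassemble_labels(labelled, h, w)
    return raster, prob_raster


# -- checkpointing -----------------------------------------------------------

def save_model(path, model: SeqTaggerModel) -> None:
    """Single-archive checkpoint: config JSON + parameter arrays (npz)."""
    d = model.dictionary
    keys = np.array(sorted(d.token_of, key=d.token_of.get), dtype=np.int64)
    meta = {
        "schema_version": model.schema_version,
        "config": asdict(model.config),
        "dictionary": {"levels_per_band": d.levels_per_band,
                       "band_count": d.band_count},
        "loss_trace": model.loss_trace,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             dict_keys=keys, band_min=d.band_min, band_max=d.band_max,
             pixel_embeddings=model.pixel_embeddings, **arrays)


def load_model(path) -> SeqTaggerModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["schema_version"] != SeqTaggerModel.schema_version:
            raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
        cfg = ModelConfig(**meta["config"])
        keys = z["dict_keys"]
        d = PixelDictionary(
            levels_per_band=meta["dictionary"]["levels_per_band"],
            band_count=meta["dictionary"]["band_count"],
            band_min=z["band_min"], band_max=z["band_max"],
            token_of={tuple(int(v) for v in k): i for i, k in enumerate(keys)},
        )
        table = z["pixel_embeddings"]
        model = SeqTaggerModel(cfg, d, table[: d.m])
        model.pixel_embeddings = table
        model.loss_trace = list(meta["loss_trace"])
        for i, p in enumerate(model.params()):
            p.data = z[f"param_{i}"]
    return model
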