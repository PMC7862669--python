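"""GloVe-style pixel word vectors fit to log co-occurrence counts.

The embedding solves the weighted least-squares problem

    J = sum_{i,j: x_ij > 0} f(x_ij) (w_i . w~_j + b_i + b~_j - log x_ij)^2

where ``x_ij`` are neighbourhood co-occurrence counts, ``w`` / ``w~`` are the
word and context vectors with their biases, and ``f`` is the standard
saturating weight ``(x / x_max)^alpha`` capped at 1 — rare, unreliable pairs
get small weight, frequent pairs saturate.  Optimization is AdaGrad over
shuffled mini-batches of nonzero pairs, fully seeded.  The downstream pixel
feature is ``w + w~`` (the sum makes the symmetric factorization
identifiable); plain ``w`` is available via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vocab import CooccurrenceMatrix

__all__ = ["GloveConfig", "EmbeddingTable", "weight_fn", "glove_loss",
           "glove_grads", "train_glove", "similarity", "save_embedding",
           "load_embedding"]

#: embedding dimensions exposed as presets
DIM_PRESETS = (100, 150, 200)


@dataclass
class GloveConfig:
    dim: int = 150
    x_max: float = 100.0
    alpha: float = 0.75
    learning_rate: float = 0.05
    epochs: int = 50
    batch_size: int = 1024
    seed: int = 0
    combine: str = "sum"  # "sum" -> w + w~, "word" -> w only

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.x_max <= 0:
            raise ValueError("x_max must be positive")
        if self.combine not in ("sum", "word"):
            raise ValueError("combine must be 'sum' or 'word'")


@dataclass
class EmbeddingTable:
    """Word/context vectors and biases of the factorization."""

    w: np.ndarray       # (m, dim) word vectors
    w_ctx: np.ndarray   # (m, dim) context vectors
    b: np.ndarray       # (m,) word biases
    b_ctx: np.ndarray   # (m,) context biases
    loss_trace: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.w.shape[0]

    @property
    def dim(self) -> int:
        return self.w.shape[1]

    def vectors(self, combine: str = "sum") -> np.ndarray:
        """Final per-token feature vectors."""
        return self.w + self.w_ctx if combine == "sum" else self.w.copy()


def weight_fn(x, x_max: float = 100.0, alpha: float = 0.75):
    """Saturating co-occurrence weight: ``(x/x_max)^alpha`` for x < x_max, else 1."""
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("co-occurrence counts must be nonnegative")
    return np.where(x < x_max, (x / x_max) ** alpha, 1.0)


def _nonzero(C: CooccurrenceMatrix):
    coo = C.counts.tocoo()
    keep = coo.data > 0
    return coo.row[keep], coo.col[keep], coo.data[keep]


def glove_loss(emb: EmbeddingTable, C: CooccurrenceMatrix, cfg: GloveConfig) -> float:
    """Objective J over all nonzero count pairs (zero counts are skipped)."""
    if emb.m != C.m:
        raise ValueError(f"embedding has m={emb.m}, matrix has m={C.m}")
    i, j, x = _nonzero(C)
    if i.size == 0:
        return 0.0
    fit = np.einsum("nd,nd->n", emb.w[i], emb.w_ctx[j]) + emb.b[i] + emb.b_ctx[j]
    resid = fit - np.log(x)
    return float(np.sum(weight_fn(x, cfg.x_max, cfg.alpha) * resid ** 2))


def glove_grads(emb: EmbeddingTable, C: CooccurrenceMatrix, cfg: GloveConfig):
    """Full-batch analytic gradients of :func:`glove_loss`.

    Returns ``(dw, dw_ctx, db, db_ctx)`` with the shapes of the table fields.
    """
    i, j, x = _nonzero(C)
    f = weight_fn(x, cfg.x_max, cfg.alpha)
    resid = (np.einsum("nd,nd->n", emb.w[i], emb.w_ctx[j])
             + emb.b[i] + emb.b_ctx[j] - np.log(x))
    g = 2.0 * f * resid
    dw = np.zeros_like(emb.w); np.add.at(dw, i, g[:, None] * emb.w_ctx[j])
    dwc = np.zeros_like(emb.w_ctx); np.add.at(dwc, j, g[:, None] * emb.w[i])
    db = np.zeros_like(emb.b); np.add.at(db, i, g)
    dbc = np.zeros_like(emb.b_ctx); np.add.at(dbc, j, g)
    return dw, dwc, db, dbc


def _init_table(m: int, cfg: GloveConfig, rng: np.random.Generator) -> EmbeddingTable:
    lim = 0.5 / cfg.dim
    return EmbeddingTable(
        w=rng.uniform(-lim, lim, size=(m, cfg.dim)),
        w_ctx=rng.uniform(-lim, lim, size=(m, cfg.dim)),
        b=rng.uniform(-lim, lim, size=m),
        b_ctx=rng.uniform(-lim, lim, size=m),
    )


def train_glove(C: CooccurrenceMatrix, cfg: GloveConfig | None = None) -> EmbeddingTable:
    """Fit the embedding by mini-batch AdaGrad on the nonzero pairs.

    Deterministic for a fixed seed.  Raises if the objective goes non-finite
    (learning rate too high for the count scale).
    """
    cfg = cfg or GloveConfig()
    i_all, j_all, x_all = _nonzero(C)
    if i_all.size == 0:
        raise ValueError("co-occurrence matrix has no positive counts")
    rng = np.random.default_rng(cfg.seed)
    emb = _init_table(C.m, cfg, rng)
    fx = weight_fn(x_all, cfg.x_max, cfg.alpha)
    logx = np.log(x_all)

    # AdaGrad accumulators
    gw = np.full_like(emb.w, 1e-8)
    gwc = np.full_like(emb.w_ctx, 1e-8)
    gb = np.full_like(emb.b, 1e-8)
    gbc = np.full_like(emb.b_ctx, 1e-8)
    lr = cfg.learning_rate

    n = i_all.size
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            i, j, f, lx = i_all[sel], j_all[sel], fx[sel], logx[sel]
            wi, wj = emb.w[i], emb.w_ctx[j]
            resid = np.einsum("nd,nd->n", wi, wj) + emb.b[i] + emb.b_ctx[j] - lx
            epoch_loss += float(np.sum(f * resid ** 2))
            g = 2.0 * f * resid  # dJ/dfit per pair
            grad_wi = g[:, None] * wj
            grad_wj = g[:, None] * wi
            # scatter-accumulate (pairs in a batch may share tokens)
            dw = np.zeros_like(emb.w); np.add.at(dw, i, grad_wi)
            dwc = np.zeros_like(emb.w_ctx); np.add.at(dwc, j, grad_wj)
            db = np.zeros_like(emb.b); np.add.at(db, i, g)
            dbc = np.zeros_like(emb.b_ctx); np.add.at(dbc, j, g)
            gw += dw ** 2; gwc += dwc ** 2; gb += db ** 2; gbc += dbc ** 2
            emb.w -= lr * dw / np.sqrt(gw)
            emb.w_ctx -= lr * dwc / np.sqrt(gwc)
            emb.b -= lr * db / np.sqrt(gb)
            emb.b_ctx -= lr * dbc / np.sqrt(gbc)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"GloVe objective diverged at epoch {epoch}; lower the learning rate"
            )
        emb.loss_trace.append(epoch_loss)
    return emb


def similarity(emb: EmbeddingTable, i: int, j: int, combine: str = "sum") -> float:
    """Cosine similarity between the final vectors of tokens ``i`` and ``j``."""
    v = emb.vectors(combine)
    a, b = v[i], v[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def save_embedding(path, emb: EmbeddingTable, combine: str = "sum") -> None:
    """word2vec text format: header ``m dim``, then ``token v1 ... vdim``."""
    v = emb.vectors(combine)
    with open(path, "w") as fh:
        fh.write(f"{emb.m} {emb.dim}\n")
        for t in range(emb.m):
            fh.write(str(t) + " " + " ".join(f"{x:.8g}" for x in v[t]) + "\n")


def load_embedding(path) -> np.ndarray:
    """Read word2vec text format back into an (m, dim) array (token order)."""
    with open(path) as fh:
        m, dim = (int(x) for x in fh.readline().split())
        out = np.zeros((m, dim))
        for line in fh:
            parts = line.split()
            out[int(parts[0])] = [float(x) for x in parts[1:]]
    return out
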