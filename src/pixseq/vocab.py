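"""Pixel dictionary, sequence extraction and neighbourhood co-occurrence.

Multiband pixels become "words": each band is linearly binned into
``levels_per_band`` equal-width bins over its observed range, and every
distinct tuple of bin indices gets a dense integer token.  Token sequences
are cut from the raster along rows or columns in fixed, non-overlapping
windows, and co-occurrence counts ``x[i, k]`` — how often token ``k`` falls
within a fixed 1-D context window of token ``i`` along those sequences —
feed the GloVe embedding fit.

Coordinates are 0-based, row-major ``(row, col)`` throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PixelDictionary",
    "TokenGrid",
    "Sequence",
    "CooccurrenceMatrix",
    "quantize",
    "tokenize",
    "extract_sequences",
    "build_cooccurrence",
    "marginal_count",
    "cooccur_prob",
    "prob_ratio",
    "save_cooccurrence",
    "load_cooccurrence",
]


@dataclass
class PixelDictionary:
    """Vocabulary of quantized multiband pixel values.

    ``token_of`` maps a tuple of per-band bin indices to a dense token id in
    ``[0, m)``.  ``m`` is the number of distinct tuples observed when the
    dictionary was built.  Two reserved ids live just past the vocabulary:
    ``pad_id = m`` (sequence padding) and ``unk_id = m + 1`` (tuples unseen
    at fit time).
    """

    levels_per_band: int
    band_count: int
    band_min: np.ndarray  # (bands,) observed minima
    band_max: np.ndarray  # (bands,) observed maxima
    token_of: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.token_of)

    @property
    def pad_id(self) -> int:
        return self.m

    @property
    def unk_id(self) -> int:
        return self.m + 1

    def bin_image(self, image: np.ndarray) -> np.ndarray:
        """Per-band equal-width binning; returns (H, W, bands) int bin indices."""
        image = _as_hwb(image)
        if image.shape[2] != self.band_count:
            raise ValueError(
                f"image has {image.shape[2]} bands, dictionary expects {self.band_count}"
            )
        width = (self.band_max - self.band_min) / self.levels_per_band
        bins = np.zeros(image.shape, dtype=np.int32)
        for b in range(self.band_count):
            if width[b] <= 0:  # constant band: one shared bin
                logger.info("band %d is constant-valued; all pixels share bin 0", b)
                continue
            idx = np.floor((image[:, :, b] - self.band_min[b]) / width[b]).astype(np.int32)
            bins[:, :, b] = np.clip(idx, 0, self.levels_per_band - 1)
        return bins

    def bin_centers(self, bins: np.ndarray) -> np.ndarray:
        """Map bin indices back to bin-centre band values (quantization inverse)."""
        width = (self.band_max - self.band_min) / self.levels_per_band
        return self.band_min + (bins + 0.5) * np.where(width > 0, width, 0.0)


@dataclass
class TokenGrid:
    """Raster of token ids sharing shape with its source image."""

    tokens: np.ndarray  # (H, W) int32
    dictionary: PixelDictionary
    valid: np.ndarray | None = None  # (H, W) bool; False = nodata

    @property
    def height(self) -> int:
        return self.tokens.shape[0]

    @property
    def width(self) -> int:
        return self.tokens.shape[1]


@dataclass
class Sequence:
    """A fixed-length token run with raster provenance."""

    tokens: np.ndarray  # (window_len,) includes PAD at the tail when short
    row: int
    col: int
    axis: str  # "row" or "column"
    n_valid: int  # positions before padding
    dictionary: PixelDictionary | None = None


@dataclass
class CooccurrenceMatrix:
    """Sparse token-pair counts over a fixed 1-D context window."""

    counts: sp.csr_matrix  # (m, m)
    context_window: int
    m: int

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()


def _as_hwb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError("image must be (H, W) or (H, W, bands)")
    return image


def _check_finite(image: np.ndarray) -> None:
    bad = ~np.isfinite(image)
    if bad.any():
        r, c, b = np.argwhere(bad)[0]
        raise ValueError(f"non-finite value at (row={r}, col={c}, band={b})")


def quantize(image: np.ndarray, levels_per_band: int | None = None,
             valid: np.ndarray | None = None) -> tuple[PixelDictionary, TokenGrid]:
    """Fit a pixel dictionary on ``image`` and tokenize it.

    Each band is binned into ``levels_per_band`` equal-width bins over its
    observed min-max (nodata excluded); the tuple of bin indices is interned
    into the dictionary in row-major scan order, so token ids are dense and
    deterministic.  The default is 32 levels for single-band imagery and 8
    for multiband, which keeps the vocabulary bound ``levels^bands`` sane.
    """
    image = _as_hwb(image)
    if levels_per_band is None:
        levels_per_band = 32 if image.shape[2] == 1 else 8
    if levels_per_band < 2:
        raise ValueError("levels_per_band must be >= 2")
    _check_finite(image)
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        obs = image[valid]
    else:
        obs = image.reshape(-1, image.shape[2])
    if obs.size == 0:
        raise ValueError("image has no valid pixels")
    d = PixelDictionary(
        levels_per_band=levels_per_band,
        band_count=image.shape[2],
        band_min=obs.min(axis=0),
        band_max=obs.max(axis=0),
    )
    bins = d.bin_image(image)
    h, w, _ = bins.shape
    tokens = np.zeros((h, w), dtype=np.int32)
    token_of = d.token_of
    for r in range(h):
        for c in range(w):
            if valid is not None and not valid[r, c]:
                tokens[r, c] = -1
                continue
            key = tuple(int(v) for v in bins[r, c])
            t = token_of.get(key)
            if t is None:
                t = len(token_of)
                token_of[key] = t
            tokens[r, c] = t
    return d, TokenGrid(tokens=tokens, dictionary=d, valid=valid)


def tokenize(image: np.ndarray, dictionary: PixelDictionary,
             valid: np.ndarray | None = None) -> TokenGrid:
    """Tokenize with an existing dictionary; unseen tuples map to ``unk_id``."""
    image = _as_hwb(image)
    _check_finite(image)
    bins = dictionary.bin_image(image)
    h, w, _ = bins.shape
    tokens = np.zeros((h, w), dtype=np.int32)
    unk = dictionary.unk_id
    n_unk = 0
    for r in range(h):
        for c in range(w):
            if valid is not None and not valid[r, c]:
                tokens[r, c] = -1
                continue
            t = dictionary.token_of.get(tuple(int(v) for v in bins[r, c]))
            if t is None:
                t = unk
                n_unk += 1
            tokens[r, c] = t
    if n_unk:
        logger.info("tokenize: %d pixels mapped to UNK", n_unk)
    return TokenGrid(tokens=tokens, dictionary=dictionary, valid=valid)


def extract_sequences(grid: TokenGrid, axis: str = "row",
                      window_len: int = 10) -> list[Sequence]:
    """Cut non-overlapping fixed windows along rows (or columns).

    Rows are scanned top-to-bottom (columns left-to-right); a final short run
    is completed with the PAD token.  Nodata cells are emitted as PAD so that
    downstream losses and metrics can mask them.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    toks = grid.tokens
    if axis == "column":
        toks = toks.T
        valid = grid.valid.T if grid.valid is not None else None
    elif axis == "row":
        valid = grid.valid
    else:
        raise ValueError("axis must be 'row' or 'column'")
    n_lines, length = toks.shape
    if length < 1 or n_lines < 1:
        raise ValueError("grid has no pixels along the requested axis")
    pad = grid.dictionary.pad_id
    out: list[Sequence] = []
    for line in range(n_lines):
        for start in range(0, length, window_len):
            run = toks[line, start:start + window_len].astype(np.int32)
            n_valid = run.size
            if valid is not None:
                vmask = valid[line, start:start + window_len]
                run = np.where(vmask, run, pad)
            window = np.full(window_len, pad, dtype=np.int32)
            window[: run.size] = run
            row, col = (line, start) if axis == "row" else (start, line)
            out.append(Sequence(tokens=window, row=row, col=col, axis=axis,
                                n_valid=n_valid, dictionary=grid.dictionary))
    return out


def build_cooccurrence(sequences, context_window: int = 5, m: int | None = None,
                       distance_weighting: bool = False) -> CooccurrenceMatrix:
    """Count token pairs within ``context_window`` positions along each sequence.

    For every position ``p`` and offset ``d`` with ``1 <= |d| <= window`` in
    the same sequence, ``x[token(p), token(p+d)]`` is incremented — by 1, or
    by ``1/|d|`` when ``distance_weighting`` is on.  PAD (and UNK) tokens are
    never counted.  A symmetric window makes the matrix symmetric.

    ``sequences`` may be a list of :class:`Sequence` / 1-D arrays, or a 2-D
    array of equal-length token runs (one run per row).
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 2:
        seq_arrays = [sequences]
    else:
        seq_arrays = [s.tokens if isinstance(s, Sequence) else np.atleast_2d(np.asarray(s))
                      for s in sequences]
        if m is None:
            dicts = [s.dictionary for s in sequences
                     if isinstance(s, Sequence) and s.dictionary is not None]
            if dicts:
                m = int(dicts[0].m)
    # stack equal-length runs so the offset scan is vectorized over sequences
    seq_arrays = [np.atleast_2d(a) for a in seq_arrays]
    by_len: dict[int, list] = {}
    for a in seq_arrays:
        by_len.setdefault(a.shape[1], []).append(a)
    batches = [np.concatenate(group, axis=0) for group in by_len.values()]
    if m is None:
        m = int(max((int(a.max()) for a in batches if a.size), default=-1)) + 1
    if not batches or all(b.size == 0 for b in batches):
        logger.warning("build_cooccurrence: empty sequence list, all-zero matrix")
    # dense accumulation over flat pair index keeps memory flat; the final
    # matrix is sparse anyway for realistic vocabularies
    dense_ok = m * m <= 64_000_000
    acc = np.zeros(m * m) if dense_ok else None
    counts = sp.csr_matrix((m, m))
    for arr in batches:
        ok = arr < m  # PAD/UNK ids sit at >= m
        for d in range(1, context_window + 1):
            if d >= arr.shape[1]:
                break
            keep = ok[:, :-d] & ok[:, d:]
            if not keep.any():
                continue
            w = (1.0 / d) if distance_weighting else 1.0
            ai = arr[:, :-d][keep].astype(np.int64)
            bi = arr[:, d:][keep].astype(np.int64)
            if dense_ok:
                flat = np.bincount(ai * m + bi, minlength=m * m)
                acc += w * flat
                acc += w * flat.reshape(m, m).T.ravel()
            else:
                block = sp.coo_matrix((np.full(ai.size, w), (ai, bi)), shape=(m, m))
                counts = counts + block.tocsr() + block.T.tocsr()
    if dense_ok:
        counts = sp.csr_matrix(acc.reshape(m, m))
    return CooccurrenceMatrix(counts=counts, context_window=context_window, m=m)


def marginal_count(C: CooccurrenceMatrix, i: int) -> float:
    """Row marginal ``x_i = sum_k x[i, k]``."""
    if not 0 <= i < C.m:
        raise IndexError(f"token {i} out of range [0, {C.m})")
    return float(C.counts[i].sum())


def cooccur_prob(C: CooccurrenceMatrix, i: int, k: int) -> float:
    """Conditional ``p_ik = x[i, k] / x_i``; rows sum to 1."""
    xi = marginal_count(C, i)
    if xi <= 0:
        raise ValueError(f"undefined conditional: token {i} has zero marginal")
    if not 0 <= k < C.m:
        raise IndexError(f"token {k} out of range [0, {C.m})")
    return float(C.counts[i, k]) / xi


def prob_ratio(C: CooccurrenceMatrix, i: int, j: int, k: int) -> float:
    """Diagnostic probability ratio ``R = p_ik / p_jk``.

    Values near 1 suggest ``i`` and ``j`` relate to ``k`` similarly; large or
    small values separate the correlated pixel from the uncorrelated one.
    """
    pik = cooccur_prob(C, i, k)
    pjk = cooccur_prob(C, j, k)
    if pjk == 0:
        raise ZeroDivisionError("ratio undefined: p_jk = 0")
    return pik / pjk


def save_cooccurrence(path, C: CooccurrenceMatrix) -> None:
    """Write as text: header ``m=<int> window=<int>`` then ``i k count`` rows."""
    coo = C.counts.tocoo()
    with open(path, "w") as fh:
        fh.write(f"m={C.m} window={C.context_window}\n")
        for i, k, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {k} {v:.10g}\n")


def load_cooccurrence(path) -> CooccurrenceMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        m = int(header[0].split("=")[1])
        window = int(header[1].split("=")[1])
        rows, cols, vals = [], [], []
        for line in fh:
            i, k, v = line.split()
            rows.append(int(i)); cols.append(int(k)); vals.append(float(v))
    counts = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
    return CooccurrenceMatrix(counts=counts, context_window=window, m=m)
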