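"""Label vocabulary, isolated-pixel smoothing and dataset serialization.

Three canonical classes cover the vegetation-mapping task: ``h``
(*Populus euphratica*), ``c`` (*Tamarix*) and ``o`` (other ground cover),
encoded 0/1/2.  Sensor-confused members of h and c may carry raw sub-labels
``h1``/``c1`` (3/4) for simulation provenance; they fold into their parent
class for the 3-class task.

The smoothing rule handles imaging artefacts: a single pixel whose two
flanking neighbours (along the serialization axis) share one class different
from its own is relabelled to that class.  Runs of two or more differing
pixels are kept — only isolated pixels are treated as artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocab import TokenGrid, extract_sequences

__all__ = ["H", "C", "O", "H1", "C1", "LABEL_NAMES", "MASKED",
           "LabelMap", "LabeledSequence",
           "smooth_labels", "map_sublabels", "serialize_dataset",
           "reassemble_labels"]

H, C, O = 0, 1, 2
H1, C1 = 3, 4
LABEL_NAMES = {H: "h", C: "c", O: "o", H1: "h1", C1: "c1"}
CANONICAL = (H, C, O)
#: mask value for padded / nodata positions in a LabeledSequence
MASKED = -1


@dataclass
class LabelMap:
    """Per-pixel class raster aligned with a TokenGrid.

    ``labels`` holds canonical classes {0, 1, 2}; ``raw`` optionally keeps the
    pre-fold sub-labels {0..4} for provenance.
    """

    labels: np.ndarray  # (H, W) int, canonical classes
    raw: np.ndarray | None = None

    def __post_init__(self):
        bad = ~np.isin(self.labels, CANONICAL)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(f"non-canonical label {self.labels[r, c]} at ({r}, {c})")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


@dataclass
class LabeledSequence:
    """Aligned token/label window with raster provenance.

    ``labels`` uses :data:`MASKED` at PAD and nodata positions; masked
    positions are excluded from the loss and from metrics.
    """

    tokens: np.ndarray
    labels: np.ndarray
    row: int
    col: int
    axis: str


def smooth_labels(seq) -> np.ndarray:
    """Single left-to-right smoothing sweep over a 1-D label run.

    A position ``p`` with ``L[p-1] == L[p+1] != L[p]`` is rewritten to the
    flanking class; the updated value is visible to later positions, so a
    strictly alternating run collapses in one pass.  Boundary pixels have no
    two flanking neighbours and are never changed.  Idempotent on its own
    output.
    """
    out = np.array(seq, dtype=np.int64, copy=True)
    for p in range(1, out.size - 1):
        if out[p - 1] == out[p + 1] != out[p]:
            out[p] = out[p - 1]
    return out


def map_sublabels(raw) -> np.ndarray:
    """Fold sensor-confused sub-labels into parents: h1 -> h, c1 -> c."""
    raw = np.asarray(raw)
    known = np.isin(raw, (H, C, O, H1, C1))
    if not known.all():
        bad = np.unique(raw[~known])
        raise ValueError(f"unknown label code(s) {bad.tolist()}")
    out = raw.copy()
    out[raw == H1] = H
    out[raw == C1] = C
    return out


def serialize_dataset(grid: TokenGrid, labels: LabelMap, axis: str = "row",
                      window_len: int = 10, smooth: bool = True) -> list[LabeledSequence]:
    """Pair fixed-window token sequences with aligned (optionally smoothed) labels.

    Smoothing runs along the full serialization axis *before* windowing, so
    the isolated-pixel rule can act across window boundaries.  PAD positions
    and nodata cells get the :data:`MASKED` label.
    """
    if labels.labels.shape != grid.tokens.shape:
        raise ValueError(
            f"label raster {labels.labels.shape} does not match grid {grid.tokens.shape}"
        )
    lab = labels.labels
    if axis == "column":
        lab_lines = lab.T
    elif axis == "row":
        lab_lines = lab
    else:
        raise ValueError("axis must be 'row' or 'column'")
    if smooth:
        lab_lines = np.stack([smooth_labels(line) for line in lab_lines])

    sequences = extract_sequences(grid, axis=axis, window_len=window_len)
    pad = grid.dictionary.pad_id
    out = []
    for s in sequences:
        line = s.row if axis == "row" else s.col
        start = s.col if axis == "row" else s.row
        window = np.full(window_len, MASKED, dtype=np.int64)
        run = lab_lines[line, start:start + window_len]
        window[: run.size] = run
        window[s.tokens == pad] = MASKED  # nodata and tail padding
        out.append(LabeledSequence(tokens=s.tokens, labels=window,
                                   row=s.row, col=s.col, axis=s.axis))
    return out


def reassemble_labels(seqs: list[LabeledSequence], height: int, width: int,
                      fill: int = MASKED) -> np.ndarray:
    """Stitch per-sequence labels back into a raster via provenance."""
    out = np.full((height, width), fill, dtype=np.int64)
    for s in seqs:
        n = s.labels.size
        if s.axis == "row":
            span = min(n, width - s.col)
            seg = s.labels[:span]
            tgt = out[s.row, s.col:s.col + span]
        else:
            span = min(n, height - s.row)
            seg = s.labels[:span]
            tgt = out[s.row:s.row + span, s.col]
        keep = seg != MASKED
        tgt[keep] = seg[keep]
    return out
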