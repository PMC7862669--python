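"""Precision / recall / F-score evaluation for label rasters.

Metrics are one-vs-rest per class: ``P = TP / (TP + FP)``,
``R = TP / (TP + FN)`` and ``F = 2PR / (P + R)``.  Zero denominators yield 0
with a warning (a class absent from both rasters scores 0, not NaN).  The
harness reports per-class values plus the macro average, rounded to 4
decimals in table output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import CANONICAL, LABEL_NAMES, MASKED

__all__ = ["ClassMetrics", "precision_recall", "f_score", "confusion_counts",
           "evaluate_labels", "evaluate_dataset", "macro_f"]


@dataclass
class ClassMetrics:
    P: float
    R: float
    F: float
    support: int


def confusion_counts(pred: np.ndarray, truth: np.ndarray, cls: int,
                     mask: np.ndarray | None = None) -> tuple[int, int, int]:
    """(TP, FP, FN) for one-vs-rest class ``cls``; masked cells excluded."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    keep = (truth != MASKED) & (pred != MASKED)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    p, t = pred[keep] == cls, truth[keep] == cls
    tp = int(np.sum(p & t))
    return tp, int(np.sum(p & ~t)), int(np.sum(~p & t))


def precision_recall(pred, truth, cls: int, mask=None) -> tuple[float, float]:
    tp, fp, fn = confusion_counts(pred, truth, cls, mask)
    if tp + fp == 0:
        warnings.warn(f"class {LABEL_NAMES.get(cls, cls)}: no predicted pixels, P := 0")
        P = 0.0
    else:
        P = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn(f"class {LABEL_NAMES.get(cls, cls)}: no true pixels, R := 0")
        R = 0.0
    else:
        R = tp / (tp + fn)
    return P, R


def f_score(P: float, R: float) -> float:
    """Harmonic mean 2PR/(P+R); defined as 0 when P + R = 0."""
    if P + R == 0:
        return 0.0
    return 2.0 * P * R / (P + R)


def evaluate_labels(pred, truth, mask=None) -> dict[int, ClassMetrics]:
    """Per-class metrics over one raster pair."""
    out = {}
    truth = np.asarray(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls in CANONICAL:
            P, R = precision_recall(pred, truth, cls, mask)
            tp, _, fn = confusion_counts(pred, truth, cls, mask)
            out[cls] = ClassMetrics(P=P, R=R, F=f_score(P, R), support=tp + fn)
    return out


def macro_f(per_class: dict[int, ClassMetrics]) -> float:
    return float(np.mean([m.F for m in per_class.values()]))


def evaluate_dataset(model, scenes, axis: str = "row") -> pd.DataFrame:
    """Predict every scene and tabulate pooled per-class + macro P/R/F.

    ``scenes`` is a list of objects with ``image`` and ``truth`` attributes
    (see :mod:`pixseq.scenes`).  Counts are pooled over scenes before the
    ratios are taken.  Values are rounded to 4 decimals in the table.
    """
    if not scenes:
        raise ValueError("empty scene list")
    totals = {cls: [0, 0, 0] for cls in CANONICAL}
    for scene in scenes:
        pred, _ = model.predict_image(scene.image, axis=axis)
        for cls in CANONICAL:
            tp, fp, fn = confusion_counts(pred, scene.truth, cls)
            totals[cls][0] += tp
            totals[cls][1] += fp
            totals[cls][2] += fn
    rows = []
    for cls in CANONICAL:
        tp, fp, fn = totals[cls]
        P = tp / (tp + fp) if tp + fp else 0.0
        R = tp / (tp + fn) if tp + fn else 0.0
        rows.append({"class": LABEL_NAMES[cls], "P": round(P, 4), "R": round(R, 4),
                     "F": round(f_score(P, R), 4), "support": tp + fn})
    macro = {"class": "macro", "P": round(float(np.mean([r["P"] for r in rows])), 4),
             "R": round(float(np.mean([r["R"] for r in rows])), 4),
             "F": round(float(np.mean([r["F"] for r in rows])), 4),
             "support": int(sum(r["support"] for r in rows))}
    return pd.DataFrame(rows + [macro])


def write_metrics(df: pd.DataFrame, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
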