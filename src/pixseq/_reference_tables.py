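"""Published precision/recall/F-score triples used to audit Eq. arithmetic.

These are transcribed evaluation tables from published vegetation-mapping and
land-use tagging experiments (UAV / QuickBird imagery and the UC Merced
land-use categories).  They serve one purpose here: validating that
:func:`pixseq.metrics.f_score` reproduces each printed F value from its
printed (P, R) pair.

A handful of printed rows are internally inconsistent — their printed F is
not the harmonic mean of their printed P and R (transcription errors in the
source tables).  :func:`audit_triples` flags them; the test suite asserts
4-decimal agreement for every consistent row and pins the recomputed value
for the discrepant ones instead of asserting an impossible equality.
"""

from __future__ import annotations

from .metrics import f_score

__all__ = ["REFERENCE_TRIPLES", "audit_triples"]

# (P, R, printed F) per row, grouped by experiment table.
REFERENCE_TRIPLES: dict[str, list[tuple[float, float, float]]] = {
    # encoder/decoder depth sweep (1/2/3 layers x decoding/LSTM/IndRNN axes)
    "layer_depth": [
        (0.8712, 0.8601, 0.8656), (0.8594, 0.8359, 0.8474), (0.8632, 0.8467, 0.8593),
        (0.9146, 0.8861, 0.9001), (0.9146, 0.8861, 0.9001), (0.9146, 0.8861, 0.9001),
        (0.8934, 0.8749, 0.8840), (0.8837, 0.8519, 0.8675), (0.8903, 0.8739, 0.8820),
    ],
    # encoder/decoder cell substitutions (IndRNN / LSTM / RNN directions)
    "cell_variants": [
        (0.9053, 0.8803, 0.8926), (0.8976, 0.8751, 0.8862), (0.9234, 0.8911, 0.9069),
        (0.8871, 0.8562, 0.8713), (0.8914, 0.8695, 0.8803), (0.8981, 0.8759, 0.8868),
    ],
    # word-vector dimension sweep (UAV then QuickBird; 100/150/200/original)
    "embedding_dim": [
        (0.9119, 0.8823, 0.8969), (0.9234, 0.8911, 0.9069),
        (0.8704, 0.8431, 0.8565), (0.8960, 0.8692, 0.8824),
        (0.8953, 0.8671, 0.8810), (0.9057, 0.8741, 0.8896),
        (0.8623, 0.8385, 0.8502), (0.8839, 0.8527, 0.8680),
    ],
    # labelling-method comparison (spectrum/texture/fusion/word/original)
    "labelling_method": [
        (0.8631, 0.8372, 0.8499), (0.8699, 0.8402, 0.8548), (0.8837, 0.8563, 0.8698),
        (0.9234, 0.8911, 0.9069), (0.8960, 0.8692, 0.8824),
        (0.8743, 0.8411, 0.8574), (0.8755, 0.8436, 0.8593), (0.8905, 0.8654, 0.8778),
        (0.9057, 0.8741, 0.8896), (0.8839, 0.8527, 0.8680),
    ],
    # UC Merced land-use categories
    "landuse_categories": [
        (0.8964, 0.8722, 0.8841), (0.9086, 0.8731, 0.8904), (0.9157, 0.8823, 0.8987),
        (0.8869, 0.8460, 0.8660), (0.8715, 0.8595, 0.8654), (0.9238, 0.8997, 0.9116),
    ],
    # deep-model comparison, UAV imagery (fusion then word features per model)
    "model_comparison_uav": [
        (0.8614, 0.8391, 0.8501), (0.8749, 0.8432, 0.8588),
        (0.8597, 0.8324, 0.8509), (0.8802, 0.8466, 0.8631),
        (0.8564, 0.8312, 0.8436), (0.8713, 0.8422, 0.8565),
        (0.8658, 0.8414, 0.8534), (0.8679, 0.8435, 0.8606),
        (0.8732, 0.8419, 0.8574), (0.8766, 0.8421, 0.8592),
        (0.8751, 0.8441, 0.8593), (0.8708, 0.8411, 0.8557),
        (0.8649, 0.8307, 0.8475), (0.8692, 0.8411, 0.8549),
        (0.8677, 0.8324, 0.8497), (0.8701, 0.8420, 0.8558),
        (0.8607, 0.8369, 0.8486), (0.8655, 0.8382, 0.8516),
        (0.8837, 0.8563, 0.8698), (0.9234, 0.8911, 0.9069),
    ],
    # deep-model comparison, QuickBird imagery
    "model_comparison_quickbird": [
        (0.8732, 0.8430, 0.8593), (0.8809, 0.8471, 0.8632),
        (0.8647, 0.8388, 0.8516), (0.8799, 0.8452, 0.8517),
        (0.8707, 0.8399, 0.8550), (0.8801, 0.8465, 0.8629),
        (0.8788, 0.8451, 0.8666), (0.8822, 0.8496, 0.8656),
        (0.8820, 0.8483, 0.8698), (0.8926, 0.8531, 0.8724),
        (0.8811, 0.8456, 0.8630), (0.8919, 0.8524, 0.8707),
        (0.8761, 0.8439, 0.8597), (0.8872, 0.8503, 0.8684),
        (0.8817, 0.8479, 0.8645), (0.8891, 0.8510, 0.8696),
        (0.8752, 0.8446, 0.8596), (0.8835, 0.8502, 0.8665),
        (0.8905, 0.8593, 0.8778), (0.9057, 0.8741, 0.8896),
    ],
}

#: the tables print 4 decimals; a row agreeing within one unit in the 4th
#: decimal is consistent (half-ulp rounding of either operand).
TOLERANCE = 1e-4 + 1e-12


def audit_triples(tables: dict | None = None) -> dict[str, list[dict]]:
    """Recompute F from each printed (P, R) and compare with the printed F.

    Returns, per table, one record per row with the recomputed value, the
    absolute deviation from the printed F, and a consistency flag.
    """
    tables = tables if tables is not None else REFERENCE_TRIPLES
    out: dict[str, list[dict]] = {}
    for name, rows in tables.items():
        audited = []
        for P, R, printed in rows:
            recomputed = round(f_score(P, R), 4)
            dev = abs(recomputed - printed)
            audited.append({
                "P": P, "R": R, "printed_F": printed,
                "recomputed_F": recomputed, "abs_dev": round(dev, 4),
                "consistent": dev <= TOLERANCE,
            })
        out[name] = audited
    return out
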