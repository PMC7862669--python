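# pixseq

Per-pixel classification of multispectral vegetation imagery by treating
pixels as words: a pixel dictionary is built by quantizing band values,
GloVe-style word vectors are fit to neighbourhood co-occurrence counts, and
fixed windows of 10 pixels are tagged by a bidirectional-LSTM encoder with
an LSTM + IndRNN decoder.  The target task is mapping *Populus euphratica*
(h) and *Tamarix* (c) against other ground cover (o) in UAV / satellite
scenes, where isolated pixels are frequently mis-imaged and context along a
scan line carries real signal.

Intended users: remote-sensing practitioners who want a sequence-labelling
alternative to pixel-wise classifiers, and method developers who need a
fully seeded, desk-scale reimplementation with synthetic ground truth.

## Model

Co-occurrence statistics over a fixed 1-D window (5 offsets each side along
the serialized sequence) define, for tokens *i, k*,

- marginal `x_i = Σ_k x_ik`, conditional `p_ik = x_ik / x_i`, and the
  diagnostic ratio `R_ijk = p_ik / p_jk`;

and the embedding minimizes the weighted least-squares objective

    J = Σ_{x_ij>0} f(x_ij) (ω_i·ω̃_j + b_i + b̃_j − log x_ij)²,
    f(x) = min((x / x_max)^0.75, 1).

The tagger encodes each 10-pixel window with a stacked Bi-LSTM (peephole
gates, 2 × 150 units per direction) and decodes with 2 LSTM layers
(200 units) followed by 2 IndRNN layers (32 units, element-wise recurrence
`h_t = relu(θx_t + υ ⊙ h_{t−1} + b)`), feeding the embedded previous label
back at every step; a softmax head scores the three classes and training
maximizes the masked log-likelihood with RMSprop (lr 0.001).  A labelling
rule repairs isolated imaging artefacts before training: a pixel flanked by
two pixels of one identical different class is relabelled to that class.
Evaluation is one-vs-rest precision/recall and `F = 2PR/(P+R)`.

Because the original UAV/QuickBird imagery is not publicly deposited, the
package ships a seeded synthetic-scene generator (clumped class regions,
per-class band signatures, sensor-confused pixels, isolated class flips,
optional blur) so every stage is testable end to end.

## Worked example

```python
import numpy as np
from pixseq import (GloveConfig, ModelConfig, SceneSpec, build_cooccurrence,
                    extract_sequences, generate_scene, quantize,
                    train_glove, train_and_evaluate, scene_battery)

scene = generate_scene(SceneSpec(height=64, width=64, seed=42))
dictionary, grid = quantize(scene.image, levels_per_band=8)
print(f"dictionary size m = {dictionary.m}")

seqs = extract_sequences(grid, axis="row", window_len=10)
C = build_cooccurrence(seqs, context_window=5)
print(f"co-occurrence: {C.counts.nnz} nonzero pairs, total mass {C.counts.sum():.0f}")

emb = train_glove(C, GloveConfig(dim=100, epochs=25, seed=0))
print(f"GloVe objective: {emb.loss_trace[0]:.1f} -> {emb.loss_trace[-1]:.1f}")

scenes = scene_battery("noisy")[:4]
report = train_and_evaluate(scenes, smooth=True, seed=0,
                            model_config=ModelConfig(epochs=4),
                            glove_config=GloveConfig(epochs=15))
macro = report["macro"]
print(f"held-out macro P={macro['P']:.4f} R={macro['R']:.4f} F={macro['F']:.4f}")
```

Output:

```
dictionary size m = 205
co-occurrence: 6040 nonzero pairs, total mass 27648
GloVe objective: 2281.9 -> 13.5
held-out macro P=0.9593 R=0.9576 F=0.9574
```

The 64×64 4-band scene quantizes to 205 distinct pixel words; 25 AdaGrad
epochs reduce the embedding objective by two orders of magnitude; and on
four moderately noisy scenes the tagger reaches macro-F ≈ 0.96 on the
held-out 20% of sequences against the clean ground truth.

## Command line

```
pixseq simulate --preset separable --out scenes/
pixseq vocab --image img.tif --levels 8 --out vocab.npz
pixseq cooccur --image img.tif --window 5 --axis row --out cooc.txt
pixseq embed --cooccurrence cooc.txt --dim 150 --epochs 50 --out vectors.txt
pixseq serialize --image img.tif --labels lab.tif --window 10 --smooth --out seqs.npz
pixseq pipeline --config cfg.yaml     # quantize -> embed -> train -> evaluate
pixseq predict --model run/model.npz --image img.tif --out pred.tif
pixseq evaluate --pred pred.tif --truth truth.tif --out metrics.json
```

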