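"""Synthetic multiband vegetation scenes with ground truth.

The UAV / QuickBird imagery the method targets is not publicly deposited, so
every stage is exercised on simulated scenes that reproduce the statistical
structure the method assumes:

* spatially clumped class regions (h = *P. euphratica*, c = *Tamarix*,
  o = other cover), built by thresholding a Gaussian-smoothed random field at
  the class-fraction quantiles;
* per-class multiband signatures with additive Gaussian noise;
* sensor-confused members of h and c (raw sub-labels h1/c1) drawn from a
  shifted parent distribution;
* isolated class-flip artefacts: a pixel flanked left and right by its own
  class is re-imaged (bands *and* annotation) as a different class while the
  ground truth keeps its true class — the corruption the smoothing rule is
  designed to repair;
* optional Gaussian blur of the image (never the truth).

What the simulator does **not** model: sensor PSFs, atmospheric effects,
georeferencing, mixed pixels, or class textures beyond noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .labels import C, C1, H, H1, O, LabelMap, map_sublabels

__all__ = ["SceneSpec", "Scene", "generate_scene", "scene_battery", "PRESETS"]

# default per-class band signatures (4 bands, reflectance-like scale);
# adjacent-band separation between any two classes is >= 0.10
DEFAULT_MEANS = {
    H: np.array([0.25, 0.45, 0.30, 0.60]),
    C: np.array([0.35, 0.40, 0.45, 0.50]),
    O: np.array([0.50, 0.35, 0.55, 0.30]),
}
# shift applied to confuser (h1/c1) signatures, toward the other vegetation class
CONFUSER_SHIFT = 0.4


@dataclass
class SceneSpec:
    height: int = 64
    width: int = 64
    band_count: int = 4
    class_means: dict = field(default_factory=lambda: {k: v.copy() for k, v in DEFAULT_MEANS.items()})
    noise_sd: float = 0.02
    patch_scale: float = 6.0
    class_fractions: tuple = (0.3, 0.3, 0.4)  # (h, c, o)
    flip_rate: float = 0.0
    confuser_rate: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        for r in (self.flip_rate, self.confuser_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("sigma values must be nonnegative")


@dataclass
class Scene:
    image: np.ndarray        # (H, W, bands)
    labels: LabelMap         # observed annotation (flips applied, raw sub-labels kept)
    truth: np.ndarray        # (H, W) clean canonical classes
    spec: SceneSpec


def _class_regions(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Clumped class raster: smoothed white noise cut at fraction quantiles."""
    fieldv = ndimage.gaussian_filter(rng.standard_normal((spec.height, spec.width)),
                                     spec.patch_scale, mode="reflect")
    qs = np.cumsum(spec.class_fractions)[:-1]
    cuts = np.quantile(fieldv, qs)
    return np.digitize(fieldv, cuts).astype(np.int64)  # 0=h, 1=c, 2=o


def _band_means(spec: SceneSpec, raw_labels: np.ndarray) -> np.ndarray:
    """Per-pixel expected band vector, including shifted confuser signatures."""
    means = np.zeros((spec.height, spec.width, spec.band_count))
    mh, mc, mo = (np.resize(spec.class_means[k], spec.band_count) for k in (H, C, O))
    lookup = {
        H: mh, C: mc, O: mo,
        H1: mh + CONFUSER_SHIFT * (mc - mh),
        C1: mc + CONFUSER_SHIFT * (mh - mc),
    }
    for code, mu in lookup.items():
        means[raw_labels == code] = mu
    return means


def generate_scene(spec: SceneSpec) -> Scene:
    """Draw one scene; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    truth = _class_regions(spec, rng)
    raw = truth.copy()

    # sensor-confused members of the vegetation classes
    if spec.confuser_rate > 0:
        for parent, sub in ((H, H1), (C, C1)):
            cells = np.argwhere(raw == parent)
            n = int(round(spec.confuser_rate * len(cells)))
            if n:
                pick = cells[rng.choice(len(cells), size=n, replace=False)]
                raw[pick[:, 0], pick[:, 1]] = sub

    # isolated class flips: both row neighbours share the pixel's true class
    if spec.flip_rate > 0:
        inner = truth[:, 1:-1]
        iso = (truth[:, :-2] == inner) & (truth[:, 2:] == inner)
        cand = np.argwhere(iso)
        cand[:, 1] += 1
        order = rng.permutation(len(cand))
        want = int(round(spec.flip_rate * truth.size))
        taken, used = [], set()
        for idx in order:
            r, c = cand[idx]
            if (r, c - 1) in used or (r, c + 1) in used or (r, c) in used:
                continue
            taken.append((r, c))
            used.add((r, c))
            if len(taken) >= want:
                break
        for r, c in taken:
            others = [k for k in (H, C, O) if k != truth[r, c]]
            raw[r, c] = others[rng.integers(len(others))]

    means = _band_means(spec, raw)
    image = means + spec.noise_sd * rng.standard_normal(means.shape)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, (spec.blur_sigma, spec.blur_sigma, 0),
                                        mode="reflect")
    observed = map_sublabels(raw)
    return Scene(image=image, labels=LabelMap(labels=observed, raw=raw),
                 truth=truth, spec=spec)


# fixed suites used across the tests: 12 scenes of 64x64 each
PRESETS = {
    # class means >= 10 x noise sd apart in every band
    "separable": dict(noise_sd=0.01),
    "noisy": dict(noise_sd=0.05),
    "blurred": dict(noise_sd=0.02, blur_sigma=1.0),
    # >= 1 isolated flip per 100 pixels so smoothing has measurable effect
    "corrupted": dict(noise_sd=0.02, flip_rate=0.02, confuser_rate=0.05),
}
BATTERY_SIZE = 12


def scene_battery(name: str, seed: int = 20260101) -> list[Scene]:
    """Seeded suite of :data:`BATTERY_SIZE` 64x64 scenes for a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    base = SceneSpec(**PRESETS[name])
    seeds = np.random.SeedSequence(seed).generate_state(BATTERY_SIZE) % (2 ** 31)
    return [generate_scene(replace(base, seed=int(s))) for s in seeds]
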