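"""Synthetic galleries: binary-code populations and vein-like images.

Two generators make the whole pipeline exercisable without any dataset:

* :func:`generate_code_population` draws, per class, a random template code
  and samples that flip each bit independently with a per-bit flip
  probability.  A fraction of bit positions is *stable* (low flip
  probability) and the rest *unstable* (near coin-flip) — exactly the
  bit-stability heterogeneity that weight-map matching exploits.  Ground
  truth (templates and flip probabilities) is returned for
  parameter-recovery tests: the trained weight of a bit whose per-sample
  probability of being 1 is pi converges to ``(2 pi - 1)**2``.
* :func:`generate_vein_image_class` renders a bright finger blob on a dark
  background with dark smooth random curves as veins, then applies
  per-sample geometric jitter and Gaussian noise, emulating transmitted
  near-infrared finger frames with intra-class geometric consistency.

All randomness flows from the explicit ``seed`` field of the spec through a
single :class:`numpy.random.Generator`; identical spec and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage

from .evaluation import Gallery
from .exceptions import InvalidInputError
from .features import BinaryCode

__all__ = [
    "CodePopulationSpec",
    "CodePopulation",
    "generate_code_population",
    "VeinImageSpec",
    "generate_vein_image_class",
    "generate_vein_gallery",
]


@dataclass(frozen=True)
class CodePopulationSpec:
    """Parameters of a per-class binary-code population.

    Defaults give a desk-scale heterogeneous-stability gallery: 20 classes
    of 16 samples over 384-bit codes, 25% stable bits that flip with
    probability 0.10 and 75% unstable coin-flip bits.  At these settings a
    stable bit survives the all-of-k constancy test of best-bit training
    with probability ``0.9**10 + 0.1**10 ~ 0.35 > f_stable``, the regime in
    which best-bit matching outperforms plain Hamming while graded
    weighting outperforms both.
    """

    n_classes: int = 20
    n_samples: int = 16
    code_length: int = 384
    f_stable: float = 0.25
    q_low: float = 0.10
    q_high: float = 0.5
    seed: int = 0
    operator_tag: str = "synthetic"

    def validate(self) -> None:
        if self.n_classes < 1 or self.n_samples < 1 or self.code_length < 1:
            raise InvalidInputError("population sizes must be positive")
        if not (0.0 <= self.f_stable <= 1.0):
            raise InvalidInputError("f_stable must lie in [0, 1]")
        if not (0.0 <= self.q_low <= self.q_high <= 0.5):
            raise InvalidInputError("need 0 <= q_low <= q_high <= 0.5")


@dataclass
class CodePopulation:
    """A generated gallery plus its ground truth."""

    gallery: Gallery
    templates: np.ndarray = field(repr=False)  # (n_classes, code_length) uint8
    flip_probs: np.ndarray = field(repr=False)  # (code_length,) float64
    spec: CodePopulationSpec = field(default_factory=CodePopulationSpec)


def generate_code_population(spec: CodePopulationSpec) -> CodePopulation:
    """Draw a code gallery with controlled per-bit stability.

    The first ``round(f_stable * code_length)`` bit positions flip with
    probability ``q_low``, the rest with ``q_high``; each class gets a
    uniform random template and each sample flips template bits
    independently.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    length = spec.code_length
    n_stable = int(round(spec.f_stable * length))
    flip_probs = np.full(length, spec.q_high, dtype=np.float64)
    flip_probs[:n_stable] = spec.q_low
    templates = rng.integers(0, 2, size=(spec.n_classes, length), dtype=np.uint8)
    classes: dict[str, list[BinaryCode]] = {}
    for c in range(spec.n_classes):
        cid = f"class{c:03d}"
        flips = rng.random((spec.n_samples, length)) < flip_probs
        samples = templates[c][None, :] ^ flips.astype(np.uint8)
        classes[cid] = [
            BinaryCode.from_bits(samples[s], spec.operator_tag)
            for s in range(spec.n_samples)
        ]
    return CodePopulation(
        gallery=Gallery(classes=classes),
        templates=templates,
        flip_probs=flip_probs,
        spec=spec,
    )


@dataclass(frozen=True)
class VeinImageSpec:
    """Parameters of a synthetic near-infrared finger-vein image class.

    Dimensions default to the nominal raw frame size 240x320 (height x
    width).  ``contrast`` is the intensity drop of a vein below the finger
    surface, ``noise_sd`` the per-pixel Gaussian noise, ``warp_sd`` the
    standard deviation (pixels) of the per-sample random translation.
    """

    height: int = 240
    width: int = 320
    n_veins: int = 5
    vein_width_px: float = 4.0
    contrast: float = 0.35
    noise_sd: float = 0.03
    warp_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise InvalidInputError("frame must be at least 32x32")
        if self.n_veins < 0 or self.vein_width_px <= 0:
            raise InvalidInputError("invalid vein geometry")
        if not (0 <= self.contrast <= 1) or self.noise_sd < 0 or self.warp_sd < 0:
            raise InvalidInputError("invalid intensity/noise parameters")


def _finger_mask(h: int, w: int) -> np.ndarray:
    """Axis-aligned ellipse occupying most of the frame (the finger)."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.36 * h, 0.44 * w
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render_base(spec: VeinImageSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Class-level base image (no jitter, no noise) and finger mask."""
    h, w = spec.height, spec.width
    mask = _finger_mask(h, w)
    base = np.where(mask, 0.78, 0.08)
    # veins: smooth random curves crossing the finger horizontally
    vein_marks = np.zeros((h, w), dtype=bool)
    x_dense = np.linspace(0.1 * w, 0.9 * w, 16 * w // 10)
    for _ in range(spec.n_veins):
        ctrl_x = np.linspace(0.1 * w, 0.9 * w, 6)
        y0 = rng.uniform(0.3 * h, 0.7 * h)
        ctrl_y = y0 + rng.normal(0.0, 0.05 * h, size=6)
        spline = interpolate.CubicSpline(ctrl_x, ctrl_y)
        y_dense = spline(x_dense)
        cols = np.clip(np.round(x_dense).astype(int), 0, w - 1)
        rows = np.clip(np.round(y_dense).astype(int), 0, h - 1)
        vein_marks[rows, cols] = True
    dist = ndimage.distance_transform_edt(~vein_marks)
    veins = (dist <= spec.vein_width_px / 2.0) & mask
    profile = ndimage.gaussian_filter(veins.astype(np.float64), sigma=0.8)
    base = np.clip(base - spec.contrast * profile, 0.0, 1.0)
    return base, mask


def generate_vein_image_class(
    spec: VeinImageSpec, n_samples: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Render one class: ``n_samples`` jittered noisy views of one vein
    geometry, plus the ground-truth finger mask of the base geometry."""
    spec.validate()
    if n_samples < 1:
        raise InvalidInputError("n_samples must be positive")
    rng = np.random.default_rng(spec.seed)
    base, mask = _render_base(spec, rng)
    samples = []
    for _ in range(n_samples):
        img = base
        if spec.warp_sd > 0:
            shift = rng.normal(0.0, spec.warp_sd, size=2)
            img = ndimage.shift(img, shift, order=1, mode="nearest")
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        samples.append(np.clip(img, 0.0, 1.0))
    return samples, mask


def generate_vein_gallery(
    spec: VeinImageSpec, n_classes: int, n_samples: int
) -> dict[str, list[np.ndarray]]:
    """Render ``n_classes`` independent classes; class c reuses ``spec``
    with seed ``spec.seed + c`` so geometries differ but remain
    reproducible."""
    if n_classes < 1:
        raise InvalidInputError("n_classes must be positive")
    out = {}
    for c in range(n_classes):
        cls_spec = VeinImageSpec(
            height=spec.height,
            width=spec.width,
            n_veins=spec.n_veins,
            vein_width_px=spec.vein_width_px,
            contrast=spec.contrast,
            noise_sd=spec.noise_sd,
            warp_sd=spec.warp_sd,
            seed=spec.seed + c,
        )
        samples, _ = generate_vein_image_class(cls_spec, n_samples)
        out[f"class{c:03d}"] = samples
    return out
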