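"""Image geometry preprocessing: backbone-specific resizing and training
augmentation (flip, translate, rotate).

Augmentation follows the usual endoscopy transfer-learning recipe: random
horizontal/vertical flips, translation sampled uniformly from a closed
pixel range (default (-30, 30) independently in x and y) and rotation
sampled uniformly from a closed degree range (default (0, 180)).  It is
meant for the end-to-end fine-tuning path, where small training sets
overfit; feature extraction for the SVM stages uses un-augmented images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .datatypes import ImageSample

__all__ = ["AugmentConfig", "resize_image", "augment"]


@dataclass(frozen=True)
class AugmentConfig:
    do_flip: bool = True
    translate_range_px: tuple[float, float] = (-30.0, 30.0)
    rotate_range_deg: tuple[float, float] = (0.0, 180.0)
    per_image_copies: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.per_image_copies < 1:
            raise ValueError("per_image_copies must be positive")
        for lo, hi in (self.translate_range_px, self.rotate_range_deg):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")


def resize_image(sample: ImageSample, target_hw: tuple[int, int]) -> ImageSample:
    """Direct bilinear resize to ``target_hw`` (aspect ratio not preserved)."""
    th, tw = target_hw
    if th < 1 or tw < 1:
        raise ValueError("target dimensions must be positive")
    if sample.shape_hw == (th, tw):
        return ImageSample(sample.pixels.copy(), sample.label, sample.ident)
    img = Image.fromarray(sample.pixels).resize((tw, th), Image.BILINEAR)
    return ImageSample(np.asarray(img), sample.label, sample.ident)


def _affine(px: np.ndarray, dx: float, dy: float, theta_deg: float) -> np.ndarray:
    """Rotate about the image centre, then translate; zero-fill exposed pixels.

    The frame size is kept, so downstream tensor shapes are unaffected.
    """
    img = Image.fromarray(px)
    if theta_deg != 0.0:
        img = img.rotate(theta_deg, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    if dx != 0.0 or dy != 0.0:
        # PIL's affine matrix maps output coords to input coords.
        img = img.transform(
            img.size,
            Image.AFFINE,
            (1.0, 0.0, -dx, 0.0, 1.0, -dy),
            resample=Image.BILINEAR,
            fillcolor=(0, 0, 0),
        )
    return np.asarray(img)


def augment(
    sample: ImageSample,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> list[ImageSample]:
    """Produce ``cfg.per_image_copies`` randomly perturbed copies.

    Each copy is flip(maybe) o translate(dx, dy) o rotate(theta) with
    dx, dy ~ U[translate_range_px] and theta ~ U[rotate_range_deg]; the
    label is never changed.  Degenerate ranges collapse to constants, so a
    zero config returns pixel-identical copies.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: list[ImageSample] = []
    t_lo, t_hi = cfg.translate_range_px
    r_lo, r_hi = cfg.rotate_range_deg
    for i in range(cfg.per_image_copies):
        theta = rng.uniform(r_lo, r_hi) if r_hi > r_lo else r_lo
        dx = rng.uniform(t_lo, t_hi) if t_hi > t_lo else t_lo
        dy = rng.uniform(t_lo, t_hi) if t_hi > t_lo else t_lo
        px = _affine(sample.pixels, dx, dy, theta)
        if cfg.do_flip:
            if rng.random() < 0.5:
                px = px[:, ::-1]
            if rng.random() < 0.5:
                px = px[::-1, :]
        out.append(ImageSample(np.ascontiguousarray(px), sample.label, f"{sample.ident}_aug{i}"))
    return out
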