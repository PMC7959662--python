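"""Deterministic synthetic fixtures for the pipeline.

Real GI endoscopy collections (Kvasir-style balanced multi-class image
sets) are large downloads; the generators here emulate their structure so
every stage — backbone tapping, spectral reduction, fusion, SVM CV — is
testable offline.  Class identity is encoded the way both the CNN taps and
the DWT/DCT reductions can see it: a class-specific dominant hue plus an
oriented sinusoidal texture of class-specific frequency, perturbed by
Gaussian pixel noise.  ``signal_strength`` scales the class-dependent part
only, so 0 makes all classes identically distributed (chance-level floor)
and 1 gives the cleanest separation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb

from .datatypes import FeatureMatrix, ImageSample, InvalidSpecificationError

__all__ = [
    "SyntheticSpec",
    "generate_image_dataset",
    "write_image_dataset",
    "read_image_dataset",
    "generate_separable_features",
    "generate_complementary_feature_sets",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a balanced synthetic multi-class RGB image set.

    noise_sd is pixel-intensity Gaussian noise on the [0, 1] scale; the
    defaults (0.05 noise, full signal, 64 px frames) are the study
    conditions used throughout the test-suite and the acceptance run.
    """

    n_classes: int = 8
    n_per_class: int = 50
    image_size: tuple[int, int] = (64, 64)
    signal_strength: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise InvalidSpecificationError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise InvalidSpecificationError("n_per_class must be positive")
        if self.image_size[0] < 1 or self.image_size[1] < 1:
            raise InvalidSpecificationError("image_size must be positive")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise InvalidSpecificationError("signal_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecificationError("noise_sd must be nonnegative")


def _class_image(
    cls: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one uint8 frame for class ``cls``.

    Hue = cls / n_classes; texture orientation = cls * pi / n_classes;
    texture frequency cycles over {3, 5, 7, 9} cycles/frame.  A random
    phase and a small hue jitter vary individual frames within a class.
    """
    h, w = spec.image_size
    s = spec.signal_strength
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.pi * cls / spec.n_classes
    freq = 3.0 + 2.0 * (cls % 4)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
    texture = np.sin(2.0 * np.pi * freq * carrier + phase)

    hue = (cls / spec.n_classes + rng.normal(0.0, 0.01)) % 1.0
    hsv = np.empty((h, w, 3), dtype=np.float64)
    hsv[..., 0] = hue
    hsv[..., 1] = 0.8 * s
    hsv[..., 2] = np.clip(0.55 + 0.30 * s * texture, 0.0, 1.0)
    rgb = hsv2rgb(hsv)
    rgb += rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def generate_image_dataset(spec: SyntheticSpec) -> list[ImageSample]:
    """Generate the balanced labelled image collection described by ``spec``.

    Deterministic: identical specs give byte-identical pixel arrays.  One
    child RNG stream per image, spawned in a fixed order from the single
    seed, so generation order cannot change the output.
    """
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_classes * spec.n_per_class)
    samples: list[ImageSample] = []
    i = 0
    for cls in range(spec.n_classes):
        label = f"class{cls:02d}"
        for j in range(spec.n_per_class):
            rng = np.random.default_rng(streams[i])
            samples.append(
                ImageSample(_class_image(cls, spec, rng), label, f"{label}_{j:04d}")
            )
            i += 1
    return samples


def write_image_dataset(samples: list[ImageSample], out_dir: str | Path) -> Path:
    """Write PNGs into a folder-per-class tree plus a labels.tsv manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "labels.tsv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["relative_path", "class_name"])
        for s in samples:
            rel = Path(s.label) / f"{s.ident}.png"
            (out / s.label).mkdir(exist_ok=True)
            Image.fromarray(s.pixels).save(out / rel)
            writer.writerow([rel.as_posix(), s.label])
    return manifest


def read_image_dataset(manifest: str | Path) -> list[ImageSample]:
    """Load a labels.tsv manifest written by :func:`write_image_dataset`."""
    from PIL import Image

    manifest = Path(manifest)
    root = manifest.parent
    samples = []
    with manifest.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            px = np.asarray(Image.open(root / row["relative_path"]).convert("RGB"))
            samples.append(
                ImageSample(px, row["class_name"], Path(row["relative_path"]).stem)
            )
    return samples


def generate_separable_features(
    n_per_class: int,
    dim: int,
    n_classes: int,
    separation: float,
    seed: int,
) -> FeatureMatrix:
    """Gaussian feature clouds with axis-aligned class means.

    Class c's mean is ``separation * e_c`` with unit-variance spherical
    noise, so separation >> 1 is arbitrarily separable and separation 0 is
    exactly chance-level — the two limits the classifier tests pin down.
    """
    if dim < n_classes:
        raise InvalidSpecificationError("dim must be >= n_classes")
    if n_per_class < 1 or n_classes < 2:
        raise InvalidSpecificationError("need n_per_class >= 1 and n_classes >= 2")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_classes * n_per_class, dim))
    labels = np.repeat([f"class{c:02d}" for c in range(n_classes)], n_per_class)
    for c in range(n_classes):
        X[c * n_per_class : (c + 1) * n_per_class, c] += separation
    return FeatureMatrix(X, labels, backbone=f"separable(sep={separation:g})")


def generate_complementary_feature_sets(
    n_classes: int,
    seed: int,
    n_per_class: int = 30,
    separation: float = 8.0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Two sample-aligned feature sets carrying complementary information.

    Set A resolves only the first half of the classes (the second half all
    share one mean); set B is the mirror image.  Either set alone is capped
    at the collapsed-class Bayes rate (1/2 + 1/n_classes for balanced
    classes under large separation); their concatenation resolves every
    class — the construction that makes the stage-3 fusion claim testable.
    """
    if n_classes < 4 or n_classes % 2:
        raise InvalidSpecificationError("n_classes must be even and >= 4")
    rng = np.random.default_rng(seed)
    half = n_classes // 2
    n = n_classes * n_per_class
    labels = np.repeat([f"class{c:02d}" for c in range(n_classes)], n_per_class)

    def build(resolved: range, tag: str) -> FeatureMatrix:
        X = rng.standard_normal((n, n_classes))
        for c in range(n_classes):
            axis = c if c in resolved else (resolved.stop % n_classes)
            X[c * n_per_class : (c + 1) * n_per_class, axis] += separation
        return FeatureMatrix(X, labels, backbone=tag)

    a = build(range(0, half), "setA")
    b = build(range(half, n_classes), "setB")
    return a, b
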