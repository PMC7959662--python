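"""Shared containers for the three-stage classification pipeline.

The pipeline moves labelled RGB images through deep-feature extraction
(stage 1), spectral reduction by level-1 DWT or truncated DCT (stage 2)
and concatenation fusion (stage 3) before multi-kernel SVM evaluation.
Every stage consumes and produces one of the containers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class InvalidSpecificationError(ValueError):
    """A generator / transform / fusion specification violates its contract."""


class AlignmentError(ValueError):
    """Feature sets that must share samples (rows + labels) do not."""


@dataclass
class ImageSample:
    """One RGB image with its class label.

    pixels are H x W x 3 uint8; ``ident`` is a stable identifier used in
    manifests and run logs.
    """

    pixels: np.ndarray
    label: str
    ident: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ImageSample.pixels must be H x W x 3")
        if self.pixels.size == 0:
            raise ValueError("empty image")

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class FeatureMatrix:
    """n x d per-image feature vectors with aligned labels and provenance."""

    values: np.ndarray
    labels: np.ndarray
    backbone: str = ""
    tap: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix.values must be 2-D")
        if self.values.shape[0] != self.labels.shape[0]:
            raise AlignmentError("row count does not match label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMatrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def name(self) -> str:
        return self.backbone or "features"


@dataclass
class TransformedFeatures(FeatureMatrix):
    """A FeatureMatrix after DWT-CA / DWT-CD / DCT-k reduction.

    ``transform`` names the reduction applied; ``source`` identifies the
    matrix it came from, so reports can trace each fused block.
    """

    transform: str = ""
    source: str = ""

    @property
    def name(self) -> str:
        base = self.source or self.backbone or "features"
        return f"{base}/{self.transform}" if self.transform else base


@dataclass
class FusionSet:
    """Ordered concatenation of sample-aligned feature sets (stage 3)."""

    components: list[Any]
    values: np.ndarray
    labels: np.ndarray
    name: str

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class FoldMetrics:
    """Metrics of one CV fold (overall accuracy + macro one-vs-rest rates)."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


@dataclass
class CVReport:
    """Per-fold and mean metrics for one feature set under one SVM kernel."""

    feature_set: str
    kernel: str
    folds: list[FoldMetrics]
    seed: int
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def mean(self, metric: str = "accuracy") -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    @property
    def mean_metrics(self) -> FoldMetrics:
        return FoldMetrics(
            *(self.mean(m) for m in ("accuracy", "sensitivity", "specificity", "precision", "f1"))
        )
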