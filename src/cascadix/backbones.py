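"""Backbone registry, deep-feature tapping and SGDM fine-tuning.

Stage 1 of the pipeline pulls a per-image feature vector from a named
intermediate layer of a CNN: AlexNet's fc7 (4,096-d), ResNet-50's global
average pool (2,048-d), DenseNet-201's final average pool (1,920-d) and
DarkNet-19's class-sized head.  The four architectures are built from
their published definitions with He-initialised random weights — the tap
widths and the pipeline mechanics are weight-independent, so no downloads
are needed; pretrained weights can be injected by assigning to the layer
parameter arrays.

``tinycnn`` (3 conv blocks + GAP + linear, configurable tap width) is the
fully trainable stand-in used for fast end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .datatypes import FeatureMatrix, ImageSample
from .preprocessing import resize_image

__all__ = [
    "BackboneSpec",
    "FineTuneConfig",
    "register_backbone",
    "get_backbone",
    "build_network",
    "extract_features",
    "fine_tune",
    "BackboneFeatureExtractor",
    "save_features_tsv",
    "load_features_tsv",
]

# ImageNet channel statistics; configurable per spec.
_IMAGENET_MEAN = (0.485, 0.456, 0.406)
_IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class BackboneSpec:
    """Identity, input geometry and tap layer of a feature extractor."""

    name: str
    input_hw: tuple[int, int]
    tap_layer: str
    expected_dim: int | str  # int, or "n_classes" for class-sized taps
    norm_mean: tuple[float, float, float] = _IMAGENET_MEAN
    norm_std: tuple[float, float, float] = _IMAGENET_STD

    def tap_dim(self, n_classes: int | None = None) -> int:
        if isinstance(self.expected_dim, int):
            return self.expected_dim
        if n_classes is None:
            raise ValueError(f"{self.name} tap width depends on the class count")
        return n_classes


@dataclass(frozen=True)
class FineTuneConfig:
    """SGDM fine-tuning hyperparameters (transfer-learning defaults)."""

    epochs: int = 10
    initial_lr: float = 1e-4
    mini_batch: int = 10
    validation_frequency: int = 3
    weight_decay: float = 5e-4
    momentum: float = 0.9
    optimizer: str = "sgdm"

    def as_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "initial_lr": self.initial_lr,
            "mini_batch": self.mini_batch,
            "validation_frequency": self.validation_frequency,
            "weight_decay": self.weight_decay,
            "momentum": self.momentum,
            "optimizer": self.optimizer,
        }


class RegistrationError(ValueError):
    pass


_REGISTRY: dict[str, tuple[BackboneSpec, Callable]] = {}


def register_backbone(spec: BackboneSpec, constructor: Callable) -> None:
    """Register a backbone under ``spec.name``; duplicates are an error.

    ``constructor(n_classes, seed, **kw)`` must return an ``nn.Sequential``
    containing ``spec.tap_layer``.
    """
    if spec.name in _REGISTRY:
        raise RegistrationError(f"backbone {spec.name!r} already registered")
    _REGISTRY[spec.name] = (spec, constructor)


def get_backbone(name: str) -> tuple[BackboneSpec, Callable]:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(_REGISTRY)}")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def build_alexnet(n_classes: int = 1000, seed: int = 0) -> nn.Sequential:
    """AlexNet (227x227 input): 5 conv layers, fc6/fc7 at 4,096, class head."""
    r = _rng(seed)
    return nn.Sequential(
        [
            ("conv1", nn.Conv2d(3, 64, 11, stride=4, pad=2, rng=r)),
            ("relu1", nn.ReLU()),
            ("pool1", nn.MaxPool2d(3, 2)),
            ("conv2", nn.Conv2d(64, 192, 5, pad=2, rng=r)),
            ("relu2", nn.ReLU()),
            ("pool2", nn.MaxPool2d(3, 2)),
            ("conv3", nn.Conv2d(192, 384, 3, pad=1, rng=r)),
            ("relu3", nn.ReLU()),
            ("conv4", nn.Conv2d(384, 256, 3, pad=1, rng=r)),
            ("relu4", nn.ReLU()),
            ("conv5", nn.Conv2d(256, 256, 3, pad=1, rng=r)),
            ("relu5", nn.ReLU()),
            ("pool5", nn.MaxPool2d(3, 2)),
            ("flatten", nn.Flatten()),
            ("drop6", nn.Dropout()),
            ("fc6", nn.Linear(256 * 6 * 6, 4096, rng=r)),
            ("relu6", nn.ReLU()),
            ("drop7", nn.Dropout()),
            ("fc7", nn.Linear(4096, 4096, rng=r)),
            ("relu7", nn.ReLU()),
            ("fc8", nn.Linear(4096, n_classes, rng=r)),
        ]
    )


def build_resnet50(n_classes: int = 1000, seed: int = 0) -> nn.Sequential:
    """ResNet-50: bottleneck stages [3, 4, 6, 3], 2,048-d global avg pool."""
    r = _rng(seed)
    layers: list[tuple[str, nn.Layer]] = [
        ("conv1", nn.Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=r)),
        ("bn1", nn.BatchNorm2d(64)),
        ("relu1", nn.LeakyReLU(0.0)),
        ("pool1", nn.MaxPool2d(3, 2, pad=1)),
    ]
    in_ch = 64
    for stage, (blocks, mid) in enumerate(zip((3, 4, 6, 3), (64, 128, 256, 512))):
        out_ch = mid * 4
        for b in range(blocks):
            stride = 2 if (b == 0 and stage > 0) else 1
            layers.append(
                (f"res{stage + 2}{chr(97 + b)}", nn.Bottleneck(in_ch, mid, out_ch, stride, r))
            )
            in_ch = out_ch
    layers += [
        ("avgpool", nn.GlobalAvgPool()),
        ("fc", nn.Linear(2048, n_classes, rng=r)),
    ]
    return nn.Sequential(layers)


_DARKNET19_CFG = [
    (32, 3), "M", (64, 3), "M", (128, 3), (64, 1), (128, 3), "M",
    (256, 3), (128, 1), (256, 3), "M",
    (512, 3), (256, 1), (512, 3), (256, 1), (512, 3), "M",
    (1024, 3), (512, 1), (1024, 3), (512, 1), (1024, 3),
]


def build_darknet19(n_classes: int = 1000, seed: int = 0) -> nn.Sequential:
    """DarkNet-19 (256x256 input): 19 conv layers, class-sized 1x1 head + GAP."""
    r = _rng(seed)
    layers: list[tuple[str, nn.Layer]] = []
    in_ch, ci, mi = 3, 0, 0
    for item in _DARKNET19_CFG:
        if item == "M":
            mi += 1
            layers.append((f"pool{mi}", nn.MaxPool2d(2, 2)))
        else:
            out_ch, k = item
            ci += 1
            layers += [
                (f"conv{ci}", nn.Conv2d(in_ch, out_ch, k, pad=k // 2, bias=False, rng=r)),
                (f"bn{ci}", nn.BatchNorm2d(out_ch)),
                (f"lrelu{ci}", nn.LeakyReLU(0.1)),
            ]
            in_ch = out_ch
    layers += [
        ("conv_head", nn.Conv2d(1024, n_classes, 1, rng=r)),
        ("avgpool", nn.GlobalAvgPool()),
    ]
    return nn.Sequential(layers)


def build_densenet201(n_classes: int = 1000, seed: int = 0) -> nn.Sequential:
    """DenseNet-201: growth 32, blocks [6, 12, 48, 32], 1,920-d final pool."""
    r = _rng(seed)
    growth = 32
    layers: list[tuple[str, nn.Layer]] = [
        ("conv1", nn.Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=r)),
        ("bn1", nn.BatchNorm2d(64)),
        ("relu1", nn.LeakyReLU(0.0)),
        ("pool1", nn.MaxPool2d(3, 2, pad=1)),
    ]
    ch = 64
    for i, n_layers in enumerate((6, 12, 48, 32), start=1):
        block = nn.DenseBlock(ch, n_layers, growth, r)
        layers.append((f"denseblock{i}", block))
        ch = block.out_ch
        if i < 4:
            layers.append((f"transition{i}", nn.Transition(ch, ch // 2, r)))
            ch //= 2
    layers += [
        ("bn_final", nn.BatchNorm2d(ch)),
        ("relu_final", nn.LeakyReLU(0.0)),
        ("avgpool", nn.GlobalAvgPool()),
        ("fc", nn.Linear(ch, n_classes, rng=r)),
    ]
    return nn.Sequential(layers)


def build_tinycnn(
    n_classes: int = 8, seed: int = 0, width: int = 32, input_hw: tuple[int, int] = (64, 64)
) -> nn.Sequential:
    """Seconds-scale trainable CNN: 3 conv blocks + GAP(width) + linear head."""
    r = _rng(seed)
    return nn.Sequential(
        [
            ("conv1", nn.Conv2d(3, 8, 3, pad=1, rng=r)),
            ("relu1", nn.ReLU()),
            ("pool1", nn.MaxPool2d(2, 2)),
            ("conv2", nn.Conv2d(8, 16, 3, pad=1, rng=r)),
            ("relu2", nn.ReLU()),
            ("pool2", nn.MaxPool2d(2, 2)),
            ("conv3", nn.Conv2d(16, width, 3, pad=1, rng=r)),
            ("relu3", nn.ReLU()),
            ("pool3", nn.MaxPool2d(2, 2)),
            ("gap", nn.GlobalAvgPool()),
            ("fc", nn.Linear(width, n_classes, rng=r)),
        ]
    )


for _spec, _ctor in [
    (BackboneSpec("alexnet", (227, 227), "fc7", 4096), build_alexnet),
    (BackboneSpec("resnet50", (224, 224), "avgpool", 2048), build_resnet50),
    (BackboneSpec("darknet19", (256, 256), "avgpool", "n_classes"), build_darknet19),
    (BackboneSpec("densenet201", (224, 224), "avgpool", 1920), build_densenet201),
    (BackboneSpec("tinycnn", (64, 64), "gap", 32), build_tinycnn),
]:
    register_backbone(_spec, _ctor)


def _to_batch(images: list[ImageSample], spec: BackboneSpec) -> np.ndarray:
    """Resize where needed, normalise channels and stack to NCHW float32."""
    mean = np.asarray(spec.norm_mean, dtype=np.float32).reshape(3, 1, 1)
    std = np.asarray(spec.norm_std, dtype=np.float32).reshape(3, 1, 1)
    arrs = []
    for s in images:
        if s.shape_hw != spec.input_hw:
            s = resize_image(s, spec.input_hw)
        x = s.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0
        arrs.append((x - mean) / std)
    return np.stack(arrs)


def extract_features(
    images: list[ImageSample],
    backbone: BackboneSpec | str,
    batch_size: int = 32,
    network: nn.Sequential | None = None,
    seed: int = 0,
    n_classes: int | None = None,
    **builder_kw,
) -> FeatureMatrix:
    """Tap ``backbone`` at its configured layer for every image, in order.

    Pass ``network`` to reuse an already-built (e.g. fine-tuned) net;
    otherwise one is constructed with random weights from ``seed``.
    """
    if isinstance(backbone, str):
        backbone = get_backbone(backbone)[0]
    if network is None:
        ctor = get_backbone(backbone.name)[1]
        k = n_classes or len({s.label for s in images})
        network = ctor(n_classes=k, seed=seed, **builder_kw)
    if backbone.tap_layer not in network.layer_names():
        raise KeyError(f"tap layer {backbone.tap_layer!r} absent from {backbone.name}")
    rows = []
    for start in range(0, len(images), batch_size):
        x = _to_batch(images[start : start + batch_size], backbone)
        out = network.forward(x, tap=backbone.tap_layer)
        rows.append(out.reshape(out.shape[0], -1).astype(np.float64))
    values = np.vstack(rows)
    labels = np.asarray([s.label for s in images])
    return FeatureMatrix(values, labels, backbone=backbone.name, tap=backbone.tap_layer)


def build_network(
    name: str, n_classes: int, seed: int = 0, **kw
) -> tuple[BackboneSpec, nn.Sequential]:
    spec, ctor = get_backbone(name)
    return spec, ctor(n_classes=n_classes, seed=seed, **kw)


def fine_tune(
    network: nn.Sequential,
    backbone: BackboneSpec,
    images: list[ImageSample],
    cfg: FineTuneConfig = FineTuneConfig(),
    n_classes: int | None = None,
    seed: int = 0,
) -> tuple[nn.Sequential, list[dict]]:
    """Train the network with SGDM softmax cross-entropy; return a loss log.

    The classification head is re-sized to the task's class count.  When
    every layer supports gradients (tinycnn) the whole network trains
    end-to-end; otherwise training falls back to the head only, with the
    trunk frozen as a feature extractor — the usual transfer-learning
    split.  ``epochs = 0`` is a no-op returning an empty log.
    """
    if not images:
        raise ValueError("empty training set")
    classes = sorted({s.label for s in images})
    k = n_classes or len(classes)
    if k < 2:
        raise ValueError("need at least two classes to fine-tune")
    rng = np.random.default_rng(seed)

    head_name = network.layer_names()[-1]
    head = network[head_name]
    if not isinstance(head, nn.Linear):
        raise ValueError("expected a Linear classification head as the last layer")
    if head.W.shape[0] != k:
        network.replace(head_name, nn.Linear(head.W.shape[1], k, rng=rng))
        head = network[head_name]

    log: list[dict] = []
    if cfg.epochs == 0:
        return network, log

    y = np.asarray([classes.index(s.label) for s in images])
    full = network.supports_backward
    if full:
        x_all = _to_batch(images, backbone)
        layers = [layer for _, layer in network.layers]
    else:  # frozen trunk: pre-compute tap features once, train head only
        feats = extract_features(images, backbone, network=network).values.astype(np.float32)
        layers = [head]
    opt = nn.SGDM(
        [l for l in layers if l.params()],
        lr=cfg.initial_lr,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
    )
    n = len(images)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.mini_batch):
            idx = order[start : start + cfg.mini_batch]
            if full:
                logits = network.forward(x_all[idx])
            else:
                logits = head.forward(feats[idx])
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
            if full:
                network.backward(grad)
            else:
                head.backward(grad)
            opt.step()
            losses.append(loss)
        log.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "train_accuracy": correct / n,
                **cfg.as_dict(),
            }
        )
    network._classes = classes  # used by predict paths
    return network, log


def predict_labels(
    network: nn.Sequential, backbone: BackboneSpec, images: list[ImageSample]
) -> np.ndarray:
    """End-to-end class predictions from a fine-tuned network."""
    classes = getattr(network, "_classes", None)
    if classes is None:
        raise ValueError("network has not been fine-tuned")
    x = _to_batch(images, backbone)
    logits = network.forward(x)
    return np.asarray(classes)[logits.argmax(axis=1)]


class BackboneFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn transformer: list of ImageSamples -> tapped feature matrix.

    Stateless apart from the lazily built network; ``fit`` only records
    the class count so class-sized taps (darknet19) are well-defined.
    """

    def __init__(self, backbone: str = "tinycnn", batch_size: int = 32, seed: int = 0):
        self.backbone = backbone
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X: list[ImageSample], y=None):
        spec, ctor = get_backbone(self.backbone)
        k = len({s.label for s in X}) if y is None else len(set(y))
        self.network_ = ctor(n_classes=max(k, 2), seed=self.seed)
        self.spec_ = spec
        return self

    def transform(self, X: list[ImageSample]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        return extract_features(
            X, self.spec_, batch_size=self.batch_size, network=self.network_
        ).values


def save_features_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    """Persist as TSV with header f0..f{d-1}, label."""
    df = pd.DataFrame(fm.values, columns=[f"f{i}" for i in range(fm.n_features)])
    df["label"] = fm.labels
    df.to_csv(path, sep="\t", index=False)


def load_features_tsv(path: str | Path, backbone: str = "", tap: str = "") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(df.to_numpy(dtype=np.float64), labels, backbone=backbone, tap=tap)
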