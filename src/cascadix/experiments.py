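"""Config-driven orchestration of the four evaluation scenarios.

  I   end-to-end CNN fine-tuning and prediction (per backbone);
  II  raw deep features -> SVM (per backbone x kernel);
  III DWT-CA / DWT-CD / DCT-truncated features -> SVM;
  IV  concatenation fusions of the reduced features -> SVM.

Fold assignments are computed once per run from (labels, seed) and shared
by experiments II-IV, so accuracy differences between feature sets are
paired comparisons.  All tables are pandas DataFrames and are written as
TSV plus a plain-text summary.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backbones as bb
from .datatypes import FeatureMatrix, ImageSample, TransformedFeatures
from .evaluation import cross_validate, metrics_from_predictions, stratified_kfold
from .fusion import enumerate_fusions
from .preprocessing import AugmentConfig, augment
from .spectral import TransformConfig, apply_transform
from .synthetic import SyntheticSpec, generate_image_dataset, read_image_dataset

__all__ = [
    "ExperimentConfig",
    "load_config",
    "load_images",
    "run_experiment_I",
    "run_experiment_II",
    "run_experiment_III",
    "run_experiment_IV",
    "run_all",
    "write_report",
]

_DEFAULT_TRANSFORMS = (
    TransformConfig(kind="dwt_ca"),
    TransformConfig(kind="dwt_cd"),
    TransformConfig(kind="dct", dct_keep=500),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """One run: data source, backbones, transforms, fusion sizes, kernels."""

    dataset_path: str | None = None
    synthetic: SyntheticSpec | None = None
    backbones: tuple[str, ...] = ("tinycnn",)
    backbone_seeds: tuple[int, ...] = ()  # per-backbone weight seeds
    backbone_widths: tuple[int, ...] = ()  # tinycnn tap widths, optional
    transforms: tuple[TransformConfig, ...] = _DEFAULT_TRANSFORMS
    fusion_sizes: tuple[int, ...] = (2, 3, 4)
    kernels: tuple[str, ...] = ("linear", "quadratic", "cubic")
    folds: int = 5
    seed: int = 0
    output_dir: str = "runs"
    augment_copies: int = 1

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for name in self.backbones:
            bb.get_backbone(name)  # raises for unknown names
        if self.dataset_path is None and self.synthetic is None:
            raise ValueError("either dataset_path or synthetic spec required")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML/JSON config file into an ExperimentConfig."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    synth = raw.pop("synthetic", None)
    if synth is not None:
        if "image_size" in synth:
            synth["image_size"] = tuple(synth["image_size"])
        synth = SyntheticSpec(**synth)
    transforms = raw.pop("transforms", None)
    if transforms is not None:
        transforms = tuple(TransformConfig(**t) for t in transforms)
    else:
        transforms = _DEFAULT_TRANSFORMS
    for key in ("backbones", "backbone_seeds", "backbone_widths", "fusion_sizes", "kernels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(synthetic=synth, transforms=transforms, **raw)


def load_images(cfg: ExperimentConfig) -> list[ImageSample]:
    cfg.validate()
    if cfg.dataset_path is not None:
        manifest = Path(cfg.dataset_path)
        if manifest.is_dir():
            manifest = manifest / "labels.tsv"
        return read_image_dataset(manifest)
    return generate_image_dataset(cfg.synthetic)


def _backbone_nets(cfg: ExperimentConfig, n_classes: int):
    """Build one network per configured backbone, with per-backbone seeds."""
    nets = []
    for i, name in enumerate(cfg.backbones):
        seed = cfg.backbone_seeds[i] if i < len(cfg.backbone_seeds) else cfg.seed + i
        kw = {}
        if name == "tinycnn" and i < len(cfg.backbone_widths):
            kw["width"] = cfg.backbone_widths[i]
        spec, net = bb.build_network(name, n_classes=n_classes, seed=seed, **kw)
        if name == "tinycnn" and "width" in kw:
            spec = replace(spec, name=f"tinycnn{kw['width']}w{i}", expected_dim=kw["width"])
        elif len(cfg.backbones) > len(set(cfg.backbones)):
            spec = replace(spec, name=f"{name}#{i}")
        nets.append((spec, net))
    return nets


def _extract_all(cfg: ExperimentConfig, images: list[ImageSample]) -> list[FeatureMatrix]:
    n_classes = len({s.label for s in images})
    out = []
    for spec, net in _backbone_nets(cfg, n_classes):
        fm = bb.extract_features(images, spec, network=net)
        fm.backbone = spec.name
        out.append(fm)
    return out


def run_experiment_I(cfg: ExperimentConfig) -> pd.DataFrame:
    """End-to-end fine-tune/predict per backbone on a held-out stratified fold.

    Training folds are augmented (flip / translate / rotate); the test
    fold never is.  Reports one accuracy row per backbone.
    """
    images = load_images(cfg)
    labels = np.asarray([s.label for s in images])
    folds = stratified_kfold(labels, k=cfg.folds, seed=cfg.seed)
    test_idx = folds[0]
    train_idx = np.setdiff1d(np.arange(len(images)), test_idx)
    n_classes = len(set(labels))
    aug_cfg = AugmentConfig(per_image_copies=cfg.augment_copies, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for spec, net in _backbone_nets(cfg, n_classes):
        train = [images[i] for i in train_idx]
        if cfg.augment_copies > 0:
            extra = []
            for s in train:
                extra.extend(augment(s, aug_cfg, rng))
            train = train + extra
        net, log = bb.fine_tune(net, spec, train, n_classes=n_classes, seed=cfg.seed)
        pred = bb.predict_labels(net, spec, [images[i] for i in test_idx])
        _, m = metrics_from_predictions(labels[test_idx], pred)
        train_pred = bb.predict_labels(net, spec, [images[i] for i in train_idx])
        rows.append(
            {
                "backbone": spec.name,
                "accuracy": m["accuracy"],
                "final_train_accuracy": float(np.mean(train_pred == labels[train_idx])),
            }
        )
    return pd.DataFrame(rows)


def _cv_table(
    feature_sets, labels, cfg: ExperimentConfig, folds, extra_cols: dict | None = None
) -> pd.DataFrame:
    rows = []
    for fs in feature_sets:
        reports = cross_validate(
            fs.values,
            labels,
            kernels=list(cfg.kernels),
            folds=folds,
            seed=cfg.seed,
            feature_set=fs.name,
        )
        for kernel, rep in reports.items():
            row = {"feature_set": fs.name, "kernel": kernel, "n_features": fs.values.shape[1]}
            row.update(rep.mean_metrics.as_dict())
            if extra_cols:
                row.update(extra_cols.get(fs.name, {}))
            rows.append(row)
    return pd.DataFrame(rows)


def run_experiment_II(cfg: ExperimentConfig) -> pd.DataFrame:
    """Raw tapped deep features -> SVM, per backbone x kernel."""
    images = load_images(cfg)
    labels = np.asarray([s.label for s in images])
    folds = stratified_kfold(labels, k=cfg.folds, seed=cfg.seed)
    return _cv_table(_extract_all(cfg, images), labels, cfg, folds)


def _reduced_sets(cfg: ExperimentConfig, feats: list[FeatureMatrix]) -> list[TransformedFeatures]:
    out = []
    for fm in feats:
        for tcfg in cfg.transforms:
            out.append(apply_transform(fm, tcfg))
    return out


def run_experiment_III(cfg: ExperimentConfig) -> pd.DataFrame:
    """Spectrally reduced features -> SVM, per backbone x transform x kernel.

    Vectors already at or below dct_keep pass through the DCT whole (the
    class-sized-tap rule), which the n_features column makes visible.
    """
    images = load_images(cfg)
    labels = np.asarray([s.label for s in images])
    folds = stratified_kfold(labels, k=cfg.folds, seed=cfg.seed)
    reduced = _reduced_sets(cfg, _extract_all(cfg, images))
    df = _cv_table(reduced, labels, cfg, folds)
    df[["backbone", "transform"]] = df["feature_set"].str.split("/", expand=True)
    return df


def run_experiment_IV(cfg: ExperimentConfig) -> pd.DataFrame:
    """Fused reduced features -> SVM, per fusion set x kernel.

    Fusion is homogeneous per transform kind (CA with CA, CD with CD,
    DCT with DCT), one row per enumerated subset of the requested sizes.
    """
    images = load_images(cfg)
    labels = np.asarray([s.label for s in images])
    folds = stratified_kfold(labels, k=cfg.folds, seed=cfg.seed)
    reduced = _reduced_sets(cfg, _extract_all(cfg, images))
    frames = []
    sizes = set(cfg.fusion_sizes)
    sizes = {k for k in sizes if k <= len(cfg.backbones)}
    for tcfg in cfg.transforms:
        group = [tf for tf in reduced if tf.transform == tcfg.label]
        fused = enumerate_fusions(group, sizes)
        df = _cv_table(fused, labels, cfg, folds)
        df["transform"] = tcfg.label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_all(cfg: ExperimentConfig, include_I: bool = True) -> dict[str, pd.DataFrame]:
    tables = {}
    if include_I:
        tables["experiment_I"] = run_experiment_I(cfg)
    tables["experiment_II"] = run_experiment_II(cfg)
    tables["experiment_III"] = run_experiment_III(cfg)
    tables["experiment_IV"] = run_experiment_IV(cfg)
    return tables


def write_report(
    tables: dict[str, pd.DataFrame], output_dir: str | Path, cfg: ExperimentConfig | None = None
) -> Path:
    """Write each table as TSV (atomically) plus a summary and a run log."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        tmp = out / f".{name}.tsv.tmp"
        df.to_csv(tmp, sep="\t", index=False)
        tmp.replace(out / f"{name}.tsv")
    lines = []
    for name, df in tables.items():
        lines.append(f"== {name} ==")
        if "accuracy" in df.columns and len(df):
            best = df.loc[df["accuracy"].idxmax()]
            ident = best.get("feature_set", best.get("backbone", "?"))
            kernel = f" [{best['kernel']}]" if "kernel" in df.columns else ""
            lines.append(f"best: {ident}{kernel} accuracy={best['accuracy']:.4f}")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
    (out / "summary.txt").write_text("\n".join(lines))
    log = {"python": sys.version.split()[0], "numpy": np.__version__}
    if cfg is not None:
        log["config"] = json.loads(json.dumps(cfg, default=lambda o: getattr(o, "__dict__", str(o))))
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
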