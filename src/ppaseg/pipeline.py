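"""Training / evaluation / prediction orchestration around the estimator.

A ``TrainConfig`` (YAML-serialisable) fixes the architecture, optimisation
settings and seed; ``train`` fits the model on the manifest's training
split and writes a checkpoint (.npz state dict + embedded JSON config) and
a JSON-lines log of per-epoch loss terms. ``evaluate_checkpoint`` and
``predict_images`` reload the checkpoint deterministically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .estimator import OTUnetSegmenter
from .metrics import MetricReport, evaluate, write_reports
from .synth import load_manifest, load_png

__all__ = ["TrainConfig", "train", "save_checkpoint", "load_checkpoint",
           "predict_images", "evaluate_checkpoint"]


@dataclass
class TrainConfig:
    """Everything needed to reproduce a training run."""

    input_size: int = 352
    backbone: str = "resnet"
    channel_counts: tuple[int, ...] | None = None
    reduce_channels: int = 32
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    max_steps: int | None = None
    weight_kernel: int = 31
    weight_gain: float = 5.0
    reduction: str = "mean"
    threshold: float = 0.5
    seed: int = 0
    pretrained: bool = False
    weights_path: str | None = None
    res2net_scale: int = 4
    res2net_width: int = 26
    output_dir: str = "runs"

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.channel_counts is not None:
            self.channel_counts = tuple(self.channel_counts)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["channel_counts"] is not None:
            d["channel_counts"] = list(d["channel_counts"])
        return d

    def make_estimator(self) -> OTUnetSegmenter:
        return OTUnetSegmenter(
            backbone=self.backbone, channel_counts=self.channel_counts,
            reduce_channels=self.reduce_channels, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            optimizer=self.optimizer, max_steps=self.max_steps,
            weight_kernel=self.weight_kernel, weight_gain=self.weight_gain,
            reduction=self.reduction, threshold=self.threshold,
            random_state=self.seed, pretrained=self.pretrained,
            weights_path=self.weights_path,
            res2net_scale=self.res2net_scale,
            res2net_width=self.res2net_width)


# ---------------------------------------------------------------------------
def _resize(arr: np.ndarray, size: tuple[int, int], binary: bool) -> np.ndarray:
    """Resize (H,W[,3]) array; bilinear for images, nearest for masks."""
    if arr.shape[:2] == size:
        return arr
    mode = Image.NEAREST if binary else Image.BILINEAR
    img = Image.fromarray((arr * 255).astype(np.uint8))
    out = np.asarray(img.resize(size[::-1], mode), dtype=np.float32) / 255.0
    return (out > 0.5).astype(np.uint8) if binary else out


def _load_split(manifest: pd.DataFrame, split: str, size: int):
    rows = manifest[manifest["split"] == split] if "split" in manifest else manifest
    X, y, e = [], [], []
    for _, r in rows.iterrows():
        X.append(_resize(load_png(r["image_path"], binary=False),
                         (size, size), binary=False))
        y.append(_resize(load_png(r["mask_path"], binary=True),
                         (size, size), binary=True))
        e.append(_resize(load_png(r["edge_path"], binary=True),
                         (size, size), binary=True))
    return np.stack(X), np.stack(y), np.stack(e), rows.reset_index(drop=True)


def train(config: TrainConfig, manifest_path) -> Path:
    """Fit on the manifest's training split; returns the checkpoint path."""
    manifest = load_manifest(manifest_path)
    X, y, edges, _ = _load_split(manifest, "train", config.input_size)
    est = config.make_estimator()
    est.fit(X, y, edges=edges)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "train_log.jsonl", "w") as fh:
        for rec in est.history_:
            fh.write(json.dumps(rec) + "\n")
    ckpt = out / "checkpoint.npz"
    save_checkpoint(ckpt, est, config)
    return ckpt


def save_checkpoint(path, est: OTUnetSegmenter, config: TrainConfig) -> None:
    state = est.model_.state_dict()
    meta = json.dumps({"config": config.as_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[OTUnetSegmenter, TrainConfig]:
    """Rebuild the estimator and restore weights bit-exactly."""
    try:
        archive = dict(np.load(path))
        meta = json.loads(archive.pop("__meta__").tobytes().decode())
    except Exception as exc:  # noqa: BLE001 - surface a clear message
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    config = TrainConfig(**meta["config"])
    est = config.make_estimator()
    est.model_ = est.build_model()
    est.model_.load_state_dict(archive)
    est.model_.eval()
    est.n_iter_ = 0
    return est, config


def predict_images(checkpoint_path, image_paths, out_dir,
                   threshold: float | None = None) -> list[dict]:
    """Write an 8-bit probability PNG and a binary mask PNG per image,
    restored to each image's original size."""
    est, config = load_checkpoint(checkpoint_path)
    thr = config.threshold if threshold is None else threshold
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    for p in image_paths:
        raw = load_png(p, binary=False)
        orig = raw.shape[:2]
        resized = _resize(raw, (config.input_size, config.input_size),
                          binary=False)
        prob = est.predict_proba(resized[None])[0]
        prob_full = _resize(prob.astype(np.float32), orig, binary=False)
        mask_full = (prob_full > thr).astype(np.uint8)
        stem = Path(p).stem
        prob_path = out / f"{stem}_prob.png"
        mask_path = out / f"{stem}_mask.png"
        Image.fromarray((np.clip(prob_full, 0, 1) * 255).astype(np.uint8)
                        ).save(prob_path)
        Image.fromarray((mask_full * 255).astype(np.uint8)).save(mask_path)
        results.append({"image": str(p), "prob_png": str(prob_path),
                        "mask_png": str(mask_path)})
    return results


def evaluate_checkpoint(checkpoint_path, manifest_path,
                        threshold: float | None = None, split: str = "test",
                        out_dir=None, average: str = "macro"
                        ) -> dict[str, MetricReport]:
    """Stratified metric report for a checkpoint on one manifest split."""
    est, config = load_checkpoint(checkpoint_path)
    thr = config.threshold if threshold is None else threshold
    manifest = load_manifest(manifest_path)
    X, y, _, rows = _load_split(manifest, split, config.input_size)

    def predict_fn(image):
        return est.predict_proba(image[None])[0]

    samples = [(X[i], y[i], rows.loc[i, "size_class"])
               for i in range(len(rows))]
    reports = evaluate(predict_fn, samples, threshold=thr, average=average)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reports(reports, json_path=out / f"metrics_{split}.json",
                      csv_path=out / f"metrics_{split}.csv")
    return reports
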