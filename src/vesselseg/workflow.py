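"""Training loop, inference and evaluation — the runnable surface.

The default :class:`TrainConfig` is the training protocol of the method:
4000 random 64x64 patches from the (augmented) training split, Adam at
learning rate 0.0005, batch size 64, 50 epochs, composite loss with
equilibrium coefficients [beta, a1..a4] = [0.1, 1, 0.2, 0.2, 0.2], constant
learning rate, no early stopping, final-epoch checkpoint.  Every run
writes a line-oriented JSON log that starts with a reproducibility block
(config, seed, package version, data fingerprint) and records per-step
component losses.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import __version__, data, losses, metrics, nn
from .model import PRESETS, TriplePathNet, build_model
from .paths import DEFAULT_WIDTHS


@dataclass
class TrainConfig:
    dataset_root: str = ""
    layout: str = "flat"
    preset: str = "tp-unet+ae+dsl"
    widths: tuple[int, int, int, int] = DEFAULT_WIDTHS
    coeffs: losses.EquilibriumCoefficients = field(default_factory=losses.EquilibriumCoefficients)
    learning_rate: float = 0.0005
    batch_size: int = 64
    epochs: int = 50
    n_patches: int = 4000
    patch_size: int = 64
    augment: bool = True
    seed: int = 0
    checkpoint: str = "model.npz"
    log_path: str | None = None
    validation_frac: float = 0.0  # opt-in validation split of the patch set

    def validate(self) -> None:
        for name in ("learning_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("batch_size", "epochs", "n_patches", "patch_size"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be at least 1, got {getattr(self, name)}")
        if self.patch_size % 8:
            raise ValueError(f"patch_size must be a multiple of 8, got {self.patch_size}")
        if not 0.0 <= self.validation_frac < 1.0:
            raise ValueError(f"validation_frac must lie in [0,1), got {self.validation_frac}")
        if self.preset.lower() not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")


class _JsonLog:
    def __init__(self, path: str | None):
        self.path = Path(path) if path else None
        self.lines: list[dict] = []
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def write(self, record: dict) -> None:
        self.lines.append(record)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(record) + "\n")


def _fingerprint(imgs: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(imgs).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()[:16]


def train(config: TrainConfig, records: list[data.FundusRecord] | None = None
          ) -> tuple[TriplePathNet, list[dict]]:
    """Run the training protocol; returns the model and the log records.

    ``records`` overrides dataset loading (useful for in-memory synthetic
    data); otherwise the training split of ``dataset_root`` is used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if records is None:
        ds = data.load_dataset(config.dataset_root, config.layout)
        records = ds.train or ds.records
    if config.augment:
        records = data.augment(records, seed=config.seed)
    patchset = data.extract_patches(
        records, n=config.n_patches, size=config.patch_size, seed=config.seed
    )
    imgs, labels = patchset.arrays()

    n_val = int(round(config.validation_frac * len(imgs)))
    val_imgs, val_labels = imgs[:n_val], labels[:n_val]
    imgs, labels = imgs[n_val:], labels[n_val:]

    model = build_model(preset=config.preset, widths=config.widths, seed=config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    log = _JsonLog(config.log_path)
    log.write({
        "event": "start", "config": _config_dict(config), "version": __version__,
        "n_patches_train": len(imgs), "n_patches_val": n_val,
        "data_fingerprint": _fingerprint(imgs, labels),
        "n_parameters": sum(p.data.size for p in model.parameters()),
    })

    step = 0
    n = len(imgs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            x = nn.Tensor(imgs[idx])
            out = model(x)
            bd = losses.total_loss(x, out, labels[idx], config.coeffs)
            val = float(bd.total)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step} "
                    f"(patch indices {idx.tolist()[:8]}...)"
                )
            opt.zero_grad()
            bd.total.backward()
            opt.step()
            step += 1
            rec = {"event": "step", "epoch": epoch, "step": step, **bd.as_floats()}
            epoch_losses.append(val)
            log.write(rec)
        summary = {"event": "epoch", "epoch": epoch,
                   "mean_loss": float(np.mean(epoch_losses)), "time": time.time()}
        if n_val:
            summary["val_dice"] = _patch_dice(model, val_imgs, val_labels)
        log.write(summary)

    model.eval()
    if config.checkpoint:
        Path(config.checkpoint).parent.mkdir(parents=True, exist_ok=True)
        model.save(config.checkpoint)
        log.write({"event": "checkpoint", "path": str(config.checkpoint)})
    return model, log.lines


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["widths"] = list(d["widths"])
    d["coeffs"]["alpha"] = list(d["coeffs"]["alpha"])
    return d


def _patch_dice(model: TriplePathNet, imgs: np.ndarray, labels: np.ndarray) -> float | None:
    counts = metrics.ConfusionCounts()
    for lo in range(0, len(imgs), 16):
        prob = model.predict(imgs[lo : lo + 16])
        pred = metrics.binarize(prob)
        counts = counts + metrics.confusion(pred, labels[lo : lo + 16])
    return metrics.compute_metrics(counts).dice


def predict_files(checkpoint, inputs: list, out_dir, threshold: float = 0.5) -> list[Path]:
    """Segment raster files: write probability and mask PNGs per input.

    Probabilities are encoded as 8-bit ([0,1] -> [0,255]), masks as 0/255.
    Per-file failures are reported and skipped; processing continues.
    """
    model = TriplePathNet.load(checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for path in map(Path, inputs):
        try:
            image = data._read_raster(path)
            gray = data.preprocess_image(image)
            padded, spec = data.pad_for_inference(gray)
            prob = data.crop_to(model.predict(padded[None, None])[0], spec)
        except Exception as exc:
            print(f"error: {path}: {exc}")
            continue
        prob_path = out_dir / f"{path.stem}_prob.png"
        mask_path = out_dir / f"{path.stem}_mask.png"
        iio.imwrite(prob_path, np.clip(prob * 255, 0, 255).astype(np.uint8))
        iio.imwrite(mask_path, (metrics.binarize(prob, threshold) * 255).astype(np.uint8))
        written += [prob_path, mask_path]
    return written


def evaluate_checkpoint(checkpoint, dataset_root, layout: str = "flat",
                        split: str = "test", roi: str | None = None,
                        gt: str = "label", threshold: float = 0.5,
                        report_path=None) -> metrics.MetricsReport:
    """Score a checkpoint on a dataset split; optionally write the CSV report."""
    model = TriplePathNet.load(checkpoint)
    ds = data.load_dataset(dataset_root, layout)
    records = {"train": ds.train, "test": ds.test, "all": ds.records}[split]
    if not records:
        records = ds.records
    report = metrics.evaluate_set(model, records, threshold=threshold, roi=roi, gt=gt)
    if report_path:
        metrics.write_report(report_path, report)
    return report
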