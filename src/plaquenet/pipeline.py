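"""Training, prediction and evaluation orchestration.

Everything here is deterministic given ``RunConfig.seed``: parameter
initialization, batch shuffling and (optional) augmentation all draw
from generators derived from it.  Each run persists its resolved
configuration, a JSONL step/epoch log, checkpoints (flat named-tensor
``.npz`` archives with the config hash embedded alongside) and a JSON
run record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .binet import joint_loss
from .config import RunConfig
from .exceptions import DataError, ShapeError
from .metrics import MetricsReport, confusion, macro_report, micro_report
from .model import PlaqueNet, build_model
from .nn import Adam
from .synthetic import load_manifest

__all__ = ["RunRecord", "train", "predict", "evaluate", "load_checkpoint",
           "save_checkpoint", "load_image", "load_mask"]


# ---------------------------------------------------------------------
# data access
# ---------------------------------------------------------------------

def load_image(path, normalize: str = "minmax") -> np.ndarray:
    """Read a grayscale PNG/TIFF into a (1, H, W) float array in [0,1]."""
    arr = np.asarray(Image.open(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if normalize == "minmax":
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    elif normalize == "none":
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    else:
        raise DataError(f"unknown normalization {normalize!r}")
    return arr[None]


def load_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.int64)


class ManifestDataset:
    """Image/mask pairs for one split of a generated manifest."""

    def __init__(self, manifest_path, split: str, normalize: str = "minmax"):
        self.root = Path(manifest_path).parent
        self.rows = [r for r in load_manifest(manifest_path)
                     if r["split"] == split]
        self.normalize = normalize
        missing = [r["id"] for r in self.rows
                   if not (self.root / r["mask"]).exists()]
        if missing:
            raise DataError(f"missing mask files for ids: {missing}")

    def __len__(self):
        return len(self.rows)

    def item(self, i: int):
        row = self.rows[i]
        return (load_image(self.root / row["image"], self.normalize),
                load_mask(self.root / row["mask"]))

    def batch(self, indices):
        images, masks = zip(*(self.item(i) for i in indices))
        return np.stack(images), np.stack(masks)


def _augment_batch(images, masks, rng):
    out_i, out_m = [], []
    for img, msk in zip(images, masks):
        k = int(rng.integers(0, 4))
        img, msk = np.rot90(img, k, axes=(1, 2)), np.rot90(msk, k)
        if rng.random() < 0.5:
            img, msk = img[:, :, ::-1], msk[:, ::-1]
        out_i.append(img.copy())
        out_m.append(msk.copy())
    return np.stack(out_i), np.stack(out_m)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(path, model: PlaqueNet, config: RunConfig) -> Path:
    path = Path(path)
    np.savez(path, **model.state_dict())
    meta = {"config": config.to_dict(), "config_hash": config.config_hash()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_checkpoint(path) -> tuple[PlaqueNet, RunConfig]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    config = RunConfig.from_dict(meta["config"])
    if config.config_hash() != meta["config_hash"]:
        raise DataError("checkpoint metadata hash mismatch")
    model = build_model(config)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model, config


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

@dataclass
class RunRecord:
    """Per-epoch loss and validation-metric history of one run."""

    config_hash: str
    epochs: list = field(default_factory=list)
    best_epoch: int = -1
    best_dice: float = -1.0
    best_checkpoint: str = ""
    last_checkpoint: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _class_weights(dataset: ManifestDataset, n_classes: int) -> np.ndarray:
    counts = np.zeros(n_classes)
    for i in range(len(dataset)):
        _, mask = dataset.item(i)
        counts += np.bincount(mask.ravel(), minlength=n_classes)
    counts = np.maximum(counts, 1.0)
    return counts.sum() / (n_classes * counts)


def _evaluate_model(model: PlaqueNet, dataset: ManifestDataset,
                    batch_size: int, n_classes: int):
    counts = []
    for start in range(0, len(dataset), batch_size):
        idx = range(start, min(start + batch_size, len(dataset)))
        images, masks = dataset.batch(idx)
        preds = model.predict(images)
        counts.extend(confusion(p, m, n_classes) for p, m in zip(preds, masks))
    return counts


def _save_train_state(out: Path, opt: Adam, rng, next_epoch: int) -> None:
    arrays = {f"m_{i}": m for i, m in enumerate(opt.m)}
    arrays.update({f"v_{i}": v for i, v in enumerate(opt.v)})
    np.savez(out / "train_state.npz", **arrays)
    (out / "train_state.json").write_text(json.dumps({
        "t": opt.t, "next_epoch": next_epoch,
        "rng_state": rng.bit_generator.state,
    }))


def _load_train_state(resume_dir: Path, opt: Adam, rng) -> int:
    meta = json.loads((resume_dir / "train_state.json").read_text())
    with np.load(resume_dir / "train_state.npz") as archive:
        opt.m = [archive[f"m_{i}"] for i in range(len(opt.params))]
        opt.v = [archive[f"v_{i}"] for i in range(len(opt.params))]
    opt.t = meta["t"]
    rng.bit_generator.state = meta["rng_state"]
    return meta["next_epoch"]


def train(config: RunConfig, manifest_path, out_dir,
          quiet: bool = True, resume_from=None) -> RunRecord:
    """Optimize the joint loss on the manifest's train split and score
    the test split after every epoch; returns the run record.

    ``resume_from`` names a previous run directory whose ``last``
    checkpoint and optimizer/shuffle state are restored, continuing the
    interrupted run deterministically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_set = ManifestDataset(manifest_path, "train", config.normalize)
    val_set = ManifestDataset(manifest_path, "test", config.normalize)
    if len(train_set) == 0:
        raise DataError("manifest has no train rows; cannot train")

    config.to_yaml(out / "config.yaml")
    model = build_model(config)
    opt = Adam(model.parameters(), lr=config.optimizer.learning_rate,
               weight_decay=config.optimizer.weight_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1])
    )
    start_epoch = 0
    if resume_from is not None:
        resume_dir = Path(resume_from)
        model, _ = load_checkpoint(resume_dir / "last.npz")
        opt = Adam(model.parameters(), lr=config.optimizer.learning_rate,
                   weight_decay=config.optimizer.weight_decay)
        start_epoch = _load_train_state(resume_dir, opt, shuffle_rng)
    weights = (_class_weights(train_set, config.n_classes)
               if config.class_weighting else None)
    record = RunRecord(config_hash=config.config_hash())
    use_aux = config.binet.enabled
    log_path = out / "log.jsonl"

    with open(log_path, "w") as log:
        for epoch in range(start_epoch, config.epochs):
            if config.optimizer.cosine_decay:
                opt.lr = config.optimizer.learning_rate * 0.5 * (
                    1 + np.cos(np.pi * epoch / max(config.epochs, 1))
                )
            order = shuffle_rng.permutation(len(train_set))
            model.train()
            losses = []
            for start in range(0, len(order), config.batch_size):
                batch_idx = order[start:start + config.batch_size]
                images, masks = train_set.batch(batch_idx)
                if config.augment:
                    images, masks = _augment_batch(images, masks, shuffle_rng)
                main, aux = model.forward_logits(images, with_aux=use_aux)
                bundle = joint_loss(main, aux, masks,
                                    config.binet.aux_weight, weights)
                if not np.isfinite(bundle.total_loss):
                    pnorm = float(np.sqrt(sum(
                        (p.data ** 2).sum() for p in model.parameters())))
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch ids "
                        f"{batch_idx.tolist()}; parameter norm {pnorm:.3g}"
                    )
                opt.zero_grad()
                bundle.graph.backward()
                opt.step()
                losses.append(bundle.as_dict())
                log.write(json.dumps({"epoch": epoch, "step": start //
                                      config.batch_size, **bundle.as_dict()})
                          + "\n")

            model.eval()
            counts = _evaluate_model(model, val_set, config.batch_size,
                                     config.n_classes)
            report = micro_report(counts) if counts else None
            mean_losses = {k: float(np.mean([l[k] for l in losses]))
                           for k in losses[0]}
            entry = {"epoch": epoch, "train_loss": mean_losses,
                     "val_metrics": report.as_dict() if report else None}
            record.epochs.append(entry)
            log.write(json.dumps({"epoch_summary": entry}) + "\n")
            if not quiet:
                msg = f"epoch {epoch}: loss {mean_losses['total_loss']:.4f}"
                if report:
                    msg += f"  val {report.format_percent()}"
                print(msg)

            record.last_checkpoint = str(save_checkpoint(out / "last.npz",
                                                         model, config))
            _save_train_state(out, opt, shuffle_rng, epoch + 1)
            if report and report.dice > record.best_dice:
                record.best_dice = report.dice
                record.best_epoch = epoch
                record.best_checkpoint = str(save_checkpoint(out / "best.npz",
                                                             model, config))
    record.to_json(out / "run_record.json")
    return record


# ---------------------------------------------------------------------
# inference & evaluation
# ---------------------------------------------------------------------

def _pad_to_stride(image: np.ndarray, stride: int):
    _, h, w = image.shape
    ph = (stride - h % stride) % stride
    pw = (stride - w % stride) % stride
    if ph or pw:
        image = np.pad(image, ((0, 0), (0, ph), (0, pw)), mode="edge")
    return image, (h, w)


def predict(checkpoint_path, image_paths, out_dir) -> list[Path]:
    """Write an argmax mask PNG ({0,255}) per input image."""
    model, config = load_checkpoint(checkpoint_path)
    stride = config.backbone.total_stride
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for path in map(Path, image_paths):
        image = load_image(path, config.normalize)
        padded, (h, w) = _pad_to_stride(image, stride)
        mask = model.predict(padded[None])[0][:h, :w]
        dest = out / f"{path.stem}_mask.png"
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(dest)
        written.append(dest)
    return written


def evaluate(checkpoint_path, manifest_path, split: str = "test",
             out_dir=None) -> dict:
    """Micro and macro metric reports for one manifest split."""
    model, config = load_checkpoint(checkpoint_path)
    dataset = ManifestDataset(manifest_path, split, config.normalize)
    if len(dataset) == 0:
        raise DataError(f"manifest has no rows for split {split!r}")
    counts = _evaluate_model(model, dataset, config.batch_size,
                             config.n_classes)
    result = {
        "split": split,
        "n_images": len(dataset),
        "micro": micro_report(counts).as_dict(percent=True),
        "macro": macro_report(counts).as_dict(percent=True),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"metrics_{split}.json").write_text(
            json.dumps(result, indent=2))
        keys = MetricsReport.SCALARS
        lines = ["aggregation," + ",".join(keys)]
        for agg in ("micro", "macro"):
            lines.append(agg + "," + ",".join(
                f"{result[agg][k]:.2f}" for k in keys))
        (out / f"metrics_{split}.csv").write_text("\n".join(lines) + "\n")
    return result
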