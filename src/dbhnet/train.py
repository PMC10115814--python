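"""Training, evaluation and prediction loops.

Training is fully seeded (initialization, data order) and optimizes the
weighted three-head loss for the dual-branch model or plain pixel
cross-entropy for single-output variants, with Adam (lr 1e-3, weight decay
1e-4, no schedule).  The checkpoint with the best validation Dice is kept;
checkpoints are ``.npz`` state dicts with a JSON sidecar recording variant,
config and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import DEFAULTS, load_config, model_from_config
from .data import SamplePair, load_pair, to_batch, write_mask
from .losses import LossWeights, pixel_ce, total_loss
from .metrics import (aggregate_reports, confusion, metrics_from_counts,
                      write_report_csv)
from .nn import Tensor


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1.0e-3
    weight_decay: float = 1.0e-4
    image_size: int = 224
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = {**DEFAULTS["train"], **d}
        lw = d.pop("loss_weights")
        if not isinstance(lw, LossWeights):
            lw = LossWeights(*lw)
        return cls(**{k: d[k] for k in
                      ("epochs", "batch_size", "learning_rate",
                       "weight_decay", "image_size", "seed")},
                   loss_weights=lw)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _model_loss(model: nn.Module, images: np.ndarray, masks: np.ndarray,
                weights: LossWeights) -> Tensor:
    out = model(Tensor(images))
    if isinstance(out, tuple):
        m_ff, m_st, m_u = out
        return total_loss(pixel_ce(m_ff, masks), pixel_ce(m_st, masks),
                          pixel_ce(m_u, masks), weights)
    return pixel_ce(out, masks)


def _predict_mask(model: nn.Module, images: np.ndarray) -> np.ndarray:
    with nn.no_grad():
        out = model(Tensor(images))
    logits = out[0] if isinstance(out, tuple) else out
    return logits.data.argmax(axis=1).astype(np.uint8)


def batch_dice(model: nn.Module, images: np.ndarray,
               masks: np.ndarray) -> float:
    """Mean per-image Dice of argmax predictions against the masks."""
    was_training = model.training
    model.eval()
    pred = _predict_mask(model, images)
    if was_training:
        model.train()
    scores = [metrics_from_counts(confusion(p, g)).dice
              for p, g in zip(pred, masks)]
    return float(np.mean(scores))


def fit_batch(model: nn.Module, images: np.ndarray, masks: np.ndarray,
              steps: int, lr: float = 1.0e-3, weight_decay: float = 0.0,
              weights: LossWeights = LossWeights(),
              target_dice: float | None = None) -> dict:
    """Optimize one fixed batch for up to ``steps`` steps (overfit probe).

    Returns the loss trajectory and final/best train Dice.  Used to verify
    end-to-end gradient flow: a correctly wired model must be able to
    memorize a handful of images.
    """
    opt = nn.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    losses: list[float] = []
    dice = 0.0
    model.train()
    for step in range(steps):
        opt.zero_grad()
        loss = _model_loss(model, images, masks, weights)
        value = loss.item()
        if not np.isfinite(value):
            raise DivergenceError(f"loss became {value} at step {step}")
        losses.append(value)
        loss.backward()
        opt.step()
        if target_dice is not None and (step + 1) % 10 == 0:
            dice = batch_dice(model, images, masks)
            if dice >= target_dice:
                break
    dice = max(dice, batch_dice(model, images, masks))
    return {"losses": losses, "dice": dice, "steps": len(losses)}


# ------------------------------------------------------------ full training
class ManifestDataset:
    """Pairs listed in a dataset manifest, resized to the training size."""

    def __init__(self, data_dir: str | Path, split: str, image_size: int):
        self.root = Path(data_dir)
        manifest = json.loads((self.root / "manifest.json").read_text())
        self.names = manifest["splits"][split]
        self.image_size = image_size

    def __len__(self) -> int:
        return len(self.names)

    def pair(self, i: int) -> SamplePair:
        name = self.names[i]
        return load_pair(self.root / "images" / f"{name}.png",
                         self.root / "masks" / f"{name}.png",
                         self.image_size)

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        order = np.arange(len(self))
        if rng is not None:
            rng.shuffle(order)
        for lo in range(0, len(order), batch_size):
            pairs = [self.pair(i) for i in order[lo:lo + batch_size]]
            yield to_batch(pairs)


def save_checkpoint(model: nn.Module, path: str | Path,
                    meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path):
    """Rebuild the model recorded in a checkpoint's JSON sidecar."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = model_from_config(meta["variant"], meta["config"],
                              seed=meta.get("seed", 0))
    state = dict(np.load(path if path.suffix == ".npz"
                         else path.with_suffix(".npz")))
    model.load_state_dict(state)
    return model, meta


def train(data_dir: str | Path, variant: str, out_dir: str | Path,
          cfg: dict | None = None, log=print) -> dict:
    """End-to-end training from a dataset manifest; keeps the best-val model."""
    if cfg is None or "model" not in cfg:
        cfg = load_config(overrides=cfg)
    tc = TrainConfig.from_dict(cfg["train"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = model_from_config(variant, cfg, seed=tc.seed)
    train_set = ManifestDataset(data_dir, "train", tc.image_size)
    try:
        val_set = ManifestDataset(data_dir, "val", tc.image_size)
        has_val = len(val_set) > 0
    except KeyError:
        has_val = False
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate,
                  weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)

    history = []
    best = {"epoch": -1, "val_dice": -1.0}
    ckpt = out_dir / "best.npz"
    for epoch in range(tc.epochs):
        t0 = time.time()
        model.train()
        losses = []
        for images, masks in train_set.batches(tc.batch_size, rng):
            opt.zero_grad()
            loss = _model_loss(model, images, masks, tc.loss_weights)
            value = loss.item()
            if not np.isfinite(value):
                raise DivergenceError(
                    f"loss became {value} in epoch {epoch}")
            losses.append(value)
            loss.backward()
            opt.step()
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "seconds": round(time.time() - t0, 2)}
        if has_val:
            dices, vlosses = [], []
            model.eval()
            for images, masks in val_set.batches(tc.batch_size):
                vlosses.append(
                    _model_loss(model, images, masks,
                                tc.loss_weights).item())
                pred = _predict_mask(model, images)
                dices += [metrics_from_counts(confusion(p, g)).dice
                          for p, g in zip(pred, masks)]
            record["val_loss"] = float(np.mean(vlosses))
            record["val_dice"] = float(np.mean(dices))
        else:
            record["val_dice"] = -np.inf
        history.append(record)
        log(f"epoch {epoch}: train loss {record['train_loss']:.4f}"
            + (f", val dice {record['val_dice']:.4f}" if has_val else ""))
        if not has_val or record["val_dice"] >= best["val_dice"]:
            best = {"epoch": epoch, "val_dice": record["val_dice"]}
            save_checkpoint(model, ckpt, {
                "variant": variant, "config": cfg, "seed": tc.seed,
                "epoch": epoch, "val_dice": record["val_dice"]})
    (out_dir / "history.json").write_text(json.dumps(history, indent=2))
    return {"history": history, "best": best, "checkpoint": str(ckpt)}


def evaluate(checkpoint: str | Path, data_dir: str | Path,
             out_csv: str | Path | None = None, split: str = "test",
             log=print) -> dict:
    """Per-image metric rows plus the aggregate summary on one split."""
    model, meta = load_checkpoint(checkpoint)
    image_size = meta["config"]["train"]["image_size"]
    dataset = ManifestDataset(data_dir, split, image_size)
    model.eval()
    names, counts, reports = [], [], []
    for i in range(len(dataset)):
        try:
            pair = dataset.pair(i)
        except ValueError as exc:
            log(f"skipping {dataset.names[i]}: {exc}")
            continue
        images, masks = to_batch([pair])
        pred = _predict_mask(model, images)[0]
        c = confusion(pred, masks[0])
        names.append(dataset.names[i])
        counts.append(c)
        reports.append(metrics_from_counts(c))
    summary = aggregate_reports(reports)
    if out_csv is not None:
        write_report_csv(out_csv, names, counts, reports)
    return summary


def overlay(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Red = ground truth only, yellow = prediction only, green = both."""
    h, w = pred.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    both = (pred == 1) & (truth == 1)
    only_truth = (truth == 1) & ~both
    only_pred = (pred == 1) & ~both
    img[only_truth] = (255, 0, 0)
    img[only_pred] = (255, 255, 0)
    img[both] = (0, 255, 0)
    return img


def predict(checkpoint: str | Path, image_path: str | Path,
            out_path: str | Path,
            mask_path: str | Path | None = None) -> np.ndarray:
    """Segment one image; writes the mask PNG (and an overlay if GT given)."""
    from .data import read_image, read_mask, resize_pair, normalize

    model, meta = load_checkpoint(checkpoint)
    size = meta["config"]["train"]["image_size"]
    image = read_image(image_path)
    pair = SamplePair(image, np.zeros(image.shape[:2], np.uint8))
    pair = resize_pair(pair, size)
    model.eval()
    pred = _predict_mask(model, normalize(pair.image)[None])[0]
    write_mask(out_path, pred)
    if mask_path is not None:
        truth = read_mask(mask_path)
        if truth.shape != pred.shape:
            truth = resize_pair(SamplePair(
                np.zeros((*truth.shape, 3), np.uint8), truth), size).mask
        from .data import write_image
        out = Path(out_path)
        write_image(out.with_name(out.stem + "_overlay.png"),
                    overlay(pred, truth))
    return pred
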