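"""Seeded generator of endoscopy-like image/mask pairs.

Real gastric endoscopy frames show a reddish-pink mucosa with smooth
illumination gradients, quasi-periodic fold structure and sensor speckle;
lesions appear as one or more smooth, irregularly-outlined blobs whose color
and texture differ from the surrounding tissue.  The generator emulates that
coarse structure — a low-frequency color field plus a sinusoidal fold
pattern plus speckle noise, with star-convex lesion blobs whose boundary
radius is modulated by a few random harmonics — and returns the *exact*
rasterized lesion support as the ground-truth mask.  It makes no attempt to
match the appearance statistics of real tissue beyond this.

Identical seeds produce bitwise-identical pairs, which is what makes every
downstream training/evaluation test reproducible without any download.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import AugmentConfig, SamplePair, augment, write_image, write_mask


class GenerationError(RuntimeError):
    """Raised when the area constraints cannot be satisfied."""


@dataclass(frozen=True)
class SyntheticConfig:
    image_size: int = 224
    n_lesions: tuple[int, int] = (1, 3)
    lesion_area_fraction: tuple[float, float] = (0.02, 0.35)
    fold_frequency: tuple[float, float] = (2.0, 5.0)
    fold_amplitude: float = 0.08
    mucosa_color: tuple[float, float, float] = (0.80, 0.45, 0.40)
    lesion_color: tuple[float, float, float] = (0.55, 0.25, 0.30)
    color_jitter: float = 0.10
    noise_level: float = 0.03
    max_retries: int = 25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(
                f"lesion_area_fraction {self.lesion_area_fraction} must lie "
                "in (0,1) with lo <= hi")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")


def _smooth_field(rng: np.random.Generator, size: int, grid: int = 6,
                  amplitude: float = 1.0) -> np.ndarray:
    """Low-frequency random field in [-amplitude, amplitude]."""
    coarse = rng.uniform(-1.0, 1.0, (grid, grid))
    zoomed = ndimage.zoom(coarse, size / grid, order=3)[:size, :size]
    return zoomed * amplitude


def _lesion_mask(rng: np.random.Generator, size: int,
                 area_fraction: float) -> np.ndarray:
    """Star-convex blob with harmonically perturbed radius; exact raster."""
    r0 = np.sqrt(area_fraction * size * size / np.pi)
    cy = rng.uniform(0.25 * size, 0.75 * size)
    cx = rng.uniform(0.25 * size, 0.75 * size)
    n_harm = rng.integers(2, 6)
    amps = rng.uniform(0.03, 0.18, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    radius = r0 * (1.0 + sum(a * np.cos((k + 1) * theta + p)
                             for k, (a, p) in enumerate(zip(amps, phases))))
    dist = np.hypot(yy - cy, xx - cx)
    return (dist <= radius).astype(np.uint8)


def generate_sample(cfg: SyntheticConfig, seed: int) -> SamplePair:
    """One seeded image/mask pair obeying the configured area constraints."""
    rng = np.random.default_rng((cfg.seed, seed))
    size = cfg.image_size
    lo, hi = cfg.lesion_area_fraction
    n_lesions = int(rng.integers(cfg.n_lesions[0], cfg.n_lesions[1] + 1))

    mask = np.zeros((size, size), dtype=np.uint8)
    if n_lesions > 0:
        for attempt in range(cfg.max_retries + 1):
            mask[:] = 0
            targets = rng.uniform(lo / n_lesions, hi / n_lesions, n_lesions)
            for t in targets:
                mask |= _lesion_mask(rng, size, t)
            frac = mask.mean()
            if lo <= frac <= hi:
                break
        else:
            raise GenerationError(
                f"could not satisfy lesion area fraction in [{lo}, {hi}] "
                f"after {cfg.max_retries} retries")

    # mucosa background: smooth color field + folds + speckle
    img = np.empty((size, size, 3), dtype=np.float64)
    for c in range(3):
        img[..., c] = cfg.mucosa_color[c] + _smooth_field(
            rng, size, amplitude=cfg.color_jitter)
    theta = rng.uniform(0, np.pi)
    freq = rng.uniform(*cfg.fold_frequency)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size] / size
    folds = np.sin(2 * np.pi * freq * (xx * np.cos(theta) +
                                       yy * np.sin(theta)) + phase)
    img += cfg.fold_amplitude * folds[..., None]

    # lesion appearance: shifted color + finer texture, blended at the rim
    lesion = np.empty_like(img)
    for c in range(3):
        lesion[..., c] = cfg.lesion_color[c] + _smooth_field(
            rng, size, grid=10, amplitude=cfg.color_jitter)
    texture = _smooth_field(rng, size, grid=20, amplitude=0.05)
    lesion += texture[..., None]
    blend = ndimage.gaussian_filter(mask.astype(np.float64), sigma=2.0)
    img = img * (1.0 - blend[..., None]) + lesion * blend[..., None]

    img += rng.normal(0.0, cfg.noise_level, img.shape)
    img = (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    return SamplePair(img, mask)


# -------------------------------------------------------------- on-disk set
def build_dataset(cfg: SyntheticConfig, n_train: int, n_test: int,
                  out_dir: str | Path, aug_factor: int = 4,
                  val_fraction: float = 0.05,
                  aug_cfg: AugmentConfig = AugmentConfig()) -> dict:
    """Write a PNG dataset with train/val/test splits and a JSON manifest.

    ``n_train`` originals are augmented ``aug_factor - 1`` times each (the
    original is kept), and ``val_fraction`` of the augmented training pool is
    carved off for validation.  Test images are held out un-augmented.
    Re-running with the same config reproduces identical files.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    names: list[str] = []
    for i in range(n_train):
        base = generate_sample(cfg, i)
        variants = [base] + [
            augment(base, int(np.random.default_rng(
                (cfg.seed, i, j)).integers(2 ** 31)), aug_cfg)
            for j in range(1, aug_factor)]
        for j, pair in enumerate(variants):
            name = f"train_{i:04d}_{j}"
            write_image(img_dir / f"{name}.png", pair.image)
            write_mask(mask_dir / f"{name}.png", pair.mask)
            names.append(name)

    rng = np.random.default_rng((cfg.seed, 4711))
    perm = rng.permutation(len(names))
    n_val = int(round(val_fraction * len(names)))
    val = sorted(names[k] for k in perm[:n_val])
    train = sorted(names[k] for k in perm[n_val:])

    test = []
    for i in range(n_test):
        pair = generate_sample(cfg, n_train + i)
        name = f"test_{i:04d}"
        write_image(img_dir / f"{name}.png", pair.image)
        write_mask(mask_dir / f"{name}.png", pair.mask)
        test.append(name)

    manifest = {
        "config": asdict(cfg),
        "augment": asdict(aug_cfg),
        "aug_factor": aug_factor,
        "splits": {"train": train, "val": val, "test": test},
    }
    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["hash"] = hashlib.sha256(blob).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
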