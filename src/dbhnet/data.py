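"""Image/mask I/O, normalization and the augmentation pipeline.

Images are 8-bit RGB PNG/JPEG; masks are single-channel PNG with 0 =
background and 255 = lesion (mapped to {0,1} in memory).  Augmentation
follows the usual endoscopy recipe: horizontal/vertical flips, rotation by
an arbitrary angle, panning and zooming applied identically to image and
mask (nearest-neighbour resampling for the mask so it stays binary), and
hue/saturation/brightness jitter applied to the image only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

# ImageNet statistics, the convention the pretrained attention branch expects
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class SamplePair:
    """An RGB image (uint8, H×W×3) with its binary lesion mask (H×W)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "spatial sizes differ")
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError("mask must be binary {0,1}")


# ------------------------------------------------------------------ file IO
def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(image.astype(np.uint8)).save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((mask.astype(np.uint8) * 255)).save(path)


def normalize(image: np.ndarray) -> np.ndarray:
    """uint8 H×W×3 -> float32 CHW, ImageNet-normalized."""
    x = image.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def to_batch(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([normalize(p.image) for p in pairs])
    masks = np.stack([p.mask for p in pairs]).astype(np.int64)
    return images, masks


def resize_pair(pair: SamplePair, size: int) -> SamplePair:
    img = np.asarray(Image.fromarray(pair.image).resize(
        (size, size), Image.BILINEAR))
    msk = np.asarray(Image.fromarray(pair.mask * 255).resize(
        (size, size), Image.NEAREST))
    return SamplePair(img, (msk > 127).astype(np.uint8))


# ------------------------------------------------------------ augmentation
@dataclass(frozen=True)
class AugmentConfig:
    p_flip: float = 0.5
    max_shift: float = 0.1        # fraction of the image size
    zoom_range: tuple[float, float] = (0.85, 1.15)
    hue_shift: float = 0.03       # fraction of the hue circle
    sat_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (0.8, 1.2)


def augment(pair: SamplePair, seed: int,
            cfg: AugmentConfig = AugmentConfig()) -> SamplePair:
    """Seeded geometric + photometric augmentation of one pair."""
    rng = np.random.default_rng(seed)
    img = pair.image.astype(np.float32) / 255.0
    msk = pair.mask.astype(np.float32)

    if rng.random() < cfg.p_flip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < cfg.p_flip:
        img, msk = img[::-1], msk[::-1]

    angle = rng.uniform(0.0, 360.0)
    img = sktransform.rotate(img, angle, order=1, mode="reflect")
    msk = sktransform.rotate(msk, angle, order=0, mode="constant", cval=0)

    h, w = msk.shape
    shift = rng.uniform(-cfg.max_shift, cfg.max_shift, 2) * (h, w)
    img = ndimage.shift(img, (*shift, 0), order=1, mode="reflect")
    msk = ndimage.shift(msk, shift, order=0, mode="constant", cval=0)

    zoom = rng.uniform(*cfg.zoom_range)
    center = sktransform.AffineTransform(translation=(-w / 2, -h / 2))
    warp = center + sktransform.AffineTransform(scale=zoom) + \
        sktransform.AffineTransform(translation=(w / 2, h / 2))
    img = sktransform.warp(img, warp.inverse, order=1, mode="reflect")
    msk = sktransform.warp(msk, warp.inverse, order=0, mode="constant",
                           cval=0)

    hsv = skcolor.rgb2hsv(np.clip(img, 0, 1))
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue_shift,
                                             cfg.hue_shift)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*cfg.sat_range), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(*cfg.brightness_range),
                          0, 1)
    img = skcolor.hsv2rgb(hsv)

    return SamplePair((np.clip(img, 0, 1) * 255).astype(np.uint8),
                      (msk > 0.5).astype(np.uint8))


# ----------------------------------------------------------------- labelme
def labelme_to_mask(annotation: dict | str | Path,
                    shape: tuple[int, int] | None = None) -> np.ndarray:
    """Convert a Labelme-style polygon annotation to a binary mask.

    Accepts the parsed dict or a path to the JSON file.  All polygon shapes
    are rasterized and unioned; ``shape`` overrides the recorded image size.
    """
    from skimage.draw import polygon as draw_polygon

    if not isinstance(annotation, dict):
        annotation = json.loads(Path(annotation).read_text())
    if shape is None:
        shape = (annotation["imageHeight"], annotation["imageWidth"])
    mask = np.zeros(shape, dtype=np.uint8)
    for item in annotation.get("shapes", []):
        if item.get("shape_type", "polygon") != "polygon":
            continue
        pts = np.asarray(item["points"], dtype=float)
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        mask[rr, cc] = 1
    return mask


# ------------------------------------------------------------ folder reads
def find_pairs(root: str | Path) -> list[tuple[Path, Path]]:
    """Discover (image, mask) pairs in an ``images/`` + ``masks/`` layout.

    Matches by stem, so Kvasir-SEG / CVC-ClinicDB style folders (after PNG
    conversion) load directly.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(
            f"expected {img_dir} and {mask_dir} directories")
    masks = {p.stem: p for ext in ("*.png", "*.jpg", "*.jpeg")
             for p in mask_dir.glob(ext)}
    pairs = []
    for ext in ("*.png", "*.jpg", "*.jpeg"):
        for img in sorted(img_dir.glob(ext)):
            if img.stem in masks:
                pairs.append((img, masks[img.stem]))
    return pairs


def load_pair(image_path: str | Path, mask_path: str | Path,
              size: int | None = None) -> SamplePair:
    pair = SamplePair(read_image(image_path), read_mask(mask_path))
    if size is not None and pair.mask.shape != (size, size):
        pair = resize_pair(pair, size)
    return pair
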