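"""Stochastic two-view augmentation for siamese pre-training.

Each source frame is augmented twice, independently, to produce the pair
of views whose representations the siamese objective pulls together.  The
pipeline is the SimSiam-lineage recipe: random resized crop, horizontal
flip, colour jitter, random grayscale, Gaussian blur, then per-channel
normalisation.  Everything is driven by an explicit
:class:`numpy.random.Generator`, so a fixed seed reproduces the views
bit-for-bit.

Images are float arrays in ``(batch, 3, H, W)`` layout with values in
``[0, 1]`` before normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

# ImageNet statistics; the backbone is typically ImageNet-initialised.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class AugmentationConfig:
    """Parameters of the two-view augmentation pipeline.

    Defaults follow the SimSiam recipe: 224-px crops with scale fraction
    0.2-1.0, flip 0.5, jitter 0.8 x (0.4, 0.4, 0.4, 0.1), grayscale 0.2,
    blur 0.5 with sigma 0.1-2.0, ImageNet normalisation.
    """

    crop_size: int = 224
    crop_scale_range: Tuple[float, float] = (0.2, 1.0)
    hflip_prob: float = 0.5
    jitter_prob: float = 0.8
    jitter_strengths: Tuple[float, float, float, float] = (0.4, 0.4, 0.4, 0.1)
    grayscale_prob: float = 0.2
    blur_prob: float = 0.5
    blur_sigma_range: Tuple[float, float] = (0.1, 2.0)
    blur_kernel_size: Optional[int] = None  # None -> sigma-dependent truncation
    normalize_mean: Tuple[float, float, float] = IMAGENET_MEAN
    normalize_std: Tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self) -> None:
        for name in ("hflip_prob", "jitter_prob", "grayscale_prob", "blur_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        lo, hi = self.crop_scale_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"crop_scale_range={self.crop_scale_range} invalid")
        if self.crop_size < 8:
            raise ValueError(f"crop_size={self.crop_size} < 8")
        if any(s <= 0 for s in self.normalize_std):
            raise ValueError("normalize_std must be strictly positive")
        if self.blur_sigma_range[0] <= 0 or \
                self.blur_sigma_range[0] > self.blur_sigma_range[1]:
            raise ValueError(f"blur_sigma_range={self.blur_sigma_range} invalid")


@dataclass
class ViewPair:
    """Two independently augmented views of one frame batch."""

    view1: np.ndarray
    view2: np.ndarray

    def __post_init__(self) -> None:
        if self.view1.shape != self.view2.shape:
            raise ValueError("views must share a shape, got "
                             f"{self.view1.shape} vs {self.view2.shape}")
        if not (np.isfinite(self.view1).all() and np.isfinite(self.view2).all()):
            raise ValueError("views contain non-finite values")


# ---------------------------------------------------------------------------
# individual transforms (HWC float in [0,1] unless noted)
# ---------------------------------------------------------------------------

def _random_resized_crop(img: np.ndarray, size: int,
                         scale: Tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Sample an area-fraction/aspect crop then resize to (size, size).

    Aspect ratio is drawn log-uniformly from (3/4, 4/3); after ten failed
    proposals the largest centred crop is used instead.
    """
    c, h, w = img.shape
    area = h * w
    for _ in range(10):
        target = rng.uniform(scale[0], scale[1]) * area
        ratio = np.exp(rng.uniform(np.log(3 / 4), np.log(4 / 3)))
        cw = int(round(np.sqrt(target * ratio)))
        ch = int(round(np.sqrt(target / ratio)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            crop = img[:, top:top + ch, left:left + cw]
            break
    else:
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        crop = img[:, top:top + side, left:left + side]
    if crop.shape[1] == size and crop.shape[2] == size:
        return crop.astype(np.float32)
    out = _sk_resize(crop, (c, size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def _color_jitter(img: np.ndarray, strengths: Sequence[float],
                  rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter in randomised order."""
    sb, sc, ss, sh = strengths
    ops = rng.permutation(4)
    factors = {
        0: rng.uniform(max(0.0, 1 - sb), 1 + sb),  # brightness
        1: rng.uniform(max(0.0, 1 - sc), 1 + sc),  # contrast
        2: rng.uniform(max(0.0, 1 - ss), 1 + ss),  # saturation
        3: rng.uniform(-sh, sh),                   # hue shift (fraction of turn)
    }
    lum_w = np.array([0.299, 0.587, 0.114], dtype=np.float32).reshape(3, 1, 1)
    for op in ops:
        if op == 0:
            img = img * factors[0]
        elif op == 1:
            mean = float((img * lum_w).sum(axis=0).mean())
            img = (img - mean) * factors[1] + mean
        elif op == 2:
            gray = (img * lum_w).sum(axis=0, keepdims=True)
            img = (img - gray) * factors[2] + gray
        else:
            img = _shift_hue(np.clip(img, 0, 1), factors[3])
        img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32)


def _shift_hue(img: np.ndarray, delta: float) -> np.ndarray:
    """Rotate hue by ``delta`` turns via HSV round-trip (CHW layout)."""
    from skimage.color import hsv2rgb, rgb2hsv

    hwc = img.transpose(1, 2, 0)
    hsv = rgb2hsv(hwc)
    hsv[..., 0] = (hsv[..., 0] + delta) % 1.0
    return hsv2rgb(hsv).transpose(2, 0, 1).astype(np.float32)


def _grayscale(img: np.ndarray) -> np.ndarray:
    lum_w = np.array([0.299, 0.587, 0.114], dtype=np.float32).reshape(3, 1, 1)
    gray = (img * lum_w).sum(axis=0, keepdims=True)
    return np.repeat(gray, 3, axis=0)


def _gaussian_blur(img: np.ndarray, sigma: float,
                   kernel_size: Optional[int]) -> np.ndarray:
    if kernel_size is None:
        truncate = 4.0
    else:
        truncate = ((kernel_size - 1) / 2) / sigma
    return ndimage.gaussian_filter(
        img, sigma=(0, sigma, sigma), truncate=truncate).astype(np.float32)


def _augment_one(img: np.ndarray, config: AugmentationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = _random_resized_crop(img, config.crop_size,
                               config.crop_scale_range, rng)
    if rng.random() < config.hflip_prob:
        out = out[:, :, ::-1].copy()
    if rng.random() < config.jitter_prob:
        out = _color_jitter(out, config.jitter_strengths, rng)
    if rng.random() < config.grayscale_prob:
        out = _grayscale(out)
    if rng.random() < config.blur_prob:
        sigma = rng.uniform(*config.blur_sigma_range)
        out = _gaussian_blur(out, sigma, config.blur_kernel_size)
    return out


def normalize(images: np.ndarray, mean: Sequence[float],
              std: Sequence[float]) -> np.ndarray:
    m = np.asarray(mean, dtype=np.float32).reshape(1, 3, 1, 1)
    s = np.asarray(std, dtype=np.float32).reshape(1, 3, 1, 1)
    return (images - m) / s


def augment_pair(images: np.ndarray, config: AugmentationConfig,
                 rng: np.random.Generator) -> ViewPair:
    """Produce two independently augmented, normalised views per frame.

    Parameters
    ----------
    images : float array, shape (batch, 3, H, W), values in [0, 1]
    config : AugmentationConfig
    rng : numpy Generator; the sole source of randomness.

    Every sample and every view consumes its own fresh draws, so the two
    views of one frame are independent transformations.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError(f"expected (batch, 3, H, W), got shape {images.shape}")
    if images.shape[0] < 1:
        raise ValueError("empty batch")
    if images.shape[1] != 3:
        raise ValueError(f"expected 3 channels, got {images.shape[1]}")
    views = [[], []]
    for img in images:
        for v in range(2):
            views[v].append(_augment_one(img, config, rng))
    v1 = normalize(np.stack(views[0]), config.normalize_mean, config.normalize_std)
    v2 = normalize(np.stack(views[1]), config.normalize_mean, config.normalize_std)
    return ViewPair(view1=v1, view2=v2)


# ---------------------------------------------------------------------------
# frame I/O
# ---------------------------------------------------------------------------

def load_frames(directory: Path | str, limit: Optional[int] = None) -> np.ndarray:
    """Read all PNG/JPEG frames under ``directory`` (recursive, sorted).

    Returns a float32 array (n, 3, H, W) in [0, 1].  All frames must share
    one size; resize beforehand if they do not.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.rglob("*")
                   if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
    if limit is not None:
        paths = paths[:limit]
    if not paths:
        raise FileNotFoundError(f"no PNG/JPEG frames under {directory}")
    frames = []
    for p in paths:
        arr = np.asarray(Image.open(p).convert("RGB"), dtype=np.float32) / 255.0
        frames.append(arr.transpose(2, 0, 1))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames under {directory} have mixed sizes: {shapes}")
    return np.stack(frames)
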