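"""Synthetic colonoscopy-like frame sequences.

Real colonoscopy pre-training corpora are video streams: frames within a
clip are temporally adjacent and highly similar, which is exactly the
property that confuses negative-pair contrastive methods and motivates a
negative-free siamese objective.  This generator reproduces the salient
structure at desk scale:

* a pinkish mucosa texture (low-frequency seeded noise) that is common to
  a whole sequence and drifts slowly;
* radial darkening toward a slowly drifting lumen centre;
* additive specular highlights whose positions random-walk frame to frame;
* optional polyp blobs rendered as shaded ellipsoid bumps, with exact
  bounding boxes recorded per frame;
* compositional degradations (Gaussian blur, foam speckle) with their own
  sub-seeded random streams;
* an AR(1) per-frame detail field whose coefficient is the target
  inter-frame correlation, so adjacent frames correlate at or above the
  requested level.

Frames are float32, ``(n_frames, 3, H, W)``, values in [0, 1].  The
on-disk corpus layout is PNG frames per sequence plus one COCO-dialect
JSON (0-based, top-left origin, ``bbox = [x, y, w, h]``, single category
``polyp``) and a YAML manifest of every spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

_ALPHA_THRESHOLD = 0.05  # polyp blob pixels above this are "rendered"


@dataclass
class SyntheticSequenceSpec:
    n_frames: int = 32
    frame_size: int = 64
    lumen_center_drift: float = 0.5
    vignette_strength: float = 0.6
    polyp_prob: float = 0.5
    polyp_axes_range: Tuple[int, int] = (6, 12)
    specular_count_range: Tuple[int, int] = (1, 4)
    blur_prob: float = 0.2
    foam_prob: float = 0.2
    interframe_rho: float = 0.9
    base_hue: Tuple[float, float, float] = (0.78, 0.42, 0.36)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("polyp_prob", "blur_prob", "foam_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 0.0 <= self.interframe_rho <= 1.0:
            raise ValueError("interframe_rho outside [0, 1]")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength outside [0, 1]")
        if self.polyp_axes_range[1] >= self.frame_size / 2:
            raise ValueError("polyp axes must be < frame_size / 2")
        if self.polyp_axes_range[0] < 1 or \
                self.polyp_axes_range[0] > self.polyp_axes_range[1]:
            raise ValueError("invalid polyp_axes_range")


@dataclass
class FrameAnnotation:
    frame_index: int
    boxes: List[Tuple[int, int, int, int]]  # (x, y, w, h), 0-based top-left
    has_polyp: bool

    def __post_init__(self) -> None:
        if self.has_polyp != bool(self.boxes):
            raise ValueError("has_polyp must mirror box presence")


@dataclass
class SyntheticSequence:
    spec: SyntheticSequenceSpec
    frames: np.ndarray  # (n, 3, H, W) float32 in [0, 1]
    annotations: List[FrameAnnotation]


def _lowfreq_noise(rng: np.random.Generator, size: int,
                   coarse: int = 8) -> np.ndarray:
    """Smooth zero-mean noise field: coarse Gaussian grid upsampled."""
    grid = rng.normal(0.0, 1.0, size=(coarse, coarse))
    out = _sk_resize(grid, (size, size), order=3, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def _render_polyp(size: int, cx: float, cy: float, ax: float, ay: float,
                  angle: float) -> Tuple[np.ndarray, np.ndarray]:
    """Shaded ellipsoid bump: returns (alpha mask, RGB layer)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    ca, sa = np.cos(angle), np.sin(angle)
    u = ((xx - cx) * ca + (yy - cy) * sa) / ax
    v = (-(xx - cx) * sa + (yy - cy) * ca) / ay
    q = u * u + v * v
    height = np.sqrt(np.maximum(0.0, 1.0 - q)).astype(np.float32)
    alpha = np.clip(height * 1.4, 0.0, 1.0)
    # Lambertian-ish shading: light from the top-left
    gy, gx = np.gradient(height)
    shade = np.clip(0.65 - 0.8 * (gx + gy), 0.3, 1.0)
    colour = np.array([0.88, 0.55, 0.50], dtype=np.float32)
    layer = colour.reshape(3, 1, 1) * shade[None] * (0.7 + 0.3 * height[None])
    return alpha, layer


def _tight_box(alpha: np.ndarray) -> Optional[Tuple[int, int, int, int]]:
    mask = alpha > _ALPHA_THRESHOLD
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    x, y = int(cols[0]), int(rows[0])
    return (x, y, int(cols[-1] - x + 1), int(rows[-1] - y + 1))


def generate_sequence(spec: SyntheticSequenceSpec
                      ) -> Tuple[np.ndarray, List[FrameAnnotation]]:
    """Render one clip; identical spec + seed gives bit-identical output."""
    size = spec.frame_size
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_tex = np.random.default_rng(streams[0])
    rng_lumen = np.random.default_rng(streams[1])
    rng_polyp = np.random.default_rng(streams[2])
    rng_spec = np.random.default_rng(streams[3])
    rng_degrade = np.random.default_rng(streams[4])

    base = np.asarray(spec.base_hue, dtype=np.float32).reshape(3, 1, 1)
    static_tex = _lowfreq_noise(rng_tex, size) * 0.18
    detail = _lowfreq_noise(rng_tex, size, coarse=16) * 0.10
    rho = spec.interframe_rho

    # lumen centre random-walks at lumen_center_drift pixels/frame
    lumen = np.array([size / 2.0, size / 2.0])
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)

    # per-sequence polyp
    has_polyp = rng_polyp.random() < spec.polyp_prob
    if has_polyp:
        ax = float(rng_polyp.uniform(*spec.polyp_axes_range))
        ay = float(rng_polyp.uniform(*spec.polyp_axes_range))
        angle = float(rng_polyp.uniform(0, np.pi))
        margin = max(ax, ay) + 2
        pcx = float(rng_polyp.uniform(margin, size - margin))
        pcy = float(rng_polyp.uniform(margin, size - margin))

    # specular highlight tracks
    n_spec = int(rng_spec.integers(spec.specular_count_range[0],
                                   spec.specular_count_range[1] + 1))
    spec_pos = rng_spec.uniform(5, size - 5, size=(n_spec, 2))
    spec_r = rng_spec.uniform(1.0, 2.5, size=n_spec)

    frames = np.empty((spec.n_frames, 3, size, size), dtype=np.float32)
    annotations: List[FrameAnnotation] = []
    for t in range(spec.n_frames):
        if t > 0:
            lumen += rng_lumen.normal(0, spec.lumen_center_drift, size=2)
            lumen = np.clip(lumen, size * 0.25, size * 0.75)
            step = _lowfreq_noise(rng_tex, size, coarse=16) * 0.10
            detail = rho * detail + np.sqrt(max(0.0, 1 - rho ** 2)) * step
            spec_pos += rng_spec.normal(0, 0.8, size=spec_pos.shape)
            spec_pos = np.clip(spec_pos, 2, size - 3)
            if has_polyp:
                pcx = float(np.clip(pcx + rng_polyp.normal(0, 0.3),
                                    margin, size - margin))
                pcy = float(np.clip(pcy + rng_polyp.normal(0, 0.3),
                                    margin, size - margin))

        r2 = ((xx - lumen[0]) ** 2 + (yy - lumen[1]) ** 2) / (size * 0.5) ** 2
        light = 1.0 - spec.vignette_strength * np.exp(-r2 * 3.0) \
            - 0.3 * spec.vignette_strength * r2
        frame = base * np.clip(light, 0.05, 1.0)[None]
        frame = frame * (1.0 + static_tex + detail)[None]

        boxes: List[Tuple[int, int, int, int]] = []
        if has_polyp:
            alpha, layer = _render_polyp(size, pcx, pcy, ax, ay, angle)
            k = 0.85
            frame = frame * (1 - k * alpha[None]) + layer * (k * alpha[None])
            box = _tight_box(alpha)
            if box is not None:
                boxes.append(box)

        # specular highlights: additive push toward white
        glare = np.zeros((size, size), dtype=np.float32)
        for (sx, sy), r in zip(spec_pos, spec_r):
            d2 = ((xx - sx) ** 2 + (yy - sy) ** 2) / (r * r)
            glare += np.exp(-d2).astype(np.float32)
        frame = frame + np.clip(glare, 0, 1)[None] * (1.0 - frame) * 0.9

        if rng_degrade.random() < spec.foam_prob:
            n_dots = int(rng_degrade.integers(5, 15))
            fx = rng_degrade.uniform(0, size, n_dots)
            fy = rng_degrade.uniform(0, size, n_dots)
            foam = np.zeros((size, size), dtype=np.float32)
            for dx, dy in zip(fx, fy):
                d2 = ((xx - dx) ** 2 + (yy - dy) ** 2) / 1.5
                foam += np.exp(-d2).astype(np.float32)
            frame = frame + np.clip(foam, 0, 1)[None] * 0.25
        if rng_degrade.random() < spec.blur_prob:
            sigma = float(rng_degrade.uniform(0.5, 1.2))
            frame = ndimage.gaussian_filter(frame, sigma=(0, sigma, sigma))

        frames[t] = np.clip(frame, 0.0, 1.0)
        annotations.append(FrameAnnotation(frame_index=t, boxes=boxes,
                                           has_polyp=bool(boxes)))
    return frames, annotations


def adjacent_frame_correlation(frames: np.ndarray) -> float:
    """Mean Pearson correlation between consecutive flattened frames."""
    flat = frames.reshape(frames.shape[0], -1)
    cors = [float(np.corrcoef(flat[i], flat[i + 1])[0, 1])
            for i in range(len(flat) - 1)]
    return float(np.mean(cors))


def make_corpus(n_frames: int, frame_size: int = 64, seq_len: int = 32,
                seed: int = 0, **spec_overrides) -> np.ndarray:
    """Concatenate enough generated sequences to reach ``n_frames``."""
    frames = []
    n_seqs = -(-n_frames // seq_len)
    for i in range(n_seqs):
        spec = SyntheticSequenceSpec(n_frames=seq_len, frame_size=frame_size,
                                     seed=seed * 10_000 + i, **spec_overrides)
        f, _ = generate_sequence(spec)
        frames.append(f)
    return np.concatenate(frames)[:n_frames]


# ---------------------------------------------------------------------------
# on-disk corpus
# ---------------------------------------------------------------------------

def write_corpus(sequences: Sequence[SyntheticSequence],
                 out_dir: Path | str) -> Path:
    """Write PNG frames, a COCO-format annotation JSON, and a manifest.

    Layout::

        out_dir/seq_000/frame_0000.png ...
        out_dir/annotations.json   # COCO: images/annotations/categories
        out_dir/manifest.yaml      # every SyntheticSequenceSpec incl. seed
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, annos = [], []
    image_id, anno_id = 0, 0
    manifest = []
    for si, seq in enumerate(sequences):
        seq_dir = out_dir / f"seq_{si:03d}"
        seq_dir.mkdir(exist_ok=True)
        manifest.append({"sequence": si, **asdict(seq.spec)})
        for ann in seq.annotations:
            t = ann.frame_index
            fname = f"seq_{si:03d}/frame_{t:04d}.png"
            arr = (np.clip(seq.frames[t], 0, 1) * 255 + 0.5).astype(np.uint8)
            Image.fromarray(arr.transpose(1, 2, 0)).save(out_dir / fname)
            h, w = seq.frames[t].shape[1:]
            images.append({"id": image_id, "file_name": fname,
                           "width": int(w), "height": int(h)})
            for (x, y, bw, bh) in ann.boxes:
                annos.append({"id": anno_id, "image_id": image_id,
                              "category_id": 1,
                              "bbox": [int(x), int(y), int(bw), int(bh)],
                              "area": int(bw) * int(bh), "iscrowd": 0})
                anno_id += 1
            image_id += 1
    coco = {"images": images, "annotations": annos,
            "categories": [{"id": 1, "name": "polyp"}]}
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump(coco, fh, indent=1)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out_dir
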