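"""Synthetic breast-image datasets with ground-truth informative regions.

Two generation modes emulate the statistical structure of the real
benchmarks the classifier targets, at desk scale:

* ``busi`` — grayscale ultrasound-like images in three imbalanced classes.
  The background is smoothed speckle noise; a "benign" image carries a
  smooth bright ellipse, a "malignant" image an irregular dark blob with a
  spiculated (jagged) border, and a "normal" image is background only.
  Class identity is therefore carried by a localized lesion-like region.
* ``breakhis`` — RGB histopathology-like images in two imbalanced classes
  whose signal is texture-borne: a tissue-like region filled with
  class-specific texture frequency and chromaticity on a neutral
  background.

Every sample comes with a binary mask of the informative region (empty
for the "normal" class), which is what the token-localization checks
score adaptive token sampling against.  Generation is deterministic given
the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = ["SyntheticDatasetSpec", "SyntheticSample", "generate", "export",
           "mask_patch_indices", "BUSI_CLASS_COUNTS", "BREAKHIS_CLASS_COUNTS"]

# printed per-class sizes of the emulated benchmarks
BUSI_CLASS_COUNTS = (487, 210, 133)        # benign / malignant / normal
BREAKHIS_CLASS_COUNTS = (2480, 5429)       # benign / malignant


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray   # H x W (grayscale) or H x W x 3, float in [0, 1]
    label: int
    mask: np.ndarray    # H x W bool, informative region (empty for normal)


@dataclass
class SyntheticDatasetSpec:
    """Generation parameters.

    ``lesion_radius`` is in pixels; the default spans one eighth to one
    quarter of the image side, so a lesion always covers several 16-pixel
    patches without filling the frame.  ``margin`` keeps lesion centers at
    least one patch-width away from the border.
    """
    mode: str = "busi"                       # "busi" | "breakhis"
    n_per_class: tuple[int, ...] | None = None
    image_size: int = 256
    lesion_radius: tuple[int, int] | None = None
    noise_level: float = 0.08
    margin: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("busi", "breakhis"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_per_class is None:
            self.n_per_class = (BUSI_CLASS_COUNTS if self.mode == "busi"
                                else BREAKHIS_CLASS_COUNTS)
        if len(self.n_per_class) < 2:
            raise ValueError("need at least 2 classes")
        if self.lesion_radius is None:
            self.lesion_radius = (self.image_size // 8, self.image_size // 4)
        if self.margin is None:
            self.margin = min(16, self.image_size // 4)
        rmax = self.lesion_radius[1]
        if 2 * rmax >= self.image_size:
            raise ValueError(
                f"lesion radius {rmax} does not fit in a "
                f"{self.image_size}-pixel image")

    @property
    def channels(self) -> int:
        return 1 if self.mode == "busi" else 3

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.mode == "busi":
            return ("benign", "malignant", "normal")[:len(self.n_per_class)]
        return ("benign", "malignant")[:len(self.n_per_class)]


def _coords(size: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:size, 0:size]
    return y.astype(float), x.astype(float)


def _speckle_background(size: int, noise: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smoothed multiplicative-noise field, ultrasound-like."""
    base = 0.35 + 0.05 * rng.standard_normal()
    grain = gaussian_filter(rng.standard_normal((size, size)), sigma=1.5)
    grain /= max(grain.std(), 1e-9)
    return np.clip(base + noise * grain, 0.0, 1.0)


def _lesion_center(spec: SyntheticDatasetSpec, r: float,
                   rng: np.random.Generator) -> tuple[float, float]:
    lo = spec.margin + r
    hi = spec.image_size - spec.margin - r
    if hi <= lo:  # tight frame: fall back to the center
        return spec.image_size / 2, spec.image_size / 2
    return rng.uniform(lo, hi), rng.uniform(lo, hi)


def _benign_lesion(spec, rng):
    """Smooth bright ellipse."""
    size = spec.image_size
    r = rng.uniform(*spec.lesion_radius)
    cy, cx = _lesion_center(spec, r, rng)
    a, b = r, r * rng.uniform(0.6, 0.9)
    theta = rng.uniform(0, np.pi)
    y, x = _coords(size)
    yr = (y - cy) * np.cos(theta) + (x - cx) * np.sin(theta)
    xr = -(y - cy) * np.sin(theta) + (x - cx) * np.cos(theta)
    mask = (yr / a) ** 2 + (xr / b) ** 2 <= 1.0
    bump = gaussian_filter(mask.astype(float), sigma=2.0)
    return rng.uniform(0.30, 0.45) * bump, mask


def _malignant_lesion(spec, rng):
    """Dark irregular blob with a spiculated border."""
    size = spec.image_size
    r0 = rng.uniform(*spec.lesion_radius)
    cy, cx = _lesion_center(spec, r0, rng)
    y, x = _coords(size)
    ang = np.arctan2(y - cy, x - cx)
    rad = np.hypot(y - cy, x - cx)
    wobble = np.zeros_like(ang)
    for harmonic in (3, 5, 9):
        wobble += rng.uniform(0.08, 0.22) * np.sin(
            harmonic * ang + rng.uniform(0, 2 * np.pi))
    mask = rad <= r0 * (1.0 + wobble)
    dip = gaussian_filter(mask.astype(float), sigma=1.0)
    return -rng.uniform(0.20, 0.32) * dip, mask


def _busi_sample(spec, label: int, rng) -> SyntheticSample:
    img = _speckle_background(spec.image_size, spec.noise_level, rng)
    mask = np.zeros((spec.image_size, spec.image_size), dtype=bool)
    if spec.class_names[label] == "benign":
        delta, mask = _benign_lesion(spec, rng)
        img = np.clip(img + delta, 0.0, 1.0)
    elif spec.class_names[label] == "malignant":
        delta, mask = _malignant_lesion(spec, rng)
        img = np.clip(img + delta, 0.0, 1.0)
    return SyntheticSample(image=img, label=label, mask=mask)


def _breakhis_sample(spec, label: int, rng) -> SyntheticSample:
    """Tissue-like textured region; texture statistics carry the class."""
    size = spec.image_size
    y, x = _coords(size)
    # neutral eosin-pink background
    base = np.array([0.86, 0.76, 0.82]) + 0.03 * rng.standard_normal(3)
    img = np.clip(base[None, None, :]
                  + spec.noise_level * gaussian_filter(
                      rng.standard_normal((size, size, 3)), sigma=(1.5, 1.5, 0)),
                  0.0, 1.0)
    # informative tissue region: a large irregular blob
    r0 = rng.uniform(*spec.lesion_radius) * 1.4
    cy, cx = _lesion_center(spec, min(r0, size / 2 - 1), rng)
    ang = np.arctan2(y - cy, x - cx)
    rad = np.hypot(y - cy, x - cx)
    wobble = sum(rng.uniform(0.05, 0.15) * np.sin(h * ang + rng.uniform(0, 2 * np.pi))
                 for h in (2, 4))
    mask = rad <= r0 * (1.0 + wobble)
    if spec.class_names[label] == "benign":
        freq, depth, chroma = 0.15, 0.18, np.array([0.62, 0.45, 0.68])
    else:
        freq, depth, chroma = 0.45, 0.30, np.array([0.42, 0.22, 0.55])
    tex = np.sin(2 * np.pi * freq * y + rng.uniform(0, 2 * np.pi)) \
        * np.sin(2 * np.pi * freq * x + rng.uniform(0, 2 * np.pi))
    tex += 0.6 * rng.standard_normal((size, size))
    tex = gaussian_filter(tex, sigma=0.8)
    region = np.where(mask[:, :, None],
                      chroma[None, None, :] + depth * tex[:, :, None],
                      img)
    img = np.clip(region, 0.0, 1.0)
    return SyntheticSample(image=img, label=label, mask=mask)


def generate(spec: SyntheticDatasetSpec) -> list[SyntheticSample]:
    """Generate the full dataset described by ``spec``, ordered by class."""
    rng = np.random.default_rng(spec.seed)
    make = _busi_sample if spec.mode == "busi" else _breakhis_sample
    samples = []
    for label, n in enumerate(spec.n_per_class):
        for _ in range(n):
            samples.append(make(spec, label, rng))
    return samples


def mask_patch_indices(mask: np.ndarray, patch_size: int,
                       min_fraction: float = 0.0) -> np.ndarray:
    """0-based row-major indices of patches overlapping the mask.

    A patch counts as overlapping when more than ``min_fraction`` of its
    pixels are inside the informative region (0 means any overlap).
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    P = patch_size
    side = W // P
    cover = (mask[:H - H % P, :W - W % P]
             .reshape(H // P, P, side, P).mean(axis=(1, 3)))
    return np.flatnonzero(cover.ravel() > min_fraction)


def export(samples: list[SyntheticSample], directory,
           class_names: tuple[str, ...] | None = None) -> Path:
    """Write PNGs into one subdirectory per class, plus masks + manifest.

    Layout: ``<dir>/<class>/<class>_<i>.png``, masks under
    ``<dir>/masks/``, and ``<dir>/manifest.csv`` with columns
    (filename, label, class, mask).  Returns the manifest path.
    """
    directory = Path(directory)
    labels = sorted({s.label for s in samples})
    if class_names is None:
        class_names = tuple(f"class{c}" for c in labels)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {c: 0 for c in labels}
    for s in samples:
        cname = class_names[s.label]
        (directory / cname).mkdir(exist_ok=True)
        i = counters[s.label]
        counters[s.label] += 1
        fname = f"{cname}/{cname}_{i:05d}.png"
        arr = np.clip(np.round(s.image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L" if arr.ndim == 2 else "RGB") \
            .save(directory / fname)
        mname = f"masks/{cname}_{i:05d}.png"
        Image.fromarray(s.mask.astype(np.uint8) * 255, mode="L") \
            .save(directory / mname)
        rows.append((fname, s.label, cname, mname))
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "class", "mask"])
        writer.writerows(rows)
    return manifest
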