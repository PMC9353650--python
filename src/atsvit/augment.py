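"""Image perturbations for consistency training.

Each transform maps an H x W (x C) float image in [0, 1] to an image of
the same shape.  The default set mirrors common medical-image
augmentation practice: random crop-and-resize, horizontal/vertical flip,
contrast scaling, and brightness jitter, all with seeded parameters so a
training run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.transform import resize

__all__ = ["AugmentationSet", "identity", "hflip", "vflip", "random_crop",
           "contrast", "brightness", "default_augmentations"]

Transform = Callable[[np.ndarray, np.random.Generator], np.ndarray]


def identity(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return img


def hflip(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return img[:, ::-1].copy()


def vflip(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return img[::-1].copy()


def random_crop(img: np.ndarray, rng: np.random.Generator,
                fraction: float = 0.875) -> np.ndarray:
    """Crop a random `fraction`-side window and resize back."""
    h, w = img.shape[:2]
    ch, cw = int(round(h * fraction)), int(round(w * fraction))
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    crop = img[y0:y0 + ch, x0:x0 + cw]
    out = resize(crop, img.shape, order=1, mode="reflect",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def contrast(img: np.ndarray, rng: np.random.Generator,
             lo: float = 0.7, hi: float = 1.3) -> np.ndarray:
    """Scale contrast about the image mean by a factor in U[lo, hi]."""
    f = rng.uniform(lo, hi)
    mu = img.mean()
    return np.clip(mu + f * (img - mu), 0.0, 1.0)


def brightness(img: np.ndarray, rng: np.random.Generator,
               delta: float = 0.1) -> np.ndarray:
    """Add a uniform brightness offset in U[-delta, delta]."""
    return np.clip(img + rng.uniform(-delta, delta), 0.0, 1.0)


@dataclass
class AugmentationSet:
    """An ordered set of perturbations with a seeded generator.

    ``apply`` draws one transform uniformly at random, applies it, and
    returns the perturbed image plus the index of the chosen transform.
    """
    transforms: list[Transform] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.transforms:
            raise ValueError("augmentation set must contain at least one transform")
        self.rng = np.random.default_rng(self.seed)

    def apply(self, img: np.ndarray) -> tuple[np.ndarray, int]:
        i = int(self.rng.integers(len(self.transforms)))
        out = self.transforms[i](np.asarray(img, dtype=np.float64), self.rng)
        if out.shape != img.shape:
            raise ValueError(
                f"transform {i} changed the image shape {img.shape} -> {out.shape}")
        return out, i


def default_augmentations(seed: int = 0) -> AugmentationSet:
    """Crop, both flips, contrast and brightness jitter."""
    return AugmentationSet(
        transforms=[random_crop, hflip, vflip, contrast, brightness],
        seed=seed)
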