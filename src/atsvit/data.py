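"""Dataset loading and run configuration.

Images live in one subdirectory per class (PNG or any format PIL reads);
class indices are assigned by lexicographic order of the directory names.
Images are decoded, resized to the configured square input size with
bilinear interpolation, and intensity-scaled to [0, 1] with no further
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = ["ImageFolderDataset", "RunConfig", "load_image_folder",
           "load_config", "save_config"]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class ImageFolderDataset:
    images: list[np.ndarray]
    labels: np.ndarray
    class_names: tuple[str, ...]
    paths: list[Path]

    def __len__(self) -> int:
        return len(self.images)


def load_image_folder(directory, input_size: int = 256,
                      channels: int | None = None) -> ImageFolderDataset:
    """Load a class-per-subdirectory image dataset.

    ``channels`` forces grayscale (1) or RGB (3); by default the first
    image decides.  Unreadable files are skipped with a warning; an empty
    class directory is an error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {directory}")
    class_dirs = sorted(d for d in directory.iterdir()
                        if d.is_dir() and d.name != "masks")
    if not class_dirs:
        raise ValueError(f"no class subdirectories in {directory}")
    images, labels, paths = [], [], []
    for label, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        count = 0
        for p in files:
            try:
                with Image.open(p) as im:
                    if channels is None:
                        channels = 1 if im.mode in ("L", "I;16", "1") else 3
                    im = im.convert("L" if channels == 1 else "RGB")
                    im = im.resize((input_size, input_size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float64) / 255.0
            except OSError as exc:
                logger.warning("skipping unreadable image %s: %s", p, exc)
                continue
            images.append(arr)
            labels.append(label)
            paths.append(p)
            count += 1
        if count == 0:
            raise ValueError(f"class directory {cdir} contains no readable images")
    return ImageFolderDataset(images=images,
                              labels=np.asarray(labels, dtype=np.intp),
                              class_names=tuple(d.name for d in class_dirs),
                              paths=paths)


@dataclass
class RunConfig:
    """Flat key-value configuration for a full run (YAML on disk)."""
    # optimization
    learning_rate: float = 2e-5
    eps: float = 1e-8
    batch_size: int = 64
    epochs: int = 300
    # model
    input_size: int = 256
    channels: int = 1
    patch_size: int = 16
    dim: int = 128
    depth: int = 6
    heads: int = 4
    num_classes: int = 3
    ats_tokens: tuple[int, ...] | None = (256, 128, 64, 32, 16, 8)
    # data protocol
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    labeled_fraction: float = 0.8
    seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self):
        r = self.split_ratios
        if any(x <= 0 for x in r) or abs(sum(r) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must be positive and sum to 1: {r}")
        if self.ats_tokens is not None:
            self.ats_tokens = tuple(int(k) for k in self.ats_tokens)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "split_ratios" in raw:
        raw["split_ratios"] = tuple(raw["split_ratios"])
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    d = asdict(cfg)
    d["split_ratios"] = list(d["split_ratios"])
    if d["ats_tokens"] is not None:
        d["ats_tokens"] = list(d["ats_tokens"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
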