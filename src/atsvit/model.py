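"""Compact vision transformer with optional adaptive token sampling.

The classifier follows the standard ViT recipe: an image is cut into
non-overlapping P x P patches, each patch is linearly embedded, a learned
CLS token is prepended and learned position vectors are added.  A stack of
pre-norm encoder blocks (multi-head self-attention + GELU feed-forward,
both with residual connections) processes the token sequence, and a linear
head maps the final CLS embedding to class logits.

With a ``token_schedule`` configured, every block ends by scoring its
patch tokens from the CLS attention row and keeping at most the scheduled
budget via inverse transform sampling (see :mod:`atsvit.sampling`).  A
live ``patch_map`` records which original grid positions survive, which is
what the token-overlay visualization and the informative-region checks
consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat_rows, stack_rows
from .sampling import inverse_transform_sample, significance_scores

__all__ = ["PatchGrid", "ViTConfig", "ViTATS", "patchify", "unpatchify"]


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of the patch decomposition."""
    image_size: int          # H = W, pixels
    channels: int            # C
    patch_size: int          # P, pixels

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError(
                f"image size {self.image_size} not divisible by patch size "
                f"{self.patch_size}")

    @property
    def side(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.side * self.side

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.channels


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut an H x W (x C) image into flattened P*P*C patch vectors.

    Patches are emitted in row-major grid order; the operation is lossless
    (``unpatchify`` reconstructs the image exactly).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    H, W, C = image.shape
    P = patch_size
    if H % P or W % P:
        raise ValueError(f"image {H}x{W} not divisible by patch size {P}")
    patches = (image.reshape(H // P, P, W // P, P, C)
                    .transpose(0, 2, 1, 3, 4)
                    .reshape(H // P * (W // P), P * P * C))
    return patches


def unpatchify(patches: np.ndarray, image_size: int, channels: int,
               patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` for a square image."""
    P, C = patch_size, channels
    side = image_size // P
    img = (np.asarray(patches)
           .reshape(side, side, P, P, C)
           .transpose(0, 2, 1, 3, 4)
           .reshape(image_size, image_size, C))
    return img[:, :, 0] if C == 1 else img


@dataclass
class ViTConfig:
    """Model hyperparameters.

    ``token_schedule`` lists the per-block retained-token budgets (length
    must equal ``depth``, non-increasing, first entry at most the patch
    count); ``None`` disables adaptive token sampling entirely.
    """
    image_size: int = 256
    channels: int = 1
    patch_size: int = 16
    dim: int = 128
    depth: int = 6
    heads: int = 4
    mlp_ratio: int = 4
    num_classes: int = 2
    token_schedule: tuple[int, ...] | None = (256, 128, 64, 32, 16, 8)
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")
        grid = self.grid  # validates divisibility
        if self.token_schedule is not None:
            sched = tuple(int(k) for k in self.token_schedule)
            if len(sched) != self.depth:
                raise ValueError(
                    f"token schedule length {len(sched)} != depth {self.depth}")
            if any(a < b for a, b in zip(sched, sched[1:])):
                raise ValueError("token schedule must be non-increasing")
            if sched[0] > grid.n_patches:
                raise ValueError(
                    f"schedule starts at {sched[0]} but the image has only "
                    f"{grid.n_patches} patches")
            object.__setattr__(self, "token_schedule", sched)

    @property
    def grid(self) -> PatchGrid:
        return PatchGrid(self.image_size, self.channels, self.patch_size)


class ViTATS:
    """Vision transformer classifier with per-block token sampling."""

    def __init__(self, config: ViTConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        init = np.random.default_rng(config.seed)
        g = config.grid
        D, depth = config.dim, config.depth

        def w(*shape):
            return Tensor(init.normal(0.0, 0.02, size=shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        p: dict[str, Tensor] = {
            "embed_w": w(g.patch_dim, D), "embed_b": zeros(D),
            "cls": w(D), "pos": w(g.n_patches, D),
            "final_ln_g": ones(D), "final_ln_b": zeros(D),
            "head_w": w(D, config.num_classes), "head_b": zeros(config.num_classes),
        }
        for i in range(depth):
            p[f"b{i}_ln1_g"] = ones(D)
            p[f"b{i}_ln1_b"] = zeros(D)
            for name in ("q", "k", "v", "o"):
                p[f"b{i}_w{name}"] = w(D, D)
                p[f"b{i}_b{name}"] = zeros(D)
            p[f"b{i}_ln2_g"] = ones(D)
            p[f"b{i}_ln2_b"] = zeros(D)
            p[f"b{i}_ff1_w"] = w(D, D * config.mlp_ratio)
            p[f"b{i}_ff1_b"] = zeros(D * config.mlp_ratio)
            p[f"b{i}_ff2_w"] = w(D * config.mlp_ratio, D)
            p[f"b{i}_ff2_b"] = zeros(D)
        self.params = p

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data[...] = state[k]

    # -- embedding ------------------------------------------------------------
    def embed(self, image: np.ndarray) -> Tensor:
        """Patchify, linearly embed, add position vectors, prepend CLS."""
        g = self.config.grid
        patches = patchify(image, g.patch_size)
        if patches.shape[0] != g.n_patches:
            raise ValueError(
                f"got {patches.shape[0]} patches, expected {g.n_patches}")
        x = Tensor(patches).affine(self.params["embed_w"], self.params["embed_b"])
        x = x + self.params["pos"]
        cls = self.params["cls"].reshape(1, -1)
        return concat_rows([cls, x])

    # -- forward --------------------------------------------------------------
    def forward_single(self, image: np.ndarray, mode: str = "deterministic",
                       rng: np.random.Generator | None = None):
        """Run one image through the encoder stack.

        Returns ``(logits, tokens, info)`` where ``logits`` is a length-
        ``num_classes`` tensor, ``tokens`` the final block's full token
        sequence (CLS first), and ``info`` carries the surviving
        ``patch_map`` (original 0-based grid indices, row-major) and the
        final block's significance scores over those survivors.
        """
        cfg = self.config
        g = cfg.grid
        if rng is None:
            rng = self.rng
        x = self.embed(image)
        patch_map = np.arange(g.n_patches)
        last_scores = None
        token_counts: list[int] = []
        dh = cfg.dim // cfg.heads
        scale = 1.0 / np.sqrt(dh)
        for i in range(cfg.depth):
            T = x.shape[0]
            h = x.layer_norm(self.params[f"b{i}_ln1_g"], self.params[f"b{i}_ln1_b"])
            q = h.affine(self.params[f"b{i}_wq"], self.params[f"b{i}_bq"]) \
                .split_heads(cfg.heads)
            k = h.affine(self.params[f"b{i}_wk"], self.params[f"b{i}_bk"]) \
                .split_heads(cfg.heads)
            v = h.affine(self.params[f"b{i}_wv"], self.params[f"b{i}_bv"]) \
                .split_heads(cfg.heads)
            att = (q @ k.transpose(0, 2, 1) * scale).softmax()
            out = (att @ v).merge_heads()
            x = x + out.affine(self.params[f"b{i}_wo"], self.params[f"b{i}_bo"])
            if cfg.token_schedule is not None:
                # the sampling module sits between attention and the
                # feed-forward: score on the head-averaged attention and the
                # concatenated per-head value rows, then keep at most the
                # scheduled budget.  Selection is discrete (no gradient
                # through the scores; gradients flow through kept rows).
                v_full = v.data.transpose(1, 0, 2).reshape(T, cfg.dim)
                scores, cdf = significance_scores(att.data, v_full,
                                                  on_degenerate="uniform")
                idx = inverse_transform_sample(cdf, cfg.token_schedule[i],
                                               mode=mode, rng=rng)
                last_scores = scores[idx]
                x = x.gather_rows(np.concatenate([[0], np.sort(idx) + 1]))
                patch_map = patch_map[np.sort(idx)]
            h2 = x.layer_norm(self.params[f"b{i}_ln2_g"], self.params[f"b{i}_ln2_b"])
            ff = h2.affine(self.params[f"b{i}_ff1_w"], self.params[f"b{i}_ff1_b"]).gelu()
            x = x + ff.affine(self.params[f"b{i}_ff2_w"], self.params[f"b{i}_ff2_b"])
            token_counts.append(x.shape[0])
        tokens = x
        h = x.layer_norm(self.params["final_ln_g"], self.params["final_ln_b"])
        logits = h.gather_rows([0]) \
            .affine(self.params["head_w"], self.params["head_b"]).reshape(-1)
        info = {"patch_map": patch_map, "last_scores": last_scores,
                "token_counts": token_counts}
        return logits, tokens, info

    def forward(self, images, mode: str = "deterministic",
                rng: np.random.Generator | None = None):
        """Batch forward.  Returns stacked logits (B, num_classes), the
        per-image final token sequences, and per-image info dicts."""
        logits, tokens, infos = [], [], []
        for img in images:
            lo, tok, info = self.forward_single(img, mode=mode, rng=rng)
            logits.append(lo)
            tokens.append(tok)
            infos.append(info)
        return stack_rows(logits), tokens, infos

    def predict_proba(self, images) -> np.ndarray:
        """Per-class sigmoid probabilities (deterministic sampling)."""
        logits, _, _ = self.forward(images, mode="deterministic")
        return logits.sigmoid().data

    def predict(self, images) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    # -- interpretation -------------------------------------------------------
    def top_tokens(self, image: np.ndarray, k: int = 8):
        """Grid coordinates of the k most significant last-block patches.

        Requires ATS to be enabled.  Returns a list of ``(row, col)`` grid
        coordinates; :meth:`patch_boxes` converts them to pixel boxes.
        """
        if self.config.token_schedule is None:
            raise ValueError("top_tokens requires adaptive token sampling")
        _, _, info = self.forward_single(image, mode="deterministic")
        survivors = info["patch_map"]
        if k > survivors.size:
            raise ValueError(
                f"k={k} exceeds the {survivors.size} surviving last-block tokens")
        order = np.argsort(info["last_scores"])[::-1][:k]
        side = self.config.grid.side
        return [(int(p // side), int(p % side)) for p in survivors[order]]

    def patch_boxes(self, coords) -> list[tuple[int, int, int, int]]:
        """Map grid coordinates to (y0, x0, y1, x1) pixel boxes."""
        P = self.config.patch_size
        return [(r * P, c * P, (r + 1) * P, (c + 1) * P) for r, c in coords]

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: config header + parameter arrays."""
        header = json.dumps({"format": "atsvit-checkpoint", "version": 1,
                             "config": asdict(self.config)})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "ViTATS":
        with np.load(path) as f:
            header = json.loads(bytes(f["__header__"]).decode())
            if header.get("format") != "atsvit-checkpoint":
                raise ValueError("not an atsvit checkpoint")
            cfg_d = header["config"]
            if cfg_d["token_schedule"] is not None:
                cfg_d["token_schedule"] = tuple(cfg_d["token_schedule"])
            model = cls(ViTConfig(**cfg_d))
            model.load_state_dict({k: f[k] for k in f.files if k != "__header__"})
        return model
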