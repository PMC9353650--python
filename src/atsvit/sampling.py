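"""Adaptive token sampling (ATS) for vision transformers.

Each encoder block scores its patch tokens by how strongly the
classification (CLS) token attends to them, weighted by the magnitude of
their value vectors, then draws at most ``K`` tokens by inverse transform
sampling over the score distribution.  Retained tokens are passed to the
next block; the CLS token is always kept.

Conventions
-----------
Token row 0 is the CLS token; rows ``1..N`` are the ``N`` patch tokens.
Significance scores, their CDF and sampled *patch indices* are expressed
in 0-based patch positions ``0..N-1`` (i.e. token row ``j`` has patch
index ``j - 1``).  ``select_tokens`` takes patch indices and returns the
CLS row followed by the chosen patch rows in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "compute_attention",
    "output_tokens",
    "significance_scores",
    "inverse_transform_sample",
    "select_tokens",
    "SamplerConfig",
    "TokenSampler",
    "DegenerateScoresError",
]


class DegenerateScoresError(ValueError):
    """All CLS-row score numerators are zero; no distribution exists."""


def compute_attention(Q: np.ndarray, K: np.ndarray, d: int | None = None) -> np.ndarray:
    """Scaled dot-product attention weights, row-softmax(Q Kᵀ / √d).

    Parameters
    ----------
    Q, K : (T, d) arrays with identical shapes, T = N + 1 tokens.
    d : key dimensionality used in the √d scale; defaults to ``Q.shape[-1]``.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if Q.shape != K.shape:
        raise ValueError(f"Q shape {Q.shape} does not match K shape {K.shape}")
    if Q.ndim != 2:
        raise ValueError(f"Q must be 2-D, got shape {Q.shape}")
    if d is None:
        d = Q.shape[-1]
    if d < 1:
        raise ValueError("key dimensionality d must be >= 1")
    logits = Q @ K.T / np.sqrt(float(d))
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def output_tokens(A: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pre-sampling block output O = A·V."""
    A = np.asarray(A, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if A.shape[-1] != V.shape[0]:
        raise ValueError(
            f"A has {A.shape[-1]} columns but V has {V.shape[0]} rows")
    return A @ V


def significance_scores(A: np.ndarray, V: np.ndarray,
                        on_degenerate: Literal["error", "uniform"] = "error",
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Patch-token significance scores and their CDF.

    The score of patch token ``j`` (token row ``j+1``) is the CLS-row
    attention weight towards it times the Euclidean norm of its value row,
    normalized over all patch tokens::

        S_j = A[0, j+1] * ||V[j+1]|| / sum_i A[0, i+1] * ||V[i+1]||

    The CLS token itself is excluded: it carries the classification
    information and is always retained.  ``A`` may be a stack of per-head
    attention matrices ``(h, T, T)``, in which case heads are averaged
    before scoring (with one head this reduces exactly to the single-head
    formula).

    Returns ``(S, CDF)``, each of length N.
    """
    A = np.asarray(A, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if A.ndim == 3:
        A = A.mean(axis=0)
    if A.shape[0] != A.shape[1] or A.shape[0] != V.shape[0]:
        raise ValueError(f"inconsistent shapes A {A.shape}, V {V.shape}")
    cls_row = A[0, 1:]
    vnorm = np.linalg.norm(V[1:], axis=-1)
    numer = cls_row * vnorm
    total = numer.sum()
    if total <= 0.0:
        if on_degenerate == "uniform":
            numer = np.ones_like(numer)
            total = numer.sum()
        else:
            raise DegenerateScoresError(
                "all significance-score numerators are zero")
    S = numer / total
    return S, np.cumsum(S)


@dataclass(frozen=True)
class SamplerConfig:
    """Token-sampling policy for one encoder block.

    k : maximum number of retained patch tokens (the budget K).
    mode : "stochastic" draws K uniforms from U[0,1]; "deterministic"
        uses the midpoint quantiles (i - 0.5)/K for reproducible selection.
    seed : seed for the stochastic draws.
    """
    k: int
    mode: Literal["stochastic", "deterministic"] = "stochastic"
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("token budget k must be >= 1")
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


def inverse_transform_sample(cdf: np.ndarray, k: int,
                             mode: str = "stochastic",
                             rng: np.random.Generator | None = None,
                             ) -> np.ndarray:
    """Draw at most ``k`` distinct patch indices through the inverse CDF.

    Each uniform variate u maps to the smallest patch index i with
    CDF[i] >= u (the generalized inverse of the step CDF); duplicates are
    removed, so the realized count K' is at most k.  With ``k >= N`` in
    deterministic mode every patch index is returned.

    Returns ascending, distinct 0-based patch indices.
    """
    cdf = np.asarray(cdf, dtype=np.float64)
    n = cdf.shape[0]
    if k < 1:
        raise ValueError("sample budget k must be >= 1")
    if k >= n:
        return np.arange(n)
    if mode == "deterministic":
        u = (np.arange(1, k + 1) - 0.5) / k
    elif mode == "stochastic":
        if rng is None:
            rng = np.random.default_rng()
        u = rng.uniform(0.0, 1.0, size=k)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    idx = np.searchsorted(cdf, u, side="left")
    idx = np.minimum(idx, n - 1)  # guard u > CDF[-1] from roundoff
    return np.unique(idx)


def select_tokens(O: np.ndarray, patch_indices: np.ndarray) -> np.ndarray:
    """Gather the CLS row plus the selected patch rows, ascending.

    ``patch_indices`` are 0-based patch positions; row ``j+1`` of ``O`` is
    patch ``j``.  The result has K' + 1 rows with CLS first.
    """
    O = np.asarray(O)
    idx = np.asarray(patch_indices, dtype=np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= O.shape[0] - 1):
        raise IndexError(
            f"patch indices out of range [0, {O.shape[0] - 2}]: {idx}")
    rows = np.concatenate([[0], np.sort(idx) + 1])
    return O[rows]


class TokenSampler:
    """Stateful sampler: owns the RNG so draws are reproducible given
    (seed, call order)."""

    def __init__(self, config: SamplerConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)

    def sample(self, A: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Score tokens and return the retained patch indices."""
        _, cdf = significance_scores(A, V, on_degenerate="uniform")
        return inverse_transform_sample(
            cdf, self.config.k, mode=self.config.mode, rng=self.rng)
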