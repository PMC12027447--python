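"""Similarity fusion by truncated SVD.

Per-entity similarity matrices are stacked vertically (miRNA: MFS, MQS,
MGS; disease: DSS1, DSS2, DGS), the stack is denoised by a rank-k SVD
reconstruction, and a per-entity feature slice of the reconstruction is
projected through a learned affine map to the model's embedding width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from gonnmda.similarity import SimilarityMatrix

DEFAULT_K_SVD = 150  # clamped to the valid range on small inputs

FUSION_MODES = ("vk_sigma", "block_mean")


@dataclass
class StackedSimilarity:
    """Vertical concatenation of B same-indexed square similarity blocks."""

    ids: List[str]
    block_names: List[str]
    stacked: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.block_names)


@dataclass
class ReconstructedFeature:
    """Rank-k reconstruction of a similarity stack plus per-entity features.

    ``features`` is the (B*n, n) reconstruction; ``entity_features`` the
    (n, k) per-entity slice that feeds the projection layer.
    """

    ids: List[str]
    features: np.ndarray
    entity_features: np.ndarray
    singular_values: np.ndarray
    k_svd: int
    mode: str = "vk_sigma"


def stack(blocks: Sequence[SimilarityMatrix]) -> StackedSimilarity:
    """Stack similarity matrices sharing one id set; order is preserved."""
    if not blocks:
        raise ValueError("at least one block required")
    ids = list(blocks[0].ids)
    for b in blocks[1:]:
        if list(b.ids) != ids:
            raise ValueError("blocks must share an identical ordered id set")
    stacked = np.vstack([b.values for b in blocks])
    return StackedSimilarity(ids, [b.name or f"block{i}" for i, b in enumerate(blocks)], stacked)


def truncated_reconstruct(
    stacked: StackedSimilarity, k_svd: int, mode: str = "vk_sigma"
) -> ReconstructedFeature:
    """Best rank-k Frobenius approximation of the stack via truncated SVD.

    ``mode`` selects the per-entity feature slice: ``vk_sigma`` takes rows
    of V_k Sigma_k (the entity coordinates in the truncated right singular
    basis, width k); ``block_mean`` averages the reconstruction over the
    stacked blocks (width n).
    """
    S = stacked.stacked
    max_k = min(S.shape)
    if not (1 <= k_svd <= max_k):
        raise ValueError(f"k_svd must be in [1, {max_k}], got {k_svd}")
    if mode not in FUSION_MODES:
        raise ValueError(f"mode must be one of {FUSION_MODES}")
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    Uk, sk, Vtk = U[:, :k_svd], s[:k_svd], Vt[:k_svd]
    recon = (Uk * sk) @ Vtk
    if mode == "vk_sigma":
        entity = Vtk.T * sk  # (n, k)
    else:
        n = len(stacked.ids)
        entity = recon.reshape(stacked.n_blocks, n, n).mean(axis=0)
    return ReconstructedFeature(
        ids=list(stacked.ids),
        features=recon,
        entity_features=entity,
        singular_values=s.copy(),
        k_svd=k_svd,
        mode=mode,
    )


def clamp_k_svd(k_svd: int, stacked_shape: tuple) -> int:
    """Clamp the configured rank to the valid range for a given stack."""
    return max(1, min(k_svd, min(stacked_shape)))


@dataclass
class LinearProjection:
    """Learnable affine map applied row-wise: X -> X @ W + b."""

    W: np.ndarray
    b: np.ndarray

    @classmethod
    def init(cls, in_dim: int, out_dim: int, rng: np.random.Generator) -> "LinearProjection":
        scale = 1.0 / np.sqrt(in_dim)
        return cls(rng.normal(0.0, scale, size=(in_dim, out_dim)), np.zeros(out_dim))

    @classmethod
    def identity(cls, dim: int) -> "LinearProjection":
        return cls(np.eye(dim), np.zeros(dim))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"input width {X.shape[1]} does not match projection {self.W.shape}"
            )
        return X @ self.W + self.b


def project(recon: ReconstructedFeature, projection: LinearProjection) -> np.ndarray:
    """Project the per-entity feature slice to the embedding width."""
    return projection(recon.entity_features)
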