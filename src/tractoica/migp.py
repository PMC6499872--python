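"""Incremental group PCA (MIGP) over random target-voxel chunks.

The seeds x targets group matrix is too wide to decompose at once at full
scale, so the reduction iterates: take a random chunk of target columns,
concatenate it to the running basis of left singular vectors weighted by
their singular values, and re-truncate to the top ``n_pca`` directions.
Chunks are a partition of a single random permutation of all targets, so
every voxel is used exactly once and the whole volume is covered.  Whenever
the matrix rank is at most ``n_pca`` the result spans the exact PCA
subspace; above capacity it is the usual MIGP approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .synthgeo import TractographyMatrix

__all__ = ["ReducedMatrix", "migp_reduce"]

# relative singular-value cutoff below which a direction is numerical noise
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class ReducedMatrix:
    """Seeds x n_pca representation of the group matrix.

    ``scores`` carries U * S (left singular vectors weighted by singular
    values), ordered by non-increasing singular value.  If the data rank is
    below ``n_pca`` the trailing numerically-zero directions are dropped and
    ``effective_rank`` records how many columns remain.
    """

    scores: np.ndarray            # (n_seeds, effective_rank <= n_pca)
    n_pca: int
    chunk_size: int
    chunk_order: np.ndarray       # realized permutation of target indices
    seed: int
    singular_values: np.ndarray
    effective_rank: int
    centered: bool = False


def migp_reduce(
    matrix: TractographyMatrix,
    n_pca: int,
    chunk_size: int,
    seed: int,
    center: bool = False,
) -> ReducedMatrix:
    """Reduce a group matrix to its top ``n_pca`` weighted left singular
    directions by chunk-wise incremental PCA.

    With ``center`` set, each target column is mean-centered (over seeds)
    before use; default is raw counts.
    """
    X = np.asarray(matrix.counts, dtype=np.float64)
    n_seeds, n_targets = X.shape
    if n_seeds == 0 or n_targets == 0:
        raise ValueError("empty matrix cannot be reduced")
    if n_pca < 1:
        raise ValueError("n_pca must be positive")
    if n_pca > n_seeds:
        raise ValueError(f"n_pca={n_pca} exceeds the seed count {n_seeds}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_targets)

    W: np.ndarray | None = None
    S = np.empty(0)
    for start in range(0, n_targets, chunk_size):
        chunk = X[:, perm[start : start + chunk_size]]
        if center:
            chunk = chunk - chunk.mean(axis=0, keepdims=True)
        C = chunk if W is None else np.hstack([W, chunk])
        U, S, _ = linalg.svd(C, full_matrices=False)
        keep = min(n_pca, C.shape[1])
        # drop numerically-zero directions so rank deficiency stays visible
        if S.size and S[0] > 0:
            keep = min(keep, int(np.sum(S > S[0] * _RANK_RTOL)))
        keep = max(keep, 1)
        W = U[:, :keep] * S[:keep]
        S = S[:keep]

    assert W is not None
    effective_rank = W.shape[1]
    if effective_rank < n_pca:
        warnings.warn(
            f"data rank {effective_rank} is below the requested n_pca={n_pca}; "
            "returning all available directions",
            stacklevel=2,
        )
    return ReducedMatrix(
        scores=W,
        n_pca=n_pca,
        chunk_size=chunk_size,
        chunk_order=perm,
        seed=seed,
        singular_values=S.copy(),
        effective_rank=effective_rank,
        centered=center,
    )
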