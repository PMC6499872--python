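"""Spatial ICA of the reduced matrix, sign alignment and back-projection.

The reduced matrix (seeds x n_pca) is decomposed by symmetric fixed-point
fastICA with independence enforced in the seed domain: each of the K
recovered sources is a spatial loading map over cortical seeds, and the
mixing matrix maps sources back into the PCA subspace.  Grey maps are fixed
to unit variance; sign ambiguity is resolved by flipping each component so
its longest tail is positive; the white-matter counterpart of each grey map
is obtained by joint linear regression of every target voxel's seed profile
onto all K grey maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .migp import ReducedMatrix
from .synthgeo import TractographyMatrix

__all__ = [
    "ComponentSet",
    "run_ica",
    "align_signs",
    "back_project",
    "variance_explained",
]

_FUN = {"logcosh": "logcosh", "pow3": "cube"}


@dataclass(frozen=True)
class ComponentSet:
    """K paired maps: grey loadings over seeds, white profiles over targets.

    Columns of ``grey`` and ``white`` correspond index-for-index; every grey
    column has unit (population) variance, and after :func:`align_signs` its
    largest-magnitude entry is positive.
    """

    grey: np.ndarray                 # (n_seeds, K), unit-variance columns
    white: np.ndarray                # (n_targets, K) or empty before back-projection
    K: int
    mixing: np.ndarray               # (n_pca, K)
    ica_params: dict = field(default_factory=dict)
    variance_explained: float | None = None


def run_ica(
    reduced: ReducedMatrix,
    K: int,
    nonlinearity: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> ComponentSet:
    """Unmix the reduced matrix into K independent seed-domain maps.

    Returns a :class:`ComponentSet` with unit-variance grey maps and the
    n_pca x K mixing matrix; ``white`` is empty until
    :func:`back_project` fills it.  Non-convergence within ``max_iter`` is
    recorded in ``ica_params['converged']`` (results are still returned).
    """
    X = reduced.scores
    n_pca = X.shape[1]
    if K < 1:
        raise ValueError("K must be positive")
    if K > n_pca:
        raise ValueError(f"K={K} exceeds the reduced dimensionality n_pca={n_pca}")
    if nonlinearity not in _FUN:
        raise ValueError(f"nonlinearity must be one of {sorted(_FUN)}")

    ica = FastICA(
        n_components=K,
        algorithm="parallel",
        whiten="unit-variance",
        fun=_FUN[nonlinearity],
        tol=tol,
        max_iter=max_iter,
        random_state=int(seed),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    if not converged:
        warnings.warn(
            f"fastICA did not converge within {max_iter} iterations "
            f"(tol={tol}); returning the last iterate",
            stacklevel=2,
        )

    # pin the scale convention exactly: population variance 1 per column
    std = sources.std(axis=0, ddof=0)
    sources = sources / std
    mixing = ica.mixing_ * std  # keeps sources @ mixing.T invariant

    return ComponentSet(
        grey=sources,
        white=np.empty((0, K)),
        K=K,
        mixing=mixing,
        ica_params={
            "nonlinearity": nonlinearity,
            "tol": tol,
            "max_iter": max_iter,
            "seed": int(seed),
            "n_iter": int(ica.n_iter_),
            "converged": converged,
        },
    )


def align_signs(components: ComponentSet) -> ComponentSet:
    """Flip components so each grey map's longest tail is positive.

    For every column: if |min| > |max| of the grey loadings, the grey
    column, its white column and its mixing column are all negated.
    Idempotent; a total function.
    """
    grey = components.grey.copy()
    white = components.white.copy()
    mixing = components.mixing.copy()
    for k in range(components.K):
        col = grey[:, k]
        if abs(col.min()) > abs(col.max()):
            grey[:, k] = -grey[:, k]
            if white.size:
                white[:, k] = -white[:, k]
            if mixing.size:
                mixing[:, k] = -mixing[:, k]
    return replace(components, grey=grey, white=white, mixing=mixing)


def back_project(grey: np.ndarray, matrix: TractographyMatrix) -> np.ndarray:
    """Reconstruct white-matter profiles by regression onto the group matrix.

    Solves, jointly over all K grey maps, the least-squares fit of each
    target voxel's seed profile; ``white[t, k]`` is voxel t's fitted
    coefficient on component k.  A rank-deficient design yields the
    minimum-norm solution with a warning.
    """
    M = np.asarray(getattr(matrix, "counts", matrix))
    if grey.shape[0] != M.shape[0]:
        raise ValueError(
            f"grey maps have {grey.shape[0]} rows but the matrix has "
            f"{M.shape[0]} seeds"
        )
    coef, _, rank, _ = np.linalg.lstsq(grey, M, rcond=None)
    if rank < grey.shape[1]:
        warnings.warn(
            f"grey design is rank deficient (rank {rank} < K={grey.shape[1]}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    return coef.T


def variance_explained(
    matrix: TractographyMatrix,
    components: ComponentSet,
) -> float:
    """Fraction of group-matrix variance captured by the rank-K model.

    Computed as 1 - ||M - grey @ white.T||_F^2 / ||M - column means||_F^2,
    i.e. residual energy of the component reconstruction relative to the
    variance of the matrix around its per-target means.
    """
    M = matrix.counts
    if components.grey.shape[0] != M.shape[0] or components.white.shape[0] != M.shape[1]:
        raise ValueError("component maps do not match the matrix dimensions")
    denom = float(np.sum((M - M.mean(axis=0, keepdims=True)) ** 2))
    if denom == 0.0:
        raise ValueError("constant matrix has zero variance; fraction undefined")
    resid = float(np.sum((M - components.grey @ components.white.T) ** 2))
    return 1.0 - resid / denom
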