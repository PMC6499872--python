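"""Hemispheric symmetry scoring and recovery evaluation.

A component's symmetry is the spatial (Pearson) correlation of its grey
loading map with the left-right flipped map of every component, taken over
all seeds of both hemispheres; the best match and its correlation summarize
how well the component is mirrored on the other side.  For synthetic runs,
recovered components are matched to planted truth by an optimal injective
(Hungarian) assignment on absolute correlations, which absorbs ICA's
permutation and sign ambiguities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .synthgeo import GroundTruth

__all__ = [
    "SymmetryReport",
    "MatchReport",
    "flip_map",
    "symmetry_scores",
    "match_to_truth",
]


@dataclass(frozen=True)
class SymmetryReport:
    """K x K flipped-map correlations and per-component best matches."""

    corr: np.ndarray                 # (K, K); NaN where undefined
    best_match: np.ndarray           # (K,) index of best flipped partner
    best_r: np.ndarray               # (K,) highest correlation per component
    group_means: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MatchReport:
    """Optimal assignment of recovered components to planted truth."""

    pairing: dict[int, int]          # recovered index -> truth index
    paired_r_grey: np.ndarray
    paired_r_white: np.ndarray
    mean_abs_r_grey: float
    mean_abs_r_white: float


def flip_map(values: np.ndarray, mirror_map: np.ndarray) -> np.ndarray:
    """Left-right flip of a per-seed map: ``out[s] = values[mirror_map[s]]``."""
    values = np.asarray(values)
    mirror_map = np.asarray(mirror_map)
    if mirror_map.shape[0] != values.shape[0]:
        raise ValueError(
            f"mirror_map covers {mirror_map.shape[0]} seeds but the map has "
            f"{values.shape[0]}"
        )
    return values[mirror_map]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def symmetry_scores(
    components,
    mirror_map: np.ndarray,
    groups: dict[str, list[int]] | None = None,
) -> SymmetryReport:
    """Correlate every grey map with every left-right flipped grey map.

    ``corr[k, j]`` is the Pearson correlation over all seeds between
    component k and the flipped component j; ``best_r[k]`` is the row
    maximum (lowest index on ties) and ``group_means`` averages best_r over
    user-supplied named component groupings.  Constant maps yield undefined
    correlations, recorded as NaN and excluded from maxima with a warning.
    """
    grey = components.grey if hasattr(components, "grey") else np.asarray(components)
    K = grey.shape[1]
    if K < 1:
        raise ValueError("need at least one component")
    flipped = flip_map(grey, mirror_map)
    corr = np.empty((K, K))
    for k in range(K):
        for j in range(K):
            corr[k, j] = _pearson(grey[:, k], flipped[:, j])
    if np.isnan(corr).any():
        warnings.warn(
            "constant map(s) produced undefined correlations; "
            "excluded from best-match maxima",
            stacklevel=2,
        )
    masked = np.where(np.isnan(corr), -np.inf, corr)
    best_match = np.argmax(masked, axis=1)
    best_r = masked[np.arange(K), best_match]

    group_means = {}
    if groups:
        for name, idx in groups.items():
            group_means[name] = float(np.mean(best_r[list(idx)]))
    return SymmetryReport(
        corr=corr, best_match=best_match, best_r=best_r, group_means=group_means
    )


def match_to_truth(components, truth: GroundTruth) -> MatchReport:
    """Optimally pair recovered components with planted components.

    Solves the assignment maximizing total absolute grey-map correlation
    (Hungarian algorithm), then reports per-pair absolute correlations for
    grey and white maps under that pairing.  Invariant to permutation and
    negation of the recovered components.
    """
    grey = components.grey
    white = components.white
    K, k_true = grey.shape[1], truth.k_true
    if K < 1 or k_true < 1:
        raise ValueError("need at least one component on both sides")

    cost = np.empty((K, k_true))
    for k in range(K):
        for j in range(k_true):
            r = _pearson(grey[:, k], truth.grey_truth[:, j])
            cost[k, j] = 0.0 if np.isnan(r) else abs(r)
    rows, cols = linear_sum_assignment(-cost)
    pairing = dict(zip(rows.tolist(), cols.tolist()))

    r_grey = np.array([cost[k, j] for k, j in pairing.items()])
    r_white = np.array(
        [
            abs(_pearson(white[:, k], truth.white_truth[:, j]))
            if white.size
            else np.nan
            for k, j in pairing.items()
        ]
    )
    return MatchReport(
        pairing=pairing,
        paired_r_grey=r_grey,
        paired_r_white=r_white,
        mean_abs_r_grey=float(np.mean(r_grey)),
        mean_abs_r_white=float(np.mean(r_white)) if white.size else np.nan,
    )
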