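"""Synthetic two-hemisphere geometries and group tractography matrices.

Emulates the data model of surface-seeded probabilistic tractography: a
matrix of streamline visitation counts from cortical seed vertices to brain
target voxels, built per subject and averaged into a group matrix.  Planted
ground-truth components (paired grey-matter loading maps and white-matter
tract profiles, optionally exact mirror images across hemispheres) make the
generator usable as a recovery benchmark for the decomposition pipeline.

The count model is Poisson on a low-rank nonnegative rate matrix::

    rate[s, t] = c * ( baseline + sum_k a_k * j_k * grey[s, k] * white[t, k] )

with ``j_k`` a per-subject multiplicative jitter (log-normal, unit mean,
spread ``noise_scale``) and ``c`` a global scale chosen so the largest
expected row total equals ``n_samples_per_seed`` — each seed emits a fixed
streamline budget, as in probtrackx-style tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


__all__ = [
    "Geometry",
    "GroundTruth",
    "TractographyMatrix",
    "make_geometry",
    "plant_components",
    "simulate_subject_matrix",
    "average_matrices",
]


@dataclass(frozen=True)
class Geometry:
    """Seed-vertex and target-voxel layout of a two-hemisphere phantom.

    Seeds ``0 .. n-1`` are the left hemisphere, ``n .. 2n-1`` the right.
    Targets are all voxels of ``volume_shape`` in C (row-major) order.  The
    first voxel axis is the left-right axis; the mirror plane sits between
    indices ``dim0/2 - 1`` and ``dim0/2``, so voxel ``i`` mirrors to
    ``dim0 - 1 - i``.
    """

    n_seeds_per_hemi: int
    seed_coords: np.ndarray          # (2n, 3) float, voxel units (1 mm iso)
    seed_hemi: np.ndarray            # (2n,) of "L" / "R"
    volume_shape: tuple[int, int, int]
    n_targets: int
    target_coords: np.ndarray        # (n_targets, 3) int voxel indices
    seed_mirror: np.ndarray          # (2n,) involutive permutation
    target_mirror: np.ndarray        # (n_targets,) involutive permutation

    @property
    def n_seeds(self) -> int:
        return 2 * self.n_seeds_per_hemi

    def validate(self) -> None:
        n = self.n_seeds
        if not np.array_equal(self.seed_mirror[self.seed_mirror], np.arange(n)):
            raise ValueError("seed_mirror is not an involution")
        if not np.array_equal(
            self.target_mirror[self.target_mirror], np.arange(self.n_targets)
        ):
            raise ValueError("target_mirror is not an involution")
        left = self.seed_hemi == "L"
        if np.any(self.seed_hemi[self.seed_mirror[left]] != "R"):
            raise ValueError("seed_mirror must pair left seeds with right seeds")


@dataclass(frozen=True)
class GroundTruth:
    """Planted components: what the decomposition should recover.

    ``grey_truth`` (seeds x k) holds nonnegative cortical loading maps,
    ``white_truth`` (targets x k) the matching tract-profile maps.  For
    every pair in ``symmetric_pairs`` the second column is the exact
    mirror image of the first.  ``winner_truth`` is the per-seed argmax
    component (lowest index on ties), -1 for seeds outside all supports.
    """

    k_true: int
    grey_truth: np.ndarray
    white_truth: np.ndarray
    baseline_rate: float
    amplitude: np.ndarray            # (k_true,) positive
    symmetric_pairs: list[tuple[int, int]] = field(default_factory=list)
    winner_truth: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class TractographyMatrix:
    """Streamline visitation counts, seeds x targets, plus geometry."""

    counts: np.ndarray               # (n_seeds, n_targets), nonnegative
    n_samples_per_seed: int
    geometry: Geometry
    subject_id: str = "subject"

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def make_geometry(
    n_seeds_per_hemi: int,
    volume_shape: tuple[int, int, int],
    seed: int,
) -> Geometry:
    """Build a mirror-symmetric two-hemisphere phantom geometry.

    Left-hemisphere seeds are sampled uniformly in the left half-volume;
    right seeds are their exact reflections across the mid-sagittal plane,
    so the seed mirror map is an involution by construction.  All voxels of
    ``volume_shape`` are targets.
    """
    if n_seeds_per_hemi < 4:
        raise ValueError(f"n_seeds_per_hemi must be >= 4, got {n_seeds_per_hemi}")
    volume_shape = tuple(int(d) for d in volume_shape)
    if len(volume_shape) != 3 or any(d < 4 for d in volume_shape):
        raise ValueError(f"each volume_shape dimension must be >= 4, got {volume_shape}")
    d0, d1, d2 = volume_shape
    if d0 % 2 != 0:
        raise ValueError(
            f"first volume axis must be even for a clean mirror plane, got {d0}"
        )

    rng = np.random.default_rng(seed)
    n = n_seeds_per_hemi
    left = np.empty((n, 3))
    left[:, 0] = rng.uniform(0.5, d0 / 2 - 0.5, size=n)
    left[:, 1] = rng.uniform(0.5, d1 - 0.5, size=n)
    left[:, 2] = rng.uniform(0.5, d2 - 0.5, size=n)
    right = left.copy()
    right[:, 0] = (d0 - 1) - left[:, 0]

    seed_coords = np.vstack([left, right])
    seed_hemi = np.array(["L"] * n + ["R"] * n)
    seed_mirror = np.concatenate([np.arange(n) + n, np.arange(n)])

    ii, jj, kk = np.indices(volume_shape)
    target_coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    # flat index of the reflected voxel (d0-1-i, j, k) in C order
    target_mirror = (
        (d0 - 1 - target_coords[:, 0]) * d1 * d2
        + target_coords[:, 1] * d2
        + target_coords[:, 2]
    )

    geom = Geometry(
        n_seeds_per_hemi=n,
        seed_coords=seed_coords,
        seed_hemi=seed_hemi,
        volume_shape=volume_shape,
        n_targets=d0 * d1 * d2,
        target_coords=target_coords,
        seed_mirror=seed_mirror,
        target_mirror=target_mirror.astype(np.intp),
    )
    geom.validate()
    return geom


def _bump_windows(n: int, k: int, overlap: float) -> list[np.ndarray]:
    """Contiguous index windows over ``range(n)`` with controlled overlap.

    Adjacent windows of length L and stride s share a Jaccard overlap of
    (L-s)/(L+s); solving for the requested value gives the stride.  At
    overlap=0 the windows are an exact partition (disjoint by construction).
    """
    if overlap == 0.0:
        bounds = np.linspace(0, n, k + 1).astype(int)
        return [np.arange(bounds[c], bounds[c + 1]) for c in range(k)]
    ratio = (1.0 - overlap) / (1.0 + overlap)
    length = n / ((k - 1) * ratio + 1.0)
    stride = length * ratio
    wins = []
    for c in range(k):
        start = int(round(c * stride))
        stop = min(n, start + int(round(length)))
        wins.append(np.arange(start, stop))
    return wins


def _bump_profile(m: int) -> np.ndarray:
    """Smooth strictly-positive half-sine bump over m support points."""
    return np.sin(np.pi * (np.arange(m) + 0.5) / m)


def _tract_blob(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    x_max: int,
) -> np.ndarray:
    """A connected 'tract' blob: a jittered path between two endpoint
    regions, dilated and smoothed, confined to voxels with i < x_max."""
    d0, d1, d2 = shape
    lo = np.minimum([1, 1, 1], [x_max - 1, d1 - 2, d2 - 2])
    hi = np.maximum(lo, [x_max - 2, d1 - 2, d2 - 2])
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    t = np.linspace(0.0, 1.0, 200)
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    # sinusoidal perpendicular wobble keeps the path tract-like, not straight
    perp = rng.normal(size=3)
    perp /= np.linalg.norm(perp)
    amp = rng.uniform(0.5, 1.5)
    pts = pts + amp * np.sin(np.pi * t)[:, None] * perp[None, :]
    vox = np.clip(np.round(pts).astype(int), lo, hi)

    mask = np.zeros(shape, dtype=bool)
    mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    # endpoint regions: small spheres at both ends
    for p in (a, b):
        ijk = np.clip(np.round(p).astype(int), lo, hi)
        mask[ijk[0], ijk[1], ijk[2]] = True
    mask = ndimage.binary_dilation(mask, iterations=1)
    vol = ndimage.gaussian_filter(mask.astype(float), sigma=0.8)
    vol[:, :] = np.where(vol < 0.05 * vol.max(), 0.0, vol)
    vol /= vol.max()
    vol[x_max:, :, :] = 0.0  # stay in hemisphere
    return vol


def plant_components(
    geometry: Geometry,
    k_true: int,
    overlap: float,
    symmetric: bool,
    seed: int,
    baseline_rate: float = 0.01,
) -> GroundTruth:
    """Plant ``k_true`` paired grey/white component maps.

    Grey maps are smooth localized bumps over seeds (contiguous windows of
    the seeds sorted along the longest in-hemisphere axis; adjacent windows
    share the requested Jaccard ``overlap``).  White maps are connected
    voxel blobs shaped like a tract path with endpoint regions.  With
    ``symmetric`` set, components come in exact mirror pairs.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if k_true < 1:
        raise ValueError("k_true must be positive")
    if symmetric and k_true % 2 != 0:
        raise ValueError(f"symmetric planting requires even k_true, got {k_true}")
    if k_true > geometry.n_seeds // 2:
        raise ValueError(
            f"k_true={k_true} exceeds seed capacity ({geometry.n_seeds} seeds)"
        )

    rng = np.random.default_rng(seed)
    n_seeds = geometry.n_seeds
    n_half = geometry.n_seeds_per_hemi
    grey = np.zeros((n_seeds, k_true))
    white = np.zeros((geometry.n_targets, k_true))
    pairs: list[tuple[int, int]] = []
    d0 = geometry.volume_shape[0]

    def sort_key(idx: np.ndarray, axis: int) -> np.ndarray:
        c = geometry.seed_coords[idx, axis]
        span = c.max() - c.min()
        return c + rng.normal(0.0, 0.01 * max(span, 1e-9), size=len(idx))

    if symmetric:
        k_half = k_true // 2
        left_idx = np.arange(n_half)
        coords = geometry.seed_coords[left_idx]
        axis = 1 + int(np.argmax(np.ptp(coords[:, 1:], axis=0)))  # y or z
        order = left_idx[np.argsort(sort_key(left_idx, axis), kind="stable")]
        for c, win in enumerate(_bump_windows(n_half, k_half, overlap)):
            sup = order[win]
            grey[sup, c] = _bump_profile(len(win))
            # exact mirror partner
            grey[geometry.seed_mirror[sup], k_half + c] = grey[sup, c]
            vol = _tract_blob(geometry.volume_shape, rng, x_max=d0 // 2)
            white[:, c] = vol.ravel()
            white[:, k_half + c] = np.flip(vol, axis=0).ravel()
            pairs.append((c, k_half + c))
    else:
        all_idx = np.arange(n_seeds)
        axis = 1 + int(np.argmax(np.ptp(geometry.seed_coords[:, 1:], axis=0)))
        order = all_idx[np.argsort(sort_key(all_idx, axis), kind="stable")]
        for c, win in enumerate(_bump_windows(n_seeds, k_true, overlap)):
            sup = order[win]
            grey[sup, c] = _bump_profile(len(win))
            vol = _tract_blob(geometry.volume_shape, rng, x_max=d0)
            white[:, c] = vol.ravel()

    amplitude = rng.uniform(0.8, 1.2, size=k_true)

    winner = np.full(n_seeds, -1, dtype=int)
    in_support = grey.max(axis=1) > 0
    winner[in_support] = np.argmax(grey[in_support], axis=1)

    return GroundTruth(
        k_true=k_true,
        grey_truth=grey,
        white_truth=white,
        baseline_rate=float(baseline_rate),
        amplitude=amplitude,
        symmetric_pairs=pairs,
        winner_truth=winner,
    )


def expected_rate(
    truth: GroundTruth,
    geometry: Geometry,
    n_samples_per_seed: int,
) -> np.ndarray:
    """Noise-free (jitter-free) Poisson rate matrix after row-budget scaling."""
    raw = truth.baseline_rate + (truth.grey_truth * truth.amplitude) @ truth.white_truth.T
    max_row = raw.sum(axis=1).max()
    if max_row <= 0:
        raise ValueError("degenerate all-zero truth: cannot scale streamline budget")
    return raw * (n_samples_per_seed / max_row)


def simulate_subject_matrix(
    truth: GroundTruth,
    geometry: Geometry,
    n_samples_per_seed: int = 10_000,
    noise_scale: float = 0.0,
    seed: int = 0,
    subject_id: str = "subject",
) -> TractographyMatrix:
    """Draw one subject's visitation-count matrix from the planted truth.

    Counts are Poisson with rate baseline + low-rank signal, modulated by a
    per-subject, per-component log-normal jitter of spread ``noise_scale``
    (unit mean), globally scaled so the largest expected row total equals
    ``n_samples_per_seed``, and clipped at ``n_samples_per_seed``.
    """
    if noise_scale < 0:
        raise ValueError(f"noise_scale must be nonnegative, got {noise_scale}")
    if truth.grey_truth.shape[0] != geometry.n_seeds:
        raise ValueError("truth / geometry seed-count mismatch")
    if truth.white_truth.shape[0] != geometry.n_targets:
        raise ValueError("truth / geometry target-count mismatch")

    rng = np.random.default_rng(seed)
    if noise_scale > 0:
        z = rng.standard_normal(truth.k_true)
        jitter = np.exp(noise_scale * z - 0.5 * noise_scale**2)
    else:
        jitter = np.ones(truth.k_true)

    raw = truth.baseline_rate + (
        truth.grey_truth * (truth.amplitude * jitter)
    ) @ truth.white_truth.T
    max_row = raw.sum(axis=1).max()
    if max_row <= 0:
        raise ValueError("degenerate all-zero truth: cannot scale streamline budget")
    rate = raw * (n_samples_per_seed / max_row)

    counts = rng.poisson(rate).astype(np.float64)
    np.minimum(counts, n_samples_per_seed, out=counts)
    return TractographyMatrix(
        counts=counts,
        n_samples_per_seed=int(n_samples_per_seed),
        geometry=geometry,
        subject_id=subject_id,
    )


def average_matrices(matrices: list[TractographyMatrix]) -> TractographyMatrix:
    """Element-wise mean of per-subject matrices -> group matrix."""
    if len(matrices) == 0:
        raise ValueError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape != first.shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {first.shape}")
        if m.geometry is not first.geometry and not np.array_equal(
            m.geometry.seed_mirror, first.geometry.seed_mirror
        ):
            raise ValueError("geometry mismatch between matrices")
        if m.n_samples_per_seed != first.n_samples_per_seed:
            raise ValueError("n_samples_per_seed mismatch between matrices")
    mean = np.mean([m.counts for m in matrices], axis=0)
    return replace(first, counts=mean, subject_id="group-average")
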