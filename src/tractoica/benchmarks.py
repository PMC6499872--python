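"""Standard recovery benchmarks on the synthetic connectome generator.

These are the package's canonical self-checks, shared by the test suite,
the acceptance script and the examples:

* :func:`migp_vs_svd` — principal angles between the MIGP subspace and the
  exact truncated-SVD subspace on a random low-rank matrix.
* :func:`laplace_ica_recovery` — unmixing of reduced matrices synthesized
  from known independent Laplace seed maps.
* :func:`standard_benchmark` — the full simulate -> average -> reduce ->
  ICA -> back-project chain on the two-hemisphere phantom (2 x 100 seeds,
  20 x 16 x 16 volume, 8 mirror-symmetric planted components, 10 subjects,
  10,000 streamlines per seed), evaluated against the planted truth.
* :func:`ggm_recovery` — Gaussian/gamma mixture parameter recovery on a
  simulated two-class map.
* :func:`symmetry_attenuation` — best flipped-map correlation under
  additive independent noise, against the analytic SNR^2/(SNR^2+1) curve.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import subspace_angles

from . import synthgeo
from .ica import ComponentSet, align_signs, back_project, run_ica, variance_explained
from .migp import ReducedMatrix, migp_reduce
from .parcellation import fit_ggm, threshold_map, winner_take_all
from .symmetry import match_to_truth, symmetry_scores

__all__ = [
    "migp_vs_svd",
    "laplace_ica_recovery",
    "standard_benchmark",
    "ggm_recovery",
    "symmetry_attenuation",
]

BENCHMARK = dict(
    n_seeds_per_hemi=100,
    volume_shape=(20, 16, 16),
    k_true=8,
    overlap=0.0,
    symmetric=True,
    n_subjects=10,
    n_samples_per_seed=10_000,
    n_pca=30,
    chunk_size=512,
    K=8,
)


def migp_vs_svd(
    n_seeds: int = 200,
    n_targets: int = 2000,
    rank: int = 10,
    n_pca: int = 20,
    chunk_size: int = 250,
    seed: int = 0,
) -> float:
    """Max principal angle (radians) between MIGP and exact-SVD subspaces
    for one random rank-deficient matrix and one random chunk order."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_seeds, rank))
    B = rng.standard_normal((rank, n_targets))
    X = A @ B  # exactly rank-deficient; MIGP must match plain PCA here
    mat = _as_matrix(X)
    red = migp_reduce(mat, n_pca=n_pca, chunk_size=chunk_size, seed=seed)
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    angles = subspace_angles(red.scores[:, :rank], U[:, :rank])
    return float(np.max(angles))


def _as_matrix(X: np.ndarray) -> synthgeo.TractographyMatrix:
    """Wrap a bare array for operations that only touch ``counts``."""

    class _Stub:
        counts = X
        shape = X.shape
        n_samples_per_seed = 0
        subject_id = "synthetic"

    return _Stub()  # type: ignore[return-value]


def laplace_ica_recovery(
    seed: int,
    n_seeds: int = 1000,
    n_sources: int = 5,
    n_pca: int = 10,
) -> float:
    """Mean paired |r| between true and recovered Laplace seed maps.

    Builds a reduced matrix as a random mixture of independent
    Laplace-distributed seed-domain sources, unmixes with run_ica and pairs
    estimates with truth by optimal assignment.
    """
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(n_seeds, n_sources))
    A = rng.standard_normal((n_pca, n_sources))
    scores = S @ A.T
    reduced = ReducedMatrix(
        scores=scores,
        n_pca=n_pca,
        chunk_size=n_pca,
        chunk_order=np.arange(n_pca),
        seed=seed,
        singular_values=np.linalg.svd(scores, compute_uv=False),
        effective_rank=min(n_sources, n_pca),
    )
    comps = run_ica(reduced, K=n_sources, seed=seed)
    truth = synthgeo.GroundTruth(
        k_true=n_sources,
        grey_truth=S,
        white_truth=np.zeros((1, n_sources)),
        baseline_rate=0.0,
        amplitude=np.ones(n_sources),
        winner_truth=np.argmax(S, axis=1),
    )
    return match_to_truth(comps, truth).mean_abs_r_grey


def standard_benchmark(master_seed: int, noise_scale: float = 0.0) -> dict:
    """Run the full chain on the standard phantom and score recovery.

    Returns a dict with the match report, winner-take-all agreement on
    in-support seeds, symmetry report, variance explained, and the raw
    objects for further inspection.
    """
    p = BENCHMARK
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(4 + p["n_subjects"]) % (2**31)
    geom = synthgeo.make_geometry(
        p["n_seeds_per_hemi"], p["volume_shape"], seed=int(seeds[0])
    )
    truth = synthgeo.plant_components(
        geom,
        k_true=p["k_true"],
        overlap=p["overlap"],
        symmetric=p["symmetric"],
        seed=int(seeds[1]),
    )
    subjects = [
        synthgeo.simulate_subject_matrix(
            truth,
            geom,
            n_samples_per_seed=p["n_samples_per_seed"],
            noise_scale=noise_scale,
            seed=int(seeds[4 + i]),
            subject_id=f"sub-{i:03d}",
        )
        for i in range(p["n_subjects"])
    ]
    group = synthgeo.average_matrices(subjects)
    reduced = migp_reduce(
        group, n_pca=p["n_pca"], chunk_size=p["chunk_size"], seed=int(seeds[2])
    )
    comps = run_ica(reduced, K=p["K"], seed=int(seeds[3]))
    white = back_project(comps.grey, group)
    comps = align_signs(
        ComponentSet(
            grey=comps.grey,
            white=white,
            K=comps.K,
            mixing=comps.mixing,
            ica_params=comps.ica_params,
        )
    )
    match = match_to_truth(comps, truth)

    # winner-take-all agreement, after relabelling through the pairing
    labels = winner_take_all(comps.grey)
    relabel = np.full(comps.K, -1)
    for rec, tru in match.pairing.items():
        relabel[rec] = tru
    mapped = np.where(labels >= 0, relabel[labels], -1)
    in_support = truth.winner_truth >= 0
    agreement = float(np.mean(mapped[in_support] == truth.winner_truth[in_support]))

    sym = symmetry_scores(comps, geom.seed_mirror)
    ve = variance_explained(group, comps)
    return {
        "geometry": geom,
        "truth": truth,
        "group": group,
        "components": comps,
        "match": match,
        "wta_agreement": agreement,
        "symmetry": sym,
        "variance_explained": ve,
    }


def ggm_recovery(seed: int, n: int = 5000) -> dict:
    """Fit the GGM to 0.7 N(0,1) + 0.3 (2 + Gamma(3,1)) and score recovery.

    Returns recovered (pi1, shape, scale), relative errors against the
    generating values, and the p>0.5 mask accuracy against the true class
    labels.
    """
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < 0.3
    x = np.where(labels, 2.0 + rng.gamma(3.0, 1.0, size=n), rng.standard_normal(n))
    fit = fit_ggm(x)
    mask = threshold_map(fit, x, p=0.5)
    return {
        "fit": fit,
        "pi1": fit.pi1,
        "shape": fit.shape,
        "scale": fit.scale,
        "rel_err": {
            "pi1": abs(fit.pi1 - 0.3) / 0.3,
            "shape": abs(fit.shape - 3.0) / 3.0,
            "scale": abs(fit.scale - 1.0) / 1.0,
        },
        "mask_accuracy": float(np.mean(mask == labels)),
    }


def symmetry_attenuation(
    snr: float,
    n_seeds_per_hemi: int = 400,
    k_true: int = 4,
    n_reps: int = 20,
    seed: int = 0,
) -> float:
    """Mean best flipped-map correlation of exact-mirror maps plus
    independent additive Gaussian noise at amplitude SNR ``snr``.

    The analytic expectation is SNR^2 / (SNR^2 + 1): both the map and its
    mirror carry independent noise, attenuating the correlation by the
    signal variance fraction.
    """
    ss = np.random.SeedSequence(seed)
    vals = []
    for rep_seed in ss.generate_state(n_reps) % (2**31):
        rng = np.random.default_rng(int(rep_seed))
        geom = synthgeo.make_geometry(n_seeds_per_hemi, (8, 8, 8), seed=int(rep_seed))
        truth = synthgeo.plant_components(
            geom, k_true=k_true, overlap=0.0, symmetric=True, seed=int(rep_seed)
        )
        grey = truth.grey_truth.astype(float).copy()
        for k in range(k_true):
            sd = grey[:, k].std()
            grey[:, k] += rng.normal(0.0, sd / snr, size=grey.shape[0])
        comps = ComponentSet(
            grey=grey,
            white=np.empty((0, k_true)),
            K=k_true,
            mixing=np.empty((0, k_true)),
        )
        rep = symmetry_scores(comps, geom.seed_mirror)
        vals.append(rep.best_r.mean())
    return float(np.mean(vals))
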