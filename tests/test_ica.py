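"""ICA unmixing, sign alignment, back-projection, variance explained."""

import numpy as np
import pytest

from tractoica import (
    ComponentSet,
    align_signs,
    back_project,
    migp_reduce,
    run_ica,
    variance_explained,
)
from tractoica.benchmarks import _as_matrix, laplace_ica_recovery
from tractoica.migp import ReducedMatrix


def _reduced_from(scores, seed=0):
    return ReducedMatrix(
        scores=scores,
        n_pca=scores.shape[1],
        chunk_size=scores.shape[1],
        chunk_order=np.arange(scores.shape[1]),
        seed=seed,
        singular_values=np.linalg.svd(scores, compute_uv=False),
        effective_rank=min(scores.shape),
    )


class TestRunICA:
    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_laplace_sources(self, seed):
        assert laplace_ica_recovery(seed) >= 0.95

    def test_rank_one_recovers_dominant_direction(self, rng):
        g = rng.laplace(size=300)
        scores = np.outer(g, rng.standard_normal(4))
        comps = run_ica(_reduced_from(scores), K=1, seed=0)
        r = np.corrcoef(comps.grey[:, 0], g)[0, 1]
        assert abs(r) > 1.0 - 1e-8

    def test_unit_variance_convention(self, rng):
        scores = rng.laplace(size=(500, 8))
        comps = run_ica(_reduced_from(scores), K=4, seed=1)
        assert np.allclose(comps.grey.var(axis=0, ddof=0), 1.0, atol=1e-8)

    def test_mixing_reconstructs_scores(self, rng):
        S = rng.laplace(size=(400, 3))
        A = rng.standard_normal((5, 3))
        scores = S @ A.T
        comps = run_ica(_reduced_from(scores), K=3, seed=2)
        recon = comps.grey @ comps.mixing.T
        # ICA centers the features; reconstruction matches up to column means
        resid = (scores - scores.mean(0)) - (recon - recon.mean(0))
        assert np.linalg.norm(resid) < 1e-6 * np.linalg.norm(scores)

    def test_rejects_k_above_n_pca(self, rng):
        scores = rng.standard_normal((50, 4))
        with pytest.raises(ValueError):
            run_ica(_reduced_from(scores), K=5, seed=0)

    def test_nonconvergence_recorded_not_raised(self, rng):
        scores = rng.standard_normal((200, 6))
        with pytest.warns(UserWarning, match="converge"):
            comps = run_ica(_reduced_from(scores), K=6, max_iter=2, seed=0)
        assert comps.ica_params["converged"] is False
        assert comps.grey.shape == (200, 6)


class TestAlignSigns:
    def _comps(self, grey):
        K = grey.shape[1]
        return ComponentSet(
            grey=grey,
            white=np.ones((3, K)),
            K=K,
            mixing=np.ones((2, K)),
        )

    def test_positive_tail_unchanged(self):
        grey = np.array([[3.0], [-1.0], [0.5]])
        out = align_signs(self._comps(grey))
        assert np.array_equal(out.grey, grey)

    def test_negative_tail_flipped_everywhere(self):
        grey = np.array([[1.0], [-3.0], [0.5]])
        out = align_signs(self._comps(grey))
        assert out.grey[:, 0].max() == 3.0
        assert np.all(out.white == -1)
        assert np.all(out.mixing == -1)

    def test_idempotent_on_random_sets(self, rng):
        for _ in range(100):
            grey = rng.standard_normal((20, 3))
            once = align_signs(self._comps(grey))
            twice = align_signs(once)
            assert np.array_equal(once.grey, twice.grey)
            assert np.array_equal(once.white, twice.white)

    def test_sign_convention_holds_after_alignment(self, rng):
        grey = rng.standard_normal((50, 6))
        out = align_signs(self._comps(grey))
        assert np.all(out.grey.max(axis=0) >= np.abs(out.grey.min(axis=0)))


class TestBackProject:
    def test_exact_rank_one_recovery(self, rng):
        g = rng.laplace(size=200)
        g = (g - g.mean()) / g.std()
        w = rng.gamma(2.0, 1.0, size=500)
        M = np.outer(g, w)
        white = back_project(g[:, None], _as_matrix(M))
        r = np.corrcoef(white[:, 0], w)[0, 1]
        assert r > 1.0 - 1e-10

    def test_orthonormal_design_collapses_to_projection(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((100, 5)))
        M = rng.standard_normal((100, 50))
        white = back_project(Q, _as_matrix(M))
        assert np.allclose(white, M.T @ Q, atol=1e-10)

    def test_rank_deficient_design_warns(self, rng):
        g = rng.standard_normal((50, 1))
        G = np.hstack([g, g])  # duplicated column
        with pytest.warns(UserWarning, match="rank deficient"):
            back_project(G, _as_matrix(rng.standard_normal((50, 20))))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            back_project(
                rng.standard_normal((10, 2)), _as_matrix(rng.standard_normal((12, 5)))
            )


class TestVarianceExplained:
    def _fitted(self, M, grey):
        white = back_project(grey, _as_matrix(M))
        return ComponentSet(
            grey=grey, white=white, K=grey.shape[1], mixing=np.empty((0, grey.shape[1]))
        )

    def test_noise_free_low_rank_fully_explained(self, rng):
        G = rng.laplace(size=(150, 4))
        W = rng.gamma(2.0, 1.0, size=(300, 4))
        M = G @ W.T
        comps = self._fitted(M, G)
        assert variance_explained(_as_matrix(M), comps) >= 0.999

    def test_orthogonal_maps_explain_nothing(self, rng):
        a = rng.standard_normal(100)
        a -= a.mean()  # zero column means, so centering changes nothing
        M = np.outer(a, rng.standard_normal(40))
        grey = np.linalg.qr(rng.standard_normal((100, 3)))[0]
        # project grey away from the data's column space: regression then
        # yields exactly zero white maps
        u = a / np.linalg.norm(a)
        grey = grey - np.outer(u, u @ grey)
        comps = self._fitted(M, grey)
        assert abs(variance_explained(_as_matrix(M), comps)) < 1e-9

    def test_monotone_in_nested_component_sets(self, rng):
        G = rng.laplace(size=(120, 8))
        M = G @ rng.gamma(2.0, 1.0, size=(200, 8)).T + 0.3 * rng.standard_normal((120, 200))
        fracs = [
            variance_explained(_as_matrix(M), self._fitted(M, G[:, :k]))
            for k in (2, 4, 8)
        ]
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_constant_matrix_rejected(self, rng):
        M = np.full((60, 30), 5.0)
        comps = ComponentSet(
            grey=rng.standard_normal((60, 2)),
            white=rng.standard_normal((30, 2)),
            K=2,
            mixing=np.empty((0, 2)),
        )
        with pytest.raises(ValueError, match="zero variance"):
            variance_explained(_as_matrix(M), comps)
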