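"""Rank-one decomposition: exact algebraic identities, oracle
equivalence against independent eigensolves and power iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cicdyn as cd
from cicdyn.separability import RankOneDecomposer, accuracy_ratio


def power_iteration_leading_pair(X, iters=2000, tol=1e-14):
    """Independent oracle: leading singular pair via power iteration on
    X X^T (no SVD call)."""
    A = X @ X.T
    v = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
    for _ in range(iters):
        w = A @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    sigma1 = np.sqrt(v @ A @ v)
    return sigma1, v


class TestDecompose:
    def test_rank_one_input(self):
        X = np.outer([1.0, 2.0], [3.0, 4.0])
        d = cd.decompose(X)
        assert d.singular_values[1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.abs(d.spatial_mode), np.array([1, 2]) / np.sqrt(5))

    def test_diagonal_matrix(self):
        d = cd.decompose(np.diag([3.0, 4.0]))
        assert np.allclose(d.singular_values, [4.0, 3.0])
        assert np.allclose(np.abs(d.spatial_mode), [0.0, 1.0], atol=1e-12)

    def test_matches_independent_eigensolve(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.random((20, 30))
            d = cd.decompose(X)
            evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
            evals = np.clip(evals, 0, None)[:20]
            assert np.allclose(d.singular_values**2, evals, rtol=1e-10, atol=1e-10)

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(0)
        X = rng.random((15, 25)) + 1.0
        d = cd.decompose(X)
        s1, u1 = power_iteration_leading_pair(X)
        assert d.singular_values[0] == pytest.approx(s1, rel=1e-8)
        assert np.allclose(np.abs(d.spatial_mode), np.abs(u1), atol=1e-8)

    def test_residual_identity(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 30))
        d = cd.decompose(X)
        resid = np.linalg.norm(X - d.reconstruction, "fro") ** 2
        assert resid == pytest.approx(np.sum(d.singular_values[1:] ** 2), rel=1e-8)

    def test_amplitude_is_projection(self):
        rng = np.random.default_rng(5)
        X = rng.random((18, 22))
        d = cd.decompose(X)
        assert np.allclose(d.temporal_amplitude, d.spatial_mode @ X)
        assert np.linalg.norm(d.spatial_mode) == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_mode_for_nonnegative_matrix(self, wt_embryo):
        stm, _ = wt_embryo
        d = cd.decompose(stm)
        assert np.all(d.spatial_mode >= -1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="non-finite"):
            cd.decompose(np.array([[1.0, np.nan], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="zero"):
            cd.decompose(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cd.decompose(np.ones((1, 5)))


class TestAccuracyRatio:
    @pytest.mark.parametrize(
        "sigmas, expected",
        [
            ((5.0, 0.0, 0.0), 1.0),
            ((4.0, 3.0), 0.8),
            ((1.0, 1.0), 1.0 / np.sqrt(2.0)),
        ],
    )
    def test_known_values(self, sigmas, expected):
        assert accuracy_ratio(np.array(sigmas)) == pytest.approx(expected, abs=1e-12)

    def test_equals_norm_ratio(self):
        rng = np.random.default_rng(11)
        X = rng.random((10, 14))
        d = cd.decompose(X)
        assert d.accuracy_ratio == pytest.approx(
            np.linalg.norm(X, 2) / np.linalg.norm(X, "fro"), rel=1e-12
        )

    @given(c=st.floats(1e-6, 1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        X = rng.random((8, 12))
        assert cd.decompose(c * X).accuracy_ratio == pytest.approx(
            cd.decompose(X).accuracy_ratio, rel=1e-9
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            accuracy_ratio(np.zeros(4))


class TestReconstruct:
    def test_rank_one_roundtrip(self):
        X = np.outer([1.0, 2.0, 5.0], [3.0, 4.0, 1.0, 2.0])
        d = cd.decompose(X)
        assert np.linalg.norm(cd.reconstruct(d) - X, "fro") <= 1e-10 * np.linalg.norm(X, "fro")

    def test_eckart_young_residual(self, wt_embryo):
        stm, _ = wt_embryo
        d = cd.decompose(stm)
        rel = np.linalg.norm(stm.values - d.reconstruction, "fro") / np.linalg.norm(
            stm.values, "fro"
        )
        assert rel <= np.sqrt(1.0 - d.accuracy_ratio**2) + 1e-12

    def test_reconstruction_is_rank_one(self, wt_embryo):
        stm, _ = wt_embryo
        rec = cd.decompose(stm).reconstruction
        s = np.linalg.svd(rec, compute_uv=False)
        assert s[1] < 1e-10 * s[0]


class TestEstimatorApi:
    def test_fit_sets_trailing_underscore_attributes(self, wt_embryo):
        stm, _ = wt_embryo
        est = RankOneDecomposer().fit(stm)
        for attr in ("singular_values_", "spatial_mode_", "temporal_amplitude_",
                     "accuracy_ratio_"):
            assert hasattr(est, attr)

    def test_transform_projects_onto_mode(self, wt_embryo):
        stm, _ = wt_embryo
        est = RankOneDecomposer().fit(stm)
        assert np.allclose(est.transform(stm), est.temporal_amplitude_)

    def test_get_params_roundtrip(self):
        est = RankOneDecomposer()
        assert est.set_params(**est.get_params()) is est

    def test_unfitted_raises(self):
        with pytest.raises(AttributeError):
            RankOneDecomposer().reconstruct()

    def test_plateau_scaled_amplitude_restores_intensity_units(
        self, noiseless_embryo
    ):
        stm, truth = noiseless_embryo
        d = cd.decompose(stm)
        scaled = d.plateau_scaled_amplitude
        # noiseless: scaled amplitude equals the generating amplitude times
        # the spatial-shape peak (which is ~1 for the default profile)
        peak = truth.spatial_profile_true.max()
        assert np.allclose(scaled, truth.amplitude_true * peak, rtol=1e-8, atol=1e-8)
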