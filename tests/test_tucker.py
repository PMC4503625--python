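"""Tucker3 ALS: exactness, monotonicity, identities, fit accounting."""

import numpy as np
import pytest

import threemode as tm
from conftest import hosvd_fit_oracle
from threemode.errors import RankAdmissibilityError, UndefinedFitError, ValidationError
from threemode.tucker import multi_mode_dot


def _random_model(rng, dims, ranks):
    mats = []
    for d, r in zip(dims, ranks):
        q, _ = np.linalg.qr(rng.standard_normal((d, r)))
        mats.append(q)
    core = rng.standard_normal(ranks)
    return tm.Tucker3Model(*mats, core, ranks)


def test_saturated_ranks_fit_100(rng):
    cube = rng.normal(size=(4, 3, 3))
    model = tm.tucker3_als(cube, (4, 3, 3))
    assert model.fit_pct == pytest.approx(100.0, abs=1e-8)
    np.testing.assert_allclose(tm.reconstruct(model), cube, atol=1e-8)


def test_noiseless_planted_exact(small_noiseless):
    cube, _ = tm.preprocess(small_noiseless.dataset)
    model = tm.tucker3_als(cube.values, (2, 2, 2))
    assert model.fit_pct == pytest.approx(100.0, abs=1e-6)
    np.testing.assert_allclose(tm.reconstruct(model), cube.values, atol=1e-8)


def test_loss_history_non_increasing(rng):
    for _ in range(10):
        cube = rng.normal(size=(8, 6, 5))
        model = tm.tucker3_als(cube, (3, 2, 2), init="random", seed=1)
        diffs = np.diff(model.loss_history)
        assert np.all(diffs <= 1e-9 * max(model.loss_history[0], 1.0))


def test_orthonormality_and_core_ss_identity(rng):
    for _ in range(5):
        cube = rng.normal(size=(7, 5, 4))
        model = tm.tucker3_als(cube, (2, 2, 2))
        model.check_orthonormal(tol=1e-10)
        ss_recon = float(np.sum(tm.reconstruct(model) ** 2))
        assert ss_recon == pytest.approx(float(np.sum(model.G**2)), rel=1e-8)


def test_als_at_least_hosvd(rng):
    """ALS refines the truncated-HOSVD start, never below it."""
    for _ in range(20):
        cube = rng.normal(size=(5, 4, 3))
        als_fit = tm.tucker3_als(cube, (2, 2, 2)).fit_pct
        assert als_fit >= hosvd_fit_oracle(cube, (2, 2, 2)) - 1e-9


def test_rank_monotonicity(rng):
    """Fit never decreases when any single rank increases."""
    for _ in range(20):
        cube = rng.normal(size=(6, 5, 4))
        base = tm.tucker3_als(cube, (2, 2, 2), n_starts=5, seed=0).fit_pct
        for bumped in [(3, 2, 2), (2, 3, 2), (2, 2, 3)]:
            up = tm.tucker3_als(cube, bumped, n_starts=5, seed=0).fit_pct
            assert up >= base - 1e-6


def test_sign_convention_deterministic(rng):
    cube = rng.normal(size=(8, 5, 4))
    m1 = tm.tucker3_als(cube, (2, 2, 2))
    m2 = tm.tucker3_als(cube.copy(), (2, 2, 2))
    np.testing.assert_allclose(m1.B, m2.B, atol=1e-10)
    for mat in m1.matrices:
        for col in range(mat.shape[1]):
            assert mat[np.argmax(np.abs(mat[:, col])), col] > 0


def test_input_validation(rng):
    cube = rng.normal(size=(5, 4, 3))
    with pytest.raises(RankAdmissibilityError):
        tm.tucker3_als(cube, (4, 1, 1))
    with pytest.raises(RankAdmissibilityError):
        tm.tucker3_als(cube, (2, 2, 4))
    bad = cube.copy()
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValidationError):
        tm.tucker3_als(bad, (2, 2, 2))


class TestReconstruct:
    def test_rank_one_outer_product(self):
        a = np.ones((3, 1)) / np.sqrt(3)
        b = np.array([[1.0], [0.0]])
        c = np.array([[0.6], [0.8]])
        model = tm.Tucker3Model(a, b, c, np.full((1, 1, 1), 2.0), (1, 1, 1))
        expected = 2.0 * np.einsum("i,j,k->ijk", a[:, 0], b[:, 0], c[:, 0])
        np.testing.assert_allclose(tm.reconstruct(model), expected)

    def test_ss_equals_core_ss_for_random_models(self, rng):
        for _ in range(10):
            model = _random_model(rng, (6, 5, 4), (3, 2, 2))
            ss = float(np.sum(tm.reconstruct(model) ** 2))
            assert ss == pytest.approx(float(np.sum(model.G**2)), rel=1e-10)


class TestFitPercentage:
    def test_perfect_model(self, rng):
        model = _random_model(rng, (5, 4, 3), (2, 2, 2))
        cube = tm.reconstruct(model)
        assert tm.fit_percentage(model, cube) == pytest.approx(100.0)

    def test_zero_model_zero_fit(self, rng):
        model = _random_model(rng, (5, 4, 3), (2, 2, 2))
        model.G[:] = 0.0
        cube = rng.normal(size=(5, 4, 3))
        assert tm.fit_percentage(model, cube) == pytest.approx(0.0)

    def test_zero_cube_rejected(self, rng):
        model = _random_model(rng, (5, 4, 3), (2, 2, 2))
        with pytest.raises(UndefinedFitError):
            tm.fit_percentage(model, np.zeros((5, 4, 3)))


class TestTotalFitWithTrend:
    def test_perfect_model_and_trend(self, small_noiseless):
        cube, state = tm.preprocess(small_noiseless.dataset)
        model = tm.tucker3_als(cube.values, (2, 2, 2))
        acc = tm.total_fit_with_trend(model, state, small_noiseless.dataset.values)
        assert acc.heterogeneity_fit_pct == pytest.approx(100.0, abs=1e-6)
        assert acc.total_fit_pct == pytest.approx(100.0, abs=1e-6)

    def test_trend_raises_total_above_heterogeneity(self, rng):
        spec = tm.study_like_spec(seed=1, missing_rate=0.0)
        synth = tm.generate_tucker3_dataset(spec)
        cube, state = tm.preprocess(synth.dataset)
        model = tm.tucker3_als(cube.values, (3, 2, 2))
        acc = tm.total_fit_with_trend(model, state, synth.dataset.values)
        assert acc.total_fit_pct > acc.heterogeneity_fit_pct
        assert acc.ss_trend > 0 and acc.ss_residual > 0
        assert acc.heterogeneity_fit_pct == pytest.approx(model.fit_pct, abs=1e-8)

    def test_shape_mismatch_rejected(self, small_noiseless, rng):
        cube, state = tm.preprocess(small_noiseless.dataset)
        model = tm.tucker3_als(cube.values, (2, 2, 2))
        with pytest.raises(ValidationError):
            tm.total_fit_with_trend(model, state, rng.normal(size=(30, 9, 5)))


def test_hosvd_core_matches_multi_mode_projection(rng):
    cube = rng.normal(size=(6, 5, 4))
    model = tm.hosvd(cube, (2, 2, 2))
    expected = multi_mode_dot(cube, tuple(m.T for m in model.matrices))
    np.testing.assert_allclose(model.G, expected, atol=1e-10)
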