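"""Rotation, alignment and Procrustes pooling invariants."""


import numpy as np
import pytest

import threemode as tm
from threemode.errors import PoolingError, UndefinedCongruenceError, ValidationError
from threemode.rotate import RotationWeights, orthomax_value
from threemode.tucker import mode_dot


def _random_model(rng, dims=(8, 6, 5), ranks=(3, 2, 2)):
    cube = rng.normal(size=dims)
    return tm.tucker3_als(cube, ranks)


class TestCongruence:
    def test_self_is_one(self, rng):
        u = rng.normal(size=10)
        assert tm.congruence(u, u) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert tm.congruence([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        u = rng.normal(size=7)
        assert tm.congruence(u, 2.0 * u) == pytest.approx(1.0)
        assert tm.congruence(u, -3.0 * u) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedCongruenceError):
            tm.congruence(np.zeros(4), np.ones(4))


class TestJointOrthomax:
    def test_reconstruction_invariance(self, rng):
        for _ in range(5):
            model = _random_model(rng)
            rot = tm.joint_orthomax(model)
            np.testing.assert_allclose(
                tm.reconstruct(rot), tm.reconstruct(model), atol=1e-10
            )

    def test_fit_unchanged(self, rng):
        cube = rng.normal(size=(8, 6, 5))
        model = tm.tucker3_als(cube, (3, 2, 2))
        rot = tm.joint_orthomax(model)
        assert abs(tm.fit_percentage(rot, cube) - model.fit_pct) < 1e-10

    def test_criterion_does_not_decrease(self, rng):
        w = RotationWeights.standard((8, 6, 5), (3, 2, 2))
        from threemode.rotate import _joint_criterion

        for _ in range(5):
            model = _random_model(rng)
            rot = tm.joint_orthomax(model, w)
            before = _joint_criterion(list(model.matrices), model.G, w)
            after = _joint_criterion(list(rot.matrices), rot.G, w)
            assert after >= before - 1e-12

    def test_reduces_to_varimax_against_statsmodels(self, rng):
        """Core weight 0 and a single active mode = plain varimax."""
        from statsmodels.multivariate.factor_rotation import rotate_factors

        for seed in range(5):
            r = np.random.default_rng(seed)
            a, _ = np.linalg.qr(r.standard_normal((10, 2)))
            g = np.zeros((2, 2, 2))
            g[0, 0, 0] = g[1, 1, 1] = 1.0
            model = tm.Tucker3Model(a, np.eye(2), np.eye(2), g, (2, 2, 2))
            ours = tm.joint_orthomax(
                model, RotationWeights(gamma=1.0, w_core=0.0, w_mode=(1, 0, 0))
            )
            sm_loadings, _t = rotate_factors(a, "varimax")
            assert orthomax_value(ours.A) == pytest.approx(
                orthomax_value(sm_loadings), abs=1e-6
            )
            phi = np.abs(tm.congruence_matrix(ours.A, sm_loadings))
            # same solution up to column order and sign
            assert np.allclose(np.sort(phi.max(axis=0)), 1.0, atol=1e-6)

    def test_orthonormality_preserved(self, rng):
        rot = tm.joint_orthomax(_random_model(rng))
        rot.check_orthonormal(tol=1e-10)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValidationError):
            RotationWeights(w_core=0.0, w_mode=(0.0, 0.0, 0.0))
        with pytest.raises(ValidationError):
            RotationWeights(w_core=-1.0)


class TestAlignSolution:
    def test_identity_when_reference_is_self(self, rng):
        model = _random_model(rng)
        aligned = tm.align_solution(model, model)
        np.testing.assert_allclose(aligned.A, model.A, atol=1e-12)
        np.testing.assert_allclose(aligned.G, model.G, atol=1e-12)

    def test_undoes_signed_permutation(self, rng):
        model = _random_model(rng, ranks=(3, 2, 2))
        scrambled = model.copy()
        perm = [2, 0, 1]
        signs = np.array([1.0, -1.0, -1.0])
        s = np.zeros((3, 3))
        for i, (p, sg) in enumerate(zip(perm, signs)):
            s[p, i] = sg
        # apply to person mode and compensate core
        scrambled.A = model.A @ s
        scrambled.G = mode_dot(model.G, s.T, 0)
        aligned = tm.align_solution(scrambled, model)
        np.testing.assert_allclose(aligned.A, model.A, atol=1e-10)
        np.testing.assert_allclose(aligned.G, model.G, atol=1e-10)
        np.testing.assert_allclose(
            tm.reconstruct(aligned), tm.reconstruct(model), atol=1e-10
        )

    def test_matches_exhaustive_enumeration(self, rng):
        """Hungarian assignment equals brute force over all 3! * 2^3
        signed permutations."""
        from conftest import signed_permutation_alignment_oracle

        for _ in range(5):
            sol = _random_model(rng, ranks=(3, 2, 2))
            ref = _random_model(rng, ranks=(3, 2, 2))
            aligned = tm.align_solution(sol, ref)
            achieved = [
                sum(
                    tm.congruence(aligned.matrices[m][:, c], ref.matrices[m][:, c])
                    for c in range(aligned.matrices[m].shape[1])
                )
                for m in range(3)
            ]
            best = signed_permutation_alignment_oracle(sol, ref)
            for a, b in zip(achieved, best):
                assert a == pytest.approx(b, abs=1e-10)

    def test_rank_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            tm.align_solution(
                _random_model(rng, ranks=(2, 2, 2)),
                _random_model(rng, ranks=(3, 2, 2)),
            )


class TestGeneralizedProcrustes:
    def test_identical_solutions(self, rng):
        model = _random_model(rng)
        pooled = tm.generalized_procrustes([model.copy() for _ in range(20)])
        for key, sd in pooled.element_sd.items():
            assert np.abs(sd).max() < 1e-10, key
        np.testing.assert_allclose(
            tm.reconstruct(pooled.mean_model), tm.reconstruct(model), atol=1e-8
        )

    def test_recovers_common_solution_from_random_rotations(self, rng):
        base = _random_model(rng, ranks=(2, 2, 2))
        solutions = []
        for _ in range(8):
            rotated = base.copy()
            for mode in range(3):
                q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
                rotated.A, rotated.B, rotated.C = (
                    m @ q if i == mode else m
                    for i, m in enumerate((rotated.A, rotated.B, rotated.C))
                )
                rotated.G = mode_dot(rotated.G, q.T, mode)
            solutions.append(rotated)
        pooled = tm.generalized_procrustes(solutions)
        assert pooled.converged
        for name in ("A", "B", "C"):
            assert pooled.per_dataset_congruence[name].min() >= 0.999

    def test_mean_model_orthonormal(self, rng):
        sols = [_random_model(rng) for _ in range(4)]
        pooled = tm.generalized_procrustes(sols)
        pooled.mean_model.check_orthonormal(tol=1e-6)

    def test_needs_two_solutions(self, rng):
        with pytest.raises(PoolingError):
            tm.generalized_procrustes([_random_model(rng)])


def test_every_transformation_preserves_fit(rng):
    """Rotation, alignment and pooling never change the fit percentage."""
    cube = rng.normal(size=(10, 6, 5))
    model = tm.tucker3_als(cube, (2, 2, 2))
    fit0 = model.fit_pct
    rot = tm.joint_orthomax(model)
    assert abs(tm.fit_percentage(rot, cube) - fit0) < 1e-10
    aligned = tm.align_solution(rot, model)
    assert abs(tm.fit_percentage(aligned, cube) - fit0) < 1e-10
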