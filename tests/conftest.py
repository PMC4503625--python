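"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import threemode as tm


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_noiseless():
    """Noiseless planted (2,2,2) cube with trend, 30 x 8 x 5."""
    spec = tm.SyntheticSpec(
        dims=(30, 8, 5),
        ranks=(2, 2, 2),
        core_pattern=[(0, 0, 0, 6.0), (1, 1, 1, 4.0)],
        trend=np.outer(np.linspace(0.4, 1.2, 8), np.linspace(1.0, 0.5, 5)),
        noise_sd=0.0,
        seed=11,
    )
    return tm.generate_tucker3_dataset(spec)


@pytest.fixture
def small_noisy():
    """High-SNR planted (2,2,2) cube, 60 x 8 x 6, ~66% structure share."""
    spec = tm.SyntheticSpec(
        dims=(60, 8, 6),
        ranks=(2, 2, 2),
        core_pattern=[(0, 0, 0, 30.0), (1, 1, 1, 22.0)],
        noise_sd=0.5,
        seed=7,
    )
    return tm.generate_tucker3_dataset(spec)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def anova_projection_oracle(cube: np.ndarray) -> dict[str, float]:
    """Three-way ANOVA SS via explicit Kronecker projection matrices.

    For each effect, modes in the effect get the centering matrix
    C_n = I - J/n and modes outside get the averaging matrix J/n; the
    effect SS is the squared norm of the projected vectorized cube.
    Brute force (materializes IJK x IJK matrices) — tiny inputs only.
    """
    i_n, j_n, k_n = cube.shape
    vec = cube.reshape(-1)  # C order: k fastest, i slowest

    def cmat(n):
        return np.eye(n) - np.ones((n, n)) / n

    def amat(n):
        return np.ones((n, n)) / n

    effects = {
        "persons": (1, 0, 0),
        "symptoms": (0, 1, 0),
        "time": (0, 0, 1),
        "persons x symptoms": (1, 1, 0),
        "persons x time": (1, 0, 1),
        "symptoms x time": (0, 1, 1),
        "three-way + error": (1, 1, 1),
    }
    out = {}
    for name, (ei, ej, ek) in effects.items():
        pi = cmat(i_n) if ei else amat(i_n)
        pj = cmat(j_n) if ej else amat(j_n)
        pk = cmat(k_n) if ek else amat(k_n)
        proj = np.kron(pi, np.kron(pj, pk))
        out[name] = float(np.sum((proj @ vec) ** 2))
    centered = vec - vec.mean()
    out["total"] = float(np.sum(centered**2))
    return out


def hosvd_fit_oracle(cube: np.ndarray, ranks: tuple[int, int, int]) -> float:
    """Truncated-HOSVD fit percentage, implemented from scratch."""
    mats = []
    for mode, r in enumerate(ranks):
        mat = np.moveaxis(cube, mode, 0).reshape(cube.shape[mode], -1)
        u, _, _ = np.linalg.svd(mat, full_matrices=False)
        mats.append(u[:, :r])
    core = cube
    for mode, u in enumerate(mats):
        core = np.moveaxis(
            np.tensordot(u.T, np.moveaxis(core, mode, 0), axes=1), 0, mode
        )
    recon = core
    for mode, u in enumerate(mats):
        recon = np.moveaxis(
            np.tensordot(u, np.moveaxis(recon, mode, 0), axes=1), 0, mode
        )
    ss = float(np.sum(cube**2))
    return 100.0 * (1.0 - float(np.sum((cube - recon) ** 2)) / ss)


def signed_permutation_alignment_oracle(sol, ref):
    """Best signed column permutation by exhaustive enumeration.

    Returns, per mode, the maximum total |congruence| achievable over
    all r! * 2^r signed permutations.
    """
    best = []
    for mode in range(3):
        u_mat = sol.matrices[mode]
        v_mat = ref.matrices[mode]
        r = u_mat.shape[1]
        top = -np.inf
        for perm in itertools.permutations(range(r)):
            total = sum(
                abs(tm.congruence(u_mat[:, perm[j]], v_mat[:, j]))
                for j in range(r)
            )
            top = max(top, total)
        best.append(top)
    return best


def conditional_rmse_oracle(synth: tm.SyntheticDataset) -> float:
    """RMSE of the ideal draw-based imputer under the true generative model.

    Person rows are MVN with covariance M M^T / I + noise_sd^2 I, where
    M maps person component scores to the vectorized (item, time) cell
    means.  A draw from the exact conditional adds the conditional
    variance twice (truth and draw both deviate from the conditional
    mean), so the ideal RMSE over missing cells is
    sqrt(mean of 2 * conditional variance).
    """
    ds = synth.dataset
    i_n, j_n, k_n = ds.shape
    b_mat, c_mat, g = synth.truth_model.B, synth.truth_model.C, synth.truth_model.G
    cols = [(b_mat @ g[p] @ c_mat.T).reshape(-1) for p in range(g.shape[0])]
    m_map = np.column_stack(cols)
    sigma = m_map @ m_map.T / i_n + synth.spec.noise_sd**2 * np.eye(j_n * k_n)
    mask = ds.mask.reshape(i_n, -1)
    total, count = 0.0, 0
    for i in range(i_n):
        mis = ~mask[i]
        if not mis.any():
            continue
        obs = mask[i]
        s_oo = sigma[np.ix_(obs, obs)]
        s_mo = sigma[np.ix_(mis, obs)]
        cond = sigma[np.ix_(mis, mis)] - s_mo @ np.linalg.solve(s_oo, s_mo.T)
        total += 2.0 * float(np.sum(np.diag(cond)))
        count += int(mis.sum())
    return float(np.sqrt(total / count))
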