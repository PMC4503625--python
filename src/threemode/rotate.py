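"""Rotation, alignment and pooling of Tucker3 solutions.

A Tucker3 decomposition is identified only up to orthogonal rotations
of each mode's components (compensated in the core), so three
interpretability tools live here:

* **Joint orthomax** — a simultaneous orthogonal rotation of the core
  and the component matrices that maximizes a weighted sum of orthomax
  simplicity criteria (the core along all three matricizations plus
  each mode's matrix).  Implemented with pairwise Jacobi plane
  rotations; for any plane the criterion reduces exactly to
  ``a + d*cos(4θ) + e*sin(4θ)``, so the optimal angle per pair is
  analytic and the criterion is monotone non-decreasing by
  construction.
* **Congruence alignment** — signed column permutations matching one
  solution's components to a reference by maximizing total absolute
  Tucker congruence (optimal assignment).
* **Generalized Procrustes pooling** — iteratively rotating the
  per-imputation solutions toward their running mean, then averaging
  components and cores element-wise, yielding a pooled model plus
  element-wise spread.

Every operation here is reconstruction-preserving: rotations of the
component matrices are counter-rotated in the core, so the fitted array
(and hence the fit percentage) never changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd
from scipy.optimize import linear_sum_assignment

from .errors import PoolingError, UndefinedCongruenceError, ValidationError
from .tucker import Tucker3Model, apply_sign_convention, mode_dot, unfold

__all__ = [
    "RotationWeights",
    "PooledSolution",
    "congruence",
    "congruence_matrix",
    "subspace_congruence",
    "orthomax_value",
    "joint_orthomax",
    "align_solution",
    "generalized_procrustes",
]


# ---------------------------------------------------------------------------
# congruence
# ---------------------------------------------------------------------------

def congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Tucker congruence coefficient φ = Σuv / sqrt(Σu² Σv²), in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedCongruenceError("congruence undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def congruence_matrix(u_mat: np.ndarray, v_mat: np.ndarray) -> np.ndarray:
    """Pairwise congruences between columns of two matrices."""
    return np.array(
        [[congruence(u_mat[:, i], v_mat[:, j]) for j in range(v_mat.shape[1])]
         for i in range(u_mat.shape[1])]
    )


def subspace_congruence(u_mat: np.ndarray, v_mat: np.ndarray) -> np.ndarray:
    """Per-column congruence of ``u_mat``'s columns with span(``v_mat``).

    Each value is the norm of the projection of a (unit-normalized)
    column of ``u_mat`` onto the column space of ``v_mat`` — i.e. the
    congruence with the best-matching vector in that subspace.  Useful
    when the comparison target is only identified up to rotation.
    """
    q, _ = np.linalg.qr(np.asarray(v_mat, dtype=float))
    out = []
    for col in range(u_mat.shape[1]):
        u = u_mat[:, col]
        nu = np.linalg.norm(u)
        if nu == 0.0:
            raise UndefinedCongruenceError("zero column")
        out.append(float(np.linalg.norm(q.T @ u) / nu))
    return np.array(out)


# ---------------------------------------------------------------------------
# joint orthomax
# ---------------------------------------------------------------------------

@dataclass
class RotationWeights:
    """Weights of the joint orthomax criterion.

    ``gamma`` is the orthomax family parameter (1 = varimax flavour);
    ``w_core`` weights the core's simplicity (applied to each of its
    three matricizations); ``w_mode`` weights each component matrix
    (person, symptom, time).
    """

    gamma: float = 1.0
    w_core: float = 1.0
    w_mode: tuple[float, float, float] = (0.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.w_core < 0 or any(w < 0 for w in self.w_mode):
            raise ValidationError("rotation weights must be nonnegative")
        if self.w_core == 0 and all(w == 0 for w in self.w_mode):
            raise ValidationError("at least one rotation weight must be positive")

    @classmethod
    def standard(
        cls,
        dims: tuple[int, int, int],
        ranks: tuple[int, int, int],
        gamma: float = 1.0,
        person_weight: bool = False,
    ) -> "RotationWeights":
        """Natural relative weights: core weight 1 per matricization and
        mode-matrix weights proportional to core size over matrix size,
        with the person-mode weight off by default (simplicity of person
        scores is not usually a goal)."""
        core_n = int(np.prod(ranks))
        w = [core_n / (d * r) for d, r in zip(dims, ranks)]
        if not person_weight:
            w[0] = 0.0
        return cls(gamma=gamma, w_core=1.0, w_mode=tuple(w))


def orthomax_value(loadings: np.ndarray, gamma: float = 1.0) -> float:
    """Orthomax simplicity of a loadings matrix (columns = components):
    Σ_cols [ Σ λ⁴  −  γ/n (Σ λ²)² ] with n = number of rows."""
    lam2 = np.asarray(loadings, dtype=float) ** 2
    n = lam2.shape[0]
    return float(np.sum(lam2**2) - (gamma / n) * np.sum(lam2.sum(axis=0) ** 2))


def _joint_criterion(
    mats: list[np.ndarray], core: np.ndarray, weights: RotationWeights
) -> float:
    val = 0.0
    if weights.w_core > 0:
        for mode in range(3):
            val += weights.w_core * orthomax_value(unfold(core, mode).T, weights.gamma)
    for mode, w in enumerate(weights.w_mode):
        if w > 0:
            val += w * orthomax_value(mats[mode], weights.gamma)
    return val


def _plane_rotate(
    mats: list[np.ndarray], core: np.ndarray, mode: int,
    i: int, j: int, theta: float,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rotate columns (i, j) of mode's matrix by theta; counter-rotate core."""
    c, s = np.cos(theta), np.sin(theta)
    rot = np.eye(mats[mode].shape[1])
    rot[i, i] = c
    rot[j, j] = c
    rot[i, j] = -s
    rot[j, i] = s
    new_mats = list(mats)
    new_mats[mode] = mats[mode] @ rot
    new_core = mode_dot(core, rot.T, mode)
    return new_mats, new_core


def joint_orthomax(
    model: Tucker3Model,
    weights: RotationWeights | None = None,
    tol: float = 1e-12,
    max_sweeps: int = 200,
) -> Tucker3Model:
    """Rotate a Tucker3 solution to joint simplicity of core and components.

    Sweeps pairwise Jacobi plane rotations over the modes in the fixed
    order (symptom, time, person) until the criterion improvement per
    sweep drops below ``tol``.  For each plane the criterion is an exact
    single-harmonic function of 4θ (every term is quartic in cos/sin
    and invariant under quarter-turns, which are signed column or row
    permutations), so three evaluations at θ = 0, π/8, π/4 determine
    the optimal angle in closed form.
    """
    if weights is None:
        weights = RotationWeights.standard(
            (model.A.shape[0], model.B.shape[0], model.C.shape[0]), model.ranks
        )
    model.check_orthonormal(tol=1e-8)
    mats = [m.copy() for m in model.matrices]
    core = model.G.copy()

    current = _joint_criterion(mats, core, weights)
    for _sweep in range(max_sweeps):
        start_val = current
        for mode in (1, 2, 0):  # symptom, time, person
            r = mats[mode].shape[1]
            for i in range(r - 1):
                for j in range(i + 1, r):
                    f0 = current
                    m1, c1 = _plane_rotate(mats, core, mode, i, j, np.pi / 8)
                    f1 = _joint_criterion(m1, c1, weights)
                    m2, c2 = _plane_rotate(mats, core, mode, i, j, np.pi / 4)
                    f2 = _joint_criterion(m2, c2, weights)
                    a = 0.5 * (f0 + f2)
                    d = f0 - a
                    e = f1 - a
                    if d == 0.0 and e == 0.0:
                        continue
                    theta = np.arctan2(e, d) / 4.0
                    best = a + np.hypot(d, e)
                    if best > current + 1e-15 * max(abs(current), 1.0):
                        mats, core = _plane_rotate(mats, core, mode, i, j, theta)
                        current = _joint_criterion(mats, core, weights)
        if current - start_val <= tol * max(abs(current), 1.0):
            break

    mats, core = apply_sign_convention(mats, core)
    out = model.copy()
    out.A, out.B, out.C = mats
    out.G = core
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_solution(
    solution: Tucker3Model, reference: Tucker3Model,
    modes: tuple[int, ...] = (0, 1, 2),
) -> Tucker3Model:
    """Permute and sign-flip each mode's columns to best match a reference.

    The assignment maximizes total absolute Tucker congruence per mode
    (Hungarian algorithm); chosen signs make the matched congruences
    positive.  The core is counter-transformed so the reconstruction is
    unchanged.  ``modes`` restricts which modes are aligned (e.g. skip
    the person mode when solutions come from disjoint person samples).
    """
    if tuple(solution.ranks) != tuple(reference.ranks):
        raise ValidationError("rank mismatch between solution and reference")
    out = solution.copy()
    mats = [m.copy() for m in out.matrices]
    core = out.G.copy()
    for mode in modes:
        phi = congruence_matrix(mats[mode], reference.matrices[mode])
        rows, cols = linear_sum_assignment(-np.abs(phi))
        r = mats[mode].shape[1]
        s_mat = np.zeros((r, r))
        for i, j in zip(rows, cols):
            s_mat[i, j] = 1.0 if phi[i, j] >= 0 else -1.0
        mats[mode] = mats[mode] @ s_mat
        core = mode_dot(core, s_mat.T, mode)
    out.A, out.B, out.C = mats
    out.G = core
    return out


# ---------------------------------------------------------------------------
# generalized Procrustes pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledSolution:
    """Procrustes-averaged Tucker3 model across imputations.

    ``mean_model`` holds the element-wise means with the component
    matrices re-orthonormalized afterwards (polar decomposition, the
    nearness correction is folded into the core).  ``element_sd`` maps
    ``"A"/"B"/"C"/"G"`` to same-shaped across-imputation standard
    deviations of the aligned solutions.  ``per_dataset_congruence``
    maps mode name to an (n_solutions, rank) array of per-column
    congruences with the mean.
    """

    mean_model: Tucker3Model
    element_sd: dict[str, np.ndarray]
    per_dataset_congruence: dict[str, np.ndarray]
    n_solutions: int
    n_iter: int
    converged: bool
    orthonormalized: bool = True


def _procrustes_rotation(m: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal R maximizing tr(R' m' target)."""
    u, _, vt = svd(m.T @ target)
    return u @ vt


def generalized_procrustes(
    solutions: list[Tucker3Model],
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PooledSolution:
    """Pool per-imputation Tucker3 solutions into one averaged model.

    Solutions are first matched to the first solution by signed column
    permutation, then iteratively rotated per mode toward the running
    mean by orthogonal Procrustes (cores counter-rotated) until the
    mean stabilizes.  The objective (sum of squared deviations from the
    mean) is non-increasing per iteration.
    """
    if len(solutions) < 2:
        raise PoolingError("generalized Procrustes needs at least 2 solutions")
    ranks = tuple(solutions[0].ranks)
    dims = tuple(m.shape[0] for m in solutions[0].matrices)
    for s in solutions[1:]:
        if tuple(s.ranks) != ranks or tuple(m.shape[0] for m in s.matrices) != dims:
            raise PoolingError("solutions disagree on ranks or dimensions")

    work = [align_solution(s, solutions[0]) for s in solutions]
    mats = [[m.copy() for m in s.matrices] for s in work]
    cores = [s.G.copy() for s in work]

    def means() -> list[np.ndarray]:
        return [np.mean([m[mode] for m in mats], axis=0) for mode in range(3)]

    converged = False
    it = 0
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        bar = means()
        for idx in range(len(work)):
            for mode in range(3):
                rot = _procrustes_rotation(mats[idx][mode], bar[mode])
                mats[idx][mode] = mats[idx][mode] @ rot
                cores[idx] = mode_dot(cores[idx], rot.T, mode)
        bar = means()
        obj = sum(
            float(np.sum((mats[idx][mode] - bar[mode]) ** 2))
            for idx in range(len(work))
            for mode in range(3)
        )
        if prev_obj - obj <= tol * max(obj, 1.0):
            converged = True
            break
        prev_obj = obj

    bar = means()
    mean_core = np.mean(cores, axis=0)

    # element-wise spread of the aligned/rotated solutions
    element_sd = {
        "A": np.std([m[0] for m in mats], axis=0, ddof=0),
        "B": np.std([m[1] for m in mats], axis=0, ddof=0),
        "C": np.std([m[2] for m in mats], axis=0, ddof=0),
        "G": np.std(cores, axis=0, ddof=0),
    }
    cong = {}
    for mode, name in enumerate(("A", "B", "C")):
        cong[name] = np.array(
            [
                [congruence(mats[idx][mode][:, c], bar[mode][:, c])
                 for c in range(ranks[mode])]
                for idx in range(len(work))
            ]
        )

    # restore orthonormality of the averaged matrices (polar
    # decomposition), folding the correction into the core
    ortho = []
    core = mean_core
    for mode in range(3):
        u, sv, vt = svd(bar[mode], full_matrices=False)
        q = u @ vt
        h = vt.T @ np.diag(sv) @ vt  # bar = q @ h
        ortho.append(q)
        core = mode_dot(core, h, mode)
    ortho, core = apply_sign_convention(ortho, core)

    mean_model = Tucker3Model(*ortho, core, ranks)
    return PooledSolution(
        mean_model=mean_model,
        element_sd=element_sd,
        per_dataset_congruence=cong,
        n_solutions=len(work),
        n_iter=it,
        converged=converged,
    )
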