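"""Tucker3 (three-mode PCA) model fitting by alternating least squares.

The model approximates a three-way array x_ijk by

    x_ijk  ~=  sum_{p,q,r}  a_ip * b_jq * c_kr * g_pqr

with orthonormal component matrices A (persons, I x P), B (symptom
items, J x Q), C (time points, K x R) and a small P x Q x R core array
G whose entries quantify the strength of each triple interaction of
components.  Because the factors are orthonormal, the fitted array is
an orthogonal projection of the data and the explained sum of squares
equals ||G||^2 exactly.

Fitting uses higher-order orthogonal iteration (TUCKALS-type ALS): each
mode's matrix is set to the leading left singular vectors of the data
matricized against the other two modes' current projections, which
makes the residual sum of squares non-increasing at every step.
Initialisation is a truncated higher-order SVD by default, optionally
with extra seeded random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RankAdmissibilityError, UndefinedFitError, ValidationError
from .preprocess import PreprocessingState

__all__ = [
    "Tucker3Model",
    "FitAccount",
    "tucker3_als",
    "reconstruct",
    "fit_percentage",
    "total_fit_with_trend",
    "check_rank_admissibility",
]


# ---------------------------------------------------------------------------
# tensor algebra primitives
# ---------------------------------------------------------------------------

def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Matricize a 3-way array along ``mode`` (rows = that mode's index)."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold`."""
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(matrix.reshape(full), 0, mode)


def mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product: contract the tensor's mode index with
    ``matrix``'s second index (result mode size = matrix rows)."""
    out_shape = list(tensor.shape)
    out_shape[mode] = matrix.shape[0]
    return fold(matrix @ unfold(tensor, mode), mode, tuple(out_shape))


def multi_mode_dot(core: np.ndarray, matrices: tuple[np.ndarray, ...]) -> np.ndarray:
    """core x1 M0 x2 M1 x3 M2 ..."""
    out = core
    for mode, m in enumerate(matrices):
        out = mode_dot(out, m, mode)
    return out


def check_rank_admissibility(ranks: tuple[int, int, int]) -> None:
    p, q, r = ranks
    if min(p, q, r) < 1:
        raise RankAdmissibilityError(f"ranks must be >= 1, got {ranks}")
    if p > q * r or q > p * r or r > p * q:
        raise RankAdmissibilityError(
            f"inadmissible Tucker3 ranks {ranks}: each rank must not exceed "
            "the product of the other two"
        )


def apply_sign_convention(
    matrices: list[np.ndarray], core: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Flip each component column so its largest-|entry| is positive.

    Flips are compensated in the core, so the reconstruction is
    unchanged.  Makes otherwise sign-indeterminate output deterministic.
    """
    core = core.copy()
    out = []
    for mode, m in enumerate(matrices):
        m = m.copy()
        for col in range(m.shape[1]):
            j = int(np.argmax(np.abs(m[:, col])))
            if m[j, col] < 0:
                m[:, col] *= -1
                idx = [slice(None)] * core.ndim
                idx[mode] = col
                core[tuple(idx)] *= -1
        out.append(m)
    return out, core


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class Tucker3Model:
    """Fitted Tucker3 decomposition.

    ``A``, ``B``, ``C`` have orthonormal columns; ``G`` is the P x Q x R
    core.  ``fit_pct`` is 100 * explained SS / total SS of the cube the
    model was fitted to.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    ranks: tuple[int, int, int]
    fit_pct: float | None = None
    converged: bool = True
    n_iter: int = 0
    loss_history: list[float] = field(default_factory=list)

    @property
    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.A, self.B, self.C)

    def copy(self) -> "Tucker3Model":
        return Tucker3Model(
            self.A.copy(), self.B.copy(), self.C.copy(), self.G.copy(),
            tuple(self.ranks), self.fit_pct, self.converged, self.n_iter,
            list(self.loss_history),
        )

    def check_orthonormal(self, tol: float = 1e-8) -> None:
        for name, m in zip("ABC", self.matrices):
            gram = m.T @ m
            if not np.allclose(gram, np.eye(m.shape[1]), atol=tol):
                raise ValidationError(f"component matrix {name} is not orthonormal")


def reconstruct(model: Tucker3Model) -> np.ndarray:
    """x_hat = G x1 A x2 B x3 C."""
    return multi_mode_dot(model.G, model.matrices)


def fit_percentage(model: Tucker3Model, cube: np.ndarray) -> float:
    """100 * (1 - SS(residual) / SS(cube))."""
    cube = np.asarray(cube, dtype=float)
    ss_total = float(np.sum(cube**2))
    if ss_total == 0.0:
        raise UndefinedFitError("fit percentage undefined for a zero-SS cube")
    resid = cube - reconstruct(model)
    return 100.0 * (1.0 - float(np.sum(resid**2)) / ss_total)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def hosvd(cube: np.ndarray, ranks: tuple[int, int, int]) -> Tucker3Model:
    """Truncated higher-order SVD (per-mode SVD of the raw unfoldings).

    Not a least-squares optimum, but the standard warm start for ALS.
    """
    check_rank_admissibility(ranks)
    mats = []
    for mode, r in enumerate(ranks):
        u, _, _ = np.linalg.svd(unfold(cube, mode), full_matrices=False)
        mats.append(u[:, :r])
    core = multi_mode_dot(cube, tuple(m.T for m in mats))
    mats, core = apply_sign_convention(mats, core)
    model = Tucker3Model(*mats, core, tuple(ranks))
    model.fit_pct = fit_percentage(model, cube)
    return model


def _als_single(
    cube: np.ndarray,
    ranks: tuple[int, int, int],
    mats: list[np.ndarray],
    tol: float,
    max_iter: int,
) -> Tucker3Model:
    ss_total = float(np.sum(cube**2))
    loss_history: list[float] = []
    prev_fit = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for mode in range(3):
            others = [m for i, m in enumerate(mats) if i != mode]
            other_modes = [i for i in range(3) if i != mode]
            proj = cube
            for om, m in zip(other_modes, others):
                proj = mode_dot(proj, m.T, om)
            u, _, _ = np.linalg.svd(unfold(proj, mode), full_matrices=False)
            mats[mode] = u[:, : ranks[mode]]
        core = multi_mode_dot(cube, tuple(m.T for m in mats))
        ss_model = float(np.sum(core**2))
        loss_history.append(ss_total - ss_model)
        fit = ss_model / ss_total if ss_total > 0 else 1.0
        if fit - prev_fit < tol * max(fit, 1e-300):
            converged = True
            break
        prev_fit = fit

    core = multi_mode_dot(cube, tuple(m.T for m in mats))
    mats, core = apply_sign_convention(mats, core)
    model = Tucker3Model(
        *mats, core, tuple(ranks),
        converged=converged, n_iter=it, loss_history=loss_history,
    )
    model.fit_pct = fit_percentage(model, cube)
    return model


def tucker3_als(
    cube: np.ndarray,
    ranks: tuple[int, int, int],
    init: str = "hosvd",
    n_starts: int = 1,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> Tucker3Model:
    """Fit a Tucker3 model by alternating least squares.

    Parameters
    ----------
    cube : complete I x J x K array (typically preprocessed).
    ranks : (P, Q, R); must satisfy rank admissibility and ranks <= dims.
    init : ``"hosvd"`` (deterministic warm start, first start) or
        ``"random"``; additional starts beyond the first are always
        random orthonormal matrices drawn from ``seed``.
    n_starts : number of starts; the best final fit wins.
    tol : relative fit-change convergence threshold.

    The per-iteration residual SS is recorded in ``loss_history`` and is
    non-increasing by construction.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise ValidationError("cube must be 3-way")
    if not np.all(np.isfinite(cube)):
        raise ValidationError("cube contains non-finite values")
    check_rank_admissibility(ranks)
    if any(r > d for r, d in zip(ranks, cube.shape)):
        raise RankAdmissibilityError(
            f"ranks {ranks} exceed cube dimensions {cube.shape}"
        )
    if init not in ("hosvd", "random"):
        raise ValidationError(f"unknown init {init!r}")
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")

    rng = np.random.default_rng(seed)
    best: Tucker3Model | None = None
    for start in range(n_starts):
        if start == 0 and init == "hosvd":
            mats = [m.copy() for m in hosvd(cube, ranks).matrices]
        else:
            mats = []
            for mode, r in enumerate(ranks):
                q, _ = np.linalg.qr(rng.standard_normal((cube.shape[mode], r)))
                mats.append(q)
        model = _als_single(cube, ranks, mats, tol, max_iter)
        if best is None or model.fit_pct > best.fit_pct:
            best = model
    return best


# ---------------------------------------------------------------------------
# fit accounting with the general trend
# ---------------------------------------------------------------------------

@dataclass
class FitAccount:
    """Explained-variance bookkeeping on the symptom-normalized scale.

    ``heterogeneity_fit_pct`` is the model's fit to the preprocessed
    (trend-removed, normalized) cube; ``total_fit_pct`` additionally
    credits the general trend, i.e. it is the fit of
    ``trend/s_j + model`` to the raw cube divided by the per-item
    scales.
    """

    heterogeneity_fit_pct: float
    total_fit_pct: float
    ss_trend: float
    ss_model: float
    ss_residual: float
    ss_total: float


def total_fit_with_trend(
    model: Tucker3Model,
    state: PreprocessingState,
    raw_cube: np.ndarray,
) -> FitAccount:
    """Combine model and general trend into a single fit account.

    ``raw_cube`` is the completed (imputed) cube on the original score
    scale; ``state`` must be the preprocessing state that produced the
    cube the model was fitted to.  All sums of squares are evaluated on
    the symptom-normalized scale x_ijk / s_j, where trend and model live
    on a common footing.
    """
    raw_cube = np.asarray(raw_cube, dtype=float)
    j_n, k_n = state.trend.shape
    if raw_cube.shape[1:] != (j_n, k_n):
        raise ValidationError("preprocessing state does not match cube shape")
    if model.A.shape[0] != raw_cube.shape[0]:
        raise ValidationError("model person mode does not match cube")

    s = state.scales[None, :, None]
    scaled = raw_cube / s
    trend_scaled = (state.trend / state.scales[:, None])[None, :, :]
    x_hat = reconstruct(model)
    prediction = trend_scaled + x_hat

    ss_total = float(np.sum(scaled**2))
    if ss_total == 0.0:
        raise UndefinedFitError("total fit undefined for a zero-SS cube")
    ss_resid = float(np.sum((scaled - prediction) ** 2))
    ss_trend = float(np.sum(trend_scaled**2)) * raw_cube.shape[0]
    ss_model = float(np.sum(model.G**2))

    centered = scaled - trend_scaled
    ss_centered = float(np.sum(centered**2))
    if ss_centered > 0:
        het = 100.0 * (1.0 - float(np.sum((centered - x_hat) ** 2)) / ss_centered)
    else:
        het = 0.0
    total = 100.0 * (1.0 - ss_resid / ss_total)
    return FitAccount(
        heterogeneity_fit_pct=het,
        total_fit_pct=total,
        ss_trend=ss_trend,
        ss_model=ss_model,
        ss_residual=ss_resid,
        ss_total=ss_total,
    )
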