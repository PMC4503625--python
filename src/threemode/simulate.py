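"""Synthetic longitudinal symptom cubes with planted Tucker3 structure.

The generator inverts the analysis model: it builds a cube as

    x_ijk = trend_jk + [G x1 A x2 B x3 C]_ijk + noise_ijk

where the trend is a shared declining mean item trajectory, A (persons)
has zero-mean orthonormal columns (so person-mode centering leaves the
planted structure untouched), B and C are orthonormal, and the noise is
i.i.d. Gaussian — matching the least-squares loss of the Tucker3
estimator.  Scores can optionally be rounded and clipped to a bounded
integer range (questionnaire items score 0-3), and missingness can be
injected completely at random or concentrated at later assessments
(dropout-like).  Person-level external covariates are generated with
stated loadings on the standardized person-component scores, so their
population correlation with component p is exactly the loading.

Everything is deterministic given the spec's seed, and the planted
truth (model, trend, covariate loadings) is recorded for test
harnesses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ThreeWayDataset, write_long_table
from .errors import RankAdmissibilityError, ValidationError
from .tucker import Tucker3Model, apply_sign_convention, check_rank_admissibility, multi_mode_dot

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_tucker3_dataset",
    "inject_missingness",
    "study_like_spec",
]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic cube.

    ``core_pattern`` lists planted core entries as (p, q, r, magnitude)
    tuples (0-based component indices).  ``score_bounds`` is either
    None (unbounded, real-valued scores) or an (min, max) integer range
    applied by rounding then clipping.  ``external_loadings`` is an
    n_external x P matrix of loadings on the standardized person
    component scores; each row must have squared norm <= 1, and the
    residual variance 1 - ||row||^2 is filled with independent noise so
    every covariate has unit variance and implied correlation equal to
    its loading.
    """

    dims: tuple[int, int, int]
    ranks: tuple[int, int, int]
    core_pattern: list[tuple[int, int, int, float]]
    trend: np.ndarray | None = None
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    score_bounds: tuple[int, int] | None = None
    n_external: int = 0
    external_loadings: np.ndarray | None = None
    symptom_loadings: np.ndarray | None = None  # optional structured B (J x Q)
    time_loadings: np.ndarray | None = None     # optional structured C (K x R)
    equalize_item_scale: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.dims) < 2:
            raise ValidationError("all dims must be >= 2")
        check_rank_admissibility(self.ranks)
        if any(r > d for r, d in zip(self.ranks, self.dims)):
            raise RankAdmissibilityError("ranks exceed dims")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.score_bounds is not None:
            lo, hi = self.score_bounds
            if lo >= hi:
                raise ValidationError("score_bounds must be (min, max) with min < max")
        if self.trend is not None:
            t = np.asarray(self.trend, dtype=float)
            if t.shape != (self.dims[1], self.dims[2]):
                raise ValidationError("trend must be J x K")
        if self.n_external > 0 and self.external_loadings is not None:
            load = np.asarray(self.external_loadings, dtype=float)
            if load.shape != (self.n_external, self.ranks[0]):
                raise ValidationError("external_loadings must be n_external x P")
            if np.any(np.sum(load**2, axis=1) > 1.0 + 1e-12):
                raise ValidationError(
                    "each external loading row must have squared norm <= 1"
                )


@dataclass
class SyntheticDataset:
    """Generated cube plus the planted ground truth."""

    dataset: ThreeWayDataset
    truth_model: Tucker3Model
    truth_trend: np.ndarray
    external_table: pd.DataFrame
    spec: SyntheticSpec


def _orthonormal(rng: np.random.Generator, n: int, r: int,
                 zero_mean: bool = False,
                 template: np.ndarray | None = None) -> np.ndarray:
    if template is not None:
        m = np.asarray(template, dtype=float).copy()
        if m.shape != (n, r):
            raise ValidationError("loading template has wrong shape")
    else:
        m = rng.standard_normal((n, r))
    if zero_mean:
        m = m - m.mean(axis=0, keepdims=True)
    q, rr = np.linalg.qr(m)
    # make QR deterministic in sign
    q = q * np.sign(np.diag(rr))[None, :]
    return q


def _equalize_slab_ss(
    b: np.ndarray, g: np.ndarray, iters: int = 300, tol: float = 1e-13
) -> np.ndarray:
    """Rescale and re-orthonormalize B so every item slab of the planted
    structure carries equal sum of squares.

    The structure's slab-j SS is the squared norm of row j of
    B @ unfold(G, 1); alternating row rescaling toward the common RMS
    with column re-orthonormalization (a Sinkhorn-style iteration)
    converges to a B that is orthonormal *and* gives equal slab SS.
    Downstream symptom-mode normalization then rescales all items by the
    same factor, so the planted component columns survive preprocessing
    unchanged — and the questionnaire analogy ("all items equally
    informative") is built in rather than broken by normalization.
    """
    g2 = np.moveaxis(g, 1, 0).reshape(g.shape[1], -1)  # Q x (P*R)
    for _ in range(iters):
        rows = np.linalg.norm(b @ g2, axis=1)
        if rows.min() == 0.0:
            return b  # an item carries no structure: nothing to equalize
        target = np.sqrt(np.mean(rows**2))
        b = b * (target / rows)[:, None]
        q, rr = np.linalg.qr(b)
        b = q * np.sign(np.diag(rr))[None, :]
        new_rows = np.linalg.norm(b @ g2, axis=1)
        if np.std(new_rows) / np.mean(new_rows) < tol:
            break
    return b


def generate_tucker3_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a cube with planted Tucker3 structure per the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    i_n, j_n, k_n = spec.dims
    p_n, q_n, r_n = spec.ranks

    a = _orthonormal(rng, i_n, p_n, zero_mean=True)
    b = _orthonormal(rng, j_n, q_n, template=spec.symptom_loadings)
    c = _orthonormal(rng, k_n, r_n, template=spec.time_loadings)
    g = np.zeros((p_n, q_n, r_n))
    for p, q, r, mag in spec.core_pattern:
        g[p, q, r] = mag
    if spec.equalize_item_scale and q_n > 1 and np.any(g != 0):
        b = _equalize_slab_ss(b, g)
    (a, b, c), g = apply_sign_convention([a, b, c], g)

    structure = multi_mode_dot(g, (a, b, c))
    trend = (
        np.zeros((j_n, k_n)) if spec.trend is None
        else np.asarray(spec.trend, dtype=float)
    )
    values = trend[None, :, :] + structure
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    if spec.score_bounds is not None:
        lo, hi = spec.score_bounds
        values = np.clip(np.rint(values), lo, hi)

    dataset = ThreeWayDataset(
        values=values,
        mask=np.ones(spec.dims, dtype=bool),
        person_ids=[f"p{i:04d}" for i in range(i_n)],
        item_labels=[f"item{j:02d}" for j in range(j_n)],
        time_labels=np.arange(k_n, dtype=float) * 3.0,  # three-monthly
        time_unit="months",
    )
    if spec.missing_rate > 0:
        dataset = inject_missingness(
            dataset, spec.missing_rate, spec.missing_mechanism,
            seed=int(rng.integers(2**31)),
        )

    # external covariates correlated with standardized person scores
    z = a * np.sqrt(i_n)  # columns: mean 0, sd 1
    cols = {}
    loadings = (
        np.zeros((spec.n_external, p_n)) if spec.external_loadings is None
        else np.asarray(spec.external_loadings, dtype=float)
    )
    for e in range(spec.n_external):
        row = loadings[e]
        resid_sd = float(np.sqrt(max(0.0, 1.0 - np.sum(row**2))))
        cols[f"ext{e:02d}"] = z @ row + rng.normal(0.0, resid_sd, size=i_n)
    external = pd.DataFrame(cols, index=pd.Index(dataset.person_ids, name="person_id"))

    truth = Tucker3Model(a, b, c, g, tuple(spec.ranks), fit_pct=100.0)
    return SyntheticDataset(
        dataset=dataset,
        truth_model=truth,
        truth_trend=trend,
        external_table=external,
        spec=spec,
    )


def inject_missingness(
    dataset: ThreeWayDataset,
    rate: float,
    mechanism: str = "MCAR",
    seed: int | None = None,
) -> ThreeWayDataset:
    """Mask exactly round(rate * I*J*K) cells.

    ``MCAR`` masks uniformly at random; ``MAR-by-time`` multiplies each
    cell's masking odds by 1.5 per later time point (dropout-like),
    still hitting the exact target count.  Selection uses Gumbel top-k
    sampling, which draws a weighted sample without replacement in one
    vectorized pass.
    """
    if not 0.0 <= rate < 1.0:
        raise ValidationError("rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR-by-time"):
        raise ValidationError(f"unknown missingness mechanism {mechanism!r}")
    n_cells = int(np.prod(dataset.shape))
    count = int(round(rate * n_cells))
    if count == 0:
        return dataset.copy()

    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        log_w = np.zeros(dataset.shape)
    else:
        k_idx = np.arange(dataset.n_times)
        log_w = np.broadcast_to(
            np.log(1.5) * k_idx[None, None, :], dataset.shape
        ).copy()
    keys = log_w + rng.gumbel(size=dataset.shape)
    threshold = np.partition(keys.ravel(), n_cells - count)[n_cells - count]
    new_missing = keys >= threshold
    # ties at the threshold are broken arbitrarily but the count is exact
    if new_missing.sum() != count:
        flat = np.flatnonzero((keys == threshold).ravel())
        drop = new_missing.sum() - count
        new_missing.ravel()[flat[:drop]] = False
    out = dataset.copy()
    out.mask = dataset.mask & ~new_missing
    return out


def write_truth_sidecar(synth: SyntheticDataset, path: str | Path) -> None:
    """Persist the planted model as a JSON sidecar for test harnesses."""
    payload = {
        "dims": list(synth.spec.dims),
        "ranks": list(synth.spec.ranks),
        "noise_sd": synth.spec.noise_sd,
        "missing_rate": synth.spec.missing_rate,
        "seed": synth.spec.seed,
        "A": synth.truth_model.A.tolist(),
        "B": synth.truth_model.B.tolist(),
        "C": synth.truth_model.C.tolist(),
        "G": synth.truth_model.G.tolist(),
        "trend": synth.truth_trend.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def write_synthetic(synth: SyntheticDataset, directory: str | Path) -> None:
    """Write the long-format CSV, the external table and the truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_long_table(synth.dataset, directory / "data_long.csv")
    synth.external_table.to_csv(directory / "external.csv")
    write_truth_sidecar(synth, directory / "truth.json")


# ---------------------------------------------------------------------------
# study-shaped preset
# ---------------------------------------------------------------------------

# Frozen defaults for the 219 x 21 x 9 study-shaped preset.  Core
# magnitudes follow the planted interaction pattern (one dominant
# persisting-somatic element), and the noise level was calibrated by
# Monte Carlo so that the planted structure carries roughly 28% of the
# post-preprocessing sum of squares, with the general trend sized so
# that trend + structure explain roughly 65% on the normalized scale.
_STUDY_DIMS = (219, 21, 9)
_STUDY_RANKS = (3, 2, 2)
_STUDY_CORE = [
    # (person, symptom, time, magnitude); the (p, r) / (p, q) / (q, r)
    # supports are pairwise disjoint per mode, so every matricization of
    # the core has orthogonal rows and the planted component columns are
    # identified up to sign and order
    (0, 0, 0, 28.0),   # severe non-persisting: improving cognitive-like block
    (1, 1, 1, 57.0),   # somatic depression: persisting somatic-like block
    (2, 0, 1, 30.0),   # cognitive depression: persisting cognitive-like block
]
_STUDY_NOISE_SD = 0.568
_STUDY_TREND_SCALE = 1.34


def _study_trend(scale: float = _STUDY_TREND_SCALE) -> np.ndarray:
    """Declining mean item trajectories: per-item severity times a
    shared recovery curve (fast early improvement, then stable)."""
    j_n, k_n = _STUDY_DIMS[1], _STUDY_DIMS[2]
    base = np.linspace(0.45, 1.35, j_n)
    base = base[(np.arange(j_n) * 7) % j_n]  # fixed interleave, not sorted
    t = np.arange(k_n)
    curve = 0.45 + 0.55 * np.exp(-t / 2.0)
    return scale * np.outer(base, curve)


def _study_symptom_loadings() -> np.ndarray:
    """Two disjoint item blocks (cognitive-like vs somatic-like) with
    mildly varying loadings."""
    j_n = _STUDY_DIMS[1]
    b = np.zeros((j_n, 2))
    half = j_n // 2  # 10 items on component 1, 11 on component 2
    b[:half, 0] = 0.8 + 0.04 * np.cos(np.arange(half))
    b[half:, 1] = 0.8 + 0.04 * np.sin(np.arange(j_n - half))
    return b


def _study_time_loadings() -> np.ndarray:
    """Improving (high early, declining) and persisting (late-rising)
    time profiles."""
    k_n = _STUDY_DIMS[2]
    t = np.arange(k_n, dtype=float)
    improving = np.exp(-t / 2.0)
    persisting = 1.0 - np.exp(-t / 3.0)
    return np.column_stack([improving, persisting])


def study_like_spec(
    seed: int = 0,
    noise_sd: float = _STUDY_NOISE_SD,
    missing_rate: float = 0.078,
    missing_mechanism: str = "MCAR",
    clip: bool = False,
    n_external: int = 2,
    external_loadings: np.ndarray | None = None,
    core_scale: float = 1.0,
    trend_scale: float = _STUDY_TREND_SCALE,
) -> SyntheticSpec:
    """Spec emulating the study conditions: a 219 x 21 x 9 cube with a
    planted (3, 2, 2) structure around a declining general trend,
    bounded 0-3 item scores when ``clip`` is on, 7.8% missing entries,
    and two external covariates loading on person components 1 and 3
    (implied correlations 0.6 and 0.45) unless overridden."""
    if external_loadings is None and n_external == 2:
        external_loadings = np.array([[0.6, 0.0, 0.0], [0.0, 0.0, 0.45]])
    return SyntheticSpec(
        dims=_STUDY_DIMS,
        ranks=_STUDY_RANKS,
        core_pattern=[(p, q, r, m * core_scale) for p, q, r, m in _STUDY_CORE],
        trend=_study_trend(trend_scale),
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        missing_mechanism=missing_mechanism,
        score_bounds=(0, 3) if clip else None,
        n_external=n_external,
        external_loadings=external_loadings,
        symptom_loadings=_study_symptom_loadings(),
        time_loadings=_study_time_loadings(),
        seed=seed,
    )
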