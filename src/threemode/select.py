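"""Model-complexity selection and stability assessment.

Rank selection follows the generalized scree idea: fit every admissible
(P, Q, R) triple up to a ceiling on each of the imputed (preprocessed)
cubes, plot mean fit against the total number of components
S = P + Q + R, and keep the triples on the upper convex hull of that
plot — models for which no cheaper or equally cheap model fits as well,
and whose fit-per-component trade-off is efficient.  Among hull models
the scree "elbow" is the entry with the largest drop ratio of
successive hull fits (DifFit-style salience), with instability across
imputations (component congruence below a threshold) vetoing a
candidate, and ties resolved toward fewer components.

Split-half stability refits the model on random person halves
(preprocessed independently, since centering is part of the estimator)
and compares symptom- and time-mode components between halves by
Tucker congruence.  Person components are excluded by construction —
the halves share no persons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ThreeWayDataset
from .errors import SelectionError, ValidationError
from .preprocess import preprocess
from .rotate import RotationWeights, align_solution, congruence, joint_orthomax
from .tucker import Tucker3Model, tucker3_als

__all__ = [
    "ScreeEntry",
    "ScreeGrid",
    "StabilityReport",
    "admissible_ranks",
    "scree_grid",
    "cross_imputation_stability",
    "select_complexity",
    "split_half_stability",
]


def admissible_ranks(
    max_ranks: tuple[int, int, int],
    dims: tuple[int, int, int] | None = None,
) -> list[tuple[int, int, int]]:
    """All rank triples up to max_ranks satisfying Tucker3 admissibility."""
    out = []
    pm, qm, rm = max_ranks
    for p in range(1, pm + 1):
        for q in range(1, qm + 1):
            for r in range(1, rm + 1):
                if p > q * r or q > p * r or r > p * q:
                    continue
                if dims is not None and (p > dims[0] or q > dims[1] or r > dims[2]):
                    continue
                out.append((p, q, r))
    return out


@dataclass
class ScreeEntry:
    ranks: tuple[int, int, int]
    total_components: int
    fits: list[float]          # per-imputation fit percentages
    mean_fit: float
    sd_fit: float
    on_hull: bool = False


@dataclass
class ScreeGrid:
    entries: list[ScreeEntry]

    def hull_entries(self) -> list[ScreeEntry]:
        return sorted(
            (e for e in self.entries if e.on_hull),
            key=lambda e: (e.total_components, -e.mean_fit),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "P": [e.ranks[0] for e in self.entries],
                "Q": [e.ranks[1] for e in self.entries],
                "R": [e.ranks[2] for e in self.entries],
                "S": [e.total_components for e in self.entries],
                "mean_fit_pct": [e.mean_fit for e in self.entries],
                "sd_fit_pct": [e.sd_fit for e in self.entries],
                "on_hull": [e.on_hull for e in self.entries],
            }
        )


def _flag_hull(entries: list[ScreeEntry]) -> None:
    """Flag entries on the upper convex hull of (S, best fit per S)."""
    best: dict[int, float] = {}
    for e in entries:
        best[e.total_components] = max(
            best.get(e.total_components, -np.inf), e.mean_fit
        )
    pts = sorted(best.items())  # (S, fit) with fit the best at that S
    # keep points that are not dominated and lie on the concave envelope
    hull: list[tuple[int, float]] = []
    for s, f in pts:
        if hull and f <= hull[-1][1]:
            continue  # dominated: more components, no more fit
        hull.append((s, f))
        while len(hull) >= 3:
            (s1, f1), (s2, f2), (s3, f3) = hull[-3:]
            if (f2 - f1) * (s3 - s2) <= (f3 - f2) * (s2 - s1):
                hull.pop(-2)  # middle point below the chord: not on hull
            else:
                break
    hull_set = set(hull)
    for e in entries:
        e.on_hull = (e.total_components, e.mean_fit) in hull_set


def scree_grid(
    preprocessed_cubes: list[np.ndarray],
    max_ranks: tuple[int, int, int],
    n_starts: int = 1,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> ScreeGrid:
    """Fit every admissible rank triple on every imputed cube."""
    if not preprocessed_cubes:
        raise ValidationError("need at least one cube")
    dims = preprocessed_cubes[0].shape
    if any(mr > d for mr, d in zip(max_ranks, dims)):
        raise ValidationError("max_ranks exceed cube dimensions")
    entries = []
    for ranks in admissible_ranks(max_ranks, dims):
        fits = [
            tucker3_als(
                cube, ranks, n_starts=n_starts, tol=tol,
                max_iter=max_iter, seed=seed,
            ).fit_pct
            for cube in preprocessed_cubes
        ]
        entries.append(
            ScreeEntry(
                ranks=ranks,
                total_components=sum(ranks),
                fits=fits,
                mean_fit=float(np.mean(fits)),
                sd_fit=float(np.std(fits)),
            )
        )
    _flag_hull(entries)
    return ScreeGrid(entries=entries)


def cross_imputation_stability(
    preprocessed_cubes: list[np.ndarray],
    ranks: tuple[int, int, int],
    weights: RotationWeights | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> float:
    """Minimum symptom/time component congruence across imputations.

    Each cube is fitted and rotated, solutions are aligned to the first,
    and per-column congruences with the element-wise mean component are
    computed for the symptom and time modes.  Returns the smallest one.
    """
    models = []
    for cube in preprocessed_cubes:
        model = tucker3_als(cube, ranks, tol=tol, max_iter=max_iter)
        models.append(joint_orthomax(model, weights))
    aligned = [models[0]] + [align_solution(m, models[0]) for m in models[1:]]
    min_phi = 1.0
    for mode in (1, 2):  # symptom, time
        stack = [m.matrices[mode] for m in aligned]
        mean = np.mean(stack, axis=0)
        for m in stack:
            for col in range(m.shape[1]):
                min_phi = min(min_phi, congruence(m[:, col], mean[:, col]))
    return float(min_phi)


def select_complexity(
    grid: ScreeGrid,
    stability: dict[tuple[int, int, int], float] | None = None,
    stability_threshold: float = 0.85,
) -> tuple[tuple[int, int, int], list[str]]:
    """Pick a rank triple from the scree grid.

    Among convex-hull entries the candidate with the largest salience —
    the drop ratio (fit gain from the previous hull entry) / (fit gain
    to the next hull entry) — wins; candidates whose cross-imputation
    congruence falls below ``stability_threshold`` are vetoed, and ties
    go to fewer total components.  Returns the chosen ranks and a
    human-readable decision trace.
    """
    if not grid.entries:
        raise SelectionError("empty scree grid")
    hull = grid.hull_entries()
    if not hull:
        raise SelectionError("no hull entries in grid")
    trace = [f"hull: {[(e.ranks, round(e.mean_fit, 2)) for e in hull]}"]
    if len(hull) == 1:
        trace.append(f"single hull entry -> {hull[0].ranks}")
        return hull[0].ranks, trace

    def stable(e: ScreeEntry) -> bool:
        if stability is None or e.ranks not in stability:
            return True
        return stability[e.ranks] >= stability_threshold

    candidates = []
    for i, e in enumerate(hull):
        if i == 0 or i == len(hull) - 1:
            continue  # endpoints have no defined drop ratio
        gain_prev = e.mean_fit - hull[i - 1].mean_fit
        gain_next = hull[i + 1].mean_fit - e.mean_fit
        salience = gain_prev / max(gain_next, 1e-12)
        candidates.append((e, salience))
    if not candidates:  # two hull points: prefer the simpler stable one
        for e in hull:
            if stable(e):
                trace.append(f"no interior hull points; simplest stable -> {e.ranks}")
                return e.ranks, trace
        trace.append(f"no stable entry; fallback to simplest -> {hull[0].ranks}")
        return hull[0].ranks, trace

    candidates.sort(key=lambda t: (-t[1], t[0].total_components))
    for e, sal in candidates:
        if stable(e):
            trace.append(
                f"selected {e.ranks} (salience {sal:.2f}, "
                f"stability ok)"
            )
            return e.ranks, trace
        trace.append(
            f"vetoed {e.ranks} (salience {sal:.2f}): cross-imputation "
            f"congruence {stability[e.ranks]:.3f} < {stability_threshold}"
        )
    # all interior candidates unstable: fall back to the simplest stable
    for e in hull:
        if stable(e):
            trace.append(f"all salient candidates unstable -> {e.ranks}")
            return e.ranks, trace
    trace.append(f"nothing stable; fallback -> {hull[0].ranks}")
    return hull[0].ranks, trace


@dataclass
class StabilityReport:
    """Split-half congruences of symptom and time components."""

    per_split_congruence: list[dict[str, np.ndarray]]
    min_congruence: float
    n_splits: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, d in enumerate(self.per_split_congruence):
            for mode, phis in d.items():
                for col, phi in enumerate(phis):
                    rows.append(
                        {"split": s, "mode": mode, "component": col, "phi": phi}
                    )
        return pd.DataFrame(rows)


def split_half_stability(
    dataset: ThreeWayDataset,
    ranks: tuple[int, int, int],
    n_splits: int = 10,
    weights: RotationWeights | None = None,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StabilityReport:
    """Refit on random person halves and compare B and C across halves.

    Each half is preprocessed independently (centering is part of the
    estimator), fitted at the given ranks, rotated, and the second
    half's solution aligned to the first's; φ is recorded per symptom
    and time component.  Requires a complete cube and I >= 4.
    """
    if dataset.n_persons < 4:
        raise ValidationError("split-half needs at least 4 persons")
    if any(r > d for r, d in zip(ranks, (dataset.n_persons // 2,
                                         dataset.n_items, dataset.n_times))):
        raise ValidationError("ranks inadmissible for half-sized samples")
    rng = np.random.default_rng(seed)
    per_split = []
    min_phi = 1.0
    for _s in range(n_splits):
        perm = rng.permutation(dataset.n_persons)
        halves = (perm[: dataset.n_persons // 2], perm[dataset.n_persons // 2:])
        models: list[Tucker3Model] = []
        for idx in halves:
            sub = ThreeWayDataset(
                dataset.values[idx],
                dataset.mask[idx],
                [dataset.person_ids[i] for i in idx],
                list(dataset.item_labels),
                dataset.time_labels.copy(),
                dataset.time_unit,
            )
            cube, _state = preprocess(sub)
            model = tucker3_als(cube.values, ranks, tol=tol, max_iter=max_iter)
            models.append(joint_orthomax(model, weights))
        second = align_solution(models[1], models[0], modes=(1, 2))
        rec: dict[str, np.ndarray] = {}
        for mode, name in ((1, "symptom"), (2, "time")):
            phis = np.array(
                [
                    congruence(
                        models[0].matrices[mode][:, c], second.matrices[mode][:, c]
                    )
                    for c in range(ranks[mode])
                ]
            )
            rec[name] = phis
            min_phi = min(min_phi, float(phis.min()))
        per_split.append(rec)
    return StabilityReport(
        per_split_congruence=per_split,
        min_congruence=min_phi,
        n_splits=n_splits,
        seed=seed,
    )
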