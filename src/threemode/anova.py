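"""Fixed-effects three-way ANOVA variance decomposition of a score cube.

After subtracting the grand mean, a complete balanced persons x items x
times cube decomposes orthogonally into three main effects, three
pairwise interactions and a three-way-interaction-plus-error remainder.
The percentage shares answer a screening question: is there a
non-negligible three-way interaction worth modelling with a Tucker3
decomposition at all?

No F tests are computed — with a single observation per cell the
three-way term is confounded with error, and only the SS shares are of
interest here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, PoolingError

EFFECTS = (
    "persons",
    "symptoms",
    "time",
    "persons x symptoms",
    "persons x time",
    "symptoms x time",
    "three-way + error",
)


@dataclass
class VarianceDecomposition:
    """Sums of squares and percentage shares for the seven effects.

    ``pct`` sums to 100 unless the cube was constant, in which case all
    shares are reported as 0 and ``zero_total`` is set.
    """

    ss: dict[str, float]
    pct: dict[str, float]
    zero_total: bool = False
    ss_sd: dict[str, float] | None = None
    pct_sd: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in (*EFFECTS, "total"):
            row = {"effect": eff, "SS": self.ss[eff], "pct": self.pct[eff]}
            if self.ss_sd is not None:
                row["SS_sd"] = self.ss_sd[eff]
                row["pct_sd"] = self.pct_sd[eff]
            rows.append(row)
        return pd.DataFrame(rows)


def three_way_anova(cube: np.ndarray) -> VarianceDecomposition:
    """Decompose a complete cube's grand-mean-centered SS into 7 effects.

    Uses the classical balanced-design formulas, e.g.
    ``SS_persons = J*K * sum_i (xbar_i.. - xbar...)^2``; pairwise terms
    come from two-way cell means minus the contained main effects; the
    remainder is total minus the six fitted terms.
    """
    x = np.asarray(cube, dtype=float)
    if x.ndim != 3:
        raise DegenerateDesignError("input must be a 3-way array")
    i_n, j_n, k_n = x.shape
    if min(i_n, j_n, k_n) < 2:
        raise DegenerateDesignError("all dimensions must be >= 2")

    grand = x.mean()
    xc = x - grand
    a = xc.mean(axis=(1, 2))           # person main effect
    b = xc.mean(axis=(0, 2))           # symptom main effect
    c = xc.mean(axis=(0, 1))           # time main effect
    ab = xc.mean(axis=2) - a[:, None] - b[None, :]
    ac = xc.mean(axis=1) - a[:, None] - c[None, :]
    bc = xc.mean(axis=0) - b[:, None] - c[None, :]

    ss = {
        "persons": j_n * k_n * float(np.sum(a**2)),
        "symptoms": i_n * k_n * float(np.sum(b**2)),
        "time": i_n * j_n * float(np.sum(c**2)),
        "persons x symptoms": k_n * float(np.sum(ab**2)),
        "persons x time": j_n * float(np.sum(ac**2)),
        "symptoms x time": i_n * float(np.sum(bc**2)),
    }
    total = float(np.sum(xc**2))
    ss["three-way + error"] = max(total - sum(ss.values()), 0.0)
    ss["total"] = total

    # a numerically constant cube has no decomposable variance
    if total <= 1e-12 * max(float(np.sum(x**2)), 1.0):
        pct = {k: 0.0 for k in ss}
        return VarianceDecomposition(ss=ss, pct=pct, zero_total=True)
    pct = {k: 100.0 * v / total for k, v in ss.items()}
    return VarianceDecomposition(ss=ss, pct=pct)


def pool_anova(
    decompositions: list[VarianceDecomposition],
) -> VarianceDecomposition:
    """Element-wise mean and s.d. of decompositions across imputations."""
    if not decompositions:
        raise PoolingError("need at least one decomposition to pool")
    keys = list(decompositions[0].ss.keys())
    for d in decompositions[1:]:
        if list(d.ss.keys()) != keys:
            raise PoolingError("decompositions have mismatched effect keys")
    ss_arr = np.array([[d.ss[k] for k in keys] for d in decompositions])
    pct_arr = np.array([[d.pct[k] for k in keys] for d in decompositions])
    mean_ss = dict(zip(keys, ss_arr.mean(axis=0)))
    mean_pct = dict(zip(keys, pct_arr.mean(axis=0)))
    sd_ss = dict(zip(keys, ss_arr.std(axis=0, ddof=0)))
    sd_pct = dict(zip(keys, pct_arr.std(axis=0, ddof=0)))
    return VarianceDecomposition(
        ss=mean_ss,
        pct=mean_pct,
        zero_total=all(d.zero_total for d in decompositions),
        ss_sd=sd_ss,
        pct_sd=sd_pct,
    )
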