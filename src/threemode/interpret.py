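"""Interpretive summaries of a pooled Tucker3 solution.

Three views are produced:

* per-core-element explained variance — since the factors are
  orthonormal, each core element g_pqr contributes g_pqr^2 to the
  model's explained SS, so 100 * g^2 / SS(preprocessed cube) allocates
  the heterogeneity fit over the component interactions;
* component trajectory curves — for each (person component p, symptom
  component q) the time curve sum_r g_pqr * c_kr, i.e. how that
  symptom dimension evolves for persons scoring on component p, with
  the general trend's projection onto the symptom components as
  context;
* external correlations — per person-component correlations with
  baseline covariates, Pearson or Spearman chosen by a normality check
  on each covariate, pooled across imputations on the Fisher-z scale
  with a Rubin-style total variance for the p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .preprocess import PreprocessingState
from .rotate import PooledSolution
from .tucker import Tucker3Model

__all__ = [
    "core_explained_variance",
    "component_trajectories",
    "external_correlations",
]


def core_explained_variance(
    pooled: PooledSolution | Tucker3Model,
    ss_preprocessed: float,
) -> pd.DataFrame:
    """Tabulate core elements and their explained-variance percentages.

    ``ss_preprocessed`` is the SS of the cube the model was fitted to
    (for a slab-RMS-1 normalized cube this is I*J*K).  The ev_pct
    column sums to the heterogeneity fit percentage up to ALS
    tolerance.  When given a :class:`PooledSolution`, across-imputation
    standard deviations of both the core elements and their EV
    percentages are included.
    """
    if ss_preprocessed <= 0:
        raise ValidationError("ss_preprocessed must be positive")
    if isinstance(pooled, PooledSolution):
        model = pooled.mean_model
        g_sd = pooled.element_sd["G"]
    else:
        model = pooled
        g_sd = None
    rows = []
    p_n, q_n, r_n = model.G.shape
    for p in range(p_n):
        for q in range(q_n):
            for r in range(r_n):
                g = float(model.G[p, q, r])
                row = {
                    "person_component": p,
                    "symptom_component": q,
                    "time_component": r,
                    "core": g,
                    "ev_pct": 100.0 * g * g / ss_preprocessed,
                }
                if g_sd is not None:
                    sd = float(g_sd[p, q, r])
                    row["core_sd"] = sd
                    # delta-method spread of g^2/SS
                    row["ev_pct_sd"] = 100.0 * 2.0 * abs(g) * sd / ss_preprocessed
                rows.append(row)
    return pd.DataFrame(rows)


def component_trajectories(
    pooled: PooledSolution | Tucker3Model,
    state: PreprocessingState | None = None,
) -> pd.DataFrame:
    """Time curves per (person component, symptom component).

    Returns a tidy frame with columns person_component (int, or the
    string ``"trend"`` for the general-trend context rows),
    symptom_component, time_index and value.  Curves are computed as
    sum_r g_pqr * c_kr and are invariant to the column sign convention
    because sign flips are compensated in the core.
    """
    model = pooled.mean_model if isinstance(pooled, PooledSolution) else pooled
    p_n, q_n, _ = model.G.shape
    k_n = model.C.shape[0]
    rows = []
    for p in range(p_n):
        for q in range(q_n):
            curve = model.C @ model.G[p, q, :]
            for k in range(k_n):
                rows.append(
                    {
                        "person_component": p,
                        "symptom_component": q,
                        "time_index": k,
                        "value": float(curve[k]),
                    }
                )
    if state is not None:
        trend_scaled = state.trend / state.scales[:, None]  # J x K
        proj = model.B.T @ trend_scaled  # Q x K
        for q in range(q_n):
            for k in range(k_n):
                rows.append(
                    {
                        "person_component": "trend",
                        "symptom_component": q,
                        "time_index": k,
                        "value": float(proj[q, k]),
                    }
                )
    return pd.DataFrame(rows)


def _choose_method(x: np.ndarray, alpha: float = 0.05) -> str:
    """Shapiro-Wilk normality check: Spearman if normality is rejected."""
    if len(np.unique(x)) < 3:
        return "spearman"
    stat_p = stats.shapiro(x).pvalue
    return "pearson" if stat_p >= alpha else "spearman"


def external_correlations(
    person_scores: list[np.ndarray],
    external: pd.DataFrame,
    method: str = "auto",
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Correlate person-component scores with external covariates.

    Parameters
    ----------
    person_scores : list over imputations of I x P person-score
        matrices (aligned, e.g. from the generalized-Procrustes step).
    external : person x covariate table, rows aligned with the scores.
    method : ``"auto"`` (Shapiro-Wilk decides per covariate),
        ``"pearson"`` or ``"spearman"``.
    alpha : significance level for flagging.
    benjamini_hochberg : apply BH correction across rows before
        flagging.

    Per (component, covariate) the coefficient is computed in every
    imputation, averaged on the Fisher-z scale, and the p-value is
    taken from the pooled z with Rubin's total variance
    T = 1/(n-3) + (1 + 1/m) * B, where B is the between-imputation
    variance of z.  Both the pooled r and the plain mean/s.d. of the
    per-imputation r's are emitted.
    """
    if not person_scores:
        raise ValidationError("need at least one imputation's scores")
    n, p_n = person_scores[0].shape
    if external.shape[0] != n:
        raise ValidationError("external table does not align with person scores")
    m = len(person_scores)

    rows = []
    for var in external.columns:
        x = external[var].to_numpy(dtype=float)
        if np.all(x == x[0]):
            raise ValidationError(f"external variable {var!r} is constant")
        use = _choose_method(x, normality_alpha) if method == "auto" else method
        for comp in range(p_n):
            rs = []
            for scores in person_scores:
                s = scores[:, comp]
                if use == "pearson":
                    r = float(stats.pearsonr(s, x).statistic)
                else:
                    r = float(stats.spearmanr(s, x).statistic)
                rs.append(r)
            # clip only for the Fisher transform; |r| = 1 maps to inf
            zs = np.arctanh(np.clip(rs, -0.999999, 0.999999))
            z_bar = float(np.mean(zs))
            within = 1.0 / (n - 3)
            between = float(np.var(zs, ddof=1)) if m > 1 else 0.0
            total_var = within + (1.0 + 1.0 / m) * between
            p_val = 2.0 * stats.norm.sf(abs(z_bar) / np.sqrt(total_var))
            rows.append(
                {
                    "component": comp,
                    "variable": var,
                    "r": float(np.tanh(z_bar)),
                    "r_mean": float(np.mean(rs)),
                    "r_sd": float(np.std(rs, ddof=0)),
                    "method": use,
                    "p": float(p_val),
                }
            )
    out = pd.DataFrame(rows)
    if benjamini_hochberg:
        pv = out["p"].to_numpy()
        order = np.argsort(pv)
        ranked = pv[order] * len(pv) / (np.arange(len(pv)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(adj)
        q[order] = np.clip(adj, 0, 1)
        out["p_adjusted"] = q
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out
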