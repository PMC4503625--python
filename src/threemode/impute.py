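"""Multiple imputation of missing cube entries by bootstrap EM.

The cube is flattened to a persons x (items * times) matrix (optionally
augmented with person-level covariate columns) and modelled as
multivariate normal.  For each of the m imputations, persons are
resampled with replacement, EM is run to a (mu, Sigma) point estimate
on the bootstrap sample — the bootstrap supplies the parameter
uncertainty that a fully Bayesian imputer would get from posterior
draws — and every original person's missing block is then drawn from
its conditional normal given that person's observed entries.

With J*K columns and a comparable number of persons the unregularized
EM covariance is near-singular, so each M-step shrinks Sigma toward its
own diagonal with a ridge prior weight (default 0.5% of the number of
persons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .data import ThreeWayDataset, write_long_table
from .errors import UnimputableColumnError, ValidationError


@dataclass
class ImputationSet:
    """m completed copies of one cube (masks all-true).

    Observed cells are identical across completions and equal to the
    input's observed cells; only originally-missing cells vary.
    """

    completed: list[ThreeWayDataset]
    m: int
    seed: int | None
    ridge: float
    em_iterations_used: list[int] = field(default_factory=list)
    em_converged: list[bool] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t, ds in enumerate(self.completed):
            write_long_table(ds, directory / f"imputation_{t:02d}.csv")
        manifest = pd.DataFrame(
            {
                "imputation": range(self.m),
                "em_iterations": self.em_iterations_used,
                "em_converged": self.em_converged,
            }
        )
        manifest.attrs["seed"] = self.seed
        manifest.to_csv(directory / "manifest.csv", index=False)
        (directory / "params.csv").write_text(
            f"m,seed,ridge\n{self.m},{self.seed},{self.ridge}\n"
        )


def _em_mvn(
    y: np.ndarray,
    observed: np.ndarray,
    ridge_weight: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """EM point estimate of (mu, Sigma) for MVN data with missing entries.

    ``ridge_weight`` is the prior weight lambda: the M-step covariance is
    (n * S_hat + lambda * diag(S_hat)) / (n + lambda).
    Convergence is declared when the relative change of (mu, Sigma)
    drops below ``tol``.
    """
    n, p = y.shape
    col_obs = observed.sum(axis=0)
    if np.any(col_obs == 0):
        j = int(np.flatnonzero(col_obs == 0)[0])
        raise UnimputableColumnError(f"flattened column {j} has no observed entries")

    work = np.where(observed, y, np.nan)
    mu = np.nanmean(work, axis=0)
    var = np.nanvar(work, axis=0)
    var = np.where(var > 0, var, np.nanmean(var[var > 0]) if np.any(var > 0) else 1.0)
    sigma = np.diag(var)

    # group persons by missingness pattern so each pattern is solved once
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(observed[i].tobytes(), []).append(i)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ey = np.where(observed, y, 0.0)
        exx_corr = np.zeros((p, p))
        for key, idx in patterns.items():
            obs = np.frombuffer(key, dtype=bool)
            mis = ~obs
            if not mis.any():
                continue
            rows = np.asarray(idx)
            s_oo = sigma[np.ix_(obs, obs)]
            s_mo = sigma[np.ix_(mis, obs)]
            jitter = 1e-10 * max(np.trace(s_oo) / obs.sum(), 1e-300)
            try:
                chol = cho_factor(s_oo + jitter * np.eye(obs.sum()), lower=True)
            except np.linalg.LinAlgError:
                chol = cho_factor(s_oo + 1e-6 * np.eye(obs.sum()), lower=True)
            gain = cho_solve(chol, s_mo.T).T  # p_m x p_o
            resid = (y[np.ix_(rows, np.flatnonzero(obs))] - mu[obs]).T
            cond_mean = mu[mis][None, :] + (gain @ resid).T
            ey[np.ix_(rows, np.flatnonzero(mis))] = cond_mean
            cond_cov = sigma[np.ix_(mis, mis)] - gain @ s_mo.T
            exx_corr[np.ix_(mis, mis)] += len(rows) * cond_cov

        new_mu = ey.mean(axis=0)
        centered = ey - new_mu
        s_hat = (centered.T @ centered + exx_corr) / n
        new_sigma = (n * s_hat + ridge_weight * np.diag(np.diag(s_hat))) / (
            n + ridge_weight
        )
        num = np.abs(new_mu - mu).max() + np.abs(new_sigma - sigma).max()
        den = max(np.abs(mu).max() + np.abs(sigma).max(), 1e-12)
        mu, sigma = new_mu, new_sigma
        if num / den < tol:
            converged = True
            break
    return mu, sigma, it, converged


def _conditional_draw(
    y: np.ndarray,
    observed: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw all persons' missing blocks from their conditional normals."""
    out = y.copy()
    n, p = y.shape
    for i in range(n):
        mis = ~observed[i]
        if not mis.any():
            continue
        obs = observed[i]
        s_oo = sigma[np.ix_(obs, obs)]
        s_mo = sigma[np.ix_(mis, obs)]
        s_mm = sigma[np.ix_(mis, mis)]
        if obs.any():
            jitter = 1e-10 * max(np.trace(s_oo) / max(obs.sum(), 1), 1e-300)
            chol = cho_factor(s_oo + jitter * np.eye(obs.sum()), lower=True)
            gain = cho_solve(chol, s_mo.T).T
            cond_mean = mu[mis] + gain @ (y[i, obs] - mu[obs])
            cond_cov = s_mm - gain @ s_mo.T
        else:
            cond_mean = mu[mis]
            cond_cov = s_mm
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        w, v = np.linalg.eigh(cond_cov)
        w = np.clip(w, 0.0, None)
        draw = cond_mean + (v * np.sqrt(w)) @ rng.standard_normal(mis.sum())
        out[i, mis] = draw
    return out


def em_bootstrap_impute(
    dataset: ThreeWayDataset,
    covariates: pd.DataFrame | None = None,
    m: int = 20,
    ridge: float = 0.005,
    max_em_iter: int = 100,
    tol: float = 1e-5,
    seed: int | None = None,
) -> ImputationSet:
    """Multiply impute a cube's missing cells.

    Parameters
    ----------
    dataset : cube with missingness mask; every person needs >= 1
        observed cell.
    covariates : optional person x variable table (index = person ids)
        joined into the EM model; covariate values may themselves be
        missing (NaN) and are imputed along the way but are not
        returned.
    m : number of imputations.
    ridge : diagonal-shrinkage prior weight as a fraction of the number
        of persons (lambda = ridge * I).
    seed : master seed; each imputation derives its own stream.

    Returns an :class:`ImputationSet` of m completed cubes.  With no
    missing cells the result is m identical copies of the input.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if ridge < 0:
        raise ValidationError("ridge must be nonnegative")
    i_n, j_n, k_n = dataset.shape
    person_obs = dataset.mask.reshape(i_n, -1).sum(axis=1)
    if np.any(person_obs == 0):
        raise ValidationError("every person must have at least one observed cell")

    y = dataset.values.reshape(i_n, j_n * k_n).copy()
    observed = dataset.mask.reshape(i_n, j_n * k_n).copy()
    n_cube_cols = j_n * k_n
    if covariates is not None:
        cov = covariates.reindex(dataset.person_ids)
        cov_vals = cov.to_numpy(dtype=float)
        y = np.hstack([y, np.where(np.isnan(cov_vals), 0.0, cov_vals)])
        observed = np.hstack([observed, ~np.isnan(cov_vals)])

    rng = np.random.default_rng(seed)
    ridge_weight = ridge * i_n
    completed: list[ThreeWayDataset] = []
    iters: list[int] = []
    convs: list[bool] = []
    no_missing = bool(observed.all())
    for _t in range(m):
        if no_missing:
            completed.append(dataset.copy())
            iters.append(0)
            convs.append(True)
            continue
        boot = rng.integers(0, i_n, size=i_n)
        mu, sigma, n_iter, conv = _em_mvn(
            y[boot], observed[boot], ridge_weight, max_em_iter, tol
        )
        filled = _conditional_draw(y, observed, mu, sigma, rng)
        cube = filled[:, :n_cube_cols].reshape(i_n, j_n, k_n)
        # observed cells are authoritative: copy them back verbatim
        cube = np.where(dataset.mask, dataset.values, cube)
        completed.append(
            dataset.with_values(cube, mask=np.ones(dataset.shape, dtype=bool))
        )
        iters.append(n_iter)
        convs.append(conv)

    return ImputationSet(
        completed=completed,
        m=m,
        seed=seed,
        ridge=ridge,
        em_iterations_used=iters,
        em_converged=convs,
    )
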