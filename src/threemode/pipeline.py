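"""Orchestration of the nine-step analysis pipeline.

The pipeline runs, in order: sample selection, multiple imputation,
three-way ANOVA, preprocessing, model-complexity selection (optional —
ranks may be fixed in the config), Tucker3 fitting per imputation,
joint orthomax rotation, generalized Procrustes pooling, fit
accounting, split-half stability and external correlations.  Every
intermediate is persisted to the run directory as CSV/JSON so each
stage can be inspected or re-run, and a machine-readable manifest
records all seeds, parameters and package version.

Configuration is a nested mapping (usually parsed from a YAML file)
with sections named after the package modules; every omitted key falls
back to the documented default.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import pool_anova, three_way_anova
from .data import (
    ThreeWayDataset,
    read_long_table,
    select_sample,
    write_long_table,
)
from .errors import MissingArtifactError, ValidationError
from .impute import em_bootstrap_impute
from .interpret import (
    component_trajectories,
    core_explained_variance,
    external_correlations,
)
from .preprocess import PreprocessingState, preprocess
from .rotate import (
    PooledSolution,
    RotationWeights,
    generalized_procrustes,
    joint_orthomax,
)
from .select import (
    cross_imputation_stability,
    scree_grid,
    select_complexity,
    split_half_stability,
)
from .tucker import Tucker3Model, total_fit_with_trend, tucker3_als

logger = logging.getLogger("threemode")

DEFAULT_CONFIG: dict[str, Any] = {
    "paths": {"input": None, "external": None, "output": "run"},
    "selection": {"min_timepoints": 5, "timepoint_rule": 0.5},
    "imputation": {"m": 20, "ridge": 0.005, "max_em_iter": 100, "tol": 1e-5,
                   "seed": 0},
    "model": {"ranks": "auto", "max_ranks": [4, 3, 3], "n_starts": 1,
              "tol": 1e-8, "max_iter": 1000, "seed": 0},
    "rotation": {"preset": "standard", "gamma": 1.0, "person_weight": False},
    "stability": {"n_splits": 10, "threshold": 0.85, "seed": 0},
    "correlation": {"alpha": 0.05, "method": "auto",
                    "benjamini_hochberg": False},
    "report": {"symptom_threshold": 0.20, "time_threshold": 0.30,
               "correlation_threshold": 0.30},
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict[str, Any]:
    """Merge a YAML config file and overrides onto the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if k not in dst:
                raise ValidationError(f"unknown config key {k!r}")
            if isinstance(v, dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        merge(cfg, loaded)
    if overrides:
        merge(cfg, overrides)
    if cfg["model"]["ranks"] == "auto" and not cfg["model"]["max_ranks"]:
        raise ValidationError('"auto" ranks require max_ranks')
    return cfg


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: Tucker3Model, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mat in zip("ABC", model.matrices):
        pd.DataFrame(mat).to_csv(directory / f"{name}.csv", index=False)
    p, q, r = model.G.shape
    pd.DataFrame(model.G.reshape(p, q * r)).to_csv(
        directory / "G_mode1.csv", index=False
    )
    manifest = {
        "ranks": list(model.ranks),
        "fit_pct": model.fit_pct,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }
    (directory / "model.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: str | Path) -> Tucker3Model:
    directory = Path(directory)
    if not (directory / "model.json").exists():
        raise MissingArtifactError(f"no model manifest in {directory}")
    meta = json.loads((directory / "model.json").read_text())
    mats = [
        pd.read_csv(directory / f"{name}.csv").to_numpy() for name in "ABC"
    ]
    p, q, r = meta["ranks"]
    core = pd.read_csv(directory / "G_mode1.csv").to_numpy().reshape(p, q, r)
    return Tucker3Model(
        *mats, core, tuple(meta["ranks"]), fit_pct=meta["fit_pct"],
        converged=meta["converged"], n_iter=meta["n_iter"],
    )


# ---------------------------------------------------------------------------
# run result
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """In-memory handles to everything a pipeline run produced."""

    output_dir: Path
    selected: ThreeWayDataset
    selection_report: Any
    anova: Any
    ranks: tuple[int, int, int]
    selection_trace: list[str]
    pooled: PooledSolution
    fit_accounts: list[Any]
    mean_heterogeneity_fit: float
    mean_total_fit: float
    stability: Any
    correlations: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: dict[str, Any],
    dataset: ThreeWayDataset | None = None,
    external: pd.DataFrame | None = None,
) -> RunResult:
    """Execute the full pipeline and persist every intermediate.

    ``dataset`` may be passed directly (e.g. from the synthetic
    generator); otherwise it is read from ``config["paths"]["input"]``.
    """
    t_start = time.time()
    out = Path(config["paths"]["output"])
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        if not config["paths"]["input"]:
            raise ValidationError("no input dataset given")
        dataset = read_long_table(config["paths"]["input"])
    if external is None and config["paths"]["external"]:
        external = pd.read_csv(config["paths"]["external"], index_col=0)

    def stage(name: str) -> None:
        logger.info("stage %-12s t=%.1fs", name, time.time() - t_start)

    # (1) sample selection
    stage("select")
    selected, report = select_sample(
        dataset,
        min_timepoints=config["selection"]["min_timepoints"],
        timepoint_rule=config["selection"]["timepoint_rule"],
    )
    (out / "selection_report.txt").write_text(report.to_text())
    write_long_table(selected, out / "selected_long.csv")

    # (2) multiple imputation
    stage("impute")
    imp_cfg = config["imputation"]
    imputations = em_bootstrap_impute(
        selected,
        covariates=external,
        m=imp_cfg["m"],
        ridge=imp_cfg["ridge"],
        max_em_iter=imp_cfg["max_em_iter"],
        tol=imp_cfg["tol"],
        seed=imp_cfg["seed"],
    )
    imputations.save(out / "imputations")

    # (3) three-way ANOVA on the grand-mean-subtracted completed cubes
    stage("anova")
    decomps = [three_way_anova(c.values) for c in imputations.completed]
    pooled_anova = pool_anova(decomps)
    pooled_anova.to_frame().to_csv(out / "anova.csv", index=False)

    # (4) preprocessing per imputed cube
    stage("preprocess")
    cubes: list[np.ndarray] = []
    states: list[PreprocessingState] = []
    for t, comp in enumerate(imputations.completed):
        pre, state = preprocess(comp)
        cubes.append(pre.values)
        states.append(state)
        state.save(out / "preprocessing" / f"imputation_{t:02d}")

    # (5) model complexity
    stage("complexity")
    model_cfg = config["model"]
    rot_weights = None  # built once ranks are known
    if model_cfg["ranks"] == "auto":
        grid = scree_grid(
            cubes,
            tuple(model_cfg["max_ranks"]),
            n_starts=model_cfg["n_starts"],
            tol=model_cfg["tol"],
            max_iter=model_cfg["max_iter"],
            seed=model_cfg["seed"],
        )
        grid.to_frame().to_csv(out / "scree.csv", index=False)
        stability_map = {
            e.ranks: cross_imputation_stability(cubes, e.ranks)
            for e in grid.hull_entries()
        }
        ranks, trace = select_complexity(
            grid, stability_map, config["stability"]["threshold"]
        )
    else:
        ranks = tuple(model_cfg["ranks"])
        trace = [f"ranks fixed by config: {ranks}"]
    (out / "complexity_trace.txt").write_text("\n".join(trace))

    dims = (selected.n_persons, selected.n_items, selected.n_times)
    if config["rotation"]["preset"] == "standard":
        rot_weights = RotationWeights.standard(
            dims, ranks,
            gamma=config["rotation"]["gamma"],
            person_weight=config["rotation"]["person_weight"],
        )
    else:
        raise ValidationError(
            f"unknown rotation preset {config['rotation']['preset']!r}"
        )

    # (6) fit + joint orthomax per imputation
    stage("fit")
    models = []
    for t, cube in enumerate(cubes):
        model = tucker3_als(
            cube, ranks,
            n_starts=model_cfg["n_starts"], tol=model_cfg["tol"],
            max_iter=model_cfg["max_iter"], seed=model_cfg["seed"],
        )
        model = joint_orthomax(model, rot_weights)
        models.append(model)
        save_model(model, out / "models" / f"imputation_{t:02d}")

    # (7) generalized Procrustes pooling
    stage("pool")
    if len(models) >= 2:
        pooled = generalized_procrustes(models)
    else:
        pooled = PooledSolution(
            mean_model=models[0],
            element_sd={k: np.zeros_like(v) for k, v in
                        zip("ABCG", (*models[0].matrices, models[0].G))},
            per_dataset_congruence={
                n: np.ones((1, r)) for n, r in zip("ABC", ranks)
            },
            n_solutions=1, n_iter=0, converged=True,
        )
    save_model(pooled.mean_model, out / "pooled_model")
    for key, sd in pooled.element_sd.items():
        pd.DataFrame(sd.reshape(sd.shape[0], -1)).to_csv(
            out / "pooled_model" / f"{key}_sd.csv", index=False
        )

    # (8) fit percentages against each imputed dataset
    stage("fit-account")
    accounts = []
    het_fits = []
    total_fits = []
    for cube, state, comp in zip(cubes, states, imputations.completed):
        # evaluate the pooled (averaged) model on every imputed cube
        person_model = pooled.mean_model
        acc = total_fit_with_trend(person_model, state, comp.values)
        accounts.append(acc)
        het_fits.append(acc.heterogeneity_fit_pct)
        total_fits.append(acc.total_fit_pct)
    pd.DataFrame(
        {
            "imputation": range(len(accounts)),
            "heterogeneity_fit_pct": het_fits,
            "total_fit_pct": total_fits,
            "ss_trend": [a.ss_trend for a in accounts],
            "ss_model": [a.ss_model for a in accounts],
            "ss_residual": [a.ss_residual for a in accounts],
            "ss_total": [a.ss_total for a in accounts],
        }
    ).to_csv(out / "fit_accounts.csv", index=False)

    # split-half stability of the chosen complexity (first imputed cube)
    stage("stability")
    stab_cfg = config["stability"]
    stability = split_half_stability(
        imputations.completed[0], ranks,
        n_splits=stab_cfg["n_splits"], weights=rot_weights,
        seed=stab_cfg["seed"],
    )
    stability.to_frame().to_csv(out / "stability.csv", index=False)

    # (9) interpretation
    stage("interpret")
    ss_pre = float(np.sum(cubes[0] ** 2))  # I*J*K by construction
    ev = core_explained_variance(pooled, ss_pre)
    ev.to_csv(out / "core_ev.csv", index=False)
    traj = component_trajectories(pooled, states[0])
    traj.to_csv(out / "trajectories.csv", index=False)

    correlations = None
    if external is not None:
        # align each imputation's person scores to the pooled mean frame
        from .rotate import align_solution

        scores = [
            align_solution(m, pooled.mean_model).A for m in models
        ]
        corr_cfg = config["correlation"]
        correlations = external_correlations(
            scores, external.loc[selected.person_ids],
            method=corr_cfg["method"], alpha=corr_cfg["alpha"],
            benjamini_hochberg=corr_cfg["benjamini_hochberg"],
        )
        correlations.to_csv(out / "correlations.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config,
        "ranks": list(ranks),
        "n_persons": selected.n_persons,
        "mean_heterogeneity_fit_pct": float(np.mean(het_fits)),
        "sd_heterogeneity_fit_pct": float(np.std(het_fits)),
        "mean_total_fit_pct": float(np.mean(total_fits)),
        "sd_total_fit_pct": float(np.std(total_fits)),
        "min_split_half_congruence": stability.min_congruence,
        "elapsed_s": time.time() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        output_dir=out,
        selected=selected,
        selection_report=report,
        anova=pooled_anova,
        ranks=ranks,
        selection_trace=trace,
        pooled=pooled,
        fit_accounts=accounts,
        mean_heterogeneity_fit=float(np.mean(het_fits)),
        mean_total_fit=float(np.mean(total_fits)),
        stability=stability,
        correlations=correlations,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# publication-style table rendering
# ---------------------------------------------------------------------------

def render_tables(run_dir: str | Path, config: dict[str, Any] | None = None) -> str:
    """Render the run's artifacts as publication-style text tables.

    Pure function of the run directory: re-rendering produces identical
    output.  Bold-worthy entries (scores above the configured salience
    thresholds) are flagged with an asterisk.
    """
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise MissingArtifactError(f"{run_dir} does not contain a completed run")
    cfg = config["report"] if config and "report" in config else DEFAULT_CONFIG["report"]
    manifest = json.loads((run_dir / "manifest.json").read_text())
    parts: list[str] = []

    anova = pd.read_csv(run_dir / "anova.csv")
    parts.append("== variance decomposition (pooled across imputations) ==")
    parts.append(anova.round(3).to_string(index=False))

    model = load_model(run_dir / "pooled_model")
    b_sd = pd.read_csv(run_dir / "pooled_model" / "B_sd.csv").to_numpy()
    rows = []
    for j in range(model.B.shape[0]):
        row = {"item": j}
        for q in range(model.B.shape[1]):
            flag = "*" if abs(model.B[j, q]) >= cfg["symptom_threshold"] else ""
            row[f"comp{q + 1}"] = f"{model.B[j, q]:+.3f}{flag}"
            row[f"sd{q + 1}"] = f"{b_sd[j, q]:.3f}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    lead = np.argmax(np.abs(model.B), axis=1)
    frame = frame.iloc[np.lexsort((-np.max(np.abs(model.B), axis=1), lead))]
    parts.append("\n== symptom-mode component scores ==")
    parts.append(frame.to_string(index=False))

    c_sd = pd.read_csv(run_dir / "pooled_model" / "C_sd.csv").to_numpy()
    rows = []
    for k in range(model.C.shape[0]):
        row = {"time": k}
        for r in range(model.C.shape[1]):
            flag = "*" if abs(model.C[k, r]) >= cfg["time_threshold"] else ""
            row[f"comp{r + 1}"] = f"{model.C[k, r]:+.3f}{flag}"
            row[f"sd{r + 1}"] = f"{c_sd[k, r]:.3f}"
        rows.append(row)
    parts.append("\n== time-mode component scores ==")
    parts.append(pd.DataFrame(rows).to_string(index=False))

    ev = pd.read_csv(run_dir / "core_ev.csv")
    parts.append("\n== core array and explained variance ==")
    parts.append(ev.round(3).to_string(index=False))

    if (run_dir / "correlations.csv").exists():
        corr = pd.read_csv(run_dir / "correlations.csv")
        corr["flag"] = np.where(
            np.abs(corr["r"]) >= cfg["correlation_threshold"], "*", ""
        )
        parts.append("\n== external correlations of person components ==")
        parts.append(corr.round(3).to_string(index=False))

    parts.append(
        "\nfit: heterogeneity %.2f%% (sd %.3f), with general trend %.2f%% (sd %.3f)"
        % (
            manifest["mean_heterogeneity_fit_pct"],
            manifest["sd_heterogeneity_fit_pct"],
            manifest["mean_total_fit_pct"],
            manifest["sd_total_fit_pct"],
        )
    )
    text = "\n".join(parts) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
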