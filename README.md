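# threemode

Three-mode principal component analysis (Tucker3) of longitudinal
item-level symptom data.

## What problem this solves

Clinical symptom data are heterogeneous in three directions at once:
patients differ from each other, symptoms differ from each other, and
everything changes over time.  Classical tools decompose at most two of
these — factor analysis summarizes symptoms, latent class analysis
groups patients, growth models describe time — and the interactions
between the three sources go unseen.  When repeated questionnaire
assessments are arranged as a persons × items × time-points "data
cube" `x_ijk`, the Tucker3 model

    x_ijk  ≈  Σ_pqr  a_ip · b_jq · c_kr · g_pqr

summarizes all three modes simultaneously: orthonormal component
matrices `A` (persons), `B` (symptom items), `C` (time points) and a
small core array `G` whose element `g_pqr` measures how strongly
person component p expresses symptom component q with time course r.
The squared core elements partition the explained variance, so the
core is directly readable as an interaction map.

The package implements the full analysis workflow around that model
for cohort questionnaire data (the motivating scale: ~200 depression
patients × 21 items × 9 three-monthly assessments):

1. sample selection (minimum provided time points per person),
2. multiple imputation of missing item scores (bootstrap-EM
   multivariate normal with ridge shrinkage),
3. three-way ANOVA variance screening,
4. preprocessing — removal of the "general trend" (per-item mean
   trajectories) and equal-importance item normalization, invertibly,
5. model-complexity selection (generalized scree / convex hull plus
   cross-imputation stability),
6. Tucker3 fitting by alternating least squares with joint orthomax
   rotation of core and components,
7. generalized Procrustes pooling of the per-imputation solutions,
8. two fit percentages (heterogeneity-only, and total including the
   general trend),
9. interpretation: per-core-element explained variance, component
   trajectory curves, split-half stability, and correlations of person
   components with external baseline variables.

A synthetic-data generator with planted, exactly recoverable Tucker3
structure stands in for patient data, so the whole pipeline is
testable end to end without any download.

## Worked example

```python
import threemode as tm
from threemode.pipeline import load_config, run_pipeline

spec = tm.study_like_spec(seed=7)          # 219 x 21 x 9, planted (3,2,2),
synth = tm.generate_tucker3_dataset(spec)  # declining trend, 7.8% missing

cfg = load_config(overrides={
    "paths": {"output": "run7"},
    "imputation": {"m": 5, "max_em_iter": 30, "tol": 1e-4, "seed": 7},
    "model": {"ranks": "auto", "max_ranks": [4, 3, 3]},
    "stability": {"n_splits": 5, "seed": 7},
})
res = run_pipeline(cfg, dataset=synth.dataset, external=synth.external_table)
print(res.ranks, round(res.mean_heterogeneity_fit, 1),
      round(res.mean_total_fit, 1), round(res.stability.min_congruence, 3))
```

prints

```
(3, 2, 2) 26.7 63.8 0.986
```

The scree-plus-stability selection recovered the planted complexity
(3, 2, 2).  The pooled model explains 26.7% of the variance around the
general trend (the planted structure carries ≈28%; imputation of the
7.8% missing entries costs about a point) and 63.8% once the trend is
credited too.  Every symptom/time component reproduces across random
person halves with Tucker congruence ≥ 0.986.  The run directory
(`run7/`) holds every intermediate as CSV — selection report,
imputations, ANOVA table, scree grid, per-imputation and pooled
models, fit accounts, stability report, correlation table — plus a
manifest with all seeds.

The same pipeline is scriptable from the shell:

```
threemode simulate --out sim --seed 7
threemode run-all --config cfg.yaml --input sim/data_long.csv --external sim/external.csv
threemode report --config cfg.yaml
```

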