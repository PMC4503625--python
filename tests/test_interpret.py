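"""Core explained variance, trajectories and external correlations."""

import numpy as np
import pandas as pd
import pytest

import threemode as tm
from threemode.errors import ValidationError


@pytest.fixture(scope="module")
def fitted_small():
    spec = tm.SyntheticSpec(
        dims=(60, 8, 6), ranks=(2, 2, 2),
        core_pattern=[(0, 0, 0, 30.0), (1, 1, 1, 22.0)],
        noise_sd=0.5, seed=7,
    )
    synth = tm.generate_tucker3_dataset(spec)
    cube, state = tm.preprocess(synth.dataset)
    model = tm.tucker3_als(cube.values, (2, 2, 2))
    return synth, cube, state, model


class TestCoreExplainedVariance:
    def test_sums_to_heterogeneity_fit(self, fitted_small):
        _synth, cube, _state, model = fitted_small
        ss = float(np.sum(cube.values**2))
        table = tm.core_explained_variance(model, ss)
        assert table["ev_pct"].sum() == pytest.approx(model.fit_pct, abs=1e-6)

    def test_saturated_model_sums_to_100(self, rng):
        cube = rng.normal(size=(5, 4, 3))
        model = tm.tucker3_als(cube, (5, 4, 3))
        table = tm.core_explained_variance(model, float(np.sum(cube**2)))
        assert table["ev_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_planted_element_owns_model_ev(self):
        a, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((6, 2)))
        g = np.zeros((2, 2, 2))
        g[1, 0, 1] = 3.0
        model = tm.Tucker3Model(a, np.eye(2), np.eye(2), g, (2, 2, 2))
        table = tm.core_explained_variance(model, 100.0)
        nz = table[table["ev_pct"] > 0]
        assert len(nz) == 1
        row = nz.iloc[0]
        assert (row["person_component"], row["symptom_component"],
                row["time_component"]) == (1, 0, 1)
        assert row["ev_pct"] == pytest.approx(9.0)

    def test_zero_ss_rejected(self, fitted_small):
        with pytest.raises(ValidationError):
            tm.core_explained_variance(fitted_small[3], 0.0)


class TestTrajectories:
    def test_zero_core_flat_curves(self, fitted_small):
        model = fitted_small[3].copy()
        model.G[:] = 0.0
        frame = tm.component_trajectories(model)
        assert np.allclose(frame["value"], 0.0)

    def test_single_element_curve_proportional_to_time_component(self, fitted_small):
        model = fitted_small[3].copy()
        model.G[:] = 0.0
        model.G[0, 1, 1] = 2.5
        frame = tm.component_trajectories(model)
        curve = frame[
            (frame["person_component"] == 0) & (frame["symptom_component"] == 1)
        ].sort_values("time_index")["value"].to_numpy()
        np.testing.assert_allclose(curve, 2.5 * model.C[:, 1], atol=1e-12)

    def test_sign_convention_invariance(self, fitted_small):
        """Flipping a component column (compensated in the core) leaves
        every curve unchanged."""
        model = fitted_small[3]
        flipped = model.copy()
        flipped.C[:, 0] *= -1
        flipped.G[:, :, 0] *= -1
        f1 = tm.component_trajectories(model)
        f2 = tm.component_trajectories(flipped)
        np.testing.assert_allclose(f1["value"], f2["value"], atol=1e-12)

    def test_trend_context_rows_present(self, fitted_small):
        _synth, _cube, state, model = fitted_small
        frame = tm.component_trajectories(model, state)
        assert (frame["person_component"] == "trend").sum() == (
            model.G.shape[1] * model.C.shape[0]
        )


class TestExternalCorrelations:
    def test_self_correlation_is_one(self, fitted_small):
        model = fitted_small[3]
        ext = pd.DataFrame({"self": model.A[:, 0]})
        table = tm.external_correlations([model.A], ext)
        row = table[(table["component"] == 0) & (table["variable"] == "self")]
        # the pooled r passes through a clipped Fisher z, so it comes
        # back as 1 only to the clipping tolerance; the plain mean is exact
        assert row["r_mean"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert row["r"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_independent_noise_small_r(self, fitted_small):
        model = fitted_small[3]
        hits = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(size=model.A.shape[0])
            table = tm.external_correlations([model.A], pd.DataFrame({"x": noise}))
            # null bound at n=60: |r| < 2.58/sqrt(n) in ~99% of draws
            hits += np.all(np.abs(table["r"]) < 2.58 / np.sqrt(60))
        assert hits >= 18

    def test_pooling_reduces_to_single_dataset(self, fitted_small):
        model = fitted_small[3]
        rng = np.random.default_rng(1)
        ext = pd.DataFrame({"x": model.A[:, 0] + rng.normal(0, 1, model.A.shape[0])})
        single = tm.external_correlations([model.A], ext)
        repeated = tm.external_correlations([model.A] * 5, ext)
        np.testing.assert_allclose(repeated["r"], single["r"], atol=1e-12)
        assert np.all(repeated["r_sd"] == 0.0)

    def test_skewed_variable_gets_spearman(self, fitted_small):
        model = fitted_small[3]
        rng = np.random.default_rng(2)
        ext = pd.DataFrame({"skew": np.exp(rng.normal(0, 1.5, model.A.shape[0]))})
        table = tm.external_correlations([model.A], ext)
        assert set(table["method"]) == {"spearman"}

    def test_constant_variable_rejected(self, fitted_small):
        model = fitted_small[3]
        with pytest.raises(ValidationError):
            tm.external_correlations(
                [model.A], pd.DataFrame({"c": np.ones(model.A.shape[0])})
            )

    def test_benjamini_hochberg_adds_adjusted_column(self, fitted_small):
        model = fitted_small[3]
        rng = np.random.default_rng(3)
        ext = pd.DataFrame(
            {f"v{i}": rng.normal(size=model.A.shape[0]) for i in range(4)}
        )
        table = tm.external_correlations([model.A], ext, benjamini_hochberg=True)
        assert "p_adjusted" in table.columns
        assert np.all(table["p_adjusted"] >= table["p"] - 1e-12)
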