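"""Chained-equations engine: terms, proper draws, cycles, full imputation."""

import numpy as np
import pytest

from missaux import (
    FCSConfig,
    ImputationModelSpec,
    SampleSizeError,
    ScenarioConfig,
    SingularDesignError,
    TermSpec,
    build_design,
    fcs_cycle,
    fcs_impute,
    generate_complete,
    initial_fill,
    make_observed,
    norm_draw_impute,
)


class TestTerms:
    def test_identity_power_reproduces_column(self):
        design = build_design({"x": np.array([1.0, 2.0, 3.0])}, (TermSpec(("x",)),))
        np.testing.assert_array_equal(design[:, 0], np.ones(3))
        np.testing.assert_array_equal(design[:, 1], [1.0, 2.0, 3.0])

    def test_cubed_and_product_terms(self):
        table = {"z": np.array([2.0]), "edu": np.array([3.0])}
        cube = TermSpec.parse("z^3")
        prod = TermSpec.parse("z^3:edu")
        assert cube.evaluate(table)[0] == 8.0
        assert prod.evaluate(table)[0] == 24.0
        design = build_design(table, (cube, prod))
        np.testing.assert_array_equal(design[0], [1.0, 8.0, 24.0])

    def test_unknown_variable_and_missing_values_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            build_design({"x": np.ones(2)}, (TermSpec(("nope",)),))
        with pytest.raises(ValueError, match="missing values"):
            build_design({"x": np.array([1.0, np.nan])}, (TermSpec(("x",)),))

    def test_target_cannot_predict_itself(self):
        with pytest.raises(ValueError, match="own predictors"):
            ImputationModelSpec("y", (TermSpec(("y",)),))

    def test_invalid_term_specs_rejected(self):
        with pytest.raises(ValueError):
            TermSpec(())
        with pytest.raises(ValueError):
            TermSpec(("x",), (0,))


class TestNormDrawImpute:
    def test_degenerate_posterior_returns_exact_fit(self, rng):
        x = np.arange(10.0)
        design = np.column_stack([np.ones(10), x])
        y = 2.0 + 3.0 * x  # zero residual variance
        design_mis = np.array([[1.0, 20.0], [1.0, -4.0]])
        out = norm_draw_impute(y, design, design_mis, rng)
        np.testing.assert_allclose(out, [62.0, -10.0], atol=1e-8)

    def test_empty_missing_design_gives_empty_output(self, rng):
        design = np.column_stack([np.ones(10), np.arange(10.0)])
        out = norm_draw_impute(np.arange(10.0), design, np.empty((0, 2)), rng)
        assert out.shape == (0,)

    def test_posterior_concentrates_on_conditional_mean(self):
        """At x=0 the imputation distribution centers on the true intercept 0."""
        rng = np.random.default_rng(77)
        n = 50_000
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n) * np.sqrt(1 - 0.36)
        design = np.column_stack([np.ones(n), x])
        at_zero = np.array([[1.0, 0.0]])
        draws = [norm_draw_impute(y, design, at_zero, rng)[0] for _ in range(200)]
        assert np.mean(draws) == pytest.approx(0.0, abs=0.02 + 3 * np.sqrt(0.64 / 200))

    def test_rank_deficient_design_names_collinear_columns(self, rng):
        x = np.arange(10.0)
        design = np.column_stack([np.ones(10), x, 2 * x])
        with pytest.raises(SingularDesignError, match="rank deficient"):
            norm_draw_impute(x, design, design[:2], rng, ("intercept", "x", "x2"))

    def test_too_few_observed_rows_rejected(self, rng):
        design = np.column_stack([np.ones(3), np.arange(3.0)])
        with pytest.raises(SampleSizeError):
            norm_draw_impute(np.arange(3.0), design, design, rng)


class TestInitialFill:
    def test_no_missing_cells_returns_input_unchanged(self, rng):
        cols = {"y": np.array([1.0, 2.0]), "x": np.array([3.0, 4.0])}
        out = initial_fill(cols, {"y": np.zeros(2, dtype=int)}, rng)
        np.testing.assert_array_equal(out["y"], cols["y"])

    def test_single_observed_value_is_forced_draw(self, rng):
        cols = {"y": np.array([5.0, np.nan, np.nan])}
        out = initial_fill(cols, {"y": np.array([0, 1, 1])}, rng)
        np.testing.assert_array_equal(out["y"], [5.0, 5.0, 5.0])

    def test_fill_distribution_matches_observed_distribution(self):
        rng = np.random.default_rng(42)
        n = 100_000
        y = rng.standard_normal(n)
        ind = (rng.uniform(size=n) < 0.5).astype(int)
        y_obs = y.copy()
        y_obs[ind == 1] = np.nan
        out = initial_fill({"y": y_obs}, {"y": ind}, rng)
        filled = out["y"][ind == 1]
        observed = y[ind == 0]
        assert abs(filled.mean() - observed.mean()) < 0.02 * observed.std()

    def test_unimputable_variable_raises(self, rng):
        with pytest.raises(ValueError, match="no observed values"):
            initial_fill({"y": np.array([np.nan, np.nan])}, {"y": np.array([1, 1])}, rng)


def _observed_columns(cfg_kwargs, seed=13):
    cfg = ScenarioConfig(**cfg_kwargs)
    complete = generate_complete(cfg, np.random.default_rng(seed))
    obs = make_observed(complete, np.random.default_rng(seed + 1))
    return obs


class TestFcsCycle:
    def test_complete_table_passes_through(self, rng):
        table = {"y": np.arange(10.0), "x": np.arange(10.0) * 2}
        spec = ImputationModelSpec("y", (TermSpec(("x",)),))
        before = {k: v.copy() for k, v in table.items()}
        fcs_cycle(table, (spec,), {"y": np.zeros(10, dtype=int)}, rng)
        np.testing.assert_array_equal(table["y"], before["y"])

    def test_only_incomplete_targets_updated(self, rng):
        obs = _observed_columns(dict(n=500, outcome_mech=1, aux_mech=2, rho_yz=0.7, pi_z=0.3, seed=13))
        table = initial_fill(obs.columns(), obs.indicators(), rng)
        x_before, w_before = table["x"].copy(), table["w"].copy()
        y_obs_before = table["y"][obs.m_y == 0].copy()
        specs = (
            ImputationModelSpec("y", (TermSpec(("x",)), TermSpec(("z",)))),
            ImputationModelSpec("z", (TermSpec(("y",)), TermSpec(("x",)))),
        )
        y_mis_before = table["y"][obs.m_y == 1].copy()
        z_mis_before = table["z"][obs.m_z == 1].copy()
        fcs_cycle(table, specs, obs.indicators(), rng)
        np.testing.assert_array_equal(table["x"], x_before)
        np.testing.assert_array_equal(table["w"], w_before)
        np.testing.assert_array_equal(table["y"][obs.m_y == 0], y_obs_before)
        assert not np.array_equal(table["y"][obs.m_y == 1], y_mis_before)
        assert not np.array_equal(table["z"][obs.m_z == 1], z_mis_before)


class TestFcsImpute:
    def test_complete_input_yields_identical_copies(self, rng):
        cols = {"y": np.arange(20.0), "x": np.arange(20.0) % 5}
        stack = fcs_impute(
            cols,
            {"y": np.zeros(20, dtype=int)},
            (ImputationModelSpec("y", (TermSpec(("x",)),)),),
            FCSConfig(m=3, burnin=2),
            rng,
        )
        assert stack.m == 3
        for table in stack.tables:
            np.testing.assert_array_equal(table["y"], cols["y"])

    def test_observed_cells_preserved_across_all_chains(self, small_fcs):
        obs = _observed_columns(dict(n=400, outcome_mech=1, aux_mech=2, rho_yz=0.7, pi_z=0.4, seed=17))
        specs = (
            ImputationModelSpec("y", (TermSpec(("x",)), TermSpec(("z",)))),
            ImputationModelSpec("z", (TermSpec(("y",)), TermSpec(("x",)))),
        )
        stack = fcs_impute(
            obs.columns(), obs.indicators(), specs, small_fcs, np.random.default_rng(0)
        )
        for table in stack.tables:
            np.testing.assert_array_equal(table["y"][obs.m_y == 0], obs.y[obs.m_y == 0])
            np.testing.assert_array_equal(table["z"][obs.m_z == 0], obs.z[obs.m_z == 0])
            assert not np.isnan(table["y"]).any()
            assert not np.isnan(table["z"]).any()

    def test_same_seed_gives_bit_identical_stack(self, small_fcs):
        obs = _observed_columns(dict(n=300, outcome_mech=2, aux_mech=3, rho_yz=0.5, pi_z=0.3, seed=19))
        specs = (
            ImputationModelSpec("y", (TermSpec(("x",)), TermSpec(("z",)))),
            ImputationModelSpec("z", (TermSpec(("y",)), TermSpec(("x",)), TermSpec(("w",)))),
        )
        a = fcs_impute(obs.columns(), obs.indicators(), specs, small_fcs, np.random.default_rng(99))
        b = fcs_impute(obs.columns(), obs.indicators(), specs, small_fcs, np.random.default_rng(99))
        for ta, tb in zip(a.tables, b.tables):
            for col in ta:
                np.testing.assert_array_equal(ta[col], tb[col])

    def test_imputed_variance_matches_bivariate_conditional_oracle(self):
        """With only y missing under p(y|x), imputations must reproduce the
        closed-form conditional variance 1 - rho^2 of the bivariate normal."""
        rho = 0.6
        rng = np.random.default_rng(314)
        n = 100_000
        x = rng.standard_normal(n)
        y = rho * x + rng.standard_normal(n) * np.sqrt(1 - rho**2)
        ind = (rng.uniform(size=n) < 0.5).astype(np.int8)
        y_obs = y.copy()
        y_obs[ind == 1] = np.nan
        stack = fcs_impute(
            {"y": y_obs, "x": x},
            {"y": ind},
            (ImputationModelSpec("y", (TermSpec(("x",)),)),),
            FCSConfig(m=2, burnin=1),
            rng,
        )
        for table in stack.tables:
            imputed = table["y"][ind == 1]
            x_mis = x[ind == 1]
            resid = imputed - rho * x_mis
            assert resid.var() == pytest.approx(1 - rho**2, rel=0.02)

    def test_missing_variable_without_model_rejected(self, small_fcs, rng):
        obs = _observed_columns(dict(n=300, outcome_mech=1, aux_mech=2, pi_z=0.3, seed=23))
        with pytest.raises(ValueError, match="without an imputation model"):
            fcs_impute(
                obs.columns(),
                obs.indicators(),
                (ImputationModelSpec("y", (TermSpec(("x",)),)),),
                small_fcs,
                rng,
            )

    def test_visit_order_must_name_modelled_targets(self, rng):
        obs = _observed_columns(dict(n=300, outcome_mech=1, aux_mech=2, pi_z=0.3, seed=29))
        specs = (
            ImputationModelSpec("y", (TermSpec(("x",)), TermSpec(("z",)))),
            ImputationModelSpec("z", (TermSpec(("y",)), TermSpec(("x",)))),
        )
        cfg = FCSConfig(m=2, burnin=1, visit_order=("z", "q"))
        with pytest.raises(ValueError, match="visit_order"):
            fcs_impute(obs.columns(), obs.indicators(), specs, cfg, rng)
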