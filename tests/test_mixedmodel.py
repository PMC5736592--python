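from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from socisol.mixedmodel import (
    MCMCConfig,
    MixedModelSpec,
    anova_repeatability,
    gibbs_fit,
    interaction_screen,
    pmcmc,
    potential_scale_reduction,
    variance_proportions,
)

from _oracles import one_way_data

FAST = MCMCConfig(n_iterations=3_000, burn_in=500, thin=5, seed=1)


def one_way_frame(y, groups):
    return pd.DataFrame({"y": y, "animal": groups})


class TestGibbsSampler:
    def test_intercept_only_matches_sample_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(3.0, 1.0, 200)
        df = pd.DataFrame({"y": y})
        fit = gibbs_fit(df, MixedModelSpec(response="y"), FAST)
        mean = fit.fixed_effects.set_index("term").loc["(Intercept)", "mean"]
        assert mean == pytest.approx(y.mean(), abs=3 * y.std() / np.sqrt(len(y)))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        y, g = one_way_data(rng, 20, 4, 0.4)
        df = one_way_frame(y, g)
        spec = MixedModelSpec(response="y", random_effects=["animal"])
        f1 = gibbs_fit(df, spec, FAST)
        f2 = gibbs_fit(df, spec, FAST)
        assert np.array_equal(f1.beta_draws, f2.beta_draws)
        assert np.array_equal(f1.sigma2_draws["animal"], f2.sigma2_draws["animal"])

    def test_no_random_effects_matches_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.5, n).astype(float)
        y = 1.0 + 0.5 * x1 - 0.8 * x2 + rng.normal(0, 0.7, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = gibbs_fit(df, MixedModelSpec(response="y", fixed_effects=["x1", "x2"]), FAST)
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        se = np.sqrt(np.diag(ols.cov_params()))
        got = fit.fixed_effects["mean"].to_numpy()
        assert np.all(np.abs(got - ols.params) < 0.5 * se + 0.02)

    def test_single_level_factor_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "y": rng.normal(size=50),
            "animal": [f"a{k % 10}" for k in range(50)],
            "grp": ["only"] * 50,
        })
        spec = MixedModelSpec(response="y", random_effects=["animal", "grp"])
        with pytest.warns(UserWarning, match="single level"):
            fit = gibbs_fit(df, spec, FAST)
        assert fit.dropped_components == ["grp"]
        assert set(fit.sigma2_draws) == {"animal", "residual"}

    def test_non_finite_response_raises(self):
        df = pd.DataFrame({"y": [1.0, np.inf, 2.0]})
        with pytest.raises(ValueError, match="non-finite"):
            gibbs_fit(df, MixedModelSpec(response="y"), FAST)

    def test_missing_responses_dropped_and_counted(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"y": rng.normal(size=30)})
        df.loc[:4, "y"] = np.nan
        fit = gibbs_fit(df, MixedModelSpec(response="y"), FAST)
        assert fit.n_obs == 25
        assert fit.n_dropped == 5

    def test_sex_subsets_select_rows(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "y": rng.normal(size=40),
            "sex": ["F"] * 25 + ["M"] * 15,
        })
        fit = gibbs_fit(
            df, MixedModelSpec(response="y", subset="males_only"), FAST
        )
        assert fit.n_obs == 15


class TestPosteriorSummaries:
    def test_pmcmc_hand_values(self):
        assert pmcmc(np.array([-1.0, 1.0, 2.0, 3.0])) == pytest.approx(0.5)
        assert pmcmc(np.ones(1000)) == pytest.approx(0.001)
        sym = np.concatenate([np.ones(500), -np.ones(500)])
        assert pmcmc(sym) == pytest.approx(1.0)

    def test_proportions_arithmetic(self):
        n = 600
        draws = {
            "a": np.full(n, 2.0), "b": np.full(n, 1.0),
            "c": np.full(n, 1.0), "residual": np.full(n, 1e-12),
        }
        props = variance_proportions(draws).set_index("component")["mean"]
        assert props["a"] == pytest.approx(0.5, abs=1e-9)
        assert props["b"] == pytest.approx(0.25, abs=1e-9)
        assert props["c"] == pytest.approx(0.25, abs=1e-9)

    def test_zero_animal_variance_gives_zero_repeatability(self):
        n = 600
        draws = {"animal": np.full(n, 0.0), "residual": np.full(n, 1.0)}
        props = variance_proportions(draws).set_index("component")
        assert props.loc["animal", "mean"] == 0.0

    def test_non_robust_flag(self):
        # mean proportion 0.195 but lower credible limit essentially zero
        n = 1000
        a = np.concatenate([np.full(950, 0.2052631), np.full(50, 1e-7)])
        draws = {"animal": a, "residual": 1.0 - a}
        props = variance_proportions(draws).set_index("component")
        assert props.loc["animal", "mean"] == pytest.approx(0.195, abs=0.01)
        assert bool(props.loc["animal", "non_robust"])

    def test_drawwise_proportions_sum_to_one(self):
        rng = np.random.default_rng(8)
        y, g = one_way_data(rng, 30, 5, 0.3)
        fit = gibbs_fit(
            one_way_frame(y, g),
            MixedModelSpec(response="y", random_effects=["animal"]),
            FAST,
        )
        mat = np.column_stack(list(fit.sigma2_draws.values()))
        props = mat / mat.sum(axis=1, keepdims=True)
        assert np.allclose(props.sum(axis=1), 1.0)


class TestDiagnostics:
    def test_two_chain_rhat_below_threshold_on_test_fit(self):
        rng = np.random.default_rng(9)
        y, g = one_way_data(rng, 40, 6, 0.4)
        df = one_way_frame(y, g)
        spec = MixedModelSpec(response="y", random_effects=["animal"])
        chains = []
        for seed in (101, 202):
            cfg = MCMCConfig(n_iterations=4_000, burn_in=1_000, thin=3, seed=seed)
            chains.append(gibbs_fit(df, spec, cfg).sigma2_draws["animal"])
        assert potential_scale_reduction(chains) < 1.1

    def test_rhat_detects_disagreement(self):
        rng = np.random.default_rng(10)
        c1 = rng.normal(0, 1, 500)
        c2 = rng.normal(5, 1, 500)
        assert potential_scale_reduction([c1, c2]) > 1.5


class TestInteractionScreen:
    def test_no_fixed_effects_unchanged(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"y": rng.normal(size=40)})
        spec = MixedModelSpec(response="y")
        assert interaction_screen(df, spec, FAST).fixed_effects == []

    def test_true_interaction_retained_null_dropped(self):
        rng = np.random.default_rng(12)
        n = 400
        age = rng.uniform(6, 25, n)
        sex = rng.binomial(1, 0.5, n).astype(float)
        x = rng.normal(size=n)
        # age x sex interacts; x does not
        y = 0.5 * sex + 0.05 * age * sex + rng.normal(0, 0.5, n)
        df = pd.DataFrame({
            "y": y, "age": age, "sex": np.where(sex > 0, "M", "F"), "x": x,
        })
        spec = MixedModelSpec(response="y", fixed_effects=["age", "sex", "x"])
        out = interaction_screen(df, spec, FAST)
        assert "age:sex" in out.fixed_effects
        assert "age:x" not in out.fixed_effects

    def test_interaction_term_codes_product(self):
        rng = np.random.default_rng(13)
        n = 500
        sex = rng.binomial(1, 0.5, n).astype(float)
        rank = rng.binomial(1, 0.5, n).astype(float)
        y = 1.0 * sex * rank + rng.normal(0, 0.3, n)
        df = pd.DataFrame({
            "y": y,
            "sex": np.where(sex > 0, "M", "F"),
            "rank_class": np.where(rank > 0, "high", "low"),
        })
        spec = MixedModelSpec(
            response="y", fixed_effects=["sex", "rank_class", "sex:rank_class"]
        )
        fit = gibbs_fit(df, spec, FAST)
        est = fit.fixed_effects.set_index("term").loc["sex:rank_class", "mean"]
        assert est == pytest.approx(1.0, abs=0.15)


class TestAnovaRepeatability:
    def test_balanced_closed_form(self):
        # two groups, known sums of squares
        y = np.array([0.0, 2.0, 10.0, 12.0])
        g = np.array(["a", "a", "b", "b"])
        # MS_A = 100, MS_W = 2, n0 = 2 -> s2a = 49, R = 49/51
        assert anova_repeatability(y, g) == pytest.approx(49 / 51)

    def test_no_between_variance_truncates_to_zero(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=200)
        g = np.repeat([f"g{k}" for k in range(40)], 5)
        assert 0.0 <= anova_repeatability(y, g) < 0.15
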