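import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from coralsieve import fitness
from coralsieve.synthetic_data import SimulationConfig, generate_transplant_data
from oracles import gh_marginal_loglik_binomial, sd_of_colony_proportions


def frame(rows):
    defaults = {"initial_weight": 10.0, "final_weight": np.nan,
                "branch_count": np.nan, "growth": np.nan}
    out = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.update(r)
        d.setdefault("fragment_id", f"F{i}")
        out.append(d)
    return pd.DataFrame(out)


class TestProportionalSurvival:
    def test_hand_arithmetic_with_missing(self):
        rows = (
            [{"colony_id": "C1", "origin": "MV", "location": "MV",
              "crate_id": "MV1", "fate": "alive"}] * 9
            + [{"colony_id": "C1", "origin": "MV", "location": "MV",
                "crate_id": "MV1", "fate": "dead"}] * 2
            + [{"colony_id": "C1", "origin": "MV", "location": "MV",
                "crate_id": "MV1", "fate": "missing"}]
        )
        props = fitness.colony_proportional_survival(frame(rows))
        assert props["C1"] == pytest.approx(9 / 11)

    def test_all_alive(self):
        rows = [{"colony_id": "C1", "origin": "HV", "location": "HV",
                 "crate_id": "HV1", "fate": "alive"}] * 4
        assert fitness.colony_proportional_survival(frame(rows))["C1"] == 1.0

    def test_all_missing_colony_flagged_nan(self):
        rows = [
            {"colony_id": "C1", "origin": "HV", "location": "HV",
             "crate_id": "HV1", "fate": "missing"},
            {"colony_id": "C2", "origin": "HV", "location": "HV",
             "crate_id": "HV1", "fate": "alive"},
        ]
        props = fitness.colony_proportional_survival(frame(rows))
        assert np.isnan(props["C1"]) and props["C2"] == 1.0


class TestCrateNormalizedScores:
    def test_two_crate_hand_ols(self):
        # crate means 0.5 and 1.0; colony X alive in both -> (0.5 + 0)/2
        rows = [
            {"colony_id": "X", "origin": "MV", "location": "MV",
             "crate_id": "A", "fate": "alive"},
            {"colony_id": "Y", "origin": "MV", "location": "MV",
             "crate_id": "A", "fate": "dead"},
            {"colony_id": "X", "origin": "MV", "location": "MV",
             "crate_id": "B", "fate": "alive"},
            {"colony_id": "Y", "origin": "MV", "location": "MV",
             "crate_id": "B", "fate": "alive"},
        ]
        scores = fitness.crate_normalized_scores(frame(rows))
        x = scores[scores["colony_id"] == "X"].iloc[0]
        assert x["survival_score"] == pytest.approx(0.25)

    def test_weighted_mean_zero_within_pool(self, default_fragments):
        scores = fitness.crate_normalized_scores(default_fragments)
        for _, pool in scores.groupby("location"):
            w = pool["n_fragments_survival"]
            assert np.average(pool["survival_score"], weights=w) == pytest.approx(0, abs=1e-10)

    def test_translation_invariance_of_growth_scores(self, default_fragments):
        scores = fitness.crate_normalized_scores(default_fragments)
        shifted = default_fragments.copy()
        shifted["growth"] = shifted["growth"] + 500.0
        scores2 = fitness.crate_normalized_scores(shifted)
        np.testing.assert_allclose(
            scores["growth_score"].to_numpy(),
            scores2["growth_score"].to_numpy(),
            atol=1e-9,
        )


class TestGLMM:
    def test_empty_random_spec_equals_glm(self, default_fragments):
        fit = fitness.fit_glmm(default_fragments, random=(), family="binomial",
                               n_restarts=1)
        df = fitness.tracked(default_fragments).assign(
            alive=lambda d: (d.fate == "alive").astype(float))
        X, _ = fitness._design_matrix(df, fitness.FULL_FIXED)
        glm = sm.GLM(df["alive"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-5)

    def test_random_effects_never_hurt_loglik(self, default_fragments):
        glmm = fitness.fit_glmm(default_fragments, family="binomial", n_restarts=2)
        glm = fitness.fit_glmm(default_fragments, random=(), family="binomial",
                               n_restarts=1)
        assert glmm.loglik >= glm.loglik - 1e-6

    def test_aic_definition(self, default_fragments):
        fit = fitness.fit_glmm(default_fragments, family="binomial", n_restarts=1)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.n_params == 4 + 2  # full fixed structure + two variances

    def test_laplace_matches_gauss_hermite_single_factor(self):
        cfg = SimulationConfig(crate_sd=0.0, loss_rate=0.0, seed=7)
        frags, _ = generate_transplant_data(cfg)
        df = fitness.tracked(frags).assign(
            alive=lambda d: (d.fate == "alive").astype(float))
        y = df["alive"].to_numpy()
        X, _ = fitness._design_matrix(df, ("origin",))
        codes = pd.factorize(df["colony_id"], sort=True)[0]
        Zs = fitness._random_design(df, ("colony_id",))
        for beta, sd in [(np.array([1.5, -1.0]), 0.8), (np.array([0.0, 0.0]), 0.3)]:
            lap = -fitness._binomial_laplace_loglik(
                np.concatenate([beta, [np.log(sd)]]), y, X, Zs, [Zs[0].shape[1]]
            )
            gh = gh_marginal_loglik_binomial(beta, sd, y, X, codes)
            assert lap == pytest.approx(gh, abs=0.5)

    def test_gaussian_fit_reasonable(self, default_fragments):
        fit = fitness.fit_glmm(default_fragments, family="gaussian",
                               outcome="growth", n_restarts=1)
        assert fit.converged
        assert fit.resid_sd > 0
        assert all(sd >= 0 for sd in fit.random_sd.values())
        # location raises growth by design in the default simulation
        assert fit.coef["locationMV"] > 0

    def test_unknown_family_rejected(self, default_fragments):
        with pytest.raises(ValueError):
            fitness.fit_glmm(default_fragments, family="poisson")


class TestStepwise:
    def test_growth_retains_location_only(self):
        cfg = SimulationConfig(seed=31)
        frags, _ = generate_transplant_data(cfg)
        fit, trail = fitness.stepwise_select(frags, family="gaussian", outcome="growth")
        assert "location" in fit.fixed_terms
        assert "origin" not in fit.fixed_terms
        assert trail[0][0] == fitness.FULL_FIXED
        # AIC improves (or stays) along the accepted trail
        aics = [a for _, a in trail]
        assert all(b <= a for a, b in zip(aics, aics[1:]))

    def test_survival_retains_origin(self):
        cfg = SimulationConfig(seed=17)
        frags, _ = generate_transplant_data(cfg)
        fit, _ = fitness.stepwise_select(frags, family="binomial")
        assert "origin" in fit.fixed_terms

    def test_pure_noise_selects_intercept_majority(self):
        hits = 0
        n_rep = 7
        for rep in range(n_rep):
            cfg = SimulationConfig(
                survival_logit_mean_by_origin={"HV": 0.5, "MV": 0.5},
                survival_logit_sd_by_origin={"HV": 0.4, "MV": 0.4},
                location_growth_means={"HV": 250.0, "MV": 250.0},
                seed=600 + rep,
            )
            frags, _ = generate_transplant_data(cfg)
            fit, _ = fitness.stepwise_select(frags, family="binomial")
            hits += fit.fixed_terms == ()
        assert hits > n_rep / 2


class TestReactionNorms:
    def test_intercept_only_gives_identical_cells(self):
        fit = fitness.MixedModelFit(
            family="binomial", fixed_terms=(), random_terms=(),
            coef={"(Intercept)": 0.3}, coef_se={"(Intercept)": 0.1},
            coef_cov=np.array([[0.01]]), random_sd={}, resid_sd=None,
            loglik=0.0, n_obs=10, converged=True,
        )
        norms = fitness.reaction_norms(fit)
        assert norms["mean"].nunique() == 1

    def test_binomial_ci_within_unit_interval(self, default_fragments):
        fit = fitness.fit_glmm(default_fragments, family="binomial", n_restarts=1)
        norms = fitness.reaction_norms(fit)
        assert ((norms[["mean", "ci_low", "ci_high"]] > 0)
                & (norms[["mean", "ci_low", "ci_high"]] < 1)).all().all()
        assert (norms["ci_low"] <= norms["mean"]).all()
        assert (norms["mean"] <= norms["ci_high"]).all()


class TestPermutationTest:
    def test_all_alive_degenerate(self):
        rows = [
            {"colony_id": c, "origin": "HV", "location": loc,
             "crate_id": f"{loc}1", "fate": "alive", "fragment_id": f"{loc}-{c}-{i}"}
            for c in ("C1", "C2", "C3")
            for i, loc in enumerate(("HV", "MV"))
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            res = fitness.survival_sd_permutation_test(frame(rows), "HV", n_perm=100)
        assert res.observed_sd == 0.0
        assert res.p_one_sided == 1.0

    def test_observed_matches_naive_sd(self, default_fragments):
        res = fitness.survival_sd_permutation_test(
            default_fragments, "MV", n_perm=10, seed=0)
        mv = default_fragments[default_fragments["origin"] == "MV"]
        assert res.observed_sd == pytest.approx(sd_of_colony_proportions(mv))

    def test_invariant_to_row_order(self, default_fragments):
        res1 = fitness.survival_sd_permutation_test(
            default_fragments, "MV", n_perm=500, seed=3)
        shuffled = default_fragments.sample(frac=1.0, random_state=9)
        res2 = fitness.survival_sd_permutation_test(shuffled, "MV", n_perm=500, seed=3)
        assert res1.p_one_sided == res2.p_one_sided
        np.testing.assert_array_equal(res1.null_sds, res2.null_sds)

    def test_invariant_to_colony_relabel(self, default_fragments):
        relabeled = default_fragments.copy()
        relabeled["colony_id"] = "X" + relabeled["colony_id"]
        res1 = fitness.survival_sd_permutation_test(
            default_fragments, "MV", n_perm=500, seed=3)
        res2 = fitness.survival_sd_permutation_test(relabeled, "MV", n_perm=500, seed=3)
        assert res1.p_one_sided == res2.p_one_sided

    def test_statistic_zero_iff_proportions_equal(self):
        rows = [
            {"colony_id": c, "origin": "MV", "location": "MV",
             "crate_id": "MV1", "fate": f, "fragment_id": f"{c}-{f}-{i}"}
            for c in ("C1", "C2")
            for i, f in enumerate(("alive", "dead"))
        ]
        res = fitness.survival_sd_permutation_test(frame(rows), "MV", n_perm=50)
        assert res.observed_sd == 0.0

    def test_needs_two_colonies(self):
        rows = [{"colony_id": "C1", "origin": "MV", "location": "MV",
                 "crate_id": "MV1", "fate": "alive"}] * 3
        with pytest.raises(ValueError):
            fitness.survival_sd_permutation_test(frame(rows), "MV")

    def test_null_sds_length(self, default_fragments):
        res = fitness.survival_sd_permutation_test(
            default_fragments, "HV", n_perm=321, seed=1)
        assert len(res.null_sds) == 321
        assert 0.0 <= res.p_one_sided <= 1.0


class TestSensitivity:
    def test_identity_perturbation(self, default_fragments):
        base = fitness.survival_sd_permutation_test(
            default_fragments, "MV", n_perm=2000, seed=5)
        frac = fitness.sensitivity_permutations(
            default_fragments, "drop_worst_k", k=0, n_outer=3, n_perm=2000, seed=5)
        assert frac == float(base.p_one_sided < 0.05)

    def test_k_too_large_rejected(self, default_fragments):
        with pytest.raises(ValueError):
            fitness.sensitivity_permutations(
                default_fragments, "drop_worst_k", k=13, n_outer=1)

    def test_unknown_mode_rejected(self, default_fragments):
        with pytest.raises(ValueError):
            fitness.sensitivity_permutations(default_fragments, "bootstrap")

    def test_match_n_runs(self, default_fragments):
        frac = fitness.sensitivity_permutations(
            default_fragments, "match_n", n_outer=4, n_perm=400, seed=2)
        assert 0.0 <= frac <= 1.0


class TestTradeoff:
    @staticmethod
    def _scores(xs, ys, origins=None):
        origins = origins or ["MV"] * len(xs)
        rows = []
        for i, (x, y, o) in enumerate(zip(xs, ys, origins)):
            rows.append({"colony_id": f"C{i}", "origin": o, "location": "HV",
                         "survival_score": x, "growth_score": np.nan})
            rows.append({"colony_id": f"C{i}", "origin": o, "location": "MV",
                         "survival_score": np.nan, "growth_score": y})
        return pd.DataFrame(rows)

    def test_colinear_toy(self):
        xs = [0.1, 0.2, 0.3, 0.5]
        ys = [-2 * x for x in xs]
        res = fitness.tradeoff_regression(self._scores(xs, ys))
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-2.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fitness.tradeoff_regression(self._scores([0.1, 0.2], [1.0, 2.0]))

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            fitness.tradeoff_regression(self._scores([0.2] * 4, [1, 2, 3, 4]))

    def test_leverage_trail_has_one_row_per_colony(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(size=10)
        ys = -xs + rng.normal(0, 0.5, size=10)
        res = fitness.tradeoff_regression(self._scores(list(xs), list(ys)))
        assert len(res.leverage_trail) == 10
        assert set(res.leverage_trail.columns) >= {"left_out", "slope", "p_value"}

    def test_planted_negative_correlation_recovers_sign(self):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = SimulationConfig(seed=900 + rep)
            frags, _ = generate_transplant_data(cfg)
            scores = fitness.crate_normalized_scores(frags)
            res = fitness.tradeoff_regression(scores)
            hits += res.slope < 0
        assert hits >= 0.75 * n_rep
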