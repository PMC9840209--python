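"""Piecewise SEM: scaling, mixed-model components, d-separation, effects."""

import math

import numpy as np
import pandas as pd
import pytest

import phylograd as pg
from phylograd.sem import DSepClaim, PathModel, _gaussian_reml


def _balanced_fui_frame(n_rows=120):
    fui = np.tile([1, 2, 3], n_rows // 3)
    return pd.DataFrame({"FUI": fui, "other": np.arange(n_rows, dtype=float)})


class TestScaleVariables:
    def test_balanced_ordinal_closed_form(self):
        # FUI in {1,2,3} replicated 40x: sd with the n-1 denominator over the
        # 120-row design is sqrt(80/119), so scaled values are +-1.219631, 0
        out = pg.scale_variables(_balanced_fui_frame(), ["FUI"])
        vals = sorted(out["FUI"].unique())
        expected = 1.0 / math.sqrt(80.0 / 119.0)
        assert vals[0] == pytest.approx(-expected, abs=1e-6)
        assert vals[1] == pytest.approx(0.0, abs=1e-12)
        assert vals[2] == pytest.approx(expected, abs=1e-6)

    def test_idempotent_on_scaled_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        once = pg.scale_variables(df, ["x"])
        twice = pg.scale_variables(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_constant_column_raises_naming_it(self):
        df = pd.DataFrame({"flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            pg.scale_variables(df, ["flat"])


class TestFitComponent:
    def test_single_group_gaussian_equals_ols(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=40),
                           "z": rng.normal(size=40),
                           "site": "only"})
        df["y"] = 1.0 + 0.5 * df.x - 0.2 * df.z + rng.normal(0, 0.3, 40)
        fit = pg.fit_component(df, "y", ["x", "z"], "gaussian")
        import statsmodels.api as sm
        X = sm.add_constant(df[["x", "z"]].to_numpy())
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-6)
        assert fit.re_var == 0.0

    def test_poisson_glmm_matches_frozen_glmer_oracle(self):
        # fixture regenerated from its seed; expected values are the output
        # of lme4::glmer(y ~ x1 + x2 + (1|site), family=poisson) on the same
        # data, frozen from an Rscript run
        rng = np.random.default_rng(2024)
        n_site, per = 8, 15
        site = np.repeat([f"S{i}" for i in range(n_site)], per)
        x1 = rng.normal(size=n_site * per)
        x2 = rng.normal(size=n_site * per)
        u = rng.normal(0, 0.3, n_site)
        eta = 2.0 + 0.4 * x1 - 0.25 * x2 + np.repeat(u, per)
        y = rng.poisson(np.exp(eta))
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "site": site})
        fit = pg.fit_component(df, "y", ["x1", "x2"], "poisson")
        glmer_coef = {"Intercept": 2.163919, "x1": 0.439295, "x2": -0.236714}
        glmer_se = {"Intercept": 0.123307, "x1": 0.032166, "x2": -0.028105}
        for name, val in glmer_coef.items():
            assert fit.params[name] == pytest.approx(val, abs=1e-3)
            assert fit.bse[name] == pytest.approx(abs(glmer_se[name]), abs=1e-3)
        assert fit.re_var == pytest.approx(0.112735, abs=1e-3)

    def test_poisson_rejects_non_integer_response(self):
        df = pd.DataFrame({"y": [1.5, 2.0, 3.0, 1.0],
                           "x": [0.0, 1.0, 2.0, 3.0], "site": ["a"] * 4})
        with pytest.raises(ValueError, match="non-negative integers"):
            pg.fit_component(df, "y", ["x"], "poisson")

    def test_component_recovers_known_effect(self):
        # true standardized temperature effect 0.4 on log richness; the mean
        # estimate over replicates should land within 0.1
        ests = []
        for rep in range(20):
            env = pg.simulate_environment(pg.DesignSpec(seed=300 + rep))
            sc = pg.scale_variables(env, ["Temp"])
            rng = np.random.default_rng(600 + rep)
            u = dict(zip(sc["site"].unique(), rng.normal(0, 0.2, 8)))
            mu = np.exp(math.log(30) + 0.4 * sc["Temp"] + sc["site"].map(u))
            sc = sc.assign(richness=rng.poisson(mu))
            fit = pg.fit_component(sc, "richness", ["Temp"], "poisson")
            ests.append(fit.coef("Temp"))
        assert np.mean(ests) == pytest.approx(0.4, abs=0.1)

    def test_permuted_response_wald_calibration(self):
        # permuting the response breaks the association: rejection rate at
        # alpha = 0.05 must stay within binomial error over 200 permutations
        rng = np.random.default_rng(11)
        env = pg.simulate_environment(pg.DesignSpec(seed=55))
        sc = pg.scale_variables(env, ["Temp", "Precip"])
        y = 0.5 * sc["Temp"].to_numpy() + rng.normal(0, 1, len(sc))
        rejections = 0
        for _ in range(200):
            sc2 = sc.assign(y=rng.permutation(y))
            fit = pg.fit_component(sc2, "y", ["Precip"], "gaussian")
            rejections += fit.pvalues["Precip"] < 0.05
        rate = rejections / 200
        assert 0.004 <= rate <= 0.1  # 0.05 +- 3 binomial SE

    def test_gaussian_reml_profile_agrees_with_mixedlm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        g = np.repeat(np.arange(8), 15)
        X = np.column_stack([np.ones(120), rng.normal(size=120),
                             rng.normal(size=120)])
        y = X @ [1.0, 0.5, -0.3] + np.repeat(rng.normal(0, 0.4, 8), 15) \
            + rng.normal(0, 1, 120)
        own = _gaussian_reml(y, X, g)
        mlm = sm.MixedLM(y, X, groups=g).fit(reml=True)
        assert np.allclose(own["params"], np.asarray(mlm.fe_params), atol=1e-4)
        assert np.allclose(own["bse"], np.asarray(mlm.bse_fe), atol=1e-4)
        assert own["re_var"] == pytest.approx(
            float(np.asarray(mlm.cov_re)[0, 0]), abs=1e-4)


class TestBasisSet:
    def test_a_priori_model_yields_single_claim_df2(self):
        model = pg.a_priori_model("richness", "poisson")
        claims = pg.basis_set(model)
        assert len(claims) == 1
        claim = claims[0]
        assert {claim.u, claim.v} == {"FUI", "PET"}
        assert claim.conditioning == ("Precip", "Temp")
        assert claim.downstream == "PET"
        assert 2 * len(claims) == 2

    def test_saturated_dag_empty_basis_set(self):
        model = PathModel(edges=(("X", "Y"), ("Y", "Z"), ("X", "Z")))
        assert pg.basis_set(model) == []
        assert pg.fishers_c([]) == (0.0, 0, 1.0)

    def test_chain_yields_textbook_claim(self):
        model = PathModel(edges=(("X", "Y"), ("Y", "Z")))
        claims = pg.basis_set(model)
        assert len(claims) == 1
        assert {claims[0].u, claims[0].v} == {"X", "Z"}
        assert claims[0].conditioning == ("Y",)

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModel(edges=(("X", "Y"), ("Y", "X")))

    def test_derived_covariates_generate_no_claims(self):
        model = pg.a_priori_model("richness", "poisson")
        for claim in pg.basis_set(model):
            assert "PET2" not in (claim.u, claim.v)


class TestDSep:
    def test_true_fui_pet_effect_is_rejected_with_power(self):
        # misspecified DAG: the generator adds a direct standardized
        # FUI -> PET effect of 0.5 that the a priori model omits
        model = pg.a_priori_model("richness", "poisson")
        claim = pg.basis_set(model)[0]
        rejected = 0
        n_rep = 50
        for rep in range(n_rep):
            env = pg.simulate_environment(pg.DesignSpec(seed=700 + rep))
            z_fui = (env["FUI"] - env["FUI"].mean()) / env["FUI"].std(ddof=1)
            env = env.assign(
                PET=env["PET"] + 0.5 * env["PET"].std(ddof=1) * z_fui)
            env["PET2"] = env["PET"] ** 2
            data = pg.scale_variables(env.assign(richness=0),
                                      ["Temp", "Precip", "PET", "PET2", "FUI"])
            rejected += pg.dsep_test(claim, model, data) < 0.05
        assert rejected >= 0.9 * n_rep

    def test_identical_data_identical_p(self):
        model = pg.a_priori_model("richness", "poisson")
        claim = pg.basis_set(model)[0]
        env = pg.simulate_environment(pg.DesignSpec(seed=77))
        data = pg.scale_variables(env.assign(richness=0),
                                  ["Temp", "Precip", "PET", "PET2", "FUI"])
        assert pg.dsep_test(claim, model, data) == pg.dsep_test(claim, model,
                                                                data)


class TestFishersC:
    def test_half_half_closed_form(self):
        C, df, P = pg.fishers_c([0.5, 0.5])
        assert C == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        assert P == pytest.approx(0.5966, abs=1e-4)

    def test_single_p_of_one_gives_zero_statistic(self):
        C, df, P = pg.fishers_c([1.0])
        assert C == 0.0 and df == 2 and P == 1.0

    def test_df2_tail_is_exp_of_minus_half_c(self):
        for C0 in (0.5, 2.594, 7.0):
            _, _, P = pg.fishers_c([math.exp(-C0 / 2.0)])
            assert P == pytest.approx(math.exp(-C0 / 2.0), abs=1e-6)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            pg.fishers_c([0.0, 0.5])


def _enumerate_paths(edges, src, dst):
    """Independent oracle: recursive enumeration of directed paths."""
    out = []

    def walk(node, path):
        if node == dst:
            out.append(list(path))
            return
        for u, v in edges:
            if u == node and v not in path:
                path.append(v)
                walk(v, path)
                path.pop()

    walk(src, [src])
    return out


class _FakeFit:
    def __init__(self, coefs):
        self.coefs = coefs

    def coef(self, predictor):
        return self.coefs[predictor]


class TestTotalEffects:
    def test_mediation_closed_form(self):
        model = PathModel(edges=(("Temp", "PET"), ("PET", "Y"), ("Temp", "Y")))
        a, b, c = 0.7, -0.4, 0.25
        components = {"PET": _FakeFit({"Temp": a}),
                      "Y": _FakeFit({"PET": b, "Temp": c})}
        eff = pg.total_effects(components, model, "Y")
        assert eff.loc["Temp", "direct"] == pytest.approx(c)
        assert eff.loc["Temp", "indirect"] == pytest.approx(a * b)
        assert eff.loc["Temp", "total"] == pytest.approx(c + a * b)

    def test_no_connecting_path_total_zero(self):
        model = PathModel(edges=(("A", "Y"), ("B", "C"), ("C", "Y"),
                                 ("A", "C")))
        components = {"C": _FakeFit({"B": 0.3, "A": 0.2}),
                      "Y": _FakeFit({"A": 0.1, "C": 0.4})}
        eff = pg.total_effects(components, model, "C")
        assert eff.loc["Y", "total"] == 0.0  # Y is downstream of C

    def test_random_dag_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        nodes = ["A", "B", "C", "D", "Y"]
        edges = [(u, v) for i, u in enumerate(nodes)
                 for v in nodes[i + 1:] if rng.random() < 0.7]
        if not any(v == "Y" for _, v in edges):
            edges.append(("A", "Y"))
        coefs = {(u, v): round(float(rng.normal()), 3) for u, v in edges}
        model = PathModel(edges=tuple(edges))
        components = {}
        for node in model.endogenous():
            components[node] = _FakeFit(
                {u: coefs[(u, node)] for u, v in edges if v == node})
        eff = pg.total_effects(components, model, "Y")
        for src in nodes[:-1]:
            paths = _enumerate_paths(edges, src, "Y")
            expected = sum(
                np.prod([coefs[(a, b)] for a, b in zip(p, p[1:])])
                for p in paths)
            assert eff.loc[src, "total"] == pytest.approx(expected, abs=1e-12)


class TestRSquared:
    def test_intercept_only_gaussian_marginal_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(size=60),
                           "site": np.repeat(list("abcd"), 15)})
        fit = pg.fit_component(df, "y", [], "gaussian")
        marginal, conditional = pg.r_squared(fit)
        assert marginal == pytest.approx(0.0, abs=1e-9)
        assert conditional >= marginal

    def test_noiseless_linear_response_marginal_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=80),
                           "site": np.repeat(list("abcd"), 20)})
        df["y"] = 2.0 * df["x"]
        fit = pg.fit_component(df, "y", ["x"], "gaussian")
        marginal, _ = pg.r_squared(fit)
        assert marginal == pytest.approx(1.0, abs=1e-3)

    def test_matches_direct_variance_decomposition_oracle(self):
        # oracle: Var(X beta_true) / Var(y) on the generating model
        # enough groups that the estimated random-effect variance matches the
        # realized one, making the model-based and direct partitions comparable
        rng = np.random.default_rng(6)
        n_site, per = 100, 10
        x = rng.normal(size=n_site * per)
        u = np.repeat(rng.normal(0, 0.5, n_site), per)
        eps = rng.normal(0, 0.8, n_site * per)
        y = 0.9 * x + u + eps
        df = pd.DataFrame({"x": x, "y": y,
                           "site": np.repeat(np.arange(n_site), per)})
        fit = pg.fit_component(df, "y", ["x"], "gaussian")
        marginal, conditional = pg.r_squared(fit)
        oracle_marginal = np.var(0.9 * x) / np.var(y)
        oracle_conditional = np.var(0.9 * x + u) / np.var(y)
        assert marginal == pytest.approx(oracle_marginal, abs=0.05)
        assert conditional == pytest.approx(oracle_conditional, abs=0.05)


@pytest.fixture(scope="module")
def sem_data(small_study):
    data = small_study.environment.copy()
    data["richness"] = (small_study.community.to_numpy() > 0).sum(axis=1)
    return data


class TestRunPsem:
    def test_full_fit_reports_df2_and_effects(self, sem_data):
        model = pg.a_priori_model("richness", "poisson")
        fit = pg.run_psem(model, sem_data)
        assert fit.df == 2
        assert 0 <= fit.pvalue <= 1
        assert set(fit.effects.index) == {"Temp", "Precip", "PET", "PET2",
                                          "FUI"}
        # exact decomposition: total = direct + indirect
        assert np.allclose(fit.effects["total"],
                           fit.effects["direct"] + fit.effects["indirect"])
        for node, (marg, cond) in fit.r2.items():
            assert 0 <= marg <= cond <= 1

    def test_same_seed_identical_serialization(self, sem_data):
        model = pg.a_priori_model("richness", "poisson")
        a = pg.run_psem(model, sem_data).to_json()
        b = pg.run_psem(model, sem_data).to_json()
        assert a == b

    def test_missing_response_rows_excluded_listwise(self, sem_data):
        data = sem_data.copy().astype({"richness": float})
        data["nri"] = np.where(np.arange(len(data)) % 7 == 0, np.nan, 0.1)
        data["nri"] += 0.3 * data["Temp"] / data["Temp"].std()
        model = pg.a_priori_model("nri", "gaussian")
        fit = pg.run_psem(model, data)
        assert fit.components["nri"].n == (~data["nri"].isna()).sum()
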