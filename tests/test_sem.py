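"""Path-model stage: design building, Gibbs correctness, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cotspred import sem, simulate


def chain_spec():
    return sem.PathModelSpec(
        nodes={"a": "exogenous", "b": "endogenous", "c": "endogenous"},
        edges=[("a", "b"), ("b", "c")],
    )


def chain_data(seed, n=500, b1=0.5, b2=-0.4):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = b1 * a + np.sqrt(1 - b1**2) * rng.normal(size=n)
    c = b2 * b + np.sqrt(1 - b2**2) * rng.normal(size=n)
    return pd.DataFrame({"a": a, "b": b, "c": c})


class TestBuildModel:
    def test_columns_are_zscored(self, survey_default):
        model = sem.build_model(sem.default_spec(), survey_default)
        for eq in model.equations.values():
            assert eq.y.mean() == pytest.approx(0.0, abs=1e-12)
            assert eq.y.std() == pytest.approx(1.0, abs=1e-12)

    def test_cycle_rejected(self):
        with pytest.raises(sem.CyclicGraphError):
            sem.PathModelSpec(
                nodes={"a": "endogenous", "b": "endogenous"},
                edges=[("a", "b"), ("b", "a")],
            )

    def test_missing_column_rejected(self):
        with pytest.raises(KeyError):
            sem.build_model(chain_spec(), pd.DataFrame({"a": [1.0, 2.0]}))

    def test_constant_column_rejected(self):
        df = chain_data(0, n=50)
        df["b"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            sem.build_model(chain_spec(), df)

    def test_default_graph_equations_match_declared_parents(self, survey_default):
        """Every endogenous node gets one equation whose design columns are
        exactly its declared parents (categoricals expanded)."""
        spec = sem.default_spec()
        model = sem.build_model(spec, survey_default)
        assert set(model.equations) == set(spec.endogenous)
        for child, eq in model.equations.items():
            declared = set(spec.parents(child))
            seen = {nm.split("~")[1].split("[")[0] for nm in eq.colnames}
            assert seen == declared


class TestSampler:
    def test_prior_recovered_with_zero_observations(self):
        """With no data the posterior of every coefficient is its N(0,1)
        prior."""
        spec = chain_spec()
        eq = sem.Equation(child="b", y=np.empty(0), X=np.empty((0, 1)), colnames=["b~a"])
        model = sem.PreparedModel(spec=spec, equations={"b": eq}, blocks=[["b"]], n=0)
        draws = sem.sample_posterior(model, chains=3, iterations=11000, burnin=1000, seed=2)
        s = draws.retained()[:, :, 0].ravel()
        assert abs(s.mean()) < 0.05
        assert 0.95 < s.std() < 1.05

    def test_known_variance_posterior_equals_ridge(self):
        """With residual variance fixed, the posterior mean is the ridge
        estimator (X'X + sigma^2 I)^-1 X'y."""
        rng = np.random.default_rng(0)
        n, p, s2 = 40, 3, 0.7
        X = rng.normal(size=(n, p))
        y = X @ np.array([0.5, -0.3, 0.2]) + rng.normal(scale=np.sqrt(s2), size=n)
        spec = sem.PathModelSpec(nodes={"x": "exogenous", "y": "endogenous"}, edges=[("x", "y")])
        eq = sem.Equation(child="y", y=y, X=X, colnames=["y~x1", "y~x2", "y~x3"])
        model = sem.PreparedModel(spec=spec, equations={"y": eq}, blocks=[["y"]], n=n)
        draws = sem.sample_posterior(
            model, chains=3, iterations=6000, burnin=1000, seed=1, fixed_resid_var=s2
        )
        post = draws.retained()[:, :, :p].reshape(-1, p)
        closed = np.linalg.solve(X.T @ X + s2 * np.eye(p), X.T @ y)
        mc_se = post.std(axis=0) / np.sqrt(post.shape[0] / 20)  # autocorr margin
        assert np.all(np.abs(post.mean(axis=0) - closed) < 2 * mc_se + 1e-3)

    def test_edge_recovery_on_survey_data(self):
        """A configured s_aspera -> CoTS path of -0.5 is recovered by the
        posterior within +-0.1 with a CI excluding zero at n = 1,000."""
        paths = {("s_aspera", "cots"): -0.5}
        cfg = simulate.SurveyConfig(
            regions=("south",), sites_per_reef=10, transects_per_site=100,
            transect_area_m2=120.0, path_coefficients=paths, seed=21,
        )
        df = simulate.generate_survey(cfg)
        spec = sem.PathModelSpec(
            nodes={"s_aspera": "exogenous", "cots": "endogenous"},
            edges=[("s_aspera", "cots")],
        )
        model = sem.build_model(spec, df)
        draws = sem.sample_posterior(model, chains=3, iterations=2000, burnin=500, seed=5)
        j = draws.names.index("cots~s_aspera")
        s = draws.retained()[:, :, j].ravel()
        lo, hi = np.percentile(s, [2.5, 97.5])
        assert s.mean() == pytest.approx(-0.5, abs=0.1)
        assert hi < 0

    def test_path_tracing_on_three_node_chain(self):
        """Standardized cov(a, c) equals the product of the chain's path
        coefficients."""
        df = chain_data(3, n=4000, b1=0.6, b2=0.5)
        model = sem.build_model(chain_spec(), df)
        draws = sem.sample_posterior(model, chains=2, iterations=1500, burnin=500, seed=4)
        ret = draws.retained()
        prod = (
            ret[:, :, draws.names.index("b~a")] * ret[:, :, draws.names.index("c~b")]
        ).mean()
        emp = np.corrcoef(df["a"], df["c"])[0, 1]
        assert prod == pytest.approx(emp, abs=0.05)
        assert prod == pytest.approx(0.3, abs=0.05)


class TestDiagnostics:
    def test_rhat_near_one_for_mixed_chains(self):
        draws = sem.sample_posterior(
            sem.build_model(chain_spec(), chain_data(5)), chains=3,
            iterations=1500, burnin=500, seed=6,
        )
        assert max(sem.rhat(draws).values()) < 1.01

    def test_rhat_flags_offset_chain(self):
        draws = sem.sample_posterior(
            sem.build_model(chain_spec(), chain_data(6)), chains=3,
            iterations=1500, burnin=500, seed=7,
        )
        draws.array[0, :, 0] += 10.0
        assert sem.rhat(draws)[draws.names[0]] > 1.05

    def test_rhat_requires_multiple_chains(self):
        model = sem.build_model(chain_spec(), chain_data(7))
        with pytest.warns(RuntimeWarning):
            draws = sem.sample_posterior(model, chains=1, iterations=1200, burnin=200, seed=8)
        with pytest.raises(ValueError):
            sem.rhat(draws)

    def test_survey_fit_converges_at_reduced_length(self, survey_default):
        """The full default graph reaches R-hat <= 1.05 on all parameters at
        the reduced chain length used throughout testing."""
        model = sem.build_model(sem.default_spec(), survey_default)
        draws = sem.sample_posterior(model, chains=3, iterations=2000, burnin=500, seed=9)
        assert max(sem.rhat(draws).values()) <= 1.05

    def test_ppp_bounded_and_stable_for_well_specified_data(self):
        ps = []
        for i in range(5):
            model = sem.build_model(chain_spec(), chain_data(30 + i, n=200))
            draws = sem.sample_posterior(model, chains=2, iterations=1500, burnin=500, seed=i)
            ps.append(sem.posterior_predictive_p(model, draws, n_rep=200, seed=i))
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert sum(0.05 <= p <= 0.95 for p in ps) >= 4

    def test_ppp_tail_statistic_detects_heavy_tailed_noise(self):
        """Cauchy-tailed residuals are flagged by the fourth-moment
        discrepancy (the default variance-adaptive chi-square statistic is
        insensitive to symmetric tails by construction)."""
        spec = sem.PathModelSpec(nodes={"a": "exogenous", "b": "endogenous"}, edges=[("a", "b")])
        hits = 0
        for i in range(4):
            rng = np.random.default_rng(200 + i)
            n = 200
            a = rng.normal(size=n)
            b = 0.5 * a + rng.standard_t(1, size=n)
            model = sem.build_model(spec, pd.DataFrame({"a": a, "b": b}))
            draws = sem.sample_posterior(model, chains=2, iterations=1500, burnin=500, seed=i)
            p = sem.posterior_predictive_p(model, draws, n_rep=200, seed=i, statistic="tails")
            hits += p < 0.05
        assert hits >= 3


class TestSummary:
    def test_ci_bounds_ordered_and_signs_consistent(self, survey_default):
        model = sem.build_model(sem.default_spec(), survey_default)
        draws = sem.sample_posterior(model, chains=2, iterations=1200, burnin=400, seed=10)
        res = sem.path_summary(draws)
        t = res.table
        assert (t["ci_low"] < t["ci_high"]).all()
        pos = t[t.sign == "positive"]
        neg = t[t.sign == "negative"]
        assert (pos["ci_low"] > 0).all()
        assert (neg["ci_high"] < 0).all()

    def test_null_coefficient_classified_nonsignificant(self):
        """A zero path is called nonsignificant in most replicate studies."""
        spec = sem.PathModelSpec(nodes={"a": "exogenous", "b": "endogenous"}, edges=[("a", "b")])
        calls = 0
        for i in range(10):
            rng = np.random.default_rng(400 + i)
            df = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
            model = sem.build_model(spec, df)
            draws = sem.sample_posterior(model, chains=2, iterations=1200, burnin=400, seed=i)
            res = sem.path_summary(draws)
            calls += (res.table.set_index("parameter").loc["b~a", "sign"] == "nonsignificant")
        assert calls >= 9
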