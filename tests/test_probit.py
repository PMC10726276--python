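import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from sdmeval import DesignMatrixBuilder, HierarchicalProbitModel, SamplerSettings
from sdmeval.probit import HierarchicalProbitResults, build_design_matrix


def covariate_frame(n, rng):
    return pd.DataFrame({
        "management": rng.integers(0, 2, n),
        "volume": np.exp(rng.normal(6, 1.5, n)),
        "decay": rng.integers(1, 6, n),
    })


class TestDesignMatrixBuilder:
    def test_standardized_columns(self):
        rng = np.random.default_rng(0)
        cov = covariate_frame(500, rng)
        x = DesignMatrixBuilder().fit_transform(cov)
        assert x.shape == (500, 5)
        assert np.allclose(x[:, 0], 1.0)
        assert np.allclose(x[:, 2:].mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(x[:, 2:].std(axis=0), 1.0, atol=1e-12)

    def test_identical_rows_and_training_constants_reused(self):
        rng = np.random.default_rng(1)
        cov = covariate_frame(100, rng)
        builder = DesignMatrixBuilder().fit(cov)
        dup = pd.DataFrame({"management": [0, 0], "volume": [np.e, np.e], "decay": [3, 3]})
        rows = builder.transform(dup)
        assert np.array_equal(rows[0], rows[1])
        # held-out transform uses the stored constants, not the new sample's
        other = builder.transform(cov.iloc[:10])
        full = builder.transform(cov)[:10]
        assert np.allclose(other, full)

    def test_domain_errors(self):
        bad_vol = pd.DataFrame({"management": [0], "volume": [-1.0], "decay": [3]})
        with pytest.raises(ValueError, match="volume"):
            DesignMatrixBuilder().fit(bad_vol)
        bad_decay = pd.DataFrame({"management": [0], "volume": [10.0], "decay": [6]})
        with pytest.raises(ValueError, match="decay"):
            DesignMatrixBuilder().fit(bad_decay)

    def test_intercept_only_variant(self):
        cov = pd.DataFrame({"management": [1], "volume": [5.0], "decay": [2]})
        x, builder = build_design_matrix(cov, DesignMatrixBuilder(intercept_only=True))
        assert x.shape == (1, 1) and builder.names == ("intercept",)


def simulate_fixed_effects_data(n, beta, seed):
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n), rng.standard_normal((n, len(beta) - 1))])
    p = ndtr(x @ beta)
    y = (rng.random(n) < p).astype(int)
    return x, y


class TestFitting:
    def test_single_class_refused(self):
        x, _ = simulate_fixed_effects_data(50, np.array([0.0, 1.0]), 0)
        with pytest.raises(ValueError, match="single-class"):
            HierarchicalProbitModel(np.ones(50, dtype=int), x)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="draws"):
            SamplerSettings(draws=0)

    def test_deterministic_given_seed(self):
        x, y = simulate_fixed_effects_data(200, np.array([-0.3, 0.8]), 1)
        s = SamplerSettings(chains=1, draws=50, burn=50, seed=5)
        r1 = HierarchicalProbitModel(y, x).fit(s)
        r2 = HierarchicalProbitModel(y, x).fit(s)
        assert np.array_equal(r1.beta_draws, r2.beta_draws)

    def test_recovers_fixed_effects(self):
        """Posterior means land near the truth for a pure fixed-effects model."""
        beta = np.array([-0.5, 0.8, -0.6])
        x, y = simulate_fixed_effects_data(2000, beta, 3)
        res = HierarchicalProbitModel(y, x).fit(SamplerSettings(chains=2, draws=500, burn=500, seed=2))
        assert np.all(np.abs(res.params - beta) < 0.3)
        assert res.bse.shape == (3,)
        ci = res.conf_int()
        assert ci.shape == (3, 2) and np.all(ci[:, 0] < ci[:, 1])

    def test_summary_mentions_terms_and_sigmas(self):
        rng = np.random.default_rng(4)
        x, y = simulate_fixed_effects_data(300, np.array([0.0, 0.5]), 4)
        site = rng.integers(0, 6, 300)
        res = HierarchicalProbitModel(y, x, site=site, exog_names=("intercept", "slope")).fit(
            SamplerSettings(chains=2, draws=100, burn=100, seed=1))
        text = res.summary()
        assert "slope" in text and "sigma_site" in text and "Rhat" in text


def zero_effect_results(x, y, site=None, sigma2=1e-12, beta_value=None):
    """Results object with hand-set posterior draws, for prediction contracts."""
    model = HierarchicalProbitModel(y, x, site=site)
    p, s = x.shape[1], 1
    settings = SamplerSettings(chains=1, draws=10, burn=0, seed=0)
    chain_beta = np.zeros((1, 10, p, s))
    if beta_value is not None:
        chain_beta[:] = np.asarray(beta_value)[None, None, :, None]
    chain_u, chain_sig2 = {}, {}
    if site is not None:
        g = len(np.unique(site))
        chain_u = {"site": np.zeros((1, 10, g, s))}
        chain_sig2 = {"site": np.full((1, 10, s), sigma2)}
    return HierarchicalProbitResults(model, settings, chain_beta, chain_u, chain_sig2)


class TestPrediction:
    def test_all_effects_zero_gives_half(self):
        x, y = simulate_fixed_effects_data(20, np.array([0.0, 0.0]), 0)
        res = zero_effect_results(x, y)
        assert np.allclose(res.predict(x), 0.5)

    def test_monotone_in_covariate_with_positive_coefficient(self):
        x, y = simulate_fixed_effects_data(20, np.array([0.0, 0.5]), 1)
        res = zero_effect_results(x, y, beta_value=[0.0, 1.0])
        grid = np.column_stack([np.ones(5), np.linspace(-2, 2, 5)])
        p = res.predict(grid)
        assert np.all(np.diff(p) > 0)

    def test_unseen_level_analytic_identity(self):
        """Simulated marginalization over an unseen group's intercept agrees
        with the closed form Phi(L / sqrt(1 + sigma^2)) within MC error."""
        rng = np.random.default_rng(6)
        n = 600
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        site = rng.integers(0, 12, n)
        p = ndtr(x @ np.array([-0.4, 0.7]) + rng.normal(0, 0.7, 12)[site])
        y = (rng.random(n) < p).astype(int)
        res = HierarchicalProbitModel(y, x, site=site).fit(
            SamplerSettings(chains=2, draws=1000, burn=300, seed=3))
        xn = np.column_stack([np.ones(6), np.linspace(-2, 2, 6)])
        new = np.array(["new"] * 6)
        sim = res.predict(xn, site=new, marginalize="simulate")
        ana = res.predict(xn, site=new, marginalize="analytic")
        assert np.max(np.abs(sim - ana)) < 0.02

    def test_seen_positive_intercept_beats_unseen(self):
        x, y = simulate_fixed_effects_data(40, np.array([0.0, 0.0]), 2)
        site = np.repeat(["a", "b"], 20)
        res = zero_effect_results(x, y, site=site, sigma2=0.25)
        res.u_draws["site"][:, 0, :] = 1.5  # strongly positive intercept for site "a"
        xn = np.array([[1.0, 0.0]])
        seen = res.predict(xn, site=np.array(["a"]), marginalize="analytic")
        unseen = res.predict(xn, site=np.array(["zzz"]), marginalize="analytic")
        assert seen[0] > unseen[0]

    def test_schema_mismatch_rejected(self):
        x, y = simulate_fixed_effects_data(30, np.array([0.0, 0.5]), 3)
        res = zero_effect_results(x, y)
        with pytest.raises(ValueError, match="columns"):
            res.predict(np.ones((5, 3)))
        site = np.repeat(["a", "b"], 15)
        res2 = zero_effect_results(x, y, site=site)
        with pytest.raises(ValueError, match="site"):
            res2.predict(x)


def test_serialization_round_trip(tmp_path):
    """A saved fit reloads with identical draws, params and predictions."""
    rng = np.random.default_rng(12)
    n = 300
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    site = np.repeat(np.arange(6), 50)
    y = (rng.random(n) < ndtr(x @ np.array([0.2, 0.6]))).astype(int)
    res = HierarchicalProbitModel(y, x, site=site).fit(
        SamplerSettings(chains=2, draws=80, burn=80, seed=1))
    path = tmp_path / "fit.npz"
    res.save(path)
    back = HierarchicalProbitResults.load(path)
    assert np.array_equal(res.beta_draws, back.beta_draws)
    assert np.allclose(res.params, back.params)
    new_site = np.array(["zz"] * 4)
    xn = x[:4]
    assert np.allclose(res.predict(xn, site=new_site), back.predict(xn, site=new_site))


def test_parameter_recovery_with_random_effects_quick():
    """Short-run version of the recovery simulation: posterior means of the
    slopes stay near truth despite site/plot heterogeneity."""
    rng = np.random.default_rng(10)
    n = 1500
    x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    site = np.repeat(np.arange(15), 100)
    plot = np.repeat(np.arange(75), 20)
    beta = np.array([-0.4, 0.7, -0.5])
    eta = rng.normal(0, 0.5, 15)[site] + rng.normal(0, 0.5, 75)[plot]
    y = (rng.random(n) < ndtr(x @ beta + eta)).astype(int)
    res = HierarchicalProbitModel(y, x, site=site, plot=plot).fit(
        SamplerSettings(chains=2, draws=400, burn=400, seed=9))
    assert np.all(np.abs(res.params[1:] - beta[1:]) < 0.2)
    assert 0.15 < res.sigma("site") < 1.2
    assert 0.15 < res.sigma("plot") < 1.2
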