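import numpy as np
import pytest
from scipy import stats

import cgiset as cg
from cgiset.containers import Pathway, PathwayCollection, ProbeAnnotation
from cgiset.errors import ValidationError
from cgiset.gibbs import GibbsSampler, _split_rhat, conjugate_posterior_oracle
from cgiset.model import design_matrix
from cgiset.topology import assemble_features

from conftest import batch_mcse


class TestReproducibility:
    def test_same_seed_identical_different_seed_not(self, small_study):
        cfg = cg.MCMCConfig(n_iter=300, n_burnin=100, thin=1, n_chains=2, seed=9)
        a = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg)
        b = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.deviance, b.deviance)
        cfg2 = cg.MCMCConfig(n_iter=300, n_burnin=100, thin=1, n_chains=2, seed=10)
        c = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg2)
        assert not np.array_equal(a.gamma, c.gamma)

    def test_draw_count_contract(self, small_study):
        cfg = cg.MCMCConfig(n_iter=1000, n_burnin=200, thin=4, n_chains=2, seed=0)
        s = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg)
        assert s.gamma.shape[:2] == (2, 200)
        assert (s.tau2_Y > 0).all() and np.isfinite(s.deviance).all()


class TestPreconditions:
    def test_too_small_data_rejected(self, small_study):
        with pytest.raises(ValidationError):
            GibbsSampler(np.zeros((1, 5)), cg.ModelSpec(form="a"), cg.Priors(),
                         small_study.features)

    def test_pathway_without_probes_rejected(self):
        col = PathwayCollection((Pathway("P1", "", ("GA",)),
                                 Pathway("P2", "", ("GZ",))))
        ann = ProbeAnnotation(("p0", "p1"), ("GA", "GA"), np.array([True, False]))
        feats = assemble_features(ann, col)
        with pytest.raises(ValidationError, match="P2"):
            GibbsSampler(np.zeros((3, 2)), cg.ModelSpec(form="b1"), cg.Priors(), feats)


class TestConjugateOracle:
    def test_flat_prior_limit_is_least_squares(self, conjugate_toy):
        toy = conjugate_toy
        mean, _ = conjugate_posterior_oracle(
            toy["theta"], toy["b"], toy["tau2"], toy["sigma2"],
            features=toy["features"], gamma_var=1e12,
        )
        x = toy["features"].membership[:, 0].astype(float)
        tb = toy["theta"].theta.mean(axis=0)
        v = toy["tau2"] + toy["sigma2"] / toy["theta"].n_pairs
        wls = (x * (tb - toy["b"]) / v).sum() / (x * x / v).sum()
        assert mean == pytest.approx(wls, rel=1e-6)

    def test_point_mass_prior_limit_is_zero(self, conjugate_toy):
        toy = conjugate_toy
        mean, var = conjugate_posterior_oracle(
            toy["theta"], toy["b"], toy["tau2"], toy["sigma2"],
            features=toy["features"], gamma_var=1e-12,
        )
        assert abs(mean) < 1e-6 and var < 1e-11

    def test_matches_quadrature(self, conjugate_toy):
        toy = conjugate_toy
        om, ov = conjugate_posterior_oracle(
            toy["theta"], toy["b"], toy["tau2"], toy["sigma2"],
            features=toy["features"], gamma_var=toy["gamma_var"],
        )
        tb = toy["theta"].theta.mean(axis=0)
        v = toy["tau2"] + toy["sigma2"] / toy["theta"].n_pairs
        grid = np.linspace(om - 8 * np.sqrt(ov), om + 8 * np.sqrt(ov), 4001)
        logp = (-0.5 * ((tb[None, :] - toy["b"] - grid[:, None]) ** 2 / v).sum(axis=1)
                - 0.5 * grid ** 2 / toy["gamma_var"])
        w = np.exp(logp - logp.max())
        w /= np.trapezoid(w, grid)
        qm = np.trapezoid(w * grid, grid)
        qv = np.trapezoid(w * (grid - qm) ** 2, grid)
        assert om == pytest.approx(qm, abs=1e-4)
        assert ov == pytest.approx(qv, abs=1e-4)

    def test_gibbs_agrees_with_oracle(self, conjugate_toy):
        toy = conjugate_toy
        spec = cg.ModelSpec(form="b1", include_pair_effect=False)
        pri = cg.Priors(gamma_var=toy["gamma_var"])
        cfg = cg.MCMCConfig(n_iter=7000, n_burnin=1000, thin=1, n_chains=1,
                            seed=3, fixed=toy["fixed"])
        s = cg.run_gibbs(toy["theta"], spec, pri, toy["features"], cfg)
        draws = s.pooled("gamma")[:, 0]
        om, ov = conjugate_posterior_oracle(
            toy["theta"], toy["b"], toy["tau2"], toy["sigma2"],
            features=toy["features"], gamma_var=toy["gamma_var"],
        )
        mcse = batch_mcse(draws)
        assert abs(draws.mean() - om) < 3 * mcse
        assert draws.var() == pytest.approx(ov, rel=0.15)


class TestNestedBehaviour:
    def test_tiny_gamma_prior_reproduces_null_model(self, small_study):
        """With the gamma prior collapsing to 0, b1's beta posterior matches (a)."""
        theta, feats = small_study.theta, small_study.features
        base = dict(n_iter=3000, n_burnin=500, thin=1, n_chains=1, seed=21)
        s_null = cg.run_gibbs(theta, cg.ModelSpec(form="a"), cg.Priors(),
                              feats, cg.MCMCConfig(**base))
        s_tiny = cg.run_gibbs(theta, cg.ModelSpec(form="b1"),
                              cg.Priors(gamma_var=1e-12), feats, cg.MCMCConfig(**base))
        m_null = s_null.pooled("beta").mean(axis=0)
        m_tiny = s_tiny.pooled("beta").mean(axis=0)
        mcse = max(batch_mcse(s_null.pooled("beta")[:, j]) for j in range(3))
        assert np.max(np.abs(m_null[:3] - m_tiny[:3])) < 6 * mcse + 1e-3


class TestGelmanRubin:
    def test_copied_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        assert _split_rhat(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_diverge(self):
        chains = np.stack([np.zeros(200), np.full(200, 10.0)])
        assert _split_rhat(chains) > 3.0

    def test_constant_everything_is_one(self):
        assert _split_rhat(np.zeros((2, 100))) == 1.0

    def test_well_mixed_model_below_1p05(self, small_study):
        cfg = cg.MCMCConfig(n_iter=2500, n_burnin=500, thin=1, n_chains=2, seed=2)
        s = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg)
        rhats = cg.gelman_rubin(s)
        for name in ("b_Y", "b_N", "gamma[PW01]", "gamma[PW02]", "sigma2_Y"):
            assert rhats[name] < 1.05, name

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        chains = rng.normal(size=(2, 800))
        ours = _split_rhat(chains)
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_requires_two_chains(self, small_study):
        cfg = cg.MCMCConfig(n_iter=200, n_burnin=50, thin=1, n_chains=1, seed=0)
        s = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg)
        with pytest.raises(ValidationError):
            cg.gelman_rubin(s)


class TestGewekeCalibration:
    """Successive-conditional simulation: parameter draws must match the prior."""

    def test_marginals_match_prior(self):
        m, n = 6, 4
        ann = ProbeAnnotation(
            tuple(f"p{i}" for i in range(m)), tuple(f"G{i // 2}" for i in range(m)),
            np.array([1, 0, 1, 0, 1, 0], dtype=bool),
        )
        col = PathwayCollection((
            Pathway("P1", "", ("G0", "G1"), (("G0", "G1"),)),
            Pathway("P2", "", ("G1", "G2")),
        ))
        feats = assemble_features(ann, col)
        spec = cg.ModelSpec(form="b1", include_pair_effect=True)
        pri = cg.Priors(b_mean=0.0, b_var=0.25, gamma_mean=0.0, gamma_var=0.25,
                        tau2_shape=3.0, tau2_scale=0.2, sigma2_shape=3.0,
                        sigma2_scale=0.2, tau2_delta_shape=3.0, tau2_delta_scale=0.2)
        X = design_matrix(spec, feats)
        rng = np.random.default_rng(42)

        def prior_state():
            t2y = pri.tau2_scale / rng.gamma(pri.tau2_shape)
            t2n = pri.tau2_scale / rng.gamma(pri.tau2_shape)
            s2 = pri.sigma2_scale / rng.gamma(pri.sigma2_shape)
            t2d = pri.tau2_delta_scale / rng.gamma(pri.tau2_delta_shape)
            bY, bN = rng.normal(0, 0.5, 2)
            gam = rng.normal(0, 0.5, X.shape[1])
            beta = np.where(feats.cgi, rng.normal(bY, np.sqrt(t2y), m),
                            rng.normal(bN, np.sqrt(t2n), m))
            return cg.ParameterState(beta=beta, gamma=gam, b_Y=bY, b_N=bN,
                                     tau2_Y=t2y, tau2_N=t2n,
                                     sigma2_eps=np.array([s2, s2]),
                                     delta=rng.normal(0, np.sqrt(t2d), n),
                                     tau2_delta=t2d)

        def sim_data(st):
            lam = st.beta + X @ st.gamma
            return lam[None, :] + st.delta[:, None] + rng.normal(
                0, np.sqrt(st.sigma2_eps[0]), (n, m))

        state = prior_state()
        theta = sim_data(state)
        sampler = GibbsSampler(theta, spec, pri, feats)
        rec = {"b_Y": [], "gamma0": [], "tau2_Y": [], "sigma2": [], "tau2_delta": []}
        for t in range(9000):
            sampler.set_theta(theta)
            state = sampler.sweep(state, rng)
            theta = sim_data(state)
            if t % 3 == 0:
                rec["b_Y"].append(state.b_Y)
                rec["gamma0"].append(state.gamma[0])
                rec["tau2_Y"].append(state.tau2_Y)
                rec["sigma2"].append(state.sigma2_eps[0])
                rec["tau2_delta"].append(state.tau2_delta)

        norm_cdf = stats.norm(0, 0.5).cdf
        ig_cdf = stats.invgamma(3.0, scale=0.2).cdf
        for name, cdf in (("b_Y", norm_cdf), ("gamma0", norm_cdf),
                          ("tau2_Y", ig_cdf), ("sigma2", ig_cdf),
                          ("tau2_delta", ig_cdf)):
            ks = stats.kstest(np.array(rec[name]), cdf).statistic
            assert ks < 0.08, f"{name}: KS={ks:.3f}"


class TestPersistence:
    def test_save_load_round_trip(self, small_study, tmp_path):
        cfg = cg.MCMCConfig(n_iter=300, n_burnin=100, thin=2, n_chains=2, seed=1)
        s = cg.run_gibbs(small_study.theta, small_study.spec, cg.Priors(),
                         small_study.features, cfg)
        cg.save_samples(s, tmp_path / "draws.npz")
        back = cg.load_samples(tmp_path / "draws.npz")
        np.testing.assert_array_equal(back.gamma, s.gamma)
        np.testing.assert_array_equal(back.lam, s.lam)
        assert back.gamma_labels == s.gamma_labels
        assert back.spec == s.spec and back.config == s.config
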