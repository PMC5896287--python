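"""Shared-component model: posterior density, sampler and summaries."""

import numpy as np
import pytest
import scipy.stats

import spacecohort as sc
from spacecohort._mh import sample_precision
from spacecohort.smbc import SMBCSamples, initial_state


def tiny_data(I=2, T=2, seed=0):
    rng = np.random.default_rng(seed)
    ids = tuple(f"a{i}" for i in range(I))
    cohorts = tuple(f"c{t}" for t in range(T))
    E = rng.uniform(5, 20, size=(I, T))
    y = rng.poisson(E).astype(float)
    x = rng.normal(size=(I, T))
    return sc.CohortData(ids, cohorts, y, E, x)


def path_graph(I):
    ids = [f"a{i}" for i in range(I)]
    return sc.graph_from_edges(ids, [(f"a{i}", f"a{i+1}") for i in range(I - 1)])


class TestLogPosterior:
    def test_null_state_gives_unit_relative_risk_likelihood(self):
        data = tiny_data()
        g = path_graph(2)
        cfg = sc.MCMCConfig(n_burnin=0, n_keep=1)
        rng = np.random.default_rng(0)
        st = initial_state(data, rng)
        st.beta0 = 0.0
        lp = sc.smbc_log_posterior(st, data, g, cfg)
        # likelihood part at theta == 1
        ll = float(np.sum(data.y * np.log(data.E) - data.E))
        # prior part: only the precision priors and their normalisers remain
        from spacecohort._mh import gamma_logpdf

        I, T = data.shape
        prior = 4 * gamma_logpdf(10.0, 0.5, 0.0005)
        prior += 0.5 * (I + I * T) * np.log(10.0)  # heterogeneity normalisers
        rank = sc.car_rank(g)
        prior += 0.5 * (rank + rank * T) * np.log(10.0)
        assert lp == pytest.approx(ll + prior, rel=1e-12)

    def test_likelihood_linear_in_counts(self):
        data = tiny_data()
        g = path_graph(2)
        cfg = sc.MCMCConfig()
        rng = np.random.default_rng(1)
        st = initial_state(data, rng)
        st.gamma_s = rng.normal(size=2)
        st.log_omega = np.array([0.3, -0.3])
        lp1 = sc.smbc_log_posterior(st, data, g, cfg)
        data2 = sc.CohortData(data.area_ids, data.cohort_labels, 2 * data.y, data.E, data.x)
        lp2 = sc.smbc_log_posterior(st, data2, g, cfg)
        eta = st.log_theta(data.x)
        assert lp2 - lp1 == pytest.approx(float(np.sum(data.y * (eta + np.log(data.E)))), rel=1e-10)

    def test_hand_expansion_two_by_two(self):
        """Term-by-term independent expansion on a 2-area, 2-cohort problem."""
        from scipy.special import gammaln

        data = tiny_data(seed=3)
        g = path_graph(2)
        cfg = sc.MCMCConfig(sigma2_omega=0.8)
        st = sc.SMBCState(
            beta0=0.2,
            beta1=-0.1,
            alpha=np.array([0.05, -0.05]),
            log_omega=np.array([0.4, -0.4]),
            gamma_s=np.array([0.1, -0.1]),
            phi_s=np.array([0.2, -0.2]),
            gamma_p=np.array([[0.03, -0.03], [-0.03, 0.03]]),
            phi_p=np.array([[0.1, -0.2], [-0.1, 0.2]]),
            lambda_gamma=3.0,
            lambda_gamma_p=4.0,
            lambda_phi=5.0,
            lambda_phi_p=6.0,
        )
        # independent scalar expansion
        expect = 0.0
        for i in range(2):
            for t in range(2):
                eta = (
                    st.beta0
                    + st.beta1 * data.x[i, t]
                    + st.alpha[t]
                    + np.exp(st.log_omega[t]) * (st.gamma_s[i] + st.phi_s[i])
                    + st.gamma_p[i, t]
                    + st.phi_p[i, t]
                )
                expect += data.y[i, t] * (eta + np.log(data.E[i, t])) - data.E[i, t] * np.exp(eta)
        expect += -0.5 * (0.2**2 + 0.1**2) / 1e4
        expect += -0.5 * (0.05**2 + 0.05**2) / 1e4
        # omega prior: z = (logw1 - logw2)/sqrt(2); subspace variance 2*sigma2
        z = (0.4 - (-0.4)) / np.sqrt(2.0)
        expect += -0.5 * z**2 / (2 * 0.8)
        # gamma fields with normalisers
        expect += 0.5 * 2 * np.log(3.0) - 0.5 * 3.0 * (0.1**2 + 0.1**2)
        expect += 0.5 * 4 * np.log(4.0) - 0.5 * 4.0 * 4 * 0.03**2
        # CAR kernels on the 2-path: quad = (phi_1 - phi_2)^2, rank 1
        expect += 0.5 * 1 * np.log(5.0) - 0.5 * 5.0 * (0.2 - (-0.2)) ** 2
        quad_p = (0.1 - (-0.1)) ** 2 + (-0.2 - 0.2) ** 2
        expect += 0.5 * 2 * np.log(6.0) - 0.5 * 6.0 * quad_p
        # Gamma(0.5, 0.0005) hyperpriors, shape-rate
        a, b = 0.5, 0.0005
        for lam in (3.0, 4.0, 5.0, 6.0):
            expect += a * np.log(b) - gammaln(a) + (a - 1) * np.log(lam) - b * lam
        assert sc.smbc_log_posterior(st, data, g, cfg) == pytest.approx(expect, rel=1e-12)

    def test_unconstrained_omega_rejected(self):
        data = tiny_data()
        g = path_graph(2)
        st = initial_state(data, np.random.default_rng(0))
        st.log_omega = np.array([0.1, 0.1])
        with pytest.raises(sc.ValidationError):
            sc.smbc_log_posterior(st, data, g, sc.MCMCConfig())


class TestSampler:
    def test_seed_reproducibility(self):
        data, _ = sc.simulate_smbc_data(sc.SimulationScenario(rows=3, cols=3, seed=2))
        g = sc.make_lattice_graph(3, 3)
        cfg = sc.MCMCConfig(n_burnin=100, n_keep=20, thin=2, seed=42)
        s1 = sc.run_smbc_mcmc(data, g, cfg)
        s2 = sc.run_smbc_mcmc(data, g, cfg)
        np.testing.assert_array_equal(s1.theta, s2.theta)
        np.testing.assert_array_equal(s1.lambdas, s2.lambdas)

    def test_constraints_on_kept_samples(self):
        data, _ = sc.simulate_smbc_data(sc.SimulationScenario(rows=3, cols=3, seed=4))
        g = sc.make_lattice_graph(3, 3)
        cfg = sc.MCMCConfig(n_burnin=200, n_keep=50, thin=2, seed=0)
        s = sc.run_smbc_mcmc(data, g, cfg)
        assert np.max(np.abs(s.log_omega.sum(axis=1))) <= 1e-12
        assert np.max(np.abs(s.phi_s.mean(axis=1))) <= 1e-12
        assert np.max(np.abs(s.phi_p.mean(axis=1))) <= 1e-12
        assert np.max(np.abs(s.gamma_p.mean(axis=1))) <= 1e-12

    def test_precision_update_matches_conjugate_gamma(self):
        """Sampler's precision draw vs the closed-form Gamma posterior."""
        rng = np.random.default_rng(9)
        g = sc.make_lattice_graph(4, 4)
        phi = sc.sample_intrinsic_car(g, 2.0, rng)
        k = sc.build_structure_matrix(g)
        quad = k.quad_form(phi)
        rank = sc.car_rank(g)  # I - #components
        draws = np.array(
            [sample_precision(0.5, 0.0005, rank, quad, rng) for _ in range(5000)]
        )
        oracle = scipy.stats.gamma(a=0.5 + rank / 2, scale=1.0 / (0.0005 + quad / 2))
        _, p = scipy.stats.kstest(draws, oracle.cdf)
        assert p > 0.01

    def test_tight_omega_prior_degrades_to_common_field(self):
        """sigma2_omega -> 0 forces the scalings to 1 (single shared field)."""
        data, _ = sc.simulate_smbc_data(sc.SimulationScenario(rows=3, cols=3, seed=6))
        g = sc.make_lattice_graph(3, 3)
        cfg = sc.MCMCConfig(n_burnin=200, n_keep=50, thin=2, seed=0, sigma2_omega=1e-10)
        s = sc.run_smbc_mcmc(data, g, cfg)
        assert np.max(np.abs(s.omega - 1.0)) < 1e-3

    def test_two_seed_marginal_agreement(self):
        """Long-run beta0 marginal is seed-invariant (two-sample KS smoke)."""
        data, _ = sc.simulate_smbc_data(
            sc.SimulationScenario(rows=1, cols=3, seed=8, e_range=(20, 40))
        )
        g = sc.make_lattice_graph(1, 3)
        samples = []
        for seed in (1, 2):
            cfg = sc.MCMCConfig(n_burnin=2000, n_keep=2000, thin=10, seed=seed)
            samples.append(sc.run_smbc_mcmc(data, g, cfg).beta0)
        _, p = scipy.stats.ks_2samp(samples[0], samples[1])
        assert p > 0.01


class TestSummaries:
    def _degenerate_samples(self):
        I, T, n = 3, 2, 5
        theta = np.tile(np.arange(1.0, 7.0).reshape(1, I, T), (n, 1, 1))
        return SMBCSamples(
            area_ids=("a", "b", "c"),
            cohort_labels=("c0", "c1"),
            beta0=np.full(n, 0.5),
            beta1=np.full(n, -0.2),
            alpha=np.zeros((n, T)),
            log_omega=np.zeros((n, T)),
            gamma_s=np.zeros((n, I)),
            phi_s=np.zeros((n, I)),
            gamma_p=np.zeros((n, I, T)),
            phi_p=np.zeros((n, I, T)),
            lambdas=np.ones((n, 4)),
            theta=theta,
        )

    def test_degenerate_samples_give_zero_width_intervals(self):
        s = self._degenerate_samples()
        summ = sc.summarize_smbc(s)
        assert summ.beta1_mean == -0.2
        assert summ.beta1_ci == (-0.2, -0.2)
        np.testing.assert_array_equal(summ.theta_lo, summ.theta_hi)
        np.testing.assert_array_equal(summ.theta_mean, s.theta[0])

    def test_zero_field_exponentiates_to_one(self):
        summ = sc.summarize_smbc(self._degenerate_samples())
        np.testing.assert_array_equal(summ.exp_psi_s_mean, np.ones(3))
        np.testing.assert_array_equal(summ.exp_psi_p_mean, np.ones((3, 2)))
        np.testing.assert_array_equal(summ.omega_mean, np.ones(2))

    def test_normal_draws_match_closed_form(self):
        """Mean/quantiles of synthetic normal posterior draws vs analytic."""
        import dataclasses

        rng = np.random.default_rng(12)
        n = 20000
        draws = rng.normal(1.5, 0.3, size=n)
        s = dataclasses.replace(
            self._degenerate_samples(),
            beta1=draws,
            beta0=np.zeros(n),
            alpha=np.zeros((n, 2)),
            log_omega=np.zeros((n, 2)),
            gamma_s=np.zeros((n, 3)),
            phi_s=np.zeros((n, 3)),
            gamma_p=np.zeros((n, 3, 2)),
            phi_p=np.zeros((n, 3, 2)),
            lambdas=np.ones((n, 4)),
            theta=np.ones((n, 3, 2)),
        )
        summ = sc.summarize_smbc(s)
        assert summ.beta1_mean == pytest.approx(1.5, abs=0.01)
        assert summ.beta1_ci[0] == pytest.approx(1.5 - 1.96 * 0.3, abs=0.02)
        assert summ.beta1_ci[1] == pytest.approx(1.5 + 1.96 * 0.3, abs=0.02)

    def test_long_frame_contains_scalar_traces(self):
        df = self._degenerate_samples().to_long_frame()
        assert {"beta0", "beta1", "lambda_phi"} <= set(df["parameter"])
        assert set(df.columns) == {"iteration", "parameter", "value"}
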