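"""Unit tests of the Gibbs sampler's full conditionals against independent
oracles (brute-force enumeration, closed-form GLS, hand computation)."""

import numpy as np
import pytest
from scipy import stats

from conntraj.connectivity import edge_pairs
from conntraj.design import build_design
from conntraj.model import ClusterTrajectoryModel, GibbsConfig, _tril_pairs


def _small_model(R=3, K=2, S=16, D=2, seed=7, **cfg_kw):
    rng = np.random.default_rng(seed)
    ages = np.linspace(12, 88, S)
    sex = np.tile([0, 1], S // 2)
    site = np.repeat(np.arange(D), S // D)
    design = build_design(ages, sex)
    edges = edge_pairs(R)
    cfg = GibbsConfig(n_iter=4, n_burn=2, seed=seed, rho0=1.0, varrho0=1.0, **cfg_kw)
    model = ClusterTrajectoryModel(
        endog=rng.normal(size=(S, edges.shape[0])),
        design=design,
        site=site,
        edge_index=edges,
        n_clusters=K,
        config=cfg,
    )
    return model


class TestLogLikelihood:
    def test_standard_normal_at_zero(self):
        model = _small_model()
        state = model.prior_draw(np.random.default_rng(0))
        state.B[:] = 0.0
        state.sigma2[:] = 1.0
        state.delta2[:] = 1.0
        model.set_endog(np.zeros_like(model.endog))
        S, E = model.n_subjects, model.n_edges
        assert np.isclose(
            model.log_likelihood(state), -(S * E / 2) * np.log(2 * np.pi), atol=1e-10
        )

    def test_matches_per_observation_oracle(self):
        model = _small_model(R=3, S=10, D=2)
        state = model.prior_draw(np.random.default_rng(1))
        oracle = 0.0
        for e, (i, j) in enumerate(model.edge_index):
            k1, k2 = state.labels[i], state.labels[j]
            beta = state.B[:, k1, k2]
            for s in range(model.n_subjects):
                var = state.sigma2[e] * state.delta2[model.site[s], e]
                mu = model.X[s] @ beta
                oracle += stats.norm.logpdf(model.endog[s, e], mu, np.sqrt(var))
        assert np.isclose(model.log_likelihood(state), oracle, atol=1e-10)

    def test_site_variance_locality(self):
        model = _small_model()
        state = model.prior_draw(np.random.default_rng(2))
        base = model.log_likelihood(state)
        # doubling site-2 multipliers changes the likelihood only through
        # site-2 subjects' terms
        site2 = model.site == 1
        r = model.endog - model.mean_matrix(state)
        var = state.sigma2[None, :] * state.delta2[model.site, :]
        terms = -0.5 * (np.log(2 * np.pi * var) + r**2 / var)
        state2 = state.copy()
        state2.delta2[1] *= 2.0
        var2 = state.sigma2[None, :] * state2.delta2[model.site, :]
        terms2 = -0.5 * (np.log(2 * np.pi * var2) + r**2 / var2)
        assert np.allclose(terms2[~site2], terms[~site2])
        assert np.isclose(
            model.log_likelihood(state2), base + (terms2[site2] - terms[site2]).sum()
        )


class TestVarianceConditionals:
    def test_xi2_shape_is_structural(self):
        model = _small_model()
        state = model.prior_draw(np.random.default_rng(3))
        state.B[:, 0, 0] = 0.0
        # with B = 0 the conditional is IG(rho0 + 1/2, rho0): check the
        # sampled median against the closed-form quantile
        draws = []
        rng = np.random.default_rng(4)
        for _ in range(4000):
            model.sample_xi2(state, rng)
            draws.append(state.xi2[0, 0, 0])
        cfg = model.config
        ref_median = 1.0 / stats.gamma(a=cfg.rho0 + 0.5, scale=1 / cfg.rho0).ppf(0.5)
        assert np.isclose(np.median(draws), ref_median, rtol=0.1)

    def test_sigma2_hand_computed_conditional(self):
        model = _small_model(R=2, S=8, D=2)
        state = model.prior_draw(np.random.default_rng(5))
        state.delta2[1] = 2.0
        resid = model.endog - model.mean_matrix(state)
        e = 0
        expected_rate = model.config.varrho0 + 0.5 * np.sum(
            resid[:, e] ** 2 / state.delta2[model.site, e]
        )
        expected_shape = model.config.varrho0 + 0.5 * model.n_subjects
        draws = []
        rng = np.random.default_rng(6)
        for _ in range(20000):
            s2 = state.copy()
            model.sample_sigma2(s2, rng)
            draws.append(s2.sigma2[e])
        ref = stats.invgamma(a=expected_shape, scale=expected_rate)
        assert np.isclose(np.median(draws), ref.ppf(0.5), rtol=0.05)
        assert np.isclose(np.mean(draws), ref.mean(), rtol=0.05)

    def test_delta2_reference_site_never_sampled(self):
        model = _small_model()
        state = model.prior_draw(np.random.default_rng(7))
        rng = np.random.default_rng(8)
        for _ in range(25):
            model.sweep(state, rng)
            assert np.array_equal(state.delta2[0], np.ones(model.n_edges))

    def test_single_site_model_has_no_multipliers_to_sample(self):
        model = _small_model(D=1)
        state = model.prior_draw(np.random.default_rng(9))
        before = state.delta2.copy()
        model.sample_delta2(state, np.random.default_rng(10))
        assert np.array_equal(state.delta2, before)
        assert state.delta2.shape[0] == 1


class TestBetaConditional:
    def test_matches_gls_closed_form(self):
        """Fixed variances: the conditional mean/cov must equal the ridge-GLS
        normal-equations solution computed by an independent loop oracle."""
        model = _small_model(R=4, K=2, S=12, D=2)
        state = model.prior_draw(np.random.default_rng(11))
        for k1, k2 in _tril_pairs(2):
            mean, cov = model.beta_conditional(state, k1, k2)
            prec_o = np.diag(1.0 / state.xi2[:, k1, k2]).astype(float)
            rhs_o = np.zeros(5)
            for e, (i, j) in enumerate(model.edge_index):
                ki, kj = state.labels[i], state.labels[j]
                if {ki, kj} != {k1, k2} and not (k1 == k2 and ki == kj == k1):
                    continue
                for s in range(model.n_subjects):
                    w = 1.0 / (state.sigma2[e] * state.delta2[model.site[s], e])
                    prec_o += w * np.outer(model.X[s], model.X[s])
                    rhs_o += w * model.X[s] * model.endog[s, e]
            cov_o = np.linalg.inv(prec_o)
            assert np.allclose(cov, cov_o, atol=1e-8)
            assert np.allclose(mean, cov_o @ rhs_o, atol=1e-8)

    def test_empty_pair_falls_back_to_prior(self):
        model = _small_model(R=3, K=2)
        state = model.prior_draw(np.random.default_rng(12))
        state.labels[:] = 0  # cluster pair (1,1) has no edges
        state.xi2[:, 1, 1] = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        rng = np.random.default_rng(13)
        draws = np.empty((30000, 5))
        for n in range(draws.shape[0]):
            model.sample_beta(state, rng)
            draws[n] = state.B[:, 1, 1]
        assert np.allclose(draws.mean(axis=0), 0, atol=0.05)
        assert np.allclose(draws.var(axis=0), state.xi2[:, 1, 1], rtol=0.05)

    def test_symmetry_after_every_sweep(self):
        model = _small_model(R=4, K=3)
        state = model.prior_draw(np.random.default_rng(14))
        rng = np.random.default_rng(15)
        for _ in range(20):
            model.sweep(state, rng)
            assert np.array_equal(state.B, np.transpose(state.B, (0, 2, 1)))
            assert np.array_equal(state.xi2, np.transpose(state.xi2, (0, 2, 1)))


class TestMixtureConditionals:
    def test_p_conditional_mean_matches_dirichlet_formula(self):
        model = _small_model(R=4, K=2, **{"alpha": 0.5})
        state = model.prior_draw(np.random.default_rng(16))
        state.labels = np.array([0, 0, 0, 1])
        rng = np.random.default_rng(17)
        draws = np.empty((20000, 2))
        for n in range(draws.shape[0]):
            model.sample_p(state, rng)
            draws[n] = state.p
        assert np.allclose(draws.mean(axis=0), [3.5 / 5, 1.5 / 5], atol=0.01)
        assert np.allclose(draws.sum(axis=1), 1.0)

    def test_label_conditional_matches_enumeration_oracle(self):
        """R=3, K=2: conditional label probabilities must equal brute-force
        enumeration of the likelihood over the K choices."""
        model = _small_model(R=3, K=2, S=10)
        state = model.prior_draw(np.random.default_rng(18))
        for i in range(3):
            probs = model.label_conditional_probs(state, i)
            logp = np.empty(2)
            for k in range(2):
                trial = state.copy()
                trial.labels[i] = k
                logp[k] = np.log(state.p[k]) + model.log_likelihood(trial)
            oracle = np.exp(logp - logp.max())
            oracle /= oracle.sum()
            assert np.allclose(probs, oracle, atol=1e-10)

    def test_symmetric_likelihood_labels_follow_p(self):
        model = _small_model(R=3, K=2)
        state = model.prior_draw(np.random.default_rng(19))
        state.B[:] = 0.0  # both labels give identical likelihood
        state.p = np.array([0.3, 0.7])
        rng = np.random.default_rng(20)
        counts = np.zeros(2)
        for _ in range(4000):
            model.sample_m(state, rng)
            counts += np.bincount(state.labels, minlength=2)
        freq = counts / counts.sum()
        assert np.allclose(freq, state.p, atol=0.02)


class TestRunGibbs:
    def test_same_seed_bitwise_identical(self):
        model = _small_model(R=4, K=2)
        init = np.array([0, 0, 1, 1])
        r1 = model.fit(init_labels=init)
        r2 = model.fit(init_labels=init)
        for name in ("B", "labels", "p", "sigma2", "delta2"):
            assert np.array_equal(getattr(r1.samples, name), getattr(r2.samples, name))

    def test_retained_count(self):
        model = _small_model(R=3, K=2)
        res = model.fit(init_labels=np.array([0, 1, 0]))
        assert res.samples.n_draws == model.config.n_iter - model.config.n_burn

    def test_k1_collapses_to_pooled_gls(self):
        """With K=1 the posterior mean of beta_11 matches the pooled GLS
        estimate computed from the final variance draws' neighborhood."""
        rng = np.random.default_rng(21)
        S, R = 200, 4
        ages = np.linspace(9, 99, S)
        sex = np.tile([0, 1], S // 2)
        site = np.zeros(S, dtype=int)
        design = build_design(ages, sex)
        edges = edge_pairs(R)
        beta = np.array([-0.4, -0.1, 0.15, 0.05, 0.02])
        F = (design.X @ beta)[:, None] + 0.3 * rng.normal(size=(S, edges.shape[0]))
        cfg = GibbsConfig(n_iter=600, n_burn=300, seed=1)
        model = ClusterTrajectoryModel(F, design, site, edges, n_clusters=1, config=cfg)
        res = model.fit(init_labels=np.zeros(R, dtype=int))
        b_post = res.samples.B[:, :, 0, 0].mean(axis=0)
        # homoscedastic edges with shared beta: GLS reduces to pooled OLS
        pooled_beta = np.linalg.lstsq(design.X, F, rcond=None)[0].mean(axis=1)
        assert np.allclose(b_post, pooled_beta, atol=0.05)

    def test_undirected_edge_contract(self):
        """Swapping every edge's endpoint order leaves the chain identical."""
        model = _small_model(R=4, K=2)
        init = np.array([0, 1, 0, 1])
        r1 = model.fit(init_labels=init)
        swapped = model.edge_index[:, ::-1]
        model2 = ClusterTrajectoryModel(
            model.endog,
            model.design,
            model.site,
            swapped,
            n_clusters=2,
            config=model.config,
        )
        r2 = model2.fit(init_labels=init)
        assert np.array_equal(r1.samples.labels, r2.samples.labels)
        assert np.array_equal(r1.samples.B, r2.samples.B)

    def test_region_without_selected_edges_warns_and_uses_p(self):
        edges = np.array([[1, 0]])  # region 2 isolated
        rng = np.random.default_rng(22)
        S = 12
        design = build_design(np.linspace(10, 90, S), np.tile([0, 1], S // 2))
        with pytest.warns(UserWarning, match="region 2"):
            model = ClusterTrajectoryModel(
                rng.normal(size=(S, 1)),
                design,
                np.zeros(S, dtype=int),
                edges,
                n_clusters=2,
                config=GibbsConfig(n_iter=4, n_burn=2, rho0=1.0, varrho0=1.0),
                n_regions=3,
            )
        state = model.prior_draw(np.random.default_rng(23))
        probs = model.label_conditional_probs(state, 2)
        assert np.allclose(probs, state.p)
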