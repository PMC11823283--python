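"""Metropolis-within-Gibbs machinery: ratios, conjugacy, determinism."""

import numpy as np
import pytest
from scipy import stats

import dsfm
from dsfm.lq import lq_from_values
from dsfm.sampler import (ModelData, MWGSampler, SamplerConfig,
                          loadings_log_target)


def small_scenario(grid=(2, 2), n_times=3, seed=5, **kw):
    cfg = dsfm.TruthConfig(grid=grid, n_times=n_times, **kw)
    panel, truth = dsfm.simulate(cfg, seed=seed)
    graph = dsfm.lattice_graph(*grid)
    data = ModelData(panel, graph, dsfm.default_pattern())
    return panel, truth, graph, data


def randomized_sampler(data, seed=1, **cfg_kw):
    cfg_kw.setdefault("n_iter", 10)
    cfg_kw.setdefault("burn_in", 0)
    cfg_kw.setdefault("thin", 1)
    s = MWGSampler(data, SamplerConfig(seed=seed, **cfg_kw))
    rng = np.random.default_rng(100 + seed)
    st = s.state
    vals = np.where(data.pattern.mask,
                    0.5 * rng.standard_normal(data.pattern.mask.shape), 0.0)
    for (k, j) in data.pattern.anchors:
        vals[k, j] = abs(vals[k, j]) + 0.2
    st.gamma = vals
    st.lq = lq_from_values(vals[data.order], data.m)
    st.delta = rng.normal(size=st.delta.shape)
    st.delta -= st.delta.mean(axis=0, keepdims=True)
    st.mu = 0.1 * rng.normal(size=st.mu.shape)
    st.epsilon = 0.3 * rng.normal(size=st.epsilon.shape)
    s._loglam = s._full_loglam()
    return s


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            SamplerConfig(n_iter=10, burn_in=10)
        with pytest.raises(ValueError, match="thin"):
            SamplerConfig(n_iter=10, burn_in=0, thin=0)
        cfg = SamplerConfig(n_iter=100, burn_in=40, thin=7)
        assert cfg.n_retained == 8

    def test_production_defaults(self):
        cfg = SamplerConfig()
        assert (cfg.n_iter, cfg.burn_in, cfg.thin) == (500_000, 250_000, 50)
        assert cfg.n_retained == 5000


class TestLoadingsUpdate:
    def test_mh_ratio_matches_brute_force(self):
        """The Metropolis ratio for a loadings move equals an independent
        recomputation of likelihood x prior at both values, to 1e-10."""
        _, _, _, data = small_scenario()
        s = randomized_sampler(data)
        st = s.state
        rng = np.random.default_rng(77)

        def oracle_log_target(gamma):
            pair = lq_from_values(gamma[data.order], data.m)
            f_tilde = np.einsum("ab,ijb->ija", pair.Q, st.f)
            loglam = np.einsum("ijm,km->ijk", f_tilde,
                               pair.L)[:, :, data.inv_order] + st.epsilon
            mu = data.E * np.exp(loglam)
            ll = 0.0
            for i in range(data.I):
                for j in range(data.J):
                    for k in range(data.K):
                        if data.cens[i, j, k]:
                            ll += np.log(sum(
                                stats.poisson.pmf(y, mu[i, j, k])
                                for y in range(1, 6)))
                        else:
                            ll += stats.poisson.logpmf(
                                int(data.panel.counts[i, j, k]), mu[i, j, k])
            lp = float(np.sum(stats.norm.logpdf(
                gamma[data.pattern.mask], 0.0, 10.0)))
            return ll + lp

        for _ in range(5):
            k, j = data.pattern.free_positions()[
                rng.integers(len(data.pattern.free_positions()))]
            prop = st.gamma.copy()
            prop[k, j] += rng.normal(0, 0.3)
            if (k, j) in s.anchor_set and prop[k, j] <= 0:
                continue
            got = (loadings_log_target(prop, data, st.f, st.epsilon)
                   - loadings_log_target(st.gamma, data, st.f, st.epsilon))
            want = oracle_log_target(prop) - oracle_log_target(st.gamma)
            assert min(1.0, np.exp(got)) == pytest.approx(
                min(1.0, np.exp(want)), abs=1e-10)

    def test_nonpositive_anchor_has_zero_density(self):
        _, _, _, data = small_scenario()
        s = randomized_sampler(data)
        bad = s.state.gamma.copy()
        k, j = data.pattern.anchors[0]
        bad[k, j] = -0.1
        assert loadings_log_target(bad, data, s.state.f,
                                   s.state.epsilon) == -np.inf

    def test_structural_zeros_never_move(self):
        _, _, _, data = small_scenario()
        s = randomized_sampler(data, n_iter=60, burn_in=30)
        for it in range(60):
            s.sweep(it)
        assert np.all(s.state.gamma[~data.pattern.mask] == 0.0)

    def test_lq_pair_tracks_loadings(self):
        _, _, _, data = small_scenario()
        s = randomized_sampler(data, n_iter=40, burn_in=20)
        for it in range(40):
            s.sweep(it)
        st = s.state
        recon = (st.lq.L @ st.lq.Q)[data.inv_order]
        assert np.max(np.abs(recon - st.gamma)) < 1e-10


class TestLikelihoodIdentity:
    def test_lq_likelihood_equals_gamma_likelihood_along_chain(self):
        """f(y|L,Q,F,eps) == f(y|Gamma,F,eps) at every retained state: the
        operational content of enforcing the decomposition."""
        from dsfm.sampler import _cell_loglik, _loglik_via_lq
        _, _, _, data = small_scenario()
        s = randomized_sampler(data, n_iter=30, burn_in=0)
        for it in range(30):
            s.sweep(it)
            st = s.state
            via_lq = _loglik_via_lq(st.lq, data, st.f, st.epsilon)
            loglam = np.einsum("ijm,km->ijk", st.f, st.gamma) + st.epsilon
            direct = float(np.sum(_cell_loglik(
                loglam, data.E, data.logE, data.y, data.cens, data.lgy)))
            assert abs(via_lq - direct) < 1e-8


class TestSigma2Conjugacy:
    def test_moments_of_conditional_draws(self):
        """With eps = 0 and n = 100 cells per outcome the conditional is
        Inv-Gamma(50.5, 0.5); sample mean of 100k draws within 2% of
        0.5/49.5."""
        _, _, _, data = small_scenario(grid=(2, 2), n_times=25)
        assert data.I * data.J == 100
        s = randomized_sampler(data, seed=3)
        s.state.epsilon[:] = 0.0
        draws = np.empty((100_000, data.K))
        for t in range(draws.shape[0]):
            s._update_sigma2()
            draws[t] = s.state.sigma2
        want = 0.5 / 49.5
        assert np.all(np.abs(draws.mean(axis=0) - want) < 0.02 * want)

    def test_scale_parameter_uses_sum_of_squares(self):
        """Conditional scale is 0.5 + sum(eps^2)/2 exactly: with a huge
        shape the draws concentrate at scale/shape."""
        _, _, _, data = small_scenario(grid=(5, 5), n_times=8)
        s = randomized_sampler(data, seed=4)
        rng = np.random.default_rng(12)
        s.state.epsilon = rng.normal(0, 0.5, size=s.state.epsilon.shape)
        brute = 0.5 + 0.5 * np.array(
            [sum(s.state.epsilon[i, j, k] ** 2
                 for i in range(data.I) for j in range(data.J))
             for k in range(data.K)])
        shape = 0.5 + 0.5 * data.I * data.J
        draws = np.empty((4000, data.K))
        for t in range(draws.shape[0]):
            s._update_sigma2()
            draws[t] = s.state.sigma2
        # Inv-Gamma mean = scale/(shape-1)
        want = brute / (shape - 1.0)
        assert np.allclose(draws.mean(axis=0), want, rtol=0.05)


class TestPriorOnlyChains:
    def test_eta_uniform_and_sigma2_invgamma_marginals(self):
        """With the likelihood switched off the chain targets the prior:
        eta draws match Uniform(0,1), sigma2 draws match Inv-Gamma(.5,.5)
        (KS at p > 0.01 on thinned draws)."""
        cfg = dsfm.TruthConfig(grid=(2, 2), n_times=1)
        panel, _ = dsfm.simulate(cfg, seed=2)
        data = ModelData(panel, dsfm.lattice_graph(2, 2),
                         dsfm.default_pattern())
        s = MWGSampler(data, SamplerConfig(
            n_iter=30000, burn_in=6000, thin=12, seed=8, prior_only=True,
            store_fields=False, n_factor_sweeps=1))
        out = s.run()
        ks_eta = stats.kstest(out.eta[:, 0], stats.uniform.cdf)
        assert ks_eta.pvalue > 0.01
        ks_sig = stats.kstest(out.sigma2[:, 0],
                              stats.invgamma(a=0.5, scale=0.5).cdf)
        assert ks_sig.pvalue > 0.01

    def test_factor_moves_preserve_icar_prior(self):
        """Site walks plus elliptical-slice refreshes, run prior-only on a
        3x3 lattice with one year, reproduce the ICAR marginal variances
        (diagonal of the Laplacian pseudo-inverse)."""
        cfg = dsfm.TruthConfig(grid=(3, 3), n_times=1)
        panel, _ = dsfm.simulate(cfg, seed=4)
        g = dsfm.lattice_graph(3, 3)
        data = ModelData(panel, g, dsfm.default_pattern())
        out = MWGSampler(data, SamplerConfig(
            n_iter=12000, burn_in=2000, thin=5, seed=3,
            prior_only=True)).run()
        delta = out.F[:, :, 0, 0] - out.mu[:, None, 0, 0]
        target = np.diag(np.linalg.pinv(g.laplacian()))
        emp = delta.var(axis=0)
        assert np.max(np.abs(emp - target) / target) < 0.15

    def test_eta_reflection_stays_inside_unit_interval(self):
        assert MWGSampler._reflect01(1.3) == pytest.approx(0.7)
        assert MWGSampler._reflect01(-0.2) == pytest.approx(0.2)
        assert MWGSampler._reflect01(2.6) == pytest.approx(0.6)
        rng = np.random.default_rng(0)
        for x in rng.normal(0, 5, size=200):
            assert 0.0 <= MWGSampler._reflect01(x) <= 1.0


class TestEpsilonUpdate:
    def test_stationary_matches_quadrature_posterior(self):
        """One cell's eps chain against a fine-grid quadrature of
        Poisson(y; E e^(gf+eps)) x N(0, s2): CDF sup-distance < 0.02."""
        _, _, _, data = small_scenario(grid=(2, 2), n_times=1,
                                       sigma2=np.full(6, 1.0))
        s = randomized_sampler(data, seed=6)
        st = s.state
        st.sigma2 = np.ones(data.K)
        draws = np.empty(50_000)
        for t in range(draws.size):
            s._update_epsilon(t)  # adapts during the default burn_in window
            draws[t] = st.epsilon[0, 0, 0]
        draws = draws[10_000:]
        # quadrature target for that cell
        y = data.y[0, 0, 0]
        E = data.E[0, 0, 0]
        base = float(np.einsum("m,m->", st.gamma[0], st.f[0, 0]))
        grid = np.linspace(-8, 8, 4001)
        mu = E * np.exp(base + grid)
        logpost = y * np.log(mu) - mu - 0.5 * grid ** 2
        post = np.exp(logpost - logpost.max())
        cdf = np.cumsum(post)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(draws), grid) / draws.size
        assert np.max(np.abs(emp - cdf)) < 0.02


class TestEtaUpdate:
    def test_recovers_ordering_of_temporal_persistence(self):
        """Chains fit to data generated with high vs low AR coefficients
        order their posterior means accordingly."""
        means = {}
        for eta_true in (0.9, 0.1):
            cfg = dsfm.TruthConfig(grid=(6, 6), n_times=5,
                                   eta=np.full(4, eta_true))
            panel, _ = dsfm.simulate(cfg, seed=21)
            data = ModelData(panel, dsfm.lattice_graph(6, 6),
                             dsfm.default_pattern())
            out = MWGSampler(data, SamplerConfig(
                n_iter=2500, burn_in=1000, thin=5, seed=9,
                store_fields=False, n_factor_sweeps=1)).run()
            means[eta_true] = out.eta.mean()
        assert means[0.9] > means[0.1]


class TestRun:
    def test_retained_draw_count_and_determinism(self):
        panel, _, graph, _ = small_scenario()
        cfg = dict(n_iter=10, burn_in=0, thin=1, seed=5)
        s1 = dsfm.run(panel, graph, dsfm.default_pattern(),
                      SamplerConfig(**cfg))
        s2 = dsfm.run(panel, graph, dsfm.default_pattern(),
                      SamplerConfig(**cfg))
        assert s1.n_draws == 10
        for name in ("gamma", "L", "mu", "eta", "sigma2", "F", "F_tilde",
                     "epsilon"):
            assert np.array_equal(getattr(s1, name), getattr(s2, name)), name

    def test_retained_L_is_identified_representative(self):
        panel, _, graph, _ = small_scenario()
        out = dsfm.run(panel, graph, dsfm.default_pattern(),
                       SamplerConfig(n_iter=30, burn_in=10, thin=2, seed=5))
        m = 4
        for L in out.L:
            lead = L[:m]
            assert np.all(np.diag(lead) > 0)
            assert np.max(np.abs(lead - np.tril(lead))) == 0.0
        # convergence diagnostics are informational but must be well formed
        from dsfm.sampler import diagnostics
        diag = diagnostics(out)
        assert len(diag) == 4 + 6  # eta per factor, sigma2 per outcome
        assert np.all(np.isfinite(diag["ess"]))

    def test_invalid_inputs_fail_before_sampling(self):
        panel, _, graph, _ = small_scenario()
        pat = dsfm.default_pattern()
        bad = dsfm.LoadingsPattern(mask=pat.mask, anchors=pat.anchors,
                                   outcome_order=(2, 3, 4, 5, 0, 1))
        with pytest.raises(ValueError, match="pattern"):
            dsfm.run(panel, graph, bad, SamplerConfig(n_iter=4, burn_in=0))
        small_graph = dsfm.lattice_graph(2, 3)
        with pytest.raises(ValueError, match="units"):
            dsfm.run(panel, small_graph, pat, SamplerConfig(n_iter=4, burn_in=0))


class TestSummarize:
    def _samples(self, chains):
        pat = dsfm.default_pattern()
        S = chains["gamma"].shape[0]
        return dsfm.PosteriorSamples(
            gamma=chains["gamma"], L=chains.get("L", chains["gamma"]),
            mu=np.zeros((S, 2, 4)), eta=np.full((S, 4), 0.5),
            sigma2=np.ones((S, 6)), F=None, F_tilde=None, epsilon=None,
            acceptance={}, pattern=pat,
            config=SamplerConfig(n_iter=S, burn_in=0, thin=1))

    def test_constant_chain(self):
        gamma = np.zeros((5, 6, 4))
        gamma[:, 0, 0] = 3.25
        table = dsfm.summarize(self._samples({"gamma": gamma}))
        row = table[table.parameter.str.startswith("gamma[outcome0,1")].iloc[0]
        assert (row["mean"], row["lo95"], row["hi95"]) == (3.25, 3.25, 3.25)

    def test_percentiles_match_sort_oracle(self):
        gamma = np.zeros((1000, 6, 4))
        chain = np.arange(1.0, 1001.0)
        gamma[:, 0, 0] = chain
        table = dsfm.summarize(self._samples({"gamma": gamma}))
        row = table.iloc[0]
        srt = np.sort(chain)

        def quantile(q):  # linear interpolation oracle
            pos = q * (len(srt) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(srt) - 1)
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        assert row["lo95"] == pytest.approx(quantile(0.025))
        assert row["hi95"] == pytest.approx(quantile(0.975))

    def test_structural_zeros_reported_as_exact_zero(self):
        gamma = np.random.default_rng(0).normal(size=(50, 6, 4))
        table = dsfm.summarize(self._samples({"gamma": gamma}))
        zero_rows = table[table.parameter == "gamma[outcome0,3]"]
        assert len(zero_rows) == 1
        assert (zero_rows.iloc[0][["mean", "lo95", "hi95"]] == 0).all()

    def test_too_few_draws(self):
        gamma = np.zeros((1, 6, 4))
        with pytest.raises(ValueError, match="two"):
            dsfm.summarize(self._samples({"gamma": gamma}))
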