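"""Metropolis-within-Gibbs sampler for the dynamic spatial factor model.

Target posterior (up to proportionality):

    pi(Gamma, F, eps, mu, eta, sigma2 | y)
      = f(y | L(Gamma), Q(Gamma), F, eps) pi(Gamma) pi(F | mu, eta)
        pi(eps | sigma2) pi(mu, eta, sigma2),

where the likelihood is evaluated through the LQ decomposition of the
loadings — every proposed Gamma is decomposed, a rank-deficient leading
block is treated as outside the support — so the chain lives on the
identified parameterisation while reporting both raw and identified draws.

Blocks per sweep, in order: loadings (scalar random-walk MH per free entry,
Algorithm-style with per-proposal LQ), factor sites (random-walk MH swept by
graph colour so that non-neighbouring units update simultaneously), the
cell-level noise field (independent random-walk MH per cell), yearly factor
means mu (random-walk MH against the likelihood; their prior is flat and
the intrinsic innovation density carries no information about a level
shift), AR coefficients eta (random-walk MH with reflection at 0 and 1),
and the noise variances sigma2 (exact conjugate inverse-gamma draws).

Proposal scales adapt per site toward 0.44 acceptance during burn-in only
(Robbins-Monro on the log scale) and are frozen afterwards, preserving the
stationary target for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .lq import LQPair, RankDeficientError, lq_from_values, validate_pattern
from .model import (CountPanel, LoadingsPattern, baseline_rates,
                    censored_interval_loglik, expected_counts)
from .prior import AdjacencyGraph, FactorField

#: Prior standard deviation of each free loading (zero-mean normal; anchors
#: truncated to the positive half-line).
LOADINGS_PRIOR_SD = 10.0
#: Inverse-gamma prior on each outcome's noise variance.
SIGMA2_PRIOR_SHAPE = 0.5
SIGMA2_PRIOR_SCALE = 0.5
#: Site-wise acceptance rate targeted by the burn-in adaptation.
TARGET_ACCEPT = 0.44
#: Bounds on adapted log proposal scales (keeps degenerate targets, e.g. a
#: flat direction, from driving a scale to overflow).
LS_MIN, LS_MAX = -12.0, 3.0

DEFAULT_PROPOSAL_SD = {
    "loadings": 0.1,
    "factors": 0.5,
    "epsilon": 0.5,
    "mu": 0.1,
    "eta": 0.1,
}


@dataclass
class SamplerConfig:
    """Chain-length and proposal settings.

    Defaults mirror a production surveillance run (500k iterations, half
    discarded, every 50th retained); tests and examples override them with
    desk-scale values.
    """

    n_iter: int = 500_000
    burn_in: int = 250_000
    thin: int = 50
    proposal_sd: dict = field(default_factory=lambda: dict(DEFAULT_PROPOSAL_SD))
    adapt: bool = True
    seed: int = 0
    prior_only: bool = False
    store_fields: bool = True
    log_every: int = 0  # 0 = silent
    #: extra site sub-sweeps over the factor fields per iteration (the
    #: fields mix slowest; >1 trades time for mixing)
    n_factor_sweeps: int = 1
    #: complement the site-wise walks with one elliptical-slice refresh of
    #: each (year, factor) field per iteration: rejection-free global moves
    #: that keep a weakly loaded factor aligned with its outcome residuals
    ess: bool = True

    def __post_init__(self):
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        sd = dict(DEFAULT_PROPOSAL_SD)
        sd.update(self.proposal_sd or {})
        if any(v <= 0 for v in sd.values()):
            raise ValueError("proposal standard deviations must be positive")
        self.proposal_sd = sd

    @property
    def n_retained(self):
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws and bookkeeping from one chain."""

    gamma: np.ndarray        # (S, K, m)
    L: np.ndarray            # (S, K, m) identified loadings (ordered outcomes)
    mu: np.ndarray           # (S, J, m)
    eta: np.ndarray          # (S, m)
    sigma2: np.ndarray       # (S, K)
    F: np.ndarray | None     # (S, I, J, m)
    F_tilde: np.ndarray | None
    epsilon: np.ndarray | None
    acceptance: dict
    pattern: LoadingsPattern
    config: SamplerConfig

    @property
    def n_draws(self):
        return self.gamma.shape[0]


@dataclass
class ModelState:
    """Current values of every parameter block plus cached quantities."""

    gamma: np.ndarray
    lq: LQPair
    delta: np.ndarray   # (I, J, m), sum-to-zero over units per (year, factor)
    mu: np.ndarray      # (J, m)
    eta: np.ndarray     # (m,)
    sigma2: np.ndarray  # (K,)
    epsilon: np.ndarray  # (I, J, K)

    @property
    def f(self):
        return self.mu[None, :, :] + self.delta

    def factor_field(self) -> FactorField:
        return FactorField(f=self.f)


class ModelData:
    """Immutable data bundle consumed by the sampler."""

    def __init__(self, panel: CountPanel, graph: AdjacencyGraph,
                 pattern: LoadingsPattern, baseline_time: int = 0,
                 rates: np.ndarray | None = None):
        diag = validate_pattern(pattern)
        if not diag:
            msg = f"invalid loadings pattern: {diag.message}"
            if diag.suggested_order is not None:
                msg += f"; a valid outcome order is {diag.suggested_order}"
            raise ValueError(msg)
        if graph.n_units != panel.n_units:
            raise ValueError("graph and panel disagree on the number of units")
        self.panel = panel
        self.graph = graph
        self.pattern = pattern
        if rates is None:
            rates = baseline_rates(panel, baseline_time)
        self.expected = expected_counts(panel, rates)
        self.E = self.expected.expected
        self.logE = np.log(self.E)
        self.y = panel.counts.astype(float)
        self.cens = panel.censored
        self.y[self.cens] = 0.0
        self.lgy = gammaln(self.y + 1.0)
        self.lgy[self.cens] = 0.0
        self.order = np.asarray(pattern.outcome_order, dtype=np.int64)
        self.inv_order = np.argsort(self.order)
        self.I, self.J, self.K = panel.shape
        self.m = pattern.n_factors
        # outcomes touched by each factor, in data order
        self.factor_outcomes = [np.where(pattern.mask[:, mm])[0]
                                for mm in range(self.m)]
        # contiguous per-factor views of the data arrays, (I, J, n_outcomes)
        self.sub = [tuple(np.ascontiguousarray(a[:, :, ks])
                          for a in (self.E, self.logE, self.y,
                                    self.cens, self.lgy))
                    for ks in self.factor_outcomes]


def _cell_loglik(loglam, E, logE, y, cens, lgy):
    """Per-cell observation log-likelihood at log relative risk ``loglam``."""
    mu = E * np.exp(loglam)
    ll = y * (logE + loglam) - mu - lgy
    if cens.any():
        ll[cens] = censored_interval_loglik(mu[cens])
    return ll


def loadings_log_target(gamma: np.ndarray, data: ModelData, f: np.ndarray,
                        epsilon: np.ndarray) -> float:
    """log[ f(y | L(Gamma), Q(Gamma), F, eps) * pi(Gamma) ] for a conforming
    loadings value; -inf if an anchor is nonpositive, raises
    RankDeficientError if the leading block is singular.

    Exposed as a pure function so the Metropolis ratio used inside the
    sampler can be recomputed independently.
    """
    for (k, j) in data.pattern.anchors:
        if gamma[k, j] <= 0:
            return -math.inf
    pair = lq_from_values(gamma[data.order], data.m)
    ll = _loglik_via_lq(pair, data, f, epsilon)
    free = data.pattern.mask
    lp = -0.5 * float(np.sum((gamma[free] / LOADINGS_PRIOR_SD) ** 2))
    return ll + lp


def _loglik_via_lq(pair: LQPair, data: ModelData, f: np.ndarray,
                   epsilon: np.ndarray) -> float:
    """Observation log-likelihood computed through the identified (L, Q)."""
    f_tilde = np.einsum("ab,ijb->ija", pair.Q, f)
    loglam_ord = np.einsum("ijm,km->ijk", f_tilde, pair.L)
    loglam = loglam_ord[:, :, data.inv_order] + epsilon
    return float(np.sum(_cell_loglik(loglam, data.E, data.logE, data.y,
                                     data.cens, data.lgy)))


class MWGSampler:
    """Metropolis-within-Gibbs sampler bound to one data bundle."""

    def __init__(self, data: ModelData, config: SamplerConfig):
        self.data = data
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        I, J, K, m = data.I, data.J, data.K, data.m
        # --- initial state: neutral and reproducible
        gamma = np.zeros((K, m))
        for (k, j) in data.pattern.anchors:
            gamma[k, j] = 1.0
        pair = lq_from_values(gamma[data.order], m)
        self.state = ModelState(
            gamma=gamma, lq=pair,
            delta=np.zeros((I, J, m)), mu=np.zeros((J, m)),
            eta=np.full(m, 0.5), sigma2=np.ones(K),
            epsilon=np.zeros((I, J, K)))
        # --- per-site log proposal scales
        sd = config.proposal_sd
        self.ls_gamma = np.full((K, m), math.log(sd["loadings"]))
        self.ls_f = np.full((I, J, m), math.log(sd["factors"]))
        self.ls_eps = np.full((I, J, K), math.log(sd["epsilon"]))
        self.ls_mu = np.full((J, m), math.log(sd["mu"]))
        self.ls_eta = np.full(m, math.log(sd["eta"]))
        self.free = data.pattern.free_positions()
        self.anchor_set = set(data.pattern.anchors)
        self._acc = {b: 0 for b in ("loadings", "factors", "epsilon", "mu", "eta")}
        self._tot = {b: 0 for b in ("loadings", "factors", "epsilon", "mu", "eta")}
        self._icar_root_cache = None
        self._loglam = self._full_loglam()

    # -- caches ------------------------------------------------------------

    def _full_loglam(self):
        st = self.state
        return (np.einsum("ijm,km->ijk", st.f, st.gamma) + st.epsilon)

    def _ll_cells(self, loglam, sub=None):
        d = self.data
        if self.config.prior_only:
            return np.zeros(np.shape(loglam))
        if sub is None:
            return _cell_loglik(loglam, d.E, d.logE, d.y, d.cens, d.lgy)
        E, logE, y, cens, lgy = sub
        return _cell_loglik(loglam, E, logE, y, cens, lgy)

    def _adapt_step(self, it):
        return min(0.1, 2.0 / math.sqrt(it + 10.0))

    # -- loadings ----------------------------------------------------------

    def _update_loadings(self, it):
        st, d, cfg = self.state, self.data, self.config
        if cfg.prior_only:
            cur_ll = 0.0
        else:
            cur_ll = _loglik_via_lq(st.lq, d, st.f, st.epsilon)
        step = self._adapt_step(it) if (cfg.adapt and it < cfg.burn_in) else 0.0
        for (k, j) in self.free:
            cur = st.gamma[k, j]
            prop = cur + math.exp(self.ls_gamma[k, j]) * self.rng.standard_normal()
            self._tot["loadings"] += 1
            accepted = False
            if (k, j) in self.anchor_set and prop <= 0:
                pass  # zero prior density: auto-reject
            else:
                g_prop = st.gamma.copy()
                g_prop[k, j] = prop
                try:
                    pair = lq_from_values(g_prop[d.order], d.m)
                except RankDeficientError:
                    pair = None  # outside the identified support
                if pair is not None:
                    if cfg.prior_only:
                        prop_ll = 0.0
                    else:
                        prop_ll = _loglik_via_lq(pair, d, st.f, st.epsilon)
                    dlp = -0.5 * ((prop / LOADINGS_PRIOR_SD) ** 2
                                  - (cur / LOADINGS_PRIOR_SD) ** 2)
                    log_acc = prop_ll - cur_ll + dlp
                    if math.log(self.rng.random()) < log_acc:
                        st.gamma = g_prop
                        st.lq = pair
                        cur_ll = prop_ll
                        accepted = True
            if accepted:
                self._acc["loadings"] += 1
            if step:
                self.ls_gamma[k, j] = np.clip(
                    self.ls_gamma[k, j] + step * ((1.0 if accepted else 0.0)
                                                  - TARGET_ACCEPT),
                    LS_MIN, LS_MAX)
        if not cfg.prior_only:
            self._loglam = self._full_loglam()

    # -- factor sites ------------------------------------------------------

    def _update_factors(self, it):
        st, d, cfg = self.state, self.data, self.config
        step = self._adapt_step(it) if (cfg.adapt and it < cfg.burn_in) else 0.0
        for mm in range(d.m):
            ks = d.factor_outcomes[mm]
            gam = st.gamma[ks, mm]
            eta = st.eta[mm]
            for j in range(d.J):
                for S in d.graph.coloring:
                    nS = len(S)
                    sd = np.exp(self.ls_f[S, j, mm])
                    dlt = sd * self.rng.standard_normal(nS)
                    # likelihood over outcomes this factor touches
                    if cfg.prior_only:
                        dll = np.zeros(nS)
                    else:
                        ll_old = self._ll_slab(S, j, mm)
                        ll_new = self._ll_slab(S, j, mm,
                                               shift=np.outer(dlt, gam))
                        dll = (ll_new - ll_old).sum(axis=1)
                    # innovation prior: year j term, and year j+1 carry-over
                    dlp = self._dlp_innovation(mm, j, S, dlt, eta)
                    log_acc = dll + dlp
                    acc = np.log(self.rng.random(nS)) < log_acc
                    self._acc["factors"] += int(acc.sum())
                    self._tot["factors"] += nS
                    if acc.any():
                        Sa = S[acc]
                        st.delta[Sa, j, mm] += dlt[acc]
                        if not cfg.prior_only:
                            self._loglam[np.ix_(Sa, [j], ks)] += \
                                np.outer(dlt[acc], gam)[:, None, :]
                    if step:
                        self.ls_f[S, j, mm] = np.clip(
                            self.ls_f[S, j, mm] + step * (acc - TARGET_ACCEPT),
                            LS_MIN, LS_MAX)
        # re-impose the centering constraint by re-attributing the level to
        # mu: f = mu + delta is unchanged, so the likelihood is untouched
        shift = st.delta.mean(axis=0, keepdims=True)
        st.mu += shift[0]
        st.delta -= shift
        self._loglam = self._full_loglam()  # refresh against round-off drift

    def _ll_slab(self, S, j, mm, shift=None):
        """Per-cell log-likelihood over units S (None = all), one year, and
        the outcomes factor ``mm`` touches."""
        d = self.data
        E, logE, y, cens, lgy = d.sub[mm]
        ks = d.factor_outcomes[mm]
        ll_j = self._loglam[:, j, :]
        if S is None:
            loglam = ll_j[:, ks]
            sub = (E[:, j], logE[:, j], y[:, j], cens[:, j], lgy[:, j])
        else:
            loglam = ll_j[S[:, None], ks[None, :]]
            sub = (E[S, j], logE[S, j], y[S, j], cens[S, j], lgy[S, j])
        if shift is not None:
            loglam = loglam + shift
        return self._ll_cells(loglam, sub)

    def _dlp_innovation(self, mm, j, S, dlt, eta):
        """Change in the ICAR innovation quadratic when delta[S, j, mm] moves
        by ``dlt`` (colour class: S contains no adjacent pair)."""
        st, d = self.state, self.data
        A, deg = d.graph.adjacency, d.graph.degrees
        dmat = st.delta[:, :, mm]
        out = np.zeros(len(S))
        # year-j innovation: e_j = delta_j - eta * delta_{j-1}
        e = dmat[:, j] - (eta * dmat[:, j - 1] if j > 0 else 0.0)
        s = A @ e
        out += -0.5 * ((2.0 * e[S] * dlt + dlt ** 2) * deg[S] - 2.0 * dlt * s[S])
        if j + 1 < d.J:
            e2 = dmat[:, j + 1] - eta * dmat[:, j]
            s2 = A @ e2
            d2 = -eta * dlt
            out += -0.5 * ((2.0 * e2[S] * d2 + d2 ** 2) * deg[S] - 2.0 * d2 * s2[S])
        return out

    # -- cell noise --------------------------------------------------------

    def _update_epsilon(self, it):
        st, d, cfg = self.state, self.data, self.config
        if cfg.prior_only:
            # without a likelihood the full conditional is exactly N(0, s2):
            # draw it directly so heavy-tailed sigma2 excursions mix
            st.epsilon = (np.sqrt(st.sigma2)[None, None, :]
                          * self.rng.standard_normal(st.epsilon.shape))
            self._acc["epsilon"] += st.epsilon.size
            self._tot["epsilon"] += st.epsilon.size
            return
        sd = np.exp(self.ls_eps)
        dz = sd * self.rng.standard_normal(st.epsilon.shape)
        dll = (self._ll_cells(self._loglam + dz)
               - self._ll_cells(self._loglam))
        eps_new = st.epsilon + dz
        dlp = -0.5 * (eps_new ** 2 - st.epsilon ** 2) / st.sigma2[None, None, :]
        acc = np.log(self.rng.random(st.epsilon.shape)) < dll + dlp
        st.epsilon = np.where(acc, eps_new, st.epsilon)
        self._loglam = np.where(acc, self._loglam + dz, self._loglam)
        self._acc["epsilon"] += int(acc.sum())
        self._tot["epsilon"] += acc.size
        if cfg.adapt and it < cfg.burn_in:
            self.ls_eps = np.clip(
                self.ls_eps + self._adapt_step(it) * (acc - TARGET_ACCEPT),
                LS_MIN, LS_MAX)

    # -- yearly means ------------------------------------------------------

    def _update_mu(self, it):
        """Random-walk MH on each mu[j, m] against the likelihood (flat prior;
        the intrinsic innovation quadratic is invariant to the level)."""
        st, d, cfg = self.state, self.data, self.config
        step = self._adapt_step(it) if (cfg.adapt and it < cfg.burn_in) else 0.0
        for mm in range(d.m):
            ks = d.factor_outcomes[mm]
            gam = st.gamma[ks, mm]
            for j in range(d.J):
                dmu = math.exp(self.ls_mu[j, mm]) * self.rng.standard_normal()
                self._tot["mu"] += 1
                if cfg.prior_only:
                    dll = 0.0
                else:
                    shift = np.broadcast_to(dmu * gam, (d.I, len(ks)))
                    ll_old = self._ll_slab(None, j, mm)
                    ll_new = self._ll_slab(None, j, mm, shift=shift)
                    dll = float((ll_new - ll_old).sum())
                accepted = math.log(self.rng.random()) < dll
                if accepted:
                    st.mu[j, mm] += dmu
                    if not cfg.prior_only:
                        self._loglam[:, j, ks] += dmu * gam[None, :]
                    self._acc["mu"] += 1
                if step:
                    self.ls_mu[j, mm] = np.clip(
                        self.ls_mu[j, mm] + step * ((1.0 if accepted else 0.0)
                                                    - TARGET_ACCEPT),
                        LS_MIN, LS_MAX)

    # -- AR coefficients ---------------------------------------------------

    def _eta_log_target(self, mm, eta):
        """Innovation log-density terms involving eta_m (years >= 2)."""
        st, d = self.state, self.data
        if d.J < 2:
            return 0.0
        dmat = st.delta[:, :, mm]
        e = dmat[:, 1:] - eta * dmat[:, :-1]
        u, v = d.graph.edges[:, 0], d.graph.edges[:, 1]
        diff = e[u] - e[v]
        return -0.5 * float(np.sum(diff * diff))

    @staticmethod
    def _reflect01(x):
        x = math.fmod(x, 2.0)
        if x < 0:
            x += 2.0
        return 2.0 - x if x > 1.0 else x

    def _update_eta(self, it):
        st, cfg = self.state, self.config
        step = self._adapt_step(it) if (cfg.adapt and it < cfg.burn_in) else 0.0
        for mm in range(self.data.m):
            prop = self._reflect01(st.eta[mm] + math.exp(self.ls_eta[mm])
                                   * self.rng.standard_normal())
            self._tot["eta"] += 1
            accepted = False
            if 0.0 < prop < 1.0:
                log_acc = (self._eta_log_target(mm, prop)
                           - self._eta_log_target(mm, st.eta[mm]))
                if math.log(self.rng.random()) < log_acc:
                    st.eta[mm] = prop
                    accepted = True
            if accepted:
                self._acc["eta"] += 1
            if step:
                self.ls_eta[mm] = np.clip(
                    self.ls_eta[mm] + step * ((1.0 if accepted else 0.0)
                                              - TARGET_ACCEPT),
                    LS_MIN, LS_MAX)

    # -- noise variances ---------------------------------------------------

    def _update_sigma2(self):
        """Exact conjugate draw: sigma2_k | eps ~ Inv-Gamma(a0 + n_k/2,
        b0 + sum(eps_k^2)/2)."""
        st, d = self.state, self.data
        n_k = d.I * d.J
        shape = SIGMA2_PRIOR_SHAPE + 0.5 * n_k
        scale = SIGMA2_PRIOR_SCALE + 0.5 * np.sum(st.epsilon ** 2, axis=(0, 1))
        st.sigma2 = scale / self.rng.gamma(shape, 1.0, size=d.K)

    # -- driver ------------------------------------------------------------

    # -- elliptical slice refresh of whole factor-year fields --------------

    @property
    def _icar_root(self):
        """Pseudo-inverse square root of the Laplacian (zero-sum subspace)."""
        if self._icar_root_cache is None:
            from .prior import _icar_sqrt_cov
            self._icar_root_cache = _icar_sqrt_cov(self.data.graph)
        return self._icar_root_cache

    def _ess_factor_year(self, mm, j):
        """Elliptical slice update of delta[:, j, mm] given everything else.

        The conditional prior of one year's field given its temporal
        neighbours is Gaussian on the sum-to-zero subspace: precision
        (1 + eta^2) (D - W) for interior years (eta^2 from the year j+1
        innovation), (D - W) for the final year, with conditional mean
        eta/(1+eta^2) (delta_{j-1} + delta_{j+1}) (terms that exist).
        Slice sampling on the ellipse through the current state and a prior
        draw targets prior x likelihood exactly and never rejects.
        """
        st, d, cfg = self.state, self.data, self.config
        eta = st.eta[mm]
        dm = st.delta[:, :, mm]
        ks = d.factor_outcomes[mm]
        gam = st.gamma[ks, mm]
        last = d.J - 1
        if j < last:
            prec = 1.0 + eta * eta
            mean = (eta / prec) * ((dm[:, j - 1] if j > 0 else 0.0)
                                   + dm[:, j + 1])
        else:
            prec = 1.0
            mean = eta * dm[:, j - 1] if j > 0 else np.zeros(d.I)
        mean = np.asarray(mean) if np.ndim(mean) else np.full(d.I, mean)
        nu = (self._icar_root @ self.rng.standard_normal(
            self._icar_root.shape[1])) / math.sqrt(prec)
        cur = dm[:, j].copy()
        # hoist the year slices: they are invariant over the slice shrinkage
        E, logE, y, cens, lgy = d.sub[mm]
        sub = (E[:, j], logE[:, j], y[:, j], cens[:, j], lgy[:, j])
        base = self._loglam[:, j, :][:, ks]

        def llh(vec):
            if cfg.prior_only:
                return 0.0
            loglam = base + np.outer(vec - cur, gam)
            return float(np.sum(_cell_loglik(loglam, *sub)))

        log_y = llh(cur) + math.log(self.rng.random())
        theta = self.rng.uniform(0.0, 2.0 * math.pi)
        lo, hi = theta - 2.0 * math.pi, theta
        r = cur - mean
        for _ in range(100):
            prop = mean + r * math.cos(theta) + nu * math.sin(theta)
            if llh(prop) > log_y:
                break
            if theta < 0:
                lo = theta
            else:
                hi = theta
            theta = self.rng.uniform(lo, hi)
        else:  # pathological shrinkage: keep the current state
            prop = cur
        if prop is not cur:
            if not cfg.prior_only:
                self._loglam[:, j, ks] += np.outer(prop - cur, gam)
            st.delta[:, j, mm] = prop

    def _update_factors_ess(self, it):
        for mm in range(self.data.m):
            for j in range(self.data.J):
                self._ess_factor_year(mm, j)
        st = self.state
        shift = st.delta.mean(axis=0, keepdims=True)
        st.mu += shift[0]
        st.delta -= shift
        if not self.config.prior_only:
            self._loglam = self._full_loglam()

    def sweep(self, it):
        self._update_loadings(it)
        for _ in range(self.config.n_factor_sweeps):
            self._update_factors(it)
        if self.config.ess:
            self._update_factors_ess(it)
        self._update_epsilon(it)
        self._update_mu(it)
        self._update_eta(it)
        self._update_sigma2()

    def acceptance_rates(self):
        return {b: (self._acc[b] / self._tot[b] if self._tot[b] else float("nan"))
                for b in self._acc}

    def run(self) -> PosteriorSamples:
        cfg, d = self.config, self.data
        S = cfg.n_retained
        I, J, K, m = d.I, d.J, d.K, d.m
        out_gamma = np.empty((S, K, m))
        out_L = np.empty((S, K, m))
        out_mu = np.empty((S, J, m))
        out_eta = np.empty((S, m))
        out_sig = np.empty((S, K))
        if cfg.store_fields:
            out_F = np.empty((S, I, J, m))
            out_Ft = np.empty((S, I, J, m))
            out_eps = np.empty((S, I, J, K))
        else:
            out_F = out_Ft = out_eps = None
        s = 0
        for it in range(cfg.n_iter):
            self.sweep(it)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and s < S:
                st = self.state
                out_gamma[s] = st.gamma
                out_L[s] = st.lq.L
                out_mu[s] = st.mu
                out_eta[s] = st.eta
                out_sig[s] = st.sigma2
                if cfg.store_fields:
                    f = st.f
                    out_F[s] = f
                    out_Ft[s] = np.einsum("ab,ijb->ija", st.lq.Q, f)
                    out_eps[s] = st.epsilon
                s += 1
            if cfg.log_every and (it + 1) % cfg.log_every == 0:
                rates = ", ".join(f"{b}={r:.2f}"
                                  for b, r in self.acceptance_rates().items())
                print(f"iter {it + 1}/{cfg.n_iter}  acceptance: {rates}",
                      flush=True)
        return PosteriorSamples(
            gamma=out_gamma[:s], L=out_L[:s], mu=out_mu[:s], eta=out_eta[:s],
            sigma2=out_sig[:s],
            F=out_F[:s] if out_F is not None else None,
            F_tilde=out_Ft[:s] if out_Ft is not None else None,
            epsilon=out_eps[:s] if out_eps is not None else None,
            acceptance=self.acceptance_rates(), pattern=d.pattern, config=cfg)


def run(panel: CountPanel, graph: AdjacencyGraph, pattern: LoadingsPattern,
        config: SamplerConfig, baseline_time: int = 0) -> PosteriorSamples:
    """Validate inputs, build the data bundle and run one chain."""
    data = ModelData(panel, graph, pattern, baseline_time=baseline_time)
    return MWGSampler(data, config).run()


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def _summary_row(name, draws):
    mean = float(np.mean(draws))
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"parameter": name, "mean": mean, "lo95": float(lo), "hi95": float(hi)}


def summarize(samples: PosteriorSamples,
              outcome_labels: list | None = None) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval per scalar parameter.

    One row per loadings entry (structural zeros reported as exact 0, as in
    a published loadings table), per identified L entry, per eta, sigma2 and
    mu component.
    """
    if samples.n_draws < 2:
        raise ValueError("need at least two retained draws to summarise")
    pat = samples.pattern
    K, m = pat.mask.shape
    labels = outcome_labels or [f"outcome{k}" for k in range(K)]
    rows = []
    for k in range(K):
        for j in range(m):
            name = f"gamma[{labels[k]},{j + 1}]"
            if pat.mask[k, j]:
                rows.append(_summary_row(name, samples.gamma[:, k, j]))
            else:
                rows.append({"parameter": name, "mean": 0.0,
                             "lo95": 0.0, "hi95": 0.0})
    ordered_labels = [labels[i] for i in pat.outcome_order]
    for k in range(K):
        for j in range(m):
            if k < m and j > k:
                continue  # upper triangle of the leading block is exactly 0
            rows.append(_summary_row(f"L[{ordered_labels[k]},{j + 1}]",
                                     samples.L[:, k, j]))
    for j in range(m):
        rows.append(_summary_row(f"eta[{j + 1}]", samples.eta[:, j]))
    for k in range(K):
        rows.append(_summary_row(f"sigma2[{labels[k]}]", samples.sigma2[:, k]))
    J = samples.mu.shape[1]
    for j in range(J):
        for mm in range(m):
            rows.append(_summary_row(f"mu[{j + 1},{mm + 1}]",
                                     samples.mu[:, j, mm]))
    return pd.DataFrame(rows, columns=["parameter", "mean", "lo95", "hi95"])


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat and effective sample size for the scalar hyperparameters
    (single-chain diagnostics via arviz); informational, not a gate."""
    import arviz as az
    # split the single chain into halves so split-R-hat is defined
    S = (samples.eta.shape[0] // 2) * 2
    data = {
        "eta": samples.eta[:S].reshape(2, S // 2, -1),
        "sigma2": samples.sigma2[:S].reshape(2, S // 2, -1),
    }
    idata = az.from_dict(posterior=data)
    ess = az.ess(idata)
    rhat = az.rhat(idata)
    rows = []
    for var in ("eta", "sigma2"):
        e = np.atleast_1d(ess[var].values)
        r = np.atleast_1d(rhat[var].values)
        for i, (ei, ri) in enumerate(zip(e, r)):
            rows.append({"parameter": f"{var}[{i + 1}]",
                         "ess": float(ei), "rhat": float(ri)})
    return pd.DataFrame(rows)
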