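"""Observation-level model for multivariate areal count panels.

The data are yearly counts ``Y[i, j, k]`` for areal unit *i*, time *j* and
outcome *k*, with unit-time populations ``P[i, j]``.  Each outcome has a
baseline rate ``r_k`` (the overall study-region rate at the baseline time),
giving expected counts ``E[i, j, k] = P[i, j] * r_k``.  Counts are modelled
as Poisson with mean ``E * lambda`` where the log relative risk is a linear
factor expansion

    log lambda[i, j, k] = Gamma[k, :] @ F[i, j, :] + eps[i, j, k],

with a K x m loadings matrix ``Gamma`` carrying structural zeros that encode
which latent factors touch which outcomes, and cell-level Gaussian noise
``eps`` for uncorrelated overdispersion.

One outcome (treatment counts, in the motivating surveillance setting) is
interval censored: whenever its count falls in [1, 5] only that fact is
released.  Censored cells contribute the probability of the whole interval
to the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

# Suppression interval for censored counts (inclusive, integers).
CENSOR_LO = 1
CENSOR_HI = 5
#: Value imputed for a censored cell when a point value is unavoidable
#: (baseline-rate computation): the integer centre of the interval.
CENSOR_MIDPOINT = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountPanel:
    """Complete panel of areal counts over units x times x outcomes.

    Parameters
    ----------
    counts
        Integer array of shape (I, J, K); entries at censored cells are
        ignored by all likelihood code.
    censored
        Boolean array of shape (I, J, K); True means the count is only known
        to lie in ``[CENSOR_LO, CENSOR_HI]``.
    populations
        Strictly positive array of shape (I, J).
    """

    counts: np.ndarray
    censored: np.ndarray
    populations: np.ndarray
    unit_labels: list = field(default_factory=list)
    time_labels: list = field(default_factory=list)
    outcome_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.populations = np.asarray(self.populations, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (units, times, outcomes)")
        I, J, K = self.counts.shape
        if self.censored.shape != (I, J, K):
            raise ValueError("censored mask shape does not match counts")
        if self.populations.shape != (I, J):
            raise ValueError("populations shape does not match counts")
        if np.any(self.populations <= 0):
            raise ValueError("populations must be strictly positive")
        obs = ~self.censored
        if np.any(self.counts[obs] < 0):
            raise ValueError("observed counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts[obs] != np.round(self.counts[obs])):
                raise ValueError("observed counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if not self.unit_labels:
            self.unit_labels = list(range(I))
        if not self.time_labels:
            self.time_labels = list(range(J))
        if not self.outcome_labels:
            self.outcome_labels = list(range(K))

    @property
    def shape(self):
        return self.counts.shape

    @property
    def n_units(self):
        return self.counts.shape[0]

    @property
    def n_times(self):
        return self.counts.shape[1]

    @property
    def n_outcomes(self):
        return self.counts.shape[2]


@dataclass
class ExpectedCounts:
    """Baseline expected counts E[i,j,k] = P[i,j] * r_k with the rates used."""

    rates: np.ndarray
    expected: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")
        if np.any(self.expected <= 0):
            raise ValueError("expected counts must be strictly positive")


@dataclass
class LoadingsPattern:
    """Structural sparsity pattern of the K x m loadings matrix.

    ``mask[k, m]`` is True where the loading is a free parameter and False
    where it is a structural zero.  ``anchors`` lists (outcome, factor)
    positions whose loading is constrained strictly positive — one per
    factor — which pins the sign of each factor.  ``outcome_order`` is the
    permutation of outcomes that places the m rows forming the leading
    square block first; identifiability requires that block to be
    generically invertible.
    """

    mask: np.ndarray
    anchors: tuple
    outcome_order: tuple

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be K x m")
        K, m = self.mask.shape
        if K < m:
            raise ValueError("need at least as many outcomes as factors")
        self.anchors = tuple((int(k), int(j)) for k, j in self.anchors)
        if self.outcome_order is None:
            self.outcome_order = tuple(range(K))
        self.outcome_order = tuple(int(i) for i in self.outcome_order)
        if sorted(self.outcome_order) != list(range(K)):
            raise ValueError("outcome_order must be a permutation of the outcomes")
        for (k, j) in self.anchors:
            if not self.mask[k, j]:
                raise ValueError(f"anchor ({k},{j}) is a structural zero")
        cols = [j for _, j in self.anchors]
        if sorted(cols) != list(range(m)):
            raise ValueError("each factor column must have exactly one anchor")

    @property
    def n_outcomes(self):
        return self.mask.shape[0]

    @property
    def n_factors(self):
        return self.mask.shape[1]

    def free_positions(self):
        """(outcome, factor) indices of free entries, row-major scan order."""
        K, m = self.mask.shape
        return [(k, j) for k in range(K) for j in range(m) if self.mask[k, j]]


def shared_plus_pairs_pattern(n_pairs: int = 3) -> LoadingsPattern:
    """The shared-component pattern: one factor loading on every outcome plus
    one factor per consecutive outcome pair.

    With the default three pairs this is the K=6, m=4 design used throughout
    the package: outcomes ordered (D, E, T, C, B, I), factor 1 shared by all
    six, factor 2 by (D, E), factor 3 by (T, B), factor 4 by (C, I).  The
    anchors are the first-listed member of each grouping: (D,1), (E,2),
    (T,3), (C,4).  Row order (D, E, T, C, B, I) makes the leading 4x4 block
    generically invertible.
    """
    m = n_pairs + 1
    K = 2 * n_pairs  # two outcomes per pair factor
    if K < m:
        raise ValueError("pattern needs 2*n_pairs >= n_pairs + 1")
    mask = np.zeros((K, m), dtype=bool)
    mask[:, 0] = True
    # pairs in data order: (0,1), (2,4), (3,5) for n_pairs=3 — i.e. rows are
    # laid out so the first m rows cover every pair column once.
    pair_rows = []
    for p in range(n_pairs):
        pair_rows.append((2 * p, 2 * p + 1))
    # data order (D,E,T,C,B,I): pair p=0 -> rows (0,1); p=1 -> rows (2,4);
    # p=2 -> rows (3,5).  Build generically: first occurrence among the first
    # m rows.
    if n_pairs == 3:
        pair_rows = [(0, 1), (2, 4), (3, 5)]
    for p, (a, b) in enumerate(pair_rows):
        mask[a, 1 + p] = True
        mask[b, 1 + p] = True
    anchors = [(0, 0), (1, 1)] + [(pair_rows[p][0], 1 + p) for p in range(1, n_pairs)]
    return LoadingsPattern(mask=mask, anchors=tuple(anchors),
                           outcome_order=tuple(range(K)))


def default_pattern() -> LoadingsPattern:
    """The K=6, m=4 shared-plus-pairs pattern."""
    return shared_plus_pairs_pattern(3)


DEFAULT_OUTCOME_LABELS = ["deaths", "ed_visits", "treatment", "hcv",
                          "buprenorphine", "hiv"]
#: Index of the outcome subject to interval censoring (treatment counts).
CENSORED_OUTCOME = 2


@dataclass
class LoadingsMatrix:
    """Current values of the loadings, exactly zero off-pattern."""

    values: np.ndarray
    pattern: LoadingsPattern

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.pattern.mask.shape:
            raise ValueError("values shape does not match pattern mask")
        if np.any(self.values[~self.pattern.mask] != 0.0):
            raise ValueError("structural zeros must be exactly 0")
        for (k, j) in self.pattern.anchors:
            if self.values[k, j] <= 0:
                raise ValueError(f"anchor loading ({k},{j}) must be positive")


@dataclass
class NoiseField:
    """Cell-level heterogeneity eps[i,j,k] with outcome variances sigma2[k]."""

    epsilon: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def baseline_rates(panel: CountPanel, baseline_time: int = 0) -> np.ndarray:
    """Per-outcome baseline rates r_k from the baseline time slice.

    r_k is the study-region total count of outcome k at ``baseline_time``
    divided by the total population at that time.  Censored cells enter the
    total at the interval midpoint (3).
    """
    J = panel.n_times
    if not (-J <= baseline_time < J):
        raise ValueError(f"invalid baseline time index {baseline_time}")
    y = panel.counts[:, baseline_time, :].astype(float).copy()
    cens = panel.censored[:, baseline_time, :]
    y[cens] = CENSOR_MIDPOINT
    totals = y.sum(axis=0)
    pop = panel.populations[:, baseline_time].sum()
    rates = totals / pop
    if np.any(rates <= 0):
        k_bad = int(np.argmin(rates))
        label = panel.outcome_labels[k_bad]
        raise ValueError(f"zero baseline rate for outcome {label!r}")
    return rates


def expected_counts(panel: CountPanel, rates: np.ndarray) -> ExpectedCounts:
    """E[i,j,k] = P[i,j] * r_k."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (panel.n_outcomes,):
        raise ValueError("rates must have one entry per outcome")
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    E = panel.populations[:, :, None] * rates[None, None, :]
    return ExpectedCounts(rates=rates, expected=E)


def linear_predictor(loadings, factors: np.ndarray,
                     noise=None) -> np.ndarray:
    """Log relative risk: log lambda[i,j,k] = Gamma[k] @ F[i,j] + eps[i,j,k].

    ``loadings`` may be a LoadingsMatrix or a bare (K, m) array; ``noise``
    may be a NoiseField, a bare (I, J, K) array, or None (no noise).
    """
    gamma = loadings.values if isinstance(loadings, LoadingsMatrix) else np.asarray(loadings, float)
    factors = np.asarray(factors, dtype=float)
    if factors.ndim != 3 or factors.shape[2] != gamma.shape[1]:
        raise ValueError("factor array must have shape (I, J, m) matching the loadings")
    loglam = np.einsum("ijm,km->ijk", factors, gamma)
    if noise is not None:
        eps = noise.epsilon if isinstance(noise, NoiseField) else np.asarray(noise, float)
        if eps.shape != loglam.shape:
            raise ValueError("noise shape does not match (I, J, K)")
        loglam = loglam + eps
    return loglam


_Y_INTERVAL = np.arange(CENSOR_LO, CENSOR_HI + 1)
_LGAMMA_INTERVAL = gammaln(_Y_INTERVAL + 1.0)


def censored_interval_loglik(mu):
    """log P(CENSOR_LO <= Y <= CENSOR_HI) for Y ~ Poisson(mu), elementwise.

    Computed as a log-sum-exp over the five interval log-pmf values, which
    is stable for means from ~1e-300 up to overflow-free large values.
    """
    mu = np.asarray(mu, dtype=float)
    logmu = np.log(mu)
    terms = (_Y_INTERVAL * logmu[..., None] - mu[..., None]
             - _LGAMMA_INTERVAL)
    # inline stable log-sum-exp over the five interval terms
    tmax = terms.max(axis=-1)
    return tmax + np.log(np.sum(np.exp(terms - tmax[..., None]), axis=-1))


def poisson_loglik(y, mu):
    """Poisson log-pmf, elementwise (with the log y! normalising constant)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def obs_loglik(panel: CountPanel, expected: ExpectedCounts,
               loglambda: np.ndarray) -> float:
    """Total observation log-likelihood.

    Observed cells contribute the Poisson log-pmf at mean E*lambda; censored
    cells contribute the log-probability of the censoring interval [1, 5].
    """
    E = expected.expected if isinstance(expected, ExpectedCounts) else np.asarray(expected, float)
    loglambda = np.asarray(loglambda, dtype=float)
    if loglambda.shape != panel.shape or E.shape != panel.shape:
        raise ValueError("shape mismatch between panel, expected counts and log lambda")
    mu = E * np.exp(loglambda)
    obs = ~panel.censored
    total = float(np.sum(poisson_loglik(panel.counts[obs], mu[obs])))
    if panel.censored.any():
        total += float(np.sum(censored_interval_loglik(mu[panel.censored])))
    return total


def variance_explained(loadings, factor_draws: np.ndarray,
                       sigma2: np.ndarray) -> np.ndarray:
    """Proportion of each outcome's log-relative-risk variability carried by
    the factors: v_k = Var(Gamma_k'F) / (Var(Gamma_k'F) + sigma2_k), with the
    variance taken empirically over all unit-time cells.
    """
    gamma = loadings.values if isinstance(loadings, LoadingsMatrix) else np.asarray(loadings, float)
    sigma2 = np.asarray(sigma2, dtype=float)
    factor_draws = np.asarray(factor_draws, dtype=float)
    signal = np.einsum("ijm,km->ijk", factor_draws, gamma)
    n_cells = signal.shape[0] * signal.shape[1]
    if n_cells < 2:
        raise ValueError("variance explained needs at least two unit-time cells")
    var_sig = signal.reshape(n_cells, -1).var(axis=0)
    denom = var_sig + sigma2
    out = np.where(denom > 0, var_sig / np.where(denom > 0, denom, 1.0), 0.0)
    return out
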