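"""Spatio-temporal prior on the latent factors: ICAR in space, AR(1) in time.

Each factor m evolves over years j on the areal adjacency graph.  The year-1
field follows an intrinsic CAR: conditionally,

    f[i,1,m] | rest ~ N( mu[1,m] + mean over neighbours of (f[l,1,m] - mu[1,m]),
                         1 / degree(i) ),

and for j >= 2 the conditional mean is shifted by the AR(1) carry-over
``eta_m (f[i,j-1,m] - mu[j-1,m])``.  Equivalently, with the factor written
as ``f = mu + delta`` (delta summing to zero over units within each year and
factor — the centering constraint that makes the intrinsic prior usable),
the innovations

    e[:, 1] = delta[:, 1],   e[:, j] = delta[:, j] - eta * delta[:, j-1]

are independent ICAR fields across years, with the pairwise-difference
log-density  -1/2 * sum over edges (i,l) of (e_i - e_l)^2.  The conditional
variance 1/degree is fully specified (no free spatial scale), which the
identification of the loadings relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp


@dataclass
class AdjacencyGraph:
    """Symmetric 0/1 neighbourhood structure on the areal units.

    Built from an edge list of unordered pairs; must be connected, without
    self-edges, and every unit must have at least one neighbour.
    """

    n_units: int
    edges: np.ndarray  # (n_edges, 2), each unordered pair listed once

    degrees: np.ndarray = field(init=False)
    adjacency: sp.csr_matrix = field(init=False)
    coloring: list = field(init=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be an (n_edges, 2) array")
        if np.any(edges < 0) or np.any(edges >= self.n_units):
            raise ValueError("edge index out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        canon = np.sort(edges, axis=1)
        canon = np.unique(canon, axis=0)
        self.edges = canon
        u, v = canon[:, 0], canon[:, 1]
        data = np.ones(len(canon))
        A = sp.coo_matrix((np.concatenate([data, data]),
                           (np.concatenate([u, v]), np.concatenate([v, u]))),
                          shape=(self.n_units, self.n_units)).tocsr()
        A.data[:] = 1.0  # collapse any duplicates
        self.adjacency = A
        self.degrees = np.asarray(A.sum(axis=1)).ravel()
        if np.any(self.degrees < 1):
            isolated = int(np.argmin(self.degrees))
            raise ValueError(f"unit {isolated} has no neighbours")
        G = nx.Graph()
        G.add_nodes_from(range(self.n_units))
        G.add_edges_from(map(tuple, canon))
        comps = list(nx.connected_components(G))
        if len(comps) != 1:
            raise ValueError(
                f"adjacency graph is disconnected ({len(comps)} components): "
                + "; ".join(str(sorted(c)[:6]) for c in comps))
        # greedy colouring: units in one colour class share no edge, so they
        # can be Metropolis-updated simultaneously
        colors = nx.greedy_color(G, strategy="largest_first")
        n_colors = max(colors.values()) + 1
        self.coloring = [np.array(sorted(i for i, c in colors.items() if c == cc),
                                  dtype=np.int64)
                         for cc in range(n_colors)]

    @property
    def n_edges(self):
        return len(self.edges)

    def neighbors(self, unit: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[unit]:self.adjacency.indptr[unit + 1]]

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (the ICAR pairwise-difference precision)."""
        return np.diag(self.degrees) - self.adjacency.toarray()


@dataclass
class FactorHyper:
    """Hyperparameters of the factor prior: yearly means and AR coefficients."""

    mu: np.ndarray   # (J, m)
    eta: np.ndarray  # (m,), each in (0, 1)

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        if self.mu.shape[1] != self.eta.shape[0]:
            raise ValueError("mu must be (J, m) with one eta per factor")
        if np.any(self.eta <= 0) or np.any(self.eta >= 1):
            raise ValueError("eta must lie strictly inside (0, 1)")


CENTER_TOL = 1e-10


@dataclass
class FactorField:
    """Latent factor values f[i, j, m] = mu[j, m] + delta[i, j, m]."""

    f: np.ndarray  # (I, J, m)

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 3:
            raise ValueError("factor field must have shape (I, J, m)")

    def deviations(self, hyper: FactorHyper) -> np.ndarray:
        return self.f - hyper.mu[None, :, :]

    def is_centered(self, hyper: FactorHyper, tol: float = CENTER_TOL) -> bool:
        dev = self.deviations(hyper).mean(axis=0)
        return bool(np.all(np.abs(dev) <= tol))


def icar_conditional(values: np.ndarray, center: float, unit: int,
                     graph: AdjacencyGraph):
    """Full-conditional (mean, variance) of one unit's ICAR value.

    mean = center + average over neighbours of (value - center);
    variance = 1 / degree.
    """
    deg = graph.degrees[unit]
    nbr = graph.neighbors(unit)
    values = np.asarray(values, dtype=float)
    mean = center + float(np.sum(values[nbr] - center)) / deg
    return mean, 1.0 / deg


def ar1_shifted_mean(mu_j: float, mu_jprev: float, eta: float, f_prev: float) -> float:
    """AR(1)-shifted yearly centre: mu_j + eta * (f_prev - mu_jprev)."""
    return mu_j + eta * (f_prev - mu_jprev)


def innovations(field: FactorField, hyper: FactorHyper) -> np.ndarray:
    """Year-wise ICAR innovations e[i, j, m] of the AR(1) construction."""
    dev = field.deviations(hyper)
    e = dev.copy()
    e[:, 1:, :] -= hyper.eta[None, None, :] * dev[:, :-1, :]
    return e


def joint_logprior(field: FactorField, hyper: FactorHyper,
                   graph: AdjacencyGraph) -> float:
    """Joint log-density of the factor field up to an additive constant.

    Sum over factors and years of the ICAR pairwise-difference quadratic of
    the innovations: -1/2 * sum over edges (e_i - e_l)^2.  Requires the field
    to satisfy the per-(year, factor) centering constraint.
    """
    if not field.is_centered(hyper):
        raise ValueError("factor field violates the centering constraint")
    e = innovations(field, hyper)
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    diff = e[u] - e[v]  # (n_edges, J, m)
    return float(-0.5 * np.sum(diff * diff))


def center(field: FactorField, hyper: FactorHyper) -> FactorField:
    """Project onto the centering constraint: per (year, factor), subtract the
    unit-mean of (f - mu).  Idempotent; returns a new field."""
    dev_mean = field.deviations(hyper).mean(axis=0)  # (J, m)
    return FactorField(f=field.f - dev_mean[None, :, :])


def _icar_sqrt_cov(graph: AdjacencyGraph):
    """Factor B with B @ z ~ centered ICAR draw (z standard normal, I-1 dims).

    Uses the eigendecomposition of the graph Laplacian restricted to the
    zero-sum subspace (the pseudo-inverse square root).
    """
    lam, V = np.linalg.eigh(graph.laplacian())
    # connected graph: exactly one ~zero eigenvalue, the constant direction
    keep = lam > 1e-9 * lam.max()
    return V[:, keep] / np.sqrt(lam[keep])[None, :]


def sample_prior(graph: AdjacencyGraph, hyper: FactorHyper, seed) -> FactorField:
    """Draw a factor field from the generative prior.

    Per (year, factor) a centered ICAR innovation field is drawn via the
    pseudo-inverse square root of the pairwise-difference precision; the
    deviations accumulate as delta_j = eta * delta_{j-1} + e_j and the field
    is f = mu + delta.  Reproducible given the seed (or Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    J, m = hyper.mu.shape
    I = graph.n_units
    B = _icar_sqrt_cov(graph)  # (I, I-1)
    z = rng.standard_normal((J, m, B.shape[1]))
    e = np.einsum("ir,jmr->ijm", B, z)
    delta = np.empty((I, J, m))
    delta[:, 0, :] = e[:, 0, :]
    for j in range(1, J):
        delta[:, j, :] = hyper.eta[None, :] * delta[:, j - 1, :] + e[:, j, :]
    return FactorField(f=hyper.mu[None, :, :] + delta)


def morans_i(x: np.ndarray, graph: AdjacencyGraph) -> float:
    """Moran's I spatial autocorrelation of a per-unit vector on the graph."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    num = float(xc @ (graph.adjacency @ xc))
    den = float(xc @ xc)
    s0 = 2.0 * graph.n_edges
    if den == 0:
        return 0.0
    return (graph.n_units / s0) * (num / den)
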