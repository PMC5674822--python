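"""Domain types and zero-inflated Poisson likelihood quantities.

The conditional model for node ``j`` given the remaining nodes is a
two-component mixture: with probability ``pi_j`` the observation is a
structural zero, otherwise it is Poisson with log-rate linear in the other
nodes' counts,

    P(X_j = x | x_{-j}) = pi_j * I(x = 0) + (1 - pi_j) * exp(-mu_j) mu_j^x / x!,
    mu_j = exp(beta_j + sum_{k != j} beta_jk x_k).

Everything downstream (EM solver, graph learner, evaluation) consumes the
quantities defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DEFAULT_CLIP_BOUND",
    "CountMatrix",
    "NodeModel",
    "PenaltySpec",
    "NetworkEstimate",
    "NetworkPath",
    "zisp_conditional_logpmf",
    "node_negloglik",
    "penalized_objective",
]

# Linear predictors are clipped to +/- this bound before exponentiation so
# that mu stays inside double-precision range even for large raw counts.
DEFAULT_CLIP_BOUND = 30.0


@dataclass
class CountMatrix:
    """A samples-by-nodes matrix of nonnegative integer counts."""

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    node_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError(f"count matrix must be 2-D, got shape {vals.shape}")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise ValueError("count matrix entries must be integral")
            vals = vals.astype(np.int64)
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(f"negative count at row {i}, column {j}")
        n, p = vals.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 nodes, got {n}x{p}")
        self.values = vals.astype(np.int64)
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.node_ids is None:
            self.node_ids = [f"v{j}" for j in range(p)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.node_ids) != p:
            raise ValueError("node_ids length does not match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def zero_index(self, j: int) -> np.ndarray:
        """Row indices where node ``j`` is zero (the set O_j)."""
        return np.flatnonzero(self.values[:, j] == 0)

    def positive_index(self, j: int) -> np.ndarray:
        """Row indices where node ``j`` is nonzero (the set P_j)."""
        return np.flatnonzero(self.values[:, j] != 0)

    def design_for(self, j: int) -> np.ndarray:
        """N x p float design for node j: all-ones column then columns k != j."""
        other = np.delete(self.values, j, axis=1).astype(np.float64)
        return np.hstack([np.ones((self.n_samples, 1)), other])


@dataclass
class NodeModel:
    """Fitted parameters of one node's zero-inflated Poisson regression."""

    node: int
    intercept: float
    coefficients: np.ndarray  # length p-1, neighbors in column order, j removed
    mixing: float
    n_em_iters: int = 0
    final_objective: float = np.nan
    converged: bool = True
    objective_trace: np.ndarray | None = None  # penalized objective per EM iter

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError(f"mixing must be in [0, 1], got {self.mixing}")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def stacked(self) -> np.ndarray:
        """Intercept followed by neighbor coefficients (the vector beta_{-j})."""
        return np.concatenate([[self.intercept], self.coefficients])


@dataclass
class PenaltySpec:
    """Weighted-lasso penalty lambda * sum_{k != j} w_jk |beta_jk|."""

    lam: float
    weights: np.ndarray = None  # type: ignore[assignment]  # p x p, diagonal ignored

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if np.any(self.weights < 0):
                raise ValueError("penalty weights must be nonnegative")

    def node_weights(self, j: int, p: int) -> np.ndarray:
        """Length p-1 weight vector for node j (unit weights if unspecified)."""
        if self.weights is None:
            return np.ones(p - 1)
        return np.delete(self.weights[j], j)


@dataclass
class NetworkEstimate:
    """Network fit at one lambda: coefficients, symmetrized adjacency, mixing."""

    lam: float
    coef: np.ndarray        # p x p; [j, k] = beta_jk for k != j, diagonal = intercepts
    adjacency: np.ndarray   # p x p binary, symmetric, zero diagonal (OR rule)
    mixing: np.ndarray      # length p, estimated pi_j
    failed_nodes: list[int] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())

    def edge_list(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in np.argwhere(np.triu(self.adjacency, k=1))]


@dataclass
class NetworkPath:
    """Network estimates along a strictly decreasing lambda grid."""

    grid: np.ndarray
    estimates: list[NetworkEstimate]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if len(self.grid) != len(self.estimates):
            raise ValueError("grid and estimates must have equal length")
        if np.any(np.diff(self.grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")


def _validate_count(x) -> int:
    xa = np.asarray(x)
    if xa.shape != ():
        raise ValueError("x must be a scalar count")
    if not np.isfinite(xa) or xa != np.floor(xa) or xa < 0:
        raise ValueError(f"x must be a nonnegative integer, got {x!r}")
    return int(xa)


def zisp_conditional_logpmf(x, pi: float, mu: float) -> float:
    """Log pmf of the zero-inflated Poisson mixture at count ``x``.

    Computed in log space: for ``x = 0`` the two mixture branches are combined
    with log-sum-exp; for ``x >= 1`` only the Poisson branch contributes.
    """
    xi = _validate_count(x)
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    if not (np.isfinite(mu) and mu > 0):
        raise ValueError(f"mu must be finite and positive, got {mu}")
    log_pois = xi * np.log(mu) - mu - gammaln(xi + 1.0)
    if xi == 0:
        if pi == 0.0:
            return float(log_pois)
        if pi == 1.0:
            return 0.0
        return float(np.logaddexp(np.log(pi), np.log1p(-pi) - mu))
    if pi == 1.0:
        return -np.inf
    return float(np.log1p(-pi) + log_pois)


def node_mu(X: CountMatrix, j: int, beta: np.ndarray,
            clip_bound: float = DEFAULT_CLIP_BOUND) -> np.ndarray:
    """Conditional Poisson rates mu_ij = exp(clip(x_{i,-j}^T beta)) for node j."""
    eta = X.design_for(j) @ np.asarray(beta, dtype=np.float64)
    return np.exp(np.clip(eta, -clip_bound, clip_bound))


def node_negloglik(X: CountMatrix, j: int, model: NodeModel,
                   clip_bound: float = DEFAULT_CLIP_BOUND) -> float:
    """Negative ZISP log-likelihood of node ``j`` given the other nodes.

    The linear predictor is clipped to ``+/- clip_bound`` before
    exponentiation; an overflow surviving the clip raises with the node index.
    """
    beta = model.stacked()
    if len(beta) != X.n_nodes:
        raise ValueError(
            f"model for node {j} has {len(beta) - 1} coefficients, "
            f"expected {X.n_nodes - 1}"
        )
    mu = node_mu(X, j, beta, clip_bound)
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError(f"non-finite rate for node {j} after clipping")
    xj = X.values[:, j].astype(np.float64)
    pi = model.mixing
    log_pois = xj * np.log(mu) - mu - gammaln(xj + 1.0)
    is_zero = xj == 0
    ll = np.empty(X.n_samples)
    if pi == 0.0:
        ll[:] = log_pois
    elif pi == 1.0:
        ll[is_zero] = 0.0
        ll[~is_zero] = -np.inf
    else:
        ll[is_zero] = np.logaddexp(np.log(pi), np.log1p(-pi) - mu[is_zero])
        ll[~is_zero] = np.log1p(-pi) + log_pois[~is_zero]
    return float(-np.sum(ll))


def penalized_objective(X: CountMatrix, j: int, model: NodeModel,
                        pen: PenaltySpec,
                        clip_bound: float = DEFAULT_CLIP_BOUND) -> float:
    """(1/N) * negative log-likelihood + lambda * sum_k w_jk |beta_jk|.

    The intercept is never penalized.
    """
    nll = node_negloglik(X, j, model, clip_bound)
    w = pen.node_weights(j, X.n_nodes)
    penalty = pen.lam * float(np.sum(w * np.abs(model.coefficients)))
    return nll / X.n_samples + penalty
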