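"""Zero-inflated Poisson network simulator.

Counts are generated as X = Y B + E, where Y holds one iid Poisson(lam_true)
latent column per node plus one per node pair, E is iid Poisson(lam_noise)
node-level noise, and the binary matrix B routes each pair column to both of
its endpoints exactly when the pair is an edge of the true adjacency A.
Adjacent nodes therefore share a latent Poisson column, giving them
covariance lam_true; non-adjacent pairs share nothing and are asymptotically
uncorrelated.  Zero inflation is imposed last: each entry of X is
independently replaced by 0 with probability pi.

Off-diagonal entries of A are iid Bernoulli(rho), so rho is the expected
edge density of the true graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CountMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "pair_index",
    "sample_adjacency",
    "build_coefficient_matrix",
    "simulate",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int
    n_nodes: int
    sparsity: float = 0.2          # rho: P(edge) for each node pair
    zero_inflation: float = 0.0    # pi: P(entry replaced by structural zero)
    lam_true: float = 1.5          # rate of the shared latent Poisson columns
    lam_noise: float = 0.5         # rate of the per-node noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_nodes < 2:
            raise ValueError("need n_samples >= 2 and n_nodes >= 2")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must be in [0, 1]")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.lam_true <= 0 or self.lam_noise < 0:
            raise ValueError("lam_true must be > 0 and lam_noise >= 0")


@dataclass
class SimulationTruth:
    """Simulated counts together with the generating adjacency."""

    counts: CountMatrix
    adjacency: np.ndarray
    pair_index: list[tuple[int, int]]
    config: SimulationConfig = None  # type: ignore[assignment]


def pair_index(p: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle ordering of the p-choose-2 node pairs."""
    return [(j, k) for j in range(p) for k in range(j + 1, p)]


def sample_adjacency(p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric binary adjacency with iid Bernoulli(rho) upper triangle."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    A = np.zeros((p, p), dtype=np.int8)
    iu = np.triu_indices(p, k=1)
    A[iu] = rng.random(len(iu[0])) < rho
    return A + A.T


def build_coefficient_matrix(A: np.ndarray) -> np.ndarray:
    """The (p + pC2) x p binary routing matrix B of the model X = Y B + E.

    The first p rows are the identity (latent column j feeds node j); each
    subsequent row corresponds to one node pair in ``pair_index`` order and
    loads 1 on both endpoints exactly when the pair is an edge of A.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("A must be symmetric")
    p = A.shape[0]
    pairs = pair_index(p)
    B = np.zeros((p + len(pairs), p), dtype=np.int64)
    B[:p, :p] = np.eye(p, dtype=np.int64)
    for m, (j, k) in enumerate(pairs):
        if A[j, k]:
            B[p + m, j] = 1
            B[p + m, k] = 1
    return B


def simulate(cfg: SimulationConfig) -> SimulationTruth:
    """Draw one zero-inflated Poisson network dataset.

    A single seeded generator is used with a fixed draw order (adjacency,
    latent Y, noise E, thinning mask) so output is reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    p, n = cfg.n_nodes, cfg.n_samples
    A = sample_adjacency(p, cfg.sparsity, rng)
    B = build_coefficient_matrix(A)
    Y = rng.poisson(cfg.lam_true, size=(n, B.shape[0]))
    E = rng.poisson(cfg.lam_noise, size=(n, p))
    X = Y @ B + E
    if cfg.zero_inflation > 0:
        keep = rng.random(size=X.shape) >= cfg.zero_inflation
        X = X * keep
    counts = CountMatrix(X)
    return SimulationTruth(counts=counts, adjacency=A,
                           pair_index=pair_index(p), config=cfg)
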