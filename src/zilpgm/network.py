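"""Network learning: node-wise fits over a lambda grid, assembled by the OR rule.

Each node is regressed on all others with a weighted lasso penalty; an edge
(j, k) is declared whenever either directed coefficient beta_jk or beta_kj is
nonzero.  The penalty grid runs from lambda_max — the largest raw
cross-product (1/N) sum_i x_ik x_ij over node pairs, above which every
penalized coefficient is zero — down to lambda_max * min_ratio on a log scale.

Adaptive weights follow a two-stage recipe: a plain l1-penalized Poisson
screening fit per node sets w_jk = 1 for retained covariates and a
prohibitively large weight (1e5) otherwise, so the final fit can only
deselect from the screened support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import CountMatrix, NetworkEstimate, NetworkPath, NodeModel
from .solver import EMConfig, fit_node

__all__ = [
    "GridSpec",
    "LARGE_WEIGHT",
    "lambda_grid",
    "adaptive_weights",
    "fit_network",
    "fit_path",
    "select_lambda_stability",
]

# Weight assigned to covariates screened out by the first-stage fit.
LARGE_WEIGHT = 1e5


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced lambda grid: n_points values on [max * min_ratio, max]."""

    n_points: int = 30
    min_ratio: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not 0.0 < self.min_ratio < 1.0:
            raise ValueError("min_ratio must be in (0, 1)")


def lambda_grid(X: CountMatrix, spec: GridSpec = GridSpec()) -> np.ndarray:
    """Decreasing log-equispaced grid from lambda_max down to lambda_max * min_ratio.

    lambda_max = max_j max_{k != j} (1/N) sum_i x_ik x_ij, the largest
    off-diagonal entry of the raw (uncentered) second-moment matrix.
    """
    gram = (X.values.T @ X.values) / X.n_samples
    np.fill_diagonal(gram, -np.inf)
    lam_max = float(np.max(gram))
    if lam_max <= 0:
        raise ValueError(
            "lambda_max is zero: no pair of nodes has co-occurring nonzero counts"
        )
    return np.geomspace(lam_max, lam_max * spec.min_ratio, spec.n_points)


def adaptive_weights(X: CountMatrix, lam: float,
                     cfg: EMConfig = EMConfig()) -> np.ndarray:
    """Two-stage screening weights: 1 on the screened support, 1e5 elsewhere.

    For each node j an l1-penalized Poisson regression (no zero inflation,
    unit weights) is fit at ``lam``; covariates with nonzero coefficients keep
    weight 1.  The diagonal is unused and set to 0.
    """
    p = X.n_nodes
    w = np.full((p, p), LARGE_WEIGHT)
    np.fill_diagonal(w, 0.0)
    screen_cfg = cfg.lpgm()
    others = [np.delete(np.arange(p), j) for j in range(p)]
    for j in range(p):
        m = fit_node(X, j, lam, weights=None, cfg=screen_cfg)
        w[j, others[j][m.coefficients != 0]] = 1.0
    return w


def _assemble(p: int, lam: float, models: dict[int, NodeModel],
              failed: list[int]) -> NetworkEstimate:
    coef = np.zeros((p, p))
    mixing = np.full(p, np.nan)
    for j, m in models.items():
        others = np.delete(np.arange(p), j)
        coef[j, others] = m.coefficients
        coef[j, j] = m.intercept
        mixing[j] = m.mixing
    off = coef.copy()
    np.fill_diagonal(off, 0.0)
    adjacency = ((off != 0) | (off.T != 0)).astype(np.int8)
    return NetworkEstimate(lam=lam, coef=coef, adjacency=adjacency,
                           mixing=mixing, failed_nodes=sorted(failed))


def fit_network(X: CountMatrix, lam: float,
                weights: np.ndarray | None = None,
                cfg: EMConfig = EMConfig()) -> NetworkEstimate:
    """Fit all p node regressions at one lambda and symmetrize by the OR rule.

    Per-node failures are collected; the network is still returned as long as
    at least p - 1 nodes succeed (failed nodes contribute no edges and are
    listed in ``failed_nodes``), otherwise an error reports the node ids.
    """
    p = X.n_nodes
    models: dict[int, NodeModel] = {}
    failures: list[tuple[int, Exception]] = []
    for j in range(p):
        w_j = None if weights is None else np.delete(weights[j], j)
        try:
            models[j] = fit_node(X, j, lam, weights=w_j, cfg=cfg)
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover - rare
            failures.append((j, exc))
    if len(models) < p - 1:
        detail = "; ".join(f"node {j}: {e}" for j, e in failures)
        raise RuntimeError(f"too many node fits failed ({len(failures)}/{p}): {detail}")
    return _assemble(p, lam, models, [j for j, _ in failures])


def fit_path(X: CountMatrix, spec: GridSpec = GridSpec(),
             cfg: EMConfig = EMConfig(),
             use_adaptive: bool = True) -> NetworkPath:
    """Fit the network at every grid lambda, from sparse (large) to dense.

    With ``use_adaptive`` the screening weights are recomputed at each lambda,
    keeping the weight definition local to each solution.
    """
    grid = lambda_grid(X, spec)
    estimates = []
    for lam in grid:
        w = adaptive_weights(X, lam, cfg) if use_adaptive else None
        estimates.append(fit_network(X, float(lam), weights=w, cfg=cfg))
    return NetworkPath(grid=grid, estimates=estimates)


def select_lambda_stability(X: CountMatrix, spec: GridSpec = GridSpec(),
                            cfg: EMConfig = EMConfig(),
                            n_subsamples: int = 20,
                            subsample_frac: float = 0.8,
                            instability_cut: float = 0.05,
                            seed: int = 0,
                            use_adaptive: bool = True) -> float:
    """Stability-based lambda selection (StARS).

    Edge-selection frequencies theta_e(lambda) are estimated over
    ``n_subsamples`` subsamples of size floor(subsample_frac * N) drawn
    without replacement; the total instability at lambda is the mean over all
    node pairs of 2 theta (1 - theta).  After monotonizing the instability
    (running maximum as lambda decreases), the smallest lambda still below
    ``instability_cut`` — the densest acceptably stable graph — is returned.
    """
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be >= 2")
    if not 0.0 < subsample_frac < 1.0:
        raise ValueError("subsample_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    grid = lambda_grid(X, spec)
    p = X.n_nodes
    n_sub = max(2, int(subsample_frac * X.n_samples))
    counts = np.zeros((len(grid), p, p))
    for _ in range(n_subsamples):
        rows = rng.choice(X.n_samples, size=n_sub, replace=False)
        sub = CountMatrix(X.values[rows], node_ids=list(X.node_ids))
        for gi, lam in enumerate(grid):
            w = adaptive_weights(sub, float(lam), cfg) if use_adaptive else None
            est = fit_network(sub, float(lam), weights=w, cfg=cfg)
            counts[gi] += est.adjacency
    theta = counts / n_subsamples
    iu = np.triu_indices(p, k=1)
    instability = np.array([np.mean(2 * t[iu] * (1 - t[iu])) for t in theta])
    monotone = np.maximum.accumulate(instability)  # nondecreasing as lambda falls
    ok = np.flatnonzero(monotone <= instability_cut)
    if len(ok) == 0:
        warnings.warn("no lambda met the instability cut; returning lambda_min",
                      stacklevel=2)
        return float(grid[-1])
    return float(grid[ok[-1]])
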