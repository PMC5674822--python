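"""EM solver for one node's penalized zero-inflated Poisson regression.

Fitting alternates an E-step (posterior responsibility of the structural-zero
state for each observed zero), a closed-form update of the mixing probability
pi, and an M-step on the regression coefficients.  The M-step majorizes the
Poisson-part complete-data likelihood by a quadratic with curvature
``sigma = max_i (1 - z_i) mu_i`` and solves the resulting weighted-lasso
problem by cyclic coordinate descent with soft-thresholding.  Each
majorize/solve cycle can only decrease the penalized objective, so the whole
EM trajectory is monotone.

Setting ``zero_inflated=False`` pins pi = 0 and z = 0, which reduces the fit
to an l1-penalized Poisson neighborhood regression (the LPGM baseline).

The hot loops (coordinate descent and the full EM iteration) are compiled
with numba; the public operations below are plain numpy and are what the
kernels implement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .model import (
    DEFAULT_CLIP_BOUND,
    CountMatrix,
    NodeModel,
    PenaltySpec,
    penalized_objective,
)

__all__ = [
    "EMConfig",
    "MajorizedProblem",
    "ConvergenceWarning",
    "estep_responsibility",
    "update_pi",
    "majorize",
    "solve_weighted_lasso",
    "fit_node",
]


class ConvergenceWarning(UserWarning):
    """Iteration cap reached before the requested tolerance."""


@dataclass(frozen=True)
class EMConfig:
    """Knobs for the EM / MM / coordinate-descent stack.

    max_mm_iters=1 takes a single majorization step per EM iteration
    (a generalized EM); descent holds after one step and this is cheaper
    than iterating the M-step to convergence.
    """

    max_em_iters: int = 200
    em_tol: float = 1e-6
    max_mm_iters: int = 1
    max_cd_iters: int = 1000
    cd_tol: float = 1e-7
    sigma_floor: float = 1e-8
    zero_inflated: bool = True
    clip_bound: float = DEFAULT_CLIP_BOUND

    def __post_init__(self) -> None:
        if self.em_tol <= 0 or self.cd_tol <= 0 or self.sigma_floor <= 0:
            raise ValueError("tolerances must be positive")
        if min(self.max_em_iters, self.max_mm_iters, self.max_cd_iters) < 1:
            raise ValueError("iteration caps must be >= 1")

    def lpgm(self) -> "EMConfig":
        """The same configuration with zero inflation switched off."""
        return replace(self, zero_inflated=False)


@dataclass
class MajorizedProblem:
    """One weighted-lasso subproblem produced by the MM majorization.

    ``design`` has a leading all-ones column (unpenalized intercept);
    ``effective_lam`` is the penalty already rescaled by the curvature,
    N * lambda / sigma, so the subproblem reads
    (1/2)||working_response - design @ beta||^2
        + effective_lam * sum_k weights[k] |beta_{k+1}|.
    """

    working_response: np.ndarray
    design: np.ndarray
    sigma: float
    effective_lam: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.working_response)):
            raise ValueError("working response must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# Public operations (numpy reference surface)
# ---------------------------------------------------------------------------

def estep_responsibility(x, pi: float, mu: float) -> float:
    """Posterior probability that observation ``x`` is a structural zero.

    Nonzero counts cannot come from the zero state, so the responsibility is
    exactly 0 for x >= 1; for x = 0 it is pi / (pi + (1 - pi) exp(-mu)).
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    xa = np.asarray(x)
    if np.any(xa < 0) or np.any(xa != np.floor(xa)):
        raise ValueError("x must be a nonnegative integer")
    if xa.shape == () and int(xa) >= 1:
        return 0.0
    denom = pi + (1.0 - pi) * math.exp(-mu)
    return pi / denom if denom > 0 else 0.0


def update_pi(z: np.ndarray, x: np.ndarray) -> float:
    """M-step update of the mixing probability: (1/N) sum_i I(x_i = 0) z_i."""
    z = np.asarray(z, dtype=np.float64)
    x = np.asarray(x)
    if z.shape != x.shape:
        raise ValueError("z and x must have the same length")
    if np.any((z < 0) | (z > 1)):
        raise ValueError("responsibilities must lie in [0, 1]")
    if np.any(z[x > 0] != 0):
        raise ValueError("responsibility must be 0 wherever the count is positive")
    return float(np.mean((x == 0) * z))


def majorize(X: CountMatrix, j: int, beta_current: np.ndarray, z: np.ndarray,
             lam: float, weights: np.ndarray, cfg: EMConfig) -> MajorizedProblem:
    """Build the quadratic upper bound of the Poisson part at ``beta_current``.

    With gradient pieces b_i = (1 - z_i)(x_ij - mu_ij) and curvature bound
    sigma = max(max_i (1 - z_i) mu_ij, sigma_floor), the working response is
    X_{-j} beta + b / sigma and the penalty is rescaled to N * lam / sigma.
    """
    beta_current = np.asarray(beta_current, dtype=np.float64)
    if not np.all(np.isfinite(beta_current)):
        raise ValueError("beta_current must be finite")
    design = X.design_for(j)
    eta = design @ beta_current
    mu = np.exp(np.clip(eta, -cfg.clip_bound, cfg.clip_bound))
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError(f"non-finite rate for node {j} after clipping")
    one_minus_z = 1.0 - np.asarray(z, dtype=np.float64)
    b = one_minus_z * (X.values[:, j] - mu)
    sigma = max(float(np.max(one_minus_z * mu)), cfg.sigma_floor)
    working = eta + b / sigma
    return MajorizedProblem(
        working_response=working,
        design=design,
        sigma=sigma,
        effective_lam=X.n_samples * lam / sigma,
        weights=np.asarray(weights, dtype=np.float64),
    )


def solve_weighted_lasso(prob: MajorizedProblem,
                         beta_init: np.ndarray | None = None,
                         max_iters: int = 1000,
                         tol: float = 1e-7) -> np.ndarray:
    """Minimize the majorized weighted-lasso subproblem by coordinate descent.

    The first column of the design (the intercept) is unpenalized.  Returns
    the best iterate; warns if the iteration cap is hit first.
    """
    X = np.asfortranarray(prob.design)
    p = X.shape[1]
    beta = (np.zeros(p) if beta_init is None
            else np.array(beta_init, dtype=np.float64))
    pen = np.concatenate([[0.0], prob.effective_lam * prob.weights])
    n_iter = _cd_weighted_lasso(X, np.ascontiguousarray(prob.working_response),
                                beta, pen, max_iters, tol)
    if n_iter >= max_iters:
        warnings.warn("coordinate descent hit its iteration cap",
                      ConvergenceWarning, stacklevel=2)
    return beta


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_weighted_lasso(X, y, beta, pen, max_iters, tol):
    """Cyclic coordinate descent on (1/2)||y - X beta||^2 + sum pen_k |beta_k|.

    pen is per-coordinate (0 for the intercept).  beta is updated in place;
    returns the number of full sweeps performed.
    """
    n, p = X.shape
    norms = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, k] * X[i, k]
        norms[k] = s
    r = y - X @ beta
    it = 0
    while it < max_iters:
        it += 1
        max_change = 0.0
        for k in range(p):
            if norms[k] <= 0.0:
                continue
            c = norms[k] * beta[k]
            for i in range(n):
                c += X[i, k] * r[i]
            if pen[k] > 0.0:
                if c > pen[k]:
                    new = (c - pen[k]) / norms[k]
                elif c < -pen[k]:
                    new = (c + pen[k]) / norms[k]
                else:
                    new = 0.0
            else:
                new = c / norms[k]
            d = new - beta[k]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * X[i, k]
                beta[k] = new
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        if max_change < tol:
            break
    return it


@njit(cache=True)
def _zisp_objective(X, xj, logfact, beta, pi, lam, pen_w, clip):
    """(1/N) * ZISP negative log-likelihood + lam * sum w |beta_neighbors|."""
    n = X.shape[0]
    nll = 0.0
    for i in range(n):
        eta = 0.0
        for k in range(X.shape[1]):
            eta += X[i, k] * beta[k]
        if eta > clip:
            eta = clip
        elif eta < -clip:
            eta = -clip
        mu = math.exp(eta)
        if xj[i] == 0.0:
            if pi <= 0.0:
                ll = -mu
            elif pi >= 1.0:
                ll = 0.0
            else:
                a = math.log(pi)
                b = math.log1p(-pi) - mu
                m = a if a > b else b
                ll = m + math.log(math.exp(a - m) + math.exp(b - m))
        else:
            if pi >= 1.0:
                ll = -np.inf
            else:
                ll = math.log1p(-pi) - mu + xj[i] * eta - logfact[i]
        nll -= ll
    pen = 0.0
    for k in range(1, len(beta)):
        pen += pen_w[k - 1] * abs(beta[k])
    return nll / n + lam * pen


@njit(cache=True)
def _em_fit(X, xj, logfact, lam, pen_w, zero_inflated, beta0, pi0,
            max_em, em_tol, max_mm, max_cd, cd_tol, sigma_floor, clip):
    """Full EM loop for one node.

    Returns (beta, pi, n_iters, obj, converged, trace) where trace holds the
    penalized objective after every EM iteration (index 0 = initial value).

    The curvature bound sigma = max_i (1-z_i) mu_i is exact only at the
    current iterate (Poisson curvature grows with the linear predictor), so
    each majorized step is safeguarded by step halving: if the coordinate
    descent solution raises the penalized objective, the step is shrunk
    toward the previous iterate until it descends.  This makes the whole
    trajectory monotone.
    """
    n, p = X.shape
    beta = beta0.copy()
    pi = pi0 if zero_inflated else 0.0
    obj = _zisp_objective(X, xj, logfact, beta, pi, lam, pen_w, clip)
    trace = np.empty(max_em + 1)
    trace[0] = obj
    converged = False
    it = 0
    pen = np.empty(p)
    pen[0] = 0.0
    z = np.zeros(n)
    for it in range(1, max_em + 1):
        eta = X @ beta
        # E-step: responsibilities at current (pi, beta); zero for x > 0
        if zero_inflated and pi > 0.0:
            zsum = 0.0
            for i in range(n):
                if xj[i] == 0.0:
                    e = eta[i]
                    if e > clip:
                        e = clip
                    elif e < -clip:
                        e = -clip
                    z[i] = pi / (pi + (1.0 - pi) * math.exp(-math.exp(e)))
                    zsum += z[i]
                else:
                    z[i] = 0.0
            pi = zsum / n
        # the pi update alone cannot raise the observed objective (EM bound)
        ref = _zisp_objective(X, xj, logfact, beta, pi, lam, pen_w, clip)
        if ref > obj:
            ref = min(ref, obj)
        # M-step: max_mm majorize/solve cycles at fixed z, each safeguarded
        for _ in range(max_mm):
            eta = X @ beta
            sigma = sigma_floor
            w = np.empty(n)
            for i in range(n):
                e = eta[i]
                if e > clip:
                    e = clip
                elif e < -clip:
                    e = -clip
                mu = math.exp(e)
                omz_mu = (1.0 - z[i]) * mu
                if omz_mu > sigma:
                    sigma = omz_mu
                w[i] = (1.0 - z[i]) * (xj[i] - mu)  # b_i, rescaled below
            for i in range(n):
                w[i] = eta[i] + w[i] / sigma
            eff = n * lam / sigma
            for k in range(1, p):
                pen[k] = eff * pen_w[k - 1]
            beta_old = beta.copy()
            _cd_weighted_lasso(X, w, beta, pen, max_cd, cd_tol)
            newf = _zisp_objective(X, xj, logfact, beta, pi, lam, pen_w, clip)
            if newf > ref:
                step = beta - beta_old
                t = 1.0
                for _ in range(40):
                    t *= 0.5
                    beta = beta_old + t * step
                    newf = _zisp_objective(X, xj, logfact, beta, pi, lam,
                                           pen_w, clip)
                    if newf <= ref:
                        break
                if newf > ref:
                    beta = beta_old
                    newf = ref
            ref = newf
        new_obj = ref
        trace[it] = new_obj
        if abs(new_obj - obj) <= em_tol * (abs(obj) + 1e-10):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return beta, pi, it, obj, converged, trace[:it + 1]


# ---------------------------------------------------------------------------
# Node-level driver
# ---------------------------------------------------------------------------

def fit_node(X: CountMatrix, j: int, lam: float,
             weights: np.ndarray | None = None,
             cfg: EMConfig = EMConfig(),
             warm_start: tuple[np.ndarray, float] | None = None) -> NodeModel:
    """Fit node ``j``'s penalized zero-inflated Poisson regression by EM.

    Initialization follows the standard recipe: pi_j^(0) is the observed zero
    fraction of column j and beta^(0) = 0 (``warm_start`` overrides both, used
    when sweeping a lambda path).  Coefficients with magnitude below 1e-10 are
    snapped to exact zero so edge determination is unambiguous.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    p = X.n_nodes
    if not 0 <= j < p:
        raise IndexError(f"node index {j} out of range for p={p}")
    xj = X.values[:, j].astype(np.float64)
    zero_frac = float(np.mean(xj == 0))
    if zero_frac == 1.0 and not cfg.zero_inflated:
        raise ValueError(
            f"node {j} has all-zero counts; a Poisson fit without zero "
            "inflation is degenerate — filter such nodes first"
        )
    w = np.ones(p - 1) if weights is None else np.asarray(weights, np.float64)
    if w.shape != (p - 1,):
        raise ValueError(f"weights must have length p-1={p - 1}")
    design = np.asfortranarray(X.design_for(j))
    logfact = _log_factorial(xj)
    if warm_start is None:
        beta0, pi0 = np.zeros(p), zero_frac
    else:
        beta0 = np.asarray(warm_start[0], dtype=np.float64).copy()
        pi0 = float(warm_start[1])
    beta, pi, n_iters, _, converged, trace = _em_fit(
        design, xj, logfact, float(lam), w, cfg.zero_inflated, beta0, pi0,
        cfg.max_em_iters, cfg.em_tol, cfg.max_mm_iters, cfg.max_cd_iters,
        cfg.cd_tol, cfg.sigma_floor, cfg.clip_bound,
    )
    if not converged:
        warnings.warn(f"EM for node {j} did not converge in "
                      f"{cfg.max_em_iters} iterations", ConvergenceWarning,
                      stacklevel=2)
    coefs = beta[1:].copy()
    coefs[np.abs(coefs) < 1e-10] = 0.0
    model = NodeModel(node=j, intercept=float(beta[0]), coefficients=coefs,
                      mixing=float(min(max(pi, 0.0), 1.0)),
                      n_em_iters=int(n_iters), converged=bool(converged),
                      objective_trace=np.asarray(trace))
    pen_w = np.ones((p, p))
    pen_w[j, np.arange(p) != j] = w
    pen = PenaltySpec(lam=lam, weights=pen_w)
    model.final_objective = penalized_objective(X, j, model, pen,
                                                clip_bound=cfg.clip_bound)
    return model


def _log_factorial(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=np.float64) + 1.0)
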