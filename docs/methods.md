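# Methods

## Model

For a samples-by-nodes count matrix X (N × p), each node j is modeled
conditionally on the others by a zero-inflated Poisson (ZIP):
with probability π_j the observation is a structural zero, otherwise it is
Poisson with log-rate linear in the other nodes' counts,
μ_ij = exp(β_j + Σ_{k≠j} β_jk x_ik).  The p conditional models are tied
together only through the pseudo-likelihood; no consistent joint
distribution exists for a Poisson Markov random field with positive
dependencies, and this package makes no such claim.  The local (Markov)
interpretation still holds: β_jk = 0 means node j is conditionally
independent of node k given the rest, under node j's model.

Estimation minimizes, separately for each j,

    (1/N) Σ_i −log ZIP(x_ij; π_j, μ_ij) + λ Σ_{k≠j} w_jk |β_jk|,

with the intercept unpenalized.  The undirected edge set is the OR rule
over the directed supports: (j,k) ∈ Ê iff β̂_jk ≠ 0 or β̂_kj ≠ 0.
Fixing π_j = 0 (`EMConfig(zero_inflated=False)`) gives the plain penalized
Poisson neighborhood regression (the LPGM baseline).

## Algorithm

Each node is fit by EM on the mixture representation:

* **E-step** — responsibility of the structural-zero state:
  z_ij = π_j / (π_j + (1−π_j) e^{−μ_ij}) for x_ij = 0, and exactly 0 for
  x_ij ≥ 1.
* **π-step** — π_j ← mean(z_·j), the closed-form maximizer.
* **M-step** — the Poisson part of the complete-data likelihood is
  approximated at the current β by a quadratic with curvature bound
  σ = max_i (1−z_i) μ_i, yielding a weighted-lasso subproblem
  ½‖w − X_{−j}β‖² + (Nλ/σ) Σ_k w_jk |β_k| with working response
  w = X_{−j}β + b/σ, b_i = (1−z_i)(x_ij − μ_ij).  It is solved by cyclic
  coordinate descent with soft-thresholding; the intercept column is never
  penalized.  (The N in Nλ/σ keeps the subproblem on the same scale as the
  1/N-scaled objective; without it the λ grid below would be meaningless.)

Two numerical points deserve emphasis:

* **The curvature bound is local.**  σ = max (1−z_i)μ_i bounds the Hessian
  at the current iterate (σX^TX − X^T diag((1−z)μ)X is PSD there), but
  Poisson curvature grows as e^η along the step, so a full majorized step
  can overshoot and raise the objective.  `fit_node` therefore applies a
  step-halving safeguard: whenever the coordinate-descent solution
  increases the penalized objective, the step is shrunk toward the previous
  iterate until it descends.  The π-step alone can never raise the
  objective (standard EM bound), so the full trajectory — recorded in
  `NodeModel.objective_trace` — is monotone, and the test suite asserts
  this on random instances.
* **Guards.**  Linear predictors are clipped to ±30 before exponentiation
  (counts can be large; e^30 ≈ 1e13 is far beyond any useful rate);
  log x! goes through log-gamma; σ is floored at 1e−8 (all-structural-zero
  columns make every (1−z_i)μ_i vanish); coefficients below 1e−10 in
  magnitude are snapped to zero so edge determination is unambiguous.

**Ordering.**  At iteration m, z is computed from (π^{(m−1)}, β^{(m−1)}),
then π^{(m)} = mean(z), then the β step — the standard mixture-EM order,
consistent with the initialization π^{(0)} = observed zero fraction,
β^{(0)} = 0.  By default one majorize/solve cycle runs per EM iteration
(a generalized EM; descent already holds after one safeguarded cycle and
further cycles per iteration rarely change the final fit); `max_mm_iters`
exposes the alternative.

**Convergence.**  Relative change of the penalized objective below
`em_tol = 1e−6` (cap 200 EM iterations); coordinate-descent stops when the
largest coefficient update is below `cd_tol = 1e−7` (cap 1000 sweeps).
Hitting a cap emits a `ConvergenceWarning`, never an exception.  The inner
loops are numba-compiled; an LPGM-mode fit reproduces glmnet-style Poisson
lasso solutions (the tests verify against a proximal-gradient oracle).

## Penalty grid and weights

λ^max = max_{j≠k} (1/N) Σ_i x_ik x_ij, the largest off-diagonal raw
second moment — above it every penalized coefficient is zero, since the
uncentered cross product dominates the null-model score.  The grid is 30
points, log-equispaced down to λ^min = 10⁻⁴ λ^max.  Predictors are kept on
the raw count scale (no standardization), matching the λ^max formula.

Adaptive weights implement a two-stage fit: a plain ℓ1 Poisson screening
fit per node at the same λ sets w_jk = 1 on its support and 10⁵ elsewhere,
so the final zero-inflated fit can only deselect from the screened
support.  This sharpens a single network estimate, but for ROC scoring of
a whole path it makes the zero-inflated ranking strictly coarser than —
and largely a copy of — the Poisson screening ranking, which both blunts
the zero-inflation advantage and lets a paired test latch onto a minute
systematic difference at π = 0.  The evaluation harness and the
acceptance script therefore score paths fitted with unit weights;
`fit_path(..., use_adaptive=True)` remains the default for estimating a
single network.

**λ selection** (optional) uses stability selection (StARS): edge-selection
frequencies θ̂_e(λ) over `n_subsamples = 20` subsamples of size
⌊0.8 N⌋ drawn without replacement give the total instability
mean_e 2θ̂(1−θ̂); after monotonizing by a running maximum as λ decreases,
the smallest λ still below the 0.05 cut — the densest acceptably stable
graph — is returned (λ^min with a warning if nothing qualifies).  These
are the standard StARS constants; the criterion is deliberately
conservative and on small data often returns a near-empty graph.

## Synthetic data

`simulate` draws X = Y B + E: Y has one iid Poisson(λ_true = 1.5) column
per node and per node pair, E is iid Poisson(λ_noise = 0.5), and the
binary routing matrix B = [I_p ; P ⊙ (1_p tri(A)^T)]^T sends a pair column
to both endpoints exactly when that pair is an edge of the adjacency A,
whose upper triangle is iid Bernoulli(ρ).  Adjacent nodes therefore share
a latent column (covariance λ_true = 1.5); every node also keeps
independent variation (its own Y column plus E), so the marginal mean
without edges is λ_true + λ_noise = 2.0.  Zero inflation is imposed last:
each entry is independently replaced by 0 with probability π.  (Read
literally, "multiply by Bernoulli(π)" would zero entries with probability
1 − π, making π = 0 destroy all data; zeroing with probability π is the
only direction under which π = 0%, 10%, 20% are increasing inflation
levels.)  Draw order is fixed (A, Y, E, thinning mask) under one seeded
generator, so datasets are bit-reproducible.

What the generator emulates: overdispersed, positively dependent counts
with a known conditional-independence graph and controllable excess
zeros.  What it does not: negative dependencies, library-size or
gene-length effects, batch structure, or the heavy right tails of real
RNA-seq — so passing recovery benchmarks here demonstrates correctness of
the machinery under the stated model, not performance on real sequencing
data, which should additionally be filtered (`filter_nodes`) since
near-all-zero genes estimate π̂_j ≈ 1 and carry no edge information.

## Evaluation protocol

Active and inactive unordered node pairs of the true A are the positives
and negatives of a binary classifier; each λ on the path yields one
(FPR, TPR) point from the OR-rule edge set; endpoints (0,0) and (1,1) are
appended, points are sorted by FPR (ties resolved by TPR), and AUC is the
trapezoidal area.  Replication is paired — every method fits the same
simulated dataset, replicate r seeded by base_seed + r — and methods are
compared by the two-sided Wilcoxon signed-rank test on per-replicate AUCs
(zero differences dropped; exact null distribution for small samples via
scipy).

At the study conditions (p = 10, ρ = 0.2), the harness reproduces the
qualitative findings: with no inflation the zero-inflated and plain
Poisson methods are statistically indistinguishable, and under 10–20%
inflation the zero-inflated method wins decisively (sign-rank p < 0.01);
means, SEs and p-values for the exact conditions are computed by
`scripts/acceptance.py` and the acceptance tests, not restated here.
Problem sizes were chosen to keep the full suite in the minutes range on a
single CPU: 100 paired replicates at N = 50 and 40–50 at N = 150.

## Known limitations

* The pseudo-likelihood has no consistent joint model; estimated β̂_jk and
  β̂_kj can disagree in sign, and only the OR-rule support is interpreted.
* π_j is a free per-node parameter; with few observed zeros it is weakly
  identified, and with an all-zero column it is estimated as exactly 1
  (such nodes should be filtered out).
* The EM objective is non-convex (mixture); different warm starts can in
  principle reach different local optima.  The default cold start
  (π^{(0)} = zero fraction, β^{(0)} = 0) is used everywhere, including
  path fits, so results are deterministic.
* Stability selection refits the path n_subsamples × |grid| times and is
  the most expensive operation in the package.
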