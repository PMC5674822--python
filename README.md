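# zilpgm — zero-inflated local Poisson graphical models

Infers undirected networks from nonnegative count data — typically RNA-seq
gene counts — in which zeros are more frequent than a Poisson model expects.
Each node j is modeled conditionally on the remaining nodes by a
zero-inflated Poisson (ZIP) regression,

    P(X_j = x | x_-j) = π_j · I(x = 0) + (1 − π_j) · e^{−μ_j} μ_j^x / x!,
    μ_j = exp(β_j + Σ_{k≠j} β_jk x_k),

and the penalized pseudo-likelihood

    (1/N) Σ_j ℓ_j(β, π_j) + λ Σ_j Σ_{k≠j} w_jk |β_jk|

is minimized node by node.  Each node's problem is solved by an EM
algorithm: the E-step computes the posterior probability z_ij that an
observed zero is structural, π_j is updated in closed form, and the
Poisson part is minimized by a majorized weighted lasso solved with
coordinate descent.  An edge (j, k) is reported when β̂_jk ≠ 0 or β̂_kj ≠ 0
(OR rule).  Setting π_j ≡ 0 gives the plain local Poisson graphical model
(LPGM) baseline.  The package also ships the matching synthetic-network
generator (shared latent Poisson variables plus Bernoulli thinning) and a
ROC/AUC replication harness for structure-recovery benchmarking, so the
whole simulation study is reproducible from scratch.

Audience: statisticians and computational biologists who want
neighborhood-selection network inference that is honest about excess zeros,
without pretending a consistent joint Poisson graphical model exists (it
does not; see `docs/methods.md`).

## Worked example

```python
import numpy as np
import zilpgm as z

truth = z.simulate(z.SimulationConfig(n_samples=150, n_nodes=10,
                                      sparsity=0.2, zero_inflation=0.2,
                                      seed=42))
X = truth.counts
print("zero fraction:", round((X.values == 0).mean(), 3))

path = z.fit_path(X, z.GridSpec(), z.EMConfig(), use_adaptive=False)
print("ZILPGM path AUC:", round(z.roc_from_path(path, truth.adjacency).auc, 4))

lpath = z.fit_path(X, z.GridSpec(), z.EMConfig(zero_inflated=False),
                   use_adaptive=False)
print("LPGM   path AUC:", round(z.roc_from_path(lpath, truth.adjacency).auc, 4))

lam = z.select_lambda_stability(X, z.GridSpec(), z.EMConfig(),
                                n_subsamples=10, seed=0, use_adaptive=False)
est = z.fit_network(X, lam, weights=z.adaptive_weights(X, lam))
print("edges at selected lambda:", est.n_edges)
print("estimated mixing (pi_j):", np.round(est.mixing, 2))
```

prints

```
zero fraction: 0.238
ZILPGM path AUC: 0.9544
LPGM   path AUC: 0.7618
edges at selected lambda: 1
estimated mixing (pi_j): [0.17 0.24 0.22 0.15 0.25 0.21 0.21 0.21 0.19 0.22]
```

With 20% of entries replaced by structural zeros, the zero-inflated fit
ranks the eight true edges far better than the plain Poisson fit (AUC 0.95
vs 0.76), and the estimated mixing probabilities π̂_j sit near the 0.2 used
to generate the data.  Stability selection at the default 0.05 instability
cut is deliberately conservative and keeps only the most reproducible edge
here.

The same workflow is available from the shell:

```sh
zilpgm simulate -n 150 -p 10 --rho 0.2 --pi 0.2 --seed 42 -o sim/
zilpgm fit -i sim/counts.tsv -o net/ --lam 0.5 --min-nonzero 1
zilpgm evaluate -i sim/counts.tsv --truth sim/truth_edges.tsv -o eval/
zilpgm replicate -n 50 -p 10 --rho 0.2 --pi 0.2 --n-reps 100 -o table.tsv
```

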