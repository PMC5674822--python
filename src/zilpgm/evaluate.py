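"""Structure-recovery scoring and the replication/comparison harness.

A fitted regularization path is scored against the true simulated adjacency
by treating the active and inactive node pairs as positives and negatives of
a binary classifier: each lambda yields one (FPR, TPR) point, the endpoints
(0, 0) and (1, 1) are appended, and AUC is the trapezoidal area after sorting
by FPR.  Method comparisons are paired — every method sees the same simulated
dataset in each replicate — and summarized by a two-sided Wilcoxon
signed-rank test on the per-replicate AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import NetworkPath
from .network import GridSpec, fit_path
from .simulate import SimulationConfig, simulate
from .solver import EMConfig

__all__ = [
    "ROCResult",
    "MethodSpec",
    "ComparisonReport",
    "roc_from_path",
    "run_replications",
    "paired_signrank",
    "compare_methods",
    "results_table",
]


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positives: int
    n_negatives: int


@dataclass(frozen=True)
class MethodSpec:
    """One fitting configuration entering the replication harness."""

    name: str
    cfg: EMConfig = EMConfig()
    use_adaptive: bool = True
    grid: GridSpec = GridSpec()


@dataclass
class ComparisonReport:
    mean_auc_a: float
    mean_auc_b: float
    se_a: float
    se_b: float
    p_value: float
    n_reps: int


def _pair_scores(adjacency: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(adjacency.shape[0], k=1)
    return np.asarray(adjacency)[iu].astype(bool)


def roc_from_path(path: NetworkPath, truth: np.ndarray) -> ROCResult:
    """ROC over unordered node pairs for every estimate along the path."""
    pos = _pair_scores(truth)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "degenerate truth: need at least one active and one inactive pair"
        )
    fprs, tprs = [0.0, 1.0], [0.0, 1.0]
    for est in path.estimates:
        sel = _pair_scores(est.adjacency)
        tprs.append(float((sel & pos).sum() / n_pos))
        fprs.append(float((sel & ~pos).sum() / n_neg))
    order = np.lexsort((tprs, fprs))  # by FPR, ties broken toward max TPR last
    fpr = np.asarray(fprs)[order]
    tpr = np.asarray(tprs)[order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc,
                     n_positives=n_pos, n_negatives=n_neg)


def run_replications(cfg: SimulationConfig, methods: list[MethodSpec],
                     n_reps: int = 100, base_seed: int = 0,
                     progress: bool = False) -> dict[str, np.ndarray]:
    """Replicate simulate-fit-score, paired across methods.

    Replicate r uses seed ``base_seed + r``; every method fits the same
    dataset so the resulting AUC vectors are paired.  A failing replicate is
    dropped for all methods to preserve the pairing.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len({m.name for m in methods}) != len(methods):
        raise ValueError("method names must be unique")
    aucs: dict[str, list[float]] = {m.name: [] for m in methods}
    for r in range(n_reps):
        truth = simulate(replace(cfg, seed=base_seed + r))
        try:
            rep = {
                m.name: roc_from_path(
                    fit_path(truth.counts, m.grid, m.cfg, m.use_adaptive),
                    truth.adjacency,
                ).auc
                for m in methods
            }
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"replicate {r} skipped: {exc}", stacklevel=2)
            continue
        for name, auc in rep.items():
            aucs[name].append(auc)
        if progress:  # pragma: no cover - cosmetic
            print(f"replicate {r + 1}/{n_reps} done", flush=True)
    return {name: np.asarray(v) for name, v in aucs.items()}


def paired_signrank(auc_a: np.ndarray, auc_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired AUC differences.

    Zero differences are dropped; if every difference is zero the methods are
    indistinguishable and p = 1 is returned with a warning.
    """
    a = np.asarray(auc_a, dtype=np.float64)
    b = np.asarray(auc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("AUC vectors must be 1-D with equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired replicates")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox",
                         alternative="two-sided", method="auto")
    return float(res.pvalue)


def compare_methods(auc_a: np.ndarray, auc_b: np.ndarray) -> ComparisonReport:
    """Paired summary of two AUC vectors (means, standard errors, p-value)."""
    a = np.asarray(auc_a, dtype=np.float64)
    b = np.asarray(auc_b, dtype=np.float64)
    n = len(a)
    return ComparisonReport(
        mean_auc_a=float(a.mean()),
        mean_auc_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(n)),
        se_b=float(b.std(ddof=1) / np.sqrt(n)),
        p_value=paired_signrank(a, b),
        n_reps=n,
    )


def results_table(cfg: SimulationConfig, aucs: dict[str, np.ndarray],
                  path=None) -> pd.DataFrame:
    """Per-condition summary table: one row per method plus pairwise p-values.

    Columns mirror a simulation-study report: p, N, rho, pi, method,
    mean_auc, se, and p_vs_<other> columns from the paired sign-rank test.
    Written as TSV when ``path`` is given.
    """
    names = list(aucs)
    rows = []
    for name in names:
        v = aucs[name]
        row = {
            "p": cfg.n_nodes, "N": cfg.n_samples, "rho": cfg.sparsity,
            "pi": cfg.zero_inflation, "method": name,
            "mean_auc": float(np.mean(v)),
            "se": float(np.std(v, ddof=1) / np.sqrt(len(v))),
            "n_reps": len(v),
        }
        for other in names:
            if other != name:
                row[f"p_vs_{other}"] = paired_signrank(aucs[name], aucs[other])
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
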