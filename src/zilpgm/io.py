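"""Reading and writing count matrices, networks, and run configuration.

Count matrices travel as TSV/CSV (header row of node ids, optional leading
sample-id column) or MatrixMarket with ``<stem>.rows.txt`` / ``<stem>.cols.txt``
id sidecars.  Networks are written as an edge list, the full coefficient
matrix, the mixing vector, a degree table, and GraphML for downstream graph
tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .model import CountMatrix, NetworkEstimate
from .network import GridSpec
from .simulate import SimulationTruth
from .solver import EMConfig

__all__ = [
    "RunConfig",
    "read_counts",
    "write_counts",
    "filter_nodes",
    "write_network",
    "write_simulation",
]


@dataclass
class RunConfig:
    """Flat run configuration; every field maps to one CLI flag."""

    input_path: str = ""
    output_dir: str = "."
    orientation: str = "samples-by-nodes"
    n_grid_points: int = 30
    grid_min_ratio: float = 1e-4
    max_em_iters: int = 200
    em_tol: float = 1e-6
    max_mm_iters: int = 1
    max_cd_iters: int = 1000
    cd_tol: float = 1e-7
    min_nonzero: int = 0
    mode: str = "zilpgm"
    use_adaptive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("zilpgm", "lpgm"):
            raise ValueError("mode must be 'zilpgm' or 'lpgm'")
        if self.min_nonzero < 0:
            raise ValueError("min_nonzero must be >= 0")

    def em_config(self) -> EMConfig:
        return EMConfig(max_em_iters=self.max_em_iters, em_tol=self.em_tol,
                        max_mm_iters=self.max_mm_iters,
                        max_cd_iters=self.max_cd_iters, cd_tol=self.cd_tol,
                        zero_inflated=self.mode == "zilpgm")

    def grid_spec(self) -> GridSpec:
        return GridSpec(n_points=self.n_grid_points,
                        min_ratio=self.grid_min_ratio)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def read(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda s: s.lower() in ("1", "true", "yes")}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown configuration key {key!r}")
            kwargs[key] = casts[types[key]](val.strip())
        return cls(**kwargs)


def _validate_integer_frame(df: pd.DataFrame, path) -> np.ndarray:
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    bad = ~np.isfinite(arr) | (arr != np.floor(arr)) | (arr < 0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: entry {arr[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} is not a nonnegative integer"
        )
    return arr.astype(np.int64)


def read_counts(path, orientation: str = "samples-by-nodes") -> CountMatrix:
    """Read a count matrix from TSV/CSV (header row) or MatrixMarket.

    ``orientation`` names the layout on disk; the returned matrix is always
    samples-by-nodes.  For MatrixMarket, ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` supply the row and column labels when present.
    """
    if orientation not in ("samples-by-nodes", "nodes-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows_file = path.with_suffix(".rows.txt")
        cols_file = path.with_suffix(".cols.txt")
        row_ids = (rows_file.read_text().split() if rows_file.exists() else None)
        col_ids = (cols_file.read_text().split() if cols_file.exists() else None)
        df = pd.DataFrame(mat, index=row_ids, columns=col_ids)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        first = df.columns[0]
        if df[first].dtype == object:  # leading sample-id column
            df = df.set_index(first)
    values = _validate_integer_frame(df, path)
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "nodes-by-samples":
        values, row_ids, col_ids = values.T, col_ids, row_ids
    return CountMatrix(values, sample_ids=row_ids, node_ids=col_ids)


def write_counts(X: CountMatrix, path) -> None:
    """Write samples-by-nodes TSV with a header row of node ids."""
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.node_ids)
    df.to_csv(path, sep="\t", index_label="sample")


def filter_nodes(X: CountMatrix, min_nonzero: int) -> tuple[CountMatrix, list[str]]:
    """Keep nodes with at least ``min_nonzero`` nonzero counts.

    Near-all-zero nodes drive the mixing estimate to one and contribute no
    usable edges, so they are dropped before fitting.  Returns the filtered
    matrix and the ids of dropped nodes.
    """
    if min_nonzero < 0:
        raise ValueError("min_nonzero must be >= 0")
    nonzero = np.count_nonzero(X.values, axis=0)
    keep = nonzero >= min_nonzero
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 nodes have >= {min_nonzero} nonzero counts"
        )
    dropped = [X.node_ids[j] for j in np.flatnonzero(~keep)]
    if not dropped:
        return X, []
    return (
        CountMatrix(X.values[:, keep], sample_ids=list(X.sample_ids),
                    node_ids=[X.node_ids[j] for j in np.flatnonzero(keep)]),
        dropped,
    )


def write_network(est: NetworkEstimate, outdir,
                  node_ids: list[str] | None = None) -> dict[str, Path]:
    """Write one network estimate to ``outdir``.

    Produces edges.tsv (node_a, node_b, beta_ab, beta_ba), coefficients.tsv
    (full p x p matrix, diagonal = intercepts), mixing.tsv, degrees.tsv
    (sorted descending), and network.graphml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = est.coef.shape[0]
    ids = node_ids if node_ids is not None else [f"v{j}" for j in range(p)]
    paths = {}

    edges = pd.DataFrame(
        [
            {"node_a": ids[j], "node_b": ids[k],
             "beta_ab": est.coef[j, k], "beta_ba": est.coef[k, j]}
            for j, k in est.edge_list()
        ],
        columns=["node_a", "node_b", "beta_ab", "beta_ba"],
    )
    paths["edges"] = outdir / "edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False)

    paths["coefficients"] = outdir / "coefficients.tsv"
    pd.DataFrame(est.coef, index=ids, columns=ids).to_csv(
        paths["coefficients"], sep="\t", index_label="node")

    paths["mixing"] = outdir / "mixing.tsv"
    pd.DataFrame({"node": ids, "mixing": est.mixing}).to_csv(
        paths["mixing"], sep="\t", index=False)

    degree = est.adjacency.sum(axis=1)
    deg = pd.DataFrame({"node": ids, "degree": degree})
    deg = deg.sort_values(["degree", "node"], ascending=[False, True])
    paths["degrees"] = outdir / "degrees.tsv"
    deg.to_csv(paths["degrees"], sep="\t", index=False)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for j, k in est.edge_list():
        g.add_edge(ids[j], ids[k],
                   beta_ab=float(est.coef[j, k]), beta_ba=float(est.coef[k, j]))
    paths["graphml"] = outdir / "network.graphml"
    nx.write_graphml(g, paths["graphml"])
    return paths


def write_simulation(truth: SimulationTruth, outdir) -> dict[str, Path]:
    """Write simulated counts (TSV), true edges (TSV), and the configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"counts": outdir / "counts.tsv",
             "truth": outdir / "truth_edges.tsv",
             "config": outdir / "sim_config.txt"}
    write_counts(truth.counts, paths["counts"])
    ids = truth.counts.node_ids
    edges = pd.DataFrame(
        [{"node_a": ids[j], "node_b": ids[k]}
         for j, k in truth.pair_index if truth.adjacency[j, k]],
        columns=["node_a", "node_b"],
    )
    edges.to_csv(paths["truth"], sep="\t", index=False)
    cfg = truth.config
    with open(paths["config"], "w") as fh:
        for f in fields(cfg):
            fh.write(f"{f.name}={getattr(cfg, f.name)}\n")
    return paths
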