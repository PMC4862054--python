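"""Drug-response profile clustering, TreeView-compatible export, and
responder-group biomarker association.

Drugs (rows) are clustered with a Spearman rank-correlation distance,
cell lines (columns) with Euclidean distance, both under complete
linkage.  Missing entries are excluded pairwise from distances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import false_discovery_control, ttest_ind

__all__ = [
    "ClusterResult",
    "MarkerTestResult",
    "spearman_distance_matrix",
    "euclidean_distance_matrix",
    "cluster_profiles",
    "export_cluster_files",
    "read_cdt",
    "read_tree_file",
    "define_responder_groups",
    "marker_ttest",
]

log = logging.getLogger(__name__)

#: Distance assigned to pairs involving a zero-variance profile under
#: Spearman (the maximum of the 1 - rho range).
MAX_SPEARMAN_DISTANCE = 2.0


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    row_labels: list
    col_labels: list
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MarkerTestResult:
    marker: str
    mean_a: float
    mean_b: float
    t: float
    p: float
    significant: bool
    p_adjusted: float = float("nan")


def _condense(d: np.ndarray) -> np.ndarray:
    return d[np.triu_indices_from(d, k=1)]


def spearman_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """1 - Spearman rho between the rows of ``profiles``.

    Ties get average ranks; missing values are excluded pairwise.
    Pairs involving a zero-variance profile are undefined under rank
    correlation and get the maximal distance 2.0 (logged).
    """
    rho = profiles.T.corr(method="spearman").to_numpy()
    dist = 1.0 - rho
    undefined = np.isnan(dist)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        rows = [profiles.index[i] for i in np.unique(np.where(undefined)[0])]
        log.warning("zero-variance profiles %s: Spearman distance set to %.1f",
                    rows, MAX_SPEARMAN_DISTANCE)
        dist[undefined] = MAX_SPEARMAN_DISTANCE
    np.fill_diagonal(dist, 0.0)
    return dist


def euclidean_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distance between rows, pairwise-complete."""
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(x[i]) | np.isnan(x[j]))
            if not both.any():
                raise ValueError(
                    f"rows {profiles.index[i]} and {profiles.index[j]} share "
                    "no observed entries")
            d = float(np.sqrt(np.sum((x[i, both] - x[j, both]) ** 2)))
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_profiles(matrix: pd.DataFrame,
                     row_metric: str = "spearman",
                     col_metric: str = "euclidean") -> ClusterResult:
    """Complete-linkage clustering of a response-profile matrix.

    Rows (drugs) default to the Spearman rank distance, columns (cell
    lines) to Euclidean distance.  The input order is the deterministic
    tie-breaker inherited from the linkage implementation.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix to cluster")
    metrics = {"spearman": spearman_distance_matrix,
               "euclidean": euclidean_distance_matrix}
    row_d = metrics[row_metric](matrix)
    col_d = metrics[col_metric](matrix.T)
    row_z = linkage(_condense(row_d), method="complete")
    col_z = linkage(_condense(col_d), method="complete")
    row_order = [matrix.index[i] for i in leaves_list(row_z)]
    col_order = [matrix.columns[i] for i in leaves_list(col_z)]
    return ClusterResult(
        row_linkage=row_z, col_linkage=col_z,
        row_order=row_order, col_order=col_order,
        row_labels=list(matrix.index), col_labels=list(matrix.columns),
        metadata={"row_metric": row_metric, "col_metric": col_metric,
                  "linkage": "complete"})


def _write_tree(path, z: np.ndarray, item_prefix: str, node_prefix: str) -> None:
    """Write a GTR/ATR merge list; 4th column is 1 - merge height."""
    n = z.shape[0] + 1

    def name(k: int) -> str:
        return (f"{item_prefix}{k}X" if k < n
                else f"{node_prefix}{k - n + 1}X")

    with open(path, "w") as fh:
        for step, (a, b, height, _) in enumerate(z, start=1):
            fh.write(f"{node_prefix}{step}X\t{name(int(a))}\t{name(int(b))}\t"
                     f"{1.0 - height:.10g}\n")


def export_cluster_files(matrix: pd.DataFrame, result: ClusterResult,
                         prefix) -> dict:
    """Write TreeView-compatible CDT/GTR/ATR files plus a JSON dump.

    The CDT holds the matrix reordered to the dendrogram leaf orders;
    GTR/ATR list the row/column merges with similarity ``1 - height``.
    Returns the paths written.
    """
    prefix = str(prefix)
    paths = {"cdt": prefix + ".cdt", "gtr": prefix + ".gtr",
             "atr": prefix + ".atr", "json": prefix + ".json"}
    reordered = matrix.loc[result.row_order, result.col_order]
    row_pos = {lab: i for i, lab in enumerate(result.row_labels)}
    col_pos = {lab: i for i, lab in enumerate(result.col_labels)}

    with open(paths["cdt"], "w") as fh:
        cols = "\t".join(str(c) for c in reordered.columns)
        fh.write(f"GID\tUNIQID\tNAME\tGWEIGHT\t{cols}\n")
        aids = "\t".join(f"ARRY{col_pos[c]}X" for c in reordered.columns)
        fh.write(f"AID\t\t\t\t{aids}\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * reordered.shape[1]) + "\n")
        for lab, row in reordered.iterrows():
            vals = "\t".join("" if pd.isna(v) else f"{v:.10g}" for v in row)
            fh.write(f"GENE{row_pos[lab]}X\t{lab}\t{lab}\t1\t{vals}\n")

    _write_tree(paths["gtr"], result.row_linkage, "GENE", "NODE")
    _write_tree(paths["atr"], result.col_linkage, "ARRY", "NODE")

    with open(paths["json"], "w") as fh:
        json.dump({
            "row_order": [str(v) for v in result.row_order],
            "col_order": [str(v) for v in result.col_order],
            "row_linkage": result.row_linkage.tolist(),
            "col_linkage": result.col_linkage.tolist(),
            "metadata": result.metadata,
        }, fh, indent=1)
    return paths


def read_cdt(path) -> pd.DataFrame:
    """Read back the reordered matrix from a CDT file."""
    df = pd.read_csv(path, sep="\t", index_col=False)
    df = df[~df["GID"].isin(["AID", "EWEIGHT"])]
    out = df.drop(columns=["GID", "NAME", "GWEIGHT"]).set_index("UNIQID")
    out.index.name = None
    return out.astype(float)


def read_tree_file(path):
    """Read a GTR/ATR file back into (node, left, right, height) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            node, left, right, sim = line.rstrip("\n").split("\t")
            rows.append((node, left, right, 1.0 - float(sim)))
    return rows


def define_responder_groups(records: pd.DataFrame, drug_class: str,
                            readout: str, threshold: float,
                            class_map: dict | None = None):
    """Split cell lines by mean class response on one readout.

    ``records`` is a long DSS table (cell_line, compound_id, readout,
    dss) with either a drug_class column or a ``class_map`` from
    compound_id to class.  A line is "sensitive" when its mean DSS over
    the class's compounds reaches ``threshold``.

    Returns ``(sensitive, insensitive, class_means)``.
    """
    df = records[records["readout"] == readout].copy()
    if "drug_class" not in df.columns:
        if class_map is None:
            raise ValueError("records lack a drug_class column and no "
                             "class_map was given")
        df["drug_class"] = df["compound_id"].map(class_map)
    df = df[df["drug_class"] == drug_class]
    if df.empty:
        raise ValueError(f"no compounds of class {drug_class!r} "
                         f"on readout {readout!r}")
    means = df.groupby("cell_line")["dss"].mean()
    sensitive = set(means.index[means >= threshold])
    insensitive = set(means.index) - sensitive
    if not sensitive:
        log.warning("no cell line reached the sensitivity threshold %.3g "
                    "for class %s", threshold, drug_class)
    return sensitive, insensitive, means


def marker_ttest(marker_table: pd.DataFrame, groups, alpha: float = 0.05,
                 equal_var: bool = False, adjust: str | None = None):
    """Two-sample t-test of every marker between two cell-line groups.

    Welch's test by default (``equal_var=True`` for the pooled-variance
    variant).  Significance is called on raw p-values at ``alpha``;
    ``adjust="bh"`` switches the call to Benjamini-Hochberg adjusted
    p-values instead.
    """
    group_a, group_b = (list(g) for g in groups)
    for name, g in (("A", group_a), ("B", group_b)):
        if len(g) < 2:
            raise ValueError(f"group {name} has fewer than 2 cell lines")
    a = marker_table[group_a].to_numpy(dtype=float)
    b = marker_table[group_b].to_numpy(dtype=float)
    t, p = ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    # zero-variance groups: define t from the mean difference alone
    bad = np.isnan(t)
    same = bad & np.isclose(mean_a, mean_b)
    t[same], p[same] = 0.0, 1.0
    diff = bad & ~same
    t[diff] = np.sign(mean_a[diff] - mean_b[diff]) * np.inf
    p[diff] = 0.0

    p_adj = false_discovery_control(p, method="bh") if adjust == "bh" else None
    results = []
    for i, marker in enumerate(marker_table.index):
        p_use = p_adj[i] if p_adj is not None else p[i]
        results.append(MarkerTestResult(
            marker=str(marker), mean_a=float(mean_a[i]), mean_b=float(mean_b[i]),
            t=float(t[i]), p=float(p[i]),
            significant=bool(p_use <= alpha),
            p_adjusted=float(p_adj[i]) if p_adj is not None else float("nan")))
    return results
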