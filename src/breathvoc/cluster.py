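"""Log transform, agglomerative clustering, and heat-map bundle export.

The exploratory view of the concentration matrix is a clustergram: samples
and VOCs are each clustered agglomeratively (Euclidean distance on log10
concentrations, complete linkage by default) and the reordered matrix is
exported together with both merge trees and annotation tracks (per-VOC screen
flags, per-sample group/site labels) so any plotting front-end can render the
figure.  No figure is rendered here; the matrix and orderings are the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .cohort import voc_columns
from .siftms import InvalidInputError, SchemaError, META_COLS


@dataclass
class ClusterResult:
    axis: str                    # "rows" | "columns"
    labels: list[str]
    linkage_matrix: np.ndarray   # scipy (n-1, 4) format; empty for single item
    leaf_order: list[str]

    @property
    def merge_tree(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    def flat_clusters(self, k: int) -> dict[str, int]:
        if len(self.labels) == 1:
            return {self.labels[0]: 1}
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assign)))

    def to_json_dict(self) -> dict:
        return {"axis": self.axis, "labels": self.labels,
                "merges": self.merge_tree, "leaf_order": self.leaf_order}


def log_transform(table: pd.DataFrame, pseudocount: float = 0.001) -> pd.DataFrame:
    """Elementwise log10(x + pseudocount) over the VOC columns.

    Strictly monotone in x and finite for all x >= 0.  Missing cells are
    imputed with the per-VOC minimum observed value first (below-LOD
    semantics).
    """
    if not pseudocount > 0:
        raise InvalidInputError("pseudocount must be > 0")
    vocs = voc_columns(table)
    x = table[vocs].astype(float)
    if (x.to_numpy() < 0).any():
        raise InvalidInputError("concentrations must be >= 0")
    x = x.fillna(x.min(axis=0))
    out = table.copy()
    out[vocs] = np.log10(x + pseudocount)
    return out


def hier_cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    distance: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative hierarchical clustering of rows or columns.

    Deterministic given the input; merge heights are non-decreasing for the
    default complete linkage.
    """
    if axis not in ("rows", "columns"):
        raise InvalidInputError("axis must be 'rows' or 'columns'")
    data = matrix.to_numpy(dtype=float) if axis == "rows" else matrix.to_numpy(dtype=float).T
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    labels = [str(v) for v in labels]
    if len(labels) == 0:
        raise InvalidInputError("empty matrix")
    if not np.isfinite(data).all():
        raise InvalidInputError("matrix must be finite (impute missing values first)")
    if len(labels) == 1:
        return ClusterResult(axis, labels, np.empty((0, 4)), labels)
    z = hierarchy.linkage(pdist(data, metric=distance), method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(axis, labels, z, order)


def export_heatmap_bundle(
    matrix: pd.DataFrame,
    row_cluster: ClusterResult,
    col_cluster: ClusterResult,
    voc_annotations: pd.DataFrame,
    sample_annotations: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the reordered matrix, both merge trees, and annotation tracks.

    ``voc_annotations`` is indexed by VOC id (e.g. significant / nondifferential
    flags from a screen); ``sample_annotations`` by sample id (group / site).
    """
    if set(map(str, matrix.index)) != set(row_cluster.labels):
        raise SchemaError("row_cluster labels do not match matrix index")
    if set(map(str, matrix.columns)) != set(col_cluster.labels):
        raise SchemaError("col_cluster labels do not match matrix columns")
    bad_voc = sorted(set(map(str, voc_annotations.index)) - set(map(str, matrix.columns)))
    if bad_voc:
        raise SchemaError(f"annotation keys not in matrix columns: {bad_voc}")
    bad_sample = sorted(set(map(str, sample_annotations.index)) - set(map(str, matrix.index)))
    if bad_sample:
        raise SchemaError(f"annotation keys not in matrix rows: {bad_sample}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = matrix.loc[row_cluster.leaf_order, col_cluster.leaf_order]
    paths = {
        "matrix": out / "heatmap_matrix.tsv",
        "trees": out / "merge_trees.json",
        "voc_annotations": out / "voc_annotations.tsv",
        "sample_annotations": out / "sample_annotations.tsv",
    }
    ordered.to_csv(paths["matrix"], sep="\t", float_format="%.10g")
    paths["trees"].write_text(json.dumps(
        {"rows": row_cluster.to_json_dict(), "columns": col_cluster.to_json_dict()}, indent=1))
    voc_annotations.loc[[v for v in col_cluster.leaf_order if v in voc_annotations.index]].to_csv(
        paths["voc_annotations"], sep="\t")
    sample_annotations.loc[[s for s in row_cluster.leaf_order if s in sample_annotations.index]].to_csv(
        paths["sample_annotations"], sep="\t")
    return paths


def cluster_table(
    table: pd.DataFrame,
    pseudocount: float = 0.001,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> tuple[pd.DataFrame, ClusterResult, ClusterResult]:
    """Log-transform a sample table and cluster samples and VOCs."""
    logged = log_transform(table, pseudocount)
    mat = logged.set_index("sample_id")[voc_columns(logged)] if "sample_id" in logged.columns \
        else logged[voc_columns(logged)]
    rows = hier_cluster(mat, "rows", distance, linkage)
    cols = hier_cluster(mat, "columns", distance, linkage)
    return mat, rows, cols
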