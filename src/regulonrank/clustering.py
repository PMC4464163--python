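"""Two-way hierarchical clustering of a DEG x sample expression submatrix.

Gene rows are standardized (mean 0, variance 1) before clustering — the
usual heatmap convention — then genes and samples are clustered
independently with agglomerative linkage on the chosen distance.  Defaults
(euclidean distance, complete linkage) follow the common R heatmap
defaults.  The clustering is deterministic given the input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError
from .io_formats import ExpressionMatrix

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("complete", "average")


@dataclass
class Dendrogram:
    """An agglomeration history over labelled leaves.

    ``merges`` is the (m-1) x 4 linkage matrix (left node, right node,
    height, cluster size) in scipy convention; ``leaf_order`` is the
    left-to-right leaf permutation of the corresponding dendrogram plot.
    """

    merges: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> dict[str, int]:
        """Label -> cluster id (1..k) from cutting the tree into k clusters."""
        assignments = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assignments)}

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center and scale each row to mean 0, variance 1 (constant rows -> 0)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (values - mu) / sd


def _cluster_axis(values: np.ndarray, labels: list[str], distance: str,
                  linkage: str) -> Dendrogram:
    dmat = pdist(values, metric=distance)
    dmat = np.maximum(dmat, 0.0)  # correlation metric can round below zero
    merges = hierarchy.linkage(dmat, method=linkage)
    leaf_order = list(hierarchy.leaves_list(merges))
    return Dendrogram(merges, leaf_order, list(labels))


def two_way_cluster(
    em: ExpressionMatrix | pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
    standardize: bool = True,
) -> tuple[Dendrogram, Dendrogram]:
    """Cluster genes (rows) and samples (columns) independently.

    Returns ``(row_dendrogram, col_dendrogram)``.  Requires at least two
    genes and two samples.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    frame = em.values if isinstance(em, ExpressionMatrix) else em
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise DegenerateInputError(
            f"need >= 2 items on both axes, got shape {frame.shape}"
        )
    arr = frame.to_numpy(dtype=float)
    if standardize:
        arr = standardize_rows(arr)
    rows = _cluster_axis(arr, list(frame.index), distance, linkage)
    cols = _cluster_axis(arr.T, list(frame.columns), distance, linkage)
    return rows, cols


def write_dendrogram(dend: Dendrogram, merges_path, leaves_path) -> None:
    dend.to_frame().to_csv(merges_path, sep="\t", index=False)
    with open(leaves_path, "w") as fh:
        fh.write("leaf\n")
        for lab in dend.ordered_labels():
            fh.write(f"{lab}\n")


def plot_heatmap(em: ExpressionMatrix | pd.DataFrame, path, **cluster_kw) -> None:
    """Convenience clustered heatmap (PNG/SVG); not a tested surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = em.values if isinstance(em, ExpressionMatrix) else em
    rows, cols = two_way_cluster(em, **cluster_kw)
    arr = standardize_rows(frame.to_numpy(dtype=float))
    arr = arr[np.ix_(rows.leaf_order, cols.leaf_order)]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(arr, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(cols.leaf_order)))
    ax.set_xticklabels(cols.ordered_labels(), rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
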