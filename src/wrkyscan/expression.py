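"""RPKM expression profiling of family genes across tissues.

RPKM = count / (gene length in kb x mapped reads in millions).  The per-tissue
mapped-read total defaults to the column sum of the supplied count table.
The heat-map export is log2(RPKM) with NA where the count is zero (rendered
white: the gene is not expressed in that tissue).  Tissues are clustered by
average-linkage hierarchical agglomeration on Euclidean distances of the log2
matrix (NA treated as 0 for distances only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def rpkm(count: float, gene_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return count / ((gene_length_bp / 1000.0) * (total_mapped_reads / 1e6))


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame                 # genes x tissues, nonnegative integers
    gene_lengths_bp: pd.Series           # indexed by gene
    library_sizes: pd.Series = field(default=None)  # per-tissue totals

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.index) - set(self.gene_lengths_bp.index)
        if missing:
            raise ValueError(f"genes without length: {sorted(missing)[:5]}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        if (self.library_sizes <= 0).any():
            raise ValueError("non-positive library size")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.counts.columns)

    def rpkm_matrix(self) -> pd.DataFrame:
        lengths_kb = self.gene_lengths_bp.loc[self.counts.index] / 1000.0
        millions = self.library_sizes / 1e6
        return self.counts.div(millions, axis=1).div(lengths_kb, axis=0)

    def heatmap_matrix(self) -> pd.DataFrame:
        """log2(RPKM), NA where the raw count is zero."""
        r = self.rpkm_matrix()
        with np.errstate(divide="ignore"):
            logs = np.log2(np.where(r.values > 0, r.values, 1.0))
        return pd.DataFrame(
            np.where(self.counts.values > 0, logs, np.nan),
            index=r.index,
            columns=r.columns,
        )

    def expressed_per_tissue(self) -> pd.Series:
        """Number of genes with a nonzero count in each tissue."""
        return (self.counts > 0).sum(axis=0)


def cluster_tissues(em: ExpressionMatrix) -> str:
    """Average-linkage dendrogram over tissues, returned as a Newick string.

    Distances are Euclidean on the log2 matrix with NA zero-filled.  Merge
    heights label internal branch lengths; ties resolve deterministically from
    tissue order.
    """
    tissues = em.tissue_names
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    mat = em.heatmap_matrix().fillna(0.0).values.T  # tissues x genes
    Z = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
    root, _ = hierarchy.to_tree(Z, rd=True)

    def _newick(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{tissues[node.id]}:{length:.6g}"
        left = _newick(node.left, node.dist)
        right = _newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({_newick(root.left, root.dist)},{_newick(root.right, root.dist)});"
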