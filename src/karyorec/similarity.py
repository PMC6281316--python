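"""Pairwise inter-nucleus similarity/divergence matrices and clade clustering.

Two pairwise datasets are built from the genotype matrix:

* ``matrix_variable`` — fraction of matching genotypes over the shared
  non-missing *filtered SNP* positions of each pair (the variable-region
  dataset);
* ``matrix_covered`` — divergence over the shared *covered* positions of
  each pair: mismatching variant genotypes divided by the length of the
  coverage-mask intersection, so invariant positions count as matches.

Nuclei are then clustered by average-linkage hierarchical clustering on
1 − matrix_variable and split into two clades (dikaryons always segregate
into two main clades).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import intervals as iv
from .genotyping import MISSING, GenotypeMatrix
from .io import write_matrix

logger = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    nuclei: list[str]
    matrix_variable: np.ndarray  # similarity over shared variant positions
    matrix_covered: np.ndarray  # divergence over shared covered positions
    shared_variable: np.ndarray  # pairwise denominators (variant positions)
    shared_covered: np.ndarray  # pairwise denominators (covered bp)
    linkage: np.ndarray | None = None
    clades: dict[str, int] = field(default_factory=dict)
    leaf_order: list[int] = field(default_factory=list)


def pairwise_similarity(matrix: GenotypeMatrix) -> SimilarityResult:
    """Compute both pairwise matrices; entries with empty denominators are NaN."""
    n = len(matrix.nuclei)
    if n < 2:
        raise ValueError("need at least two nuclei for pairwise comparison")
    calls = matrix.calls
    present = calls != MISSING
    mat_var = np.full((n, n), np.nan)
    mat_cov = np.full((n, n), np.nan)
    shared_var = np.zeros((n, n), dtype=np.int64)
    shared_cov = np.zeros((n, n), dtype=np.int64)

    masks = matrix.coverage_masks
    np.fill_diagonal(mat_var, 1.0)
    np.fill_diagonal(mat_cov, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            n_shared = int(both.sum())
            matches = int((calls[i][both] == calls[j][both]).sum())
            mismatches = n_shared - matches
            shared_var[i, j] = shared_var[j, i] = n_shared
            if n_shared > 0:
                mat_var[i, j] = mat_var[j, i] = matches / n_shared
            mi = masks.get(matrix.nuclei[i], {})
            mj = masks.get(matrix.nuclei[j], {})
            cov = sum(
                iv.total_length(iv.intersect(mi[s], mj[s]))
                for s in set(mi) & set(mj)
            )
            shared_cov[i, j] = shared_cov[j, i] = cov
            if cov > 0:
                mat_cov[i, j] = mat_cov[j, i] = mismatches / cov
    return SimilarityResult(
        list(matrix.nuclei), mat_var, mat_cov, shared_var, shared_cov
    )


def cluster_nuclei(result: SimilarityResult, k: int = 2) -> SimilarityResult:
    """Average-linkage clustering on 1 − similarity; clade labels from a k-cut.

    NaN similarities are imputed with the mean of the defined off-diagonal
    entries (for clustering only; the matrices are left untouched).  Clade
    numbering is deterministic: clade 1 is the clade of the first nucleus in
    input order.
    """
    sim = result.matrix_variable.copy()
    off = ~np.eye(len(sim), dtype=bool)
    defined = off & ~np.isnan(sim)
    if not defined.any():
        raise ValueError("all pairwise similarities undefined")
    n_missing = int((off & np.isnan(sim)).sum())
    if n_missing:
        fill = float(np.nanmean(sim[off]))
        logger.info(
            "imputing %d undefined pairwise entries with mean similarity %.4f "
            "(clustering only)",
            n_missing,
            fill,
        )
        sim[np.isnan(sim)] = fill
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    result.linkage = linkage
    result.clades = {
        name: relabel[lab] for name, lab in zip(result.nuclei, raw)
    }
    result.leaf_order = list(hierarchy.leaves_list(linkage))
    return result


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = recurse(node.left), recurse(node.right)
        ld = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        rd = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{ld:.6g},{right}:{rd:.6g})"

    return recurse(tree) + ";"


def render_heatmap(
    result: SimilarityResult,
    mat_assignment=None,
    path: str | Path | None = None,
    tsv_path: str | Path | None = None,
):
    """Similarity heatmap in linkage leaf order, MAT labels annotated.

    NaN entries are rendered in a sentinel colour and written as ``NA`` in
    the companion TSV.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not result.leaf_order:
        raise ValueError("cluster_nuclei must be run before rendering")
    order = result.leaf_order
    names = [result.nuclei[i] for i in order]
    mat = result.matrix_variable[np.ix_(order, order)]
    if mat_assignment is not None:
        names = [
            f"{n} [{mat_assignment.assignment.get(n, '?')}]" for n in names
        ]
    ordered = pd.DataFrame(mat, index=names, columns=names)
    if tsv_path is not None:
        write_matrix(ordered, tsv_path)
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(names)),) * 2)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(np.ma.masked_invalid(mat), cmap=cmap, vmin=np.nanmin(mat), vmax=1.0)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    fig.colorbar(im, ax=ax, label="similarity (shared variant positions)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig, ordered
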