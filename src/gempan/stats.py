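"""Statistics over binary phenotype / presence matrices.

Strains are compared by Jaccard distance on their binary growth (or
presence) profiles, clustered agglomeratively (average linkage by default)
and projected by PCA. The agglomeration is implemented explicitly rather
than delegated so that tie-breaking is fully specified: when two cluster
pairs are equidistant, the pair whose leaf-label-sorted identifiers are
lexicographically smallest merges first, making dendrograms reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .model import Model

__all__ = [
    "Dendrogram",
    "PCAResult",
    "jaccard_distance",
    "hierarchical_cluster",
    "pca_project",
    "gene_reaction_correlation",
]


def jaccard_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between rows: d = 1 - |x&y| / |x|y|.

    Two all-zero rows are at distance 0 (the 0/0 case is defined as
    identity). Entries must be binary.
    """
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("Jaccard distance needs a binary matrix")
    b = vals.astype(bool)
    inter = (b[:, None, :] & b[None, :, :]).sum(axis=2).astype(float)
    union = (b[:, None, :] | b[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class Merge:
    left: Tuple[str, ...]
    right: Tuple[str, ...]
    height: float

    @property
    def members(self) -> Tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass
class Dendrogram:
    """Binary merge tree; heights are non-decreasing root-ward."""

    leaves: List[str]
    merges: List[Merge]
    linkage_method: str

    def cut(self, k: int) -> pd.Series:
        """Labels for k clusters (undo the last k-1 merges)."""
        if not 1 <= k <= len(self.leaves):
            raise ValueError(f"k must be in [1, {len(self.leaves)}]")
        clusters = {(leaf,) for leaf in self.leaves}
        for merge in self.merges[: len(self.merges) - (k - 1)]:
            clusters.discard(merge.left)
            clusters.discard(merge.right)
            clusters.add(merge.members)
        labels = {}
        for i, cl in enumerate(sorted(clusters)):
            for leaf in cl:
                labels[leaf] = i
        return pd.Series({leaf: labels[leaf] for leaf in self.leaves}, name="cluster")

    def leaf_order(self) -> List[str]:
        """Left-to-right leaf order of the dendrogram (for heatmap axes)."""
        order: Dict[Tuple[str, ...], List[str]] = {(leaf,): [leaf] for leaf in self.leaves}
        for merge in self.merges:
            order[merge.members] = order[merge.left] + order[merge.right]
        if self.merges:
            return order[self.merges[-1].members]
        return list(self.leaves)

    def to_linkage_matrix(self) -> Tuple[np.ndarray, List[str]]:
        """scipy-format (n-1, 4) linkage matrix plus the leaf ordering it
        indexes into."""
        leaves = sorted(self.leaves)
        ids: Dict[Tuple[str, ...], int] = {(leaf,): i for i, leaf in enumerate(leaves)}
        Z = np.zeros((len(self.merges), 4))
        for i, merge in enumerate(self.merges):
            a, b_ = ids[merge.left], ids[merge.right]
            ids[merge.members] = len(leaves) + i
            Z[i] = [min(a, b_), max(a, b_), merge.height, len(merge.members)]
        return Z, leaves

    def to_newick(self) -> str:
        """Newick with branch lengths = merge-height differences."""
        height_of: Dict[Tuple[str, ...], float] = {(leaf,): 0.0 for leaf in self.leaves}
        text: Dict[Tuple[str, ...], str] = {(leaf,): leaf for leaf in self.leaves}
        for merge in self.merges:
            bl_l = merge.height - height_of[merge.left]
            bl_r = merge.height - height_of[merge.right]
            text[merge.members] = (
                f"({text[merge.left]}:{bl_l:.6g},{text[merge.right]}:{bl_r:.6g})"
            )
            height_of[merge.members] = merge.height
        root = self.merges[-1].members if self.merges else (self.leaves[0],)
        return text[root] + ";"


def _cluster_distance(
    d: np.ndarray, a: List[int], b: List[int], method: str
) -> float:
    block = d[np.ix_(a, b)]
    if method == "average":
        return float(block.mean())
    if method == "single":
        return float(block.min())
    if method == "complete":
        return float(block.max())
    raise ValueError(f"unknown linkage method {method!r}")


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    Cluster-cluster distances are recomputed from the original matrix
    (average / single / complete supported), so the result is exactly the
    naive agglomeration with the documented tie-break.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    leaves = [str(x) for x in dist.index]
    clusters: List[Tuple[Tuple[str, ...], List[int]]] = [
        ((leaf,), [i]) for i, leaf in enumerate(leaves)
    ]
    merges: List[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = _cluster_distance(d, clusters[i][1], clusters[j][1], linkage)
                pair_key = tuple(sorted([clusters[i][0], clusters[j][0]]))
                cand = (dij, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, pair_key, i, j = best
        (ka, ia), (kb, ib) = clusters[i], clusters[j]
        left, right = sorted([ka, kb])
        merges.append(Merge(left=left, right=right, height=dij))
        merged = (tuple(sorted(ka + kb)), ia + ib)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return Dendrogram(leaves=leaves, merges=merges, linkage_method=linkage)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # components x features
    scores: pd.DataFrame  # strains x components
    explained_variance_ratio: np.ndarray


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-centred SVD principal components of a strains x features
    matrix. Component signs are fixed by making the largest-magnitude
    loading of each component positive."""
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 strains")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, Vt.shape[0])
    var = s**2 / (X.shape[0] - 1)
    total = Xc.var(axis=0, ddof=1).sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    V = Vt[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(V[i])))
        if V[i, j] < 0:
            V[i] = -V[i]
    scores = Xc @ V.T
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(V, index=comp_names, columns=matrix.columns),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained_variance_ratio=ratio[:n_components],
    )


def gene_reaction_correlation(
    models: Mapping[str, Model] | Iterable[Model],
) -> Tuple[float, float, float]:
    """Least-squares line and Pearson r between per-strain gene counts (x)
    and reaction counts (y). Returns (slope, intercept, r)."""
    if not isinstance(models, Mapping):
        models = {m.id: m for m in models}
    if len(models) < 3:
        raise ValueError("need at least 3 models")
    genes = np.array([len(m.genes) for m in models.values()], dtype=float)
    rxns = np.array([len(m.reactions) for m in models.values()], dtype=float)
    if np.ptp(genes) == 0:
        raise ValueError("gene counts are constant; correlation undefined")
    if np.ptp(rxns) == 0:
        return 0.0, float(rxns[0]), 0.0
    fit = sp_stats.linregress(genes, rxns)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
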