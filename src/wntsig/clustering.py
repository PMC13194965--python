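"""Hierarchical clustering of signature genes into H-clusters.

Genes are clustered on centered-Pearson distance, ``d(g, h) = 1 - r(g, h)``,
with Ward's minimum-variance linkage; samples (when requested) use Euclidean
distance with the same linkage.  Because ``1 - r`` is not Euclidean-embeddable
in general, the Ward update is applied to the squared input distances — the
common "Ward.D2 on provided distances" dialect — and merge heights are the
square roots of the updated squared distances, which keeps the dendrogram
monotone.

The agglomeration is implemented directly (Lance–Williams recurrence) so the
tie rule is explicit: among pairs attaining the minimal criterion, the pair
with the lexicographically smallest cluster identifiers is merged.  Cutting
the tree into ``k`` clusters and ordering the clusters by descending mean
expression in the focal subtype yields the labels H1, H2, ....
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree

from .errors import DegenerateDataError, UsageError
from .scoring import ExpressionCohort
from .signatures import GeneSignature

__all__ = [
    "WardTree",
    "GeneClustering",
    "gene_distance",
    "ward_tree",
    "extract_h_clusters",
    "subtype_cluster_profile",
]


@dataclass(frozen=True)
class WardTree:
    """An agglomeration tree in scipy linkage layout.

    ``linkage`` has one row per merge: (id_i, id_j, height, leaf count),
    with leaves numbered 0..n-1 in ``labels`` order and merge m creating
    cluster id n+m.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height - child height."""
        n = self.n_leaves
        if n == 1:
            return f"{self.labels[0]};"

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.linkage[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            i, j = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            h = height(node)
            return f"({render(i, h)},{render(j, h)}):{bl:.6g}"

        root = 2 * n - 2
        i, j = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        h = height(root)
        return f"({render(i, h)},{render(j, h)});"


@dataclass(frozen=True)
class GeneClustering:
    """A cut of the gene tree into labeled H-clusters."""

    tree: WardTree
    k: int
    assignment: dict[str, str]           # gene -> H-label
    clusters: dict[str, tuple[str, ...]]  # H-label -> genes (stable order)
    chosen_by: str = "fixed"             # "fixed" or "silhouette"

    def signatures(self) -> list[GeneSignature]:
        """Each cluster as an (undirected) signature for downstream scoring."""
        return [
            GeneSignature(name=label, up=frozenset(genes))
            for label, genes in self.clusters.items()
        ]


def gene_distance(cohort: ExpressionCohort, genes) -> pd.DataFrame:
    """Centered-Pearson distance matrix ``1 - r`` between gene profiles.

    Values lie in [0, 2]: identical profiles are at 0, perfectly
    anti-correlated ones at 2.  Constant genes have no defined correlation
    and are rejected by name.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise UsageError(f"need >= 2 genes to build a distance matrix, got {len(genes)}")
    missing = [g for g in genes if g not in cohort.values.index]
    if missing:
        raise UsageError(f"gene(s) absent from cohort: {missing[:5]}")
    X = cohort.values.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = [g for g, s in zip(genes, sd) if s == 0]
    if flat:
        raise DegenerateDataError(
            f"constant gene(s) have undefined correlation: {flat[:5]}"
        )
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry and range
    return pd.DataFrame(d, index=genes, columns=genes)


def ward_tree(distances) -> WardTree:
    """Agglomerate a distance matrix under the Ward criterion.

    Accepts a symmetric DataFrame (labels from its index) or a square
    ndarray.  The Lance–Williams recurrence is applied to squared
    distances; at every step the active pair with the smallest criterion
    value is merged, ties going to the lexicographically smallest pair of
    cluster identifiers.
    """
    if isinstance(distances, pd.DataFrame):
        labels = tuple(str(g) for g in distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        labels = tuple(f"item{i}" for i in range(D.shape[0]))
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise UsageError("distance matrix must be square")
    if n < 2:
        raise UsageError(f"need >= 2 items to build a tree, got {n}")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise UsageError("distance matrix must be symmetric with zero diagonal")

    # squared-distance criterion, padded to hold the 2n-1 cluster ids
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = D ** 2
    np.fill_diagonal(big, np.inf)
    size = np.zeros(2 * n - 1, dtype=int)
    size[:n] = 1
    active = list(range(n))
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        # smallest criterion among active pairs; ties -> smallest (i, j)
        best = (np.inf, -1, -1)
        for ai, ci in enumerate(active):
            row = big[ci, active[ai + 1:]]
            if row.size == 0:
                continue
            m = row.min()
            if m < best[0]:
                cj = active[ai + 1 + int(np.argmin(row))]
                best = (m, ci, cj)
        crit, ci, cj = best
        new = n + step
        Z[step] = (ci, cj, np.sqrt(crit), size[ci] + size[cj])
        size[new] = size[ci] + size[cj]
        ni, nj = size[ci], size[cj]
        for ck in active:
            if ck in (ci, cj):
                continue
            nk = size[ck]
            upd = (
                (ni + nk) * big[ci, ck]
                + (nj + nk) * big[cj, ck]
                - nk * crit
            ) / (ni + nj + nk)
            big[new, ck] = big[ck, new] = upd
        active = [c for c in active if c not in (ci, cj)] + [new]

    return WardTree(labels=labels, linkage=Z)


def _silhouette_k(distances: np.ndarray, tree: WardTree, k_range) -> int:
    from sklearn.metrics import silhouette_score

    best_k, best_s = None, -np.inf
    cuts = cut_tree(tree.linkage, n_clusters=list(k_range))
    for col, k in enumerate(k_range):
        labels = cuts[:, col]
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(distances, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise DegenerateDataError("silhouette selection failed for every k")
    return best_k


def extract_h_clusters(
    tree: WardTree,
    cohort: ExpressionCohort,
    k: int = 2,
    *,
    focal: str = "MLIA",
    auto_k: bool = False,
    distances: pd.DataFrame | None = None,
) -> GeneClustering:
    """Cut the gene tree into ``k`` clusters labeled H1..Hk.

    Clusters are ordered by descending mean expression of their genes in the
    focal subtype, so H1 is the most focal-elevated module.  With
    ``auto_k=True`` the cut is chosen among k = 2..10 by maximal mean
    silhouette width on the provided gene distances.
    """
    n = tree.n_leaves
    if auto_k:
        if distances is None:
            raise UsageError("auto_k requires the gene distance matrix")
        k_range = range(2, min(10, n - 1) + 1)
        k = _silhouette_k(distances.to_numpy(dtype=float), tree, k_range)
        chosen_by = "silhouette"
    else:
        chosen_by = "fixed"
    if not (1 <= k <= n):
        raise UsageError(f"k={k} outside [1, {n}] for {n} genes")
    if focal not in set(cohort.subtype):
        raise UsageError(f"focal subtype {focal!r} not present in cohort labels")

    if k == n:
        flat = np.arange(n)
    else:
        flat = cut_tree(tree.linkage, n_clusters=k).ravel()
    genes = list(tree.labels)
    focal_samples = cohort.samples_of(focal)
    focal_expr = cohort.values.loc[genes, focal_samples]

    groups: dict[int, list[str]] = {}
    for g, c in zip(genes, flat):
        groups.setdefault(int(c), []).append(g)
    # order clusters by descending focal-subtype mean; ties by member genes
    ordered = sorted(
        groups.items(),
        key=lambda kv: (-float(focal_expr.loc[kv[1]].to_numpy().mean()), kv[1]),
    )
    assignment: dict[str, str] = {}
    clusters: dict[str, tuple[str, ...]] = {}
    for rank, (_, members) in enumerate(ordered, start=1):
        label = f"H{rank}"
        clusters[label] = tuple(members)
        for g in members:
            assignment[g] = label
    return GeneClustering(
        tree=tree, k=k, assignment=assignment, clusters=clusters, chosen_by=chosen_by
    )


def subtype_cluster_profile(
    cohort: ExpressionCohort, clustering: GeneClustering
) -> tuple[pd.DataFrame, list[GeneSignature]]:
    """Mean expression of each H-cluster within each subtype.

    Returns a tidy table of (cluster, subtype, n_genes, mean_expression)
    and the per-cluster gene lists as signatures for downstream GES scoring
    and correlation.
    """
    records = []
    for label, genes in clustering.clusters.items():
        missing = [g for g in genes if g not in cohort.values.index]
        if missing:
            raise UsageError(f"cluster {label} gene(s) absent from cohort: {missing[:5]}")
        block = cohort.values.loc[list(genes)]
        for subtype in cohort.subtypes:
            vals = block.loc[:, cohort.samples_of(subtype)].to_numpy()
            records.append((label, subtype, len(genes), float(vals.mean())))
    profile = pd.DataFrame(
        records, columns=["cluster", "subtype", "n_genes", "mean_expression"]
    )
    return profile, clustering.signatures()
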