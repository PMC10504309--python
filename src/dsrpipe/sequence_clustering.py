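"""Identity-graph Markov clustering, redundancy reduction, and hierarchical
clustering of identity matrices.

The Markov cluster (MCL) procedure operates on an all-vs-all percent-identity
graph thresholded strictly above a cutoff (90% by default in the pipeline):
a column-stochastic transition matrix with unit self-loops is alternately
expanded (matrix squaring) and inflated (elementwise power, column
renormalisation) until the matrix stops changing, and clusters are the
connected components of the converged nonzero pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DsrPipeError
from .io_formats import ProteinSequence

__all__ = [
    "IdentityGraph",
    "SequenceCluster",
    "mcl_cluster",
    "reduce_redundancy",
    "hierarchical_cluster",
    "Dendrogram",
]


@dataclass
class IdentityGraph:
    """Symmetric all-vs-all percent-identity relations between proteins."""

    labels: list[str]
    matrix: np.ndarray  # percent identities, diagonal 100
    threshold_applied: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("identity matrix must be symmetric")

    def threshold(self, min_identity: float) -> "IdentityGraph":
        """Zero out off-diagonal weights not strictly above ``min_identity``."""
        m = self.matrix.copy()
        off = ~np.eye(len(self.labels), dtype=bool)
        m[off & ~(m > min_identity)] = 0.0
        return IdentityGraph(list(self.labels), m, threshold_applied=min_identity)


@dataclass
class SequenceCluster:
    """One MCL cluster; representatives are filled by redundancy reduction."""

    cluster_id: int
    members: set[str]
    representatives: dict[str, str] = field(default_factory=dict)  # genus -> protein


def mcl_cluster(
    graph: IdentityGraph,
    inflation: float = 2.0,
    prune_below: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[SequenceCluster]:
    """Markov clustering of a weighted identity graph.

    Returns a partition of the node set; cluster ids are assigned in order of
    each cluster's lexicographically smallest member so the labelling is
    deterministic.
    """
    n = len(graph.labels)
    if n == 0:
        raise ValueError("empty graph")
    weights = graph.matrix.copy().astype(float)
    if (weights < 0).any():
        raise ValueError("negative edge weight")
    np.fill_diagonal(weights, 0.0)
    m = weights + np.eye(n)  # unit self-loops
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m  # expansion
        m = np.power(m, inflation)  # inflation
        m[m < prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "returning the current partition",
            stacklevel=2,
        )

    pattern = csr_matrix((m > 0) | (m.T > 0))
    _, comp = connected_components(pattern, directed=False)
    groups: dict[int, list[str]] = {}
    for label, c in zip(graph.labels, comp):
        groups.setdefault(int(c), []).append(label)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    return [
        SequenceCluster(cluster_id=i, members=set(ms)) for i, ms in enumerate(ordered)
    ]


def reduce_redundancy(
    clusters: Sequence[SequenceCluster],
    proteins: Mapping[str, ProteinSequence],
    complete_only: bool = False,
    completeness: Mapping[str, bool] | None = None,
) -> list[str]:
    """Keep the longest sequence per genus per cluster.

    Length ties break to the lexicographically smallest protein id.  With
    ``complete_only`` the per-genus representatives from incomplete genome
    assemblies are dropped afterwards (``completeness`` maps genome id to a
    flag; genomes absent from the map count as complete).
    """
    kept: list[str] = []
    for cluster in clusters:
        by_genus: dict[str, list[str]] = {}
        for pid in sorted(cluster.members):
            prot = proteins[pid]
            if not prot.genus:
                raise DsrPipeError(f"protein {pid} lacks a genus label")
            by_genus.setdefault(prot.genus, []).append(pid)
        cluster.representatives = {}
        for genus in sorted(by_genus):
            best = min(by_genus[genus], key=lambda p: (-len(proteins[p]), p))
            cluster.representatives[genus] = best
        reps = list(cluster.representatives.values())
        if complete_only:
            comp = completeness or {}
            reps = [
                p for p in reps if comp.get(proteins[p].genome_id, True)
            ]
        kept.extend(reps)
    return kept


def clusters_to_tsv(
    clusters: Sequence[SequenceCluster],
    kept: Sequence[str],
    path,
) -> None:
    """Write clusters as TSV (cluster_id, protein_id, kept flag)."""
    from pathlib import Path

    kept_set = set(kept)
    with Path(path).open("w") as fh:
        fh.write("cluster_id\tprotein_id\tkept\n")
        for cluster in clusters:
            for pid in sorted(cluster.members):
                fh.write(f"{cluster.cluster_id}\t{pid}\t{int(pid in kept_set)}\n")


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Serialise merge heights as an ultrametric newick tree."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.linkage) - 1] + ";\n" if len(self.linkage) else (
            nodes[0] + ";\n"
        )


def hierarchical_cluster(
    matrix: IdentityGraph,
    metric: str = "euclidean",
    method: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of the rows of an identity matrix.

    Rows are sorted by label before linkage so the result is independent of
    input order; euclidean distances between identity-profile rows with
    complete linkage reproduce the similarity-heatmap grouping used for the
    Qmo/Apr comparisons.
    """
    order = np.argsort(np.asarray(matrix.labels))
    labels = [matrix.labels[i] for i in order]
    rows = matrix.matrix[np.ix_(order, order)]
    if rows.shape[0] != rows.shape[1]:
        raise ValueError("identity matrix must be square")
    if rows.shape[0] < 2:
        return Dendrogram(labels, np.empty((0, 4)), labels)
    z = hierarchy.linkage(rows, method=method, metric=metric)
    leaves = hierarchy.leaves_list(z)
    return Dendrogram(labels, z, [labels[i] for i in leaves])
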