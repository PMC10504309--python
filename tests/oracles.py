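"""Independent oracles used by the test suite.

These deliberately re-derive results through different code paths than the
package: a plain-Python affine-gap DP for alignment scores, a dendropy-based
grid search for MAD root positions, and closed-form expectations for the
substitution model and Yule process.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np


# ----------------------------------------------------- brute-force alignment
def gotoh_score(a: str, b: str, matrix, gap_open: float, gap_extend: float,
                mode: str = "global") -> float:
    """Three-state affine-gap DP, scores only.

    Global mode penalises end gaps (classic Needleman-Wunsch-Gotoh); local
    mode is Smith-Waterman with a zero floor and best-anywhere maximum.
    """
    n, m = len(a), len(b)
    neg = -1e30
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    local = mode == "local"
    M[0][0] = 0.0
    best_local = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
        if local:
            M[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
        if local:
            M[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1]][b[j - 1]]
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            M[i][j] = max(diag, 0.0) if local else diag
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            if local and M[i][j] > best_local:
                best_local = M[i][j]
    if local:
        return best_local
    return max(M[n][m], X[n][m], Y[n][m])


# --------------------------------------------------------- MAD grid search
def mad_grid_search(newick: str, resolution: float = 1e-4):
    """Exhaustive MAD scan via dendropy with rho on a fixed grid.

    Returns (best child-side leaf tuple, best rho, best deviation).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    idx = {t.label: k for k, t in enumerate(taxa)}

    # node depths from the root; node-to-leaf distances via common ancestors
    depth = {}
    for node in tree.preorder_node_iter():
        depth[node] = (0.0 if node.parent_node is None
                       else depth[node.parent_node] + (node.edge.length or 0.0))

    ancestors = {}
    for node in tree.preorder_node_iter():
        chain = []
        cur = node
        while cur is not None:
            chain.append(cur)
            cur = cur.parent_node
        ancestors[node] = chain

    def node_to_leaf(node, leaf):
        chain = set(ancestors[node])
        cur = leaf
        while cur not in chain:
            cur = cur.parent_node
        return depth[node] + depth[leaf] - 2 * depth[cur]

    leaves = list(tree.leaf_node_iter())
    best = None
    eps = 1e-9
    for edge in tree.preorder_edge_iter():
        child = edge.head_node
        if child.parent_node is None:
            continue
        t = max(edge.length or 0.0, eps)
        side = {l.taxon.label for l in child.leaf_iter()}
        other = [l for l in leaves if l.taxon.label not in side]
        side_nodes = [l for l in leaves if l.taxon.label in side]
        if not other:
            continue
        grid = np.arange(0.0, 1.0 + resolution, resolution)
        sums = np.zeros_like(grid)
        # spanning pairs
        for b_leaf in side_nodes:
            d_ib = node_to_leaf(child, b_leaf)
            for c_leaf in other:
                dbc = max(D[idx[b_leaf.taxon.label], idx[c_leaf.taxon.label]], eps)
                r = np.abs(2.0 * (d_ib + grid * t) / dbc - 1.0)
                sums += r * r
        const = 0.0
        for group, anchor in ((side_nodes, child), (other, child.parent_node)):
            for x in range(len(group)):
                for y in range(x + 1, len(group)):
                    bl, cl = group[x], group[y]
                    dbc = max(D[idx[bl.taxon.label], idx[cl.taxon.label]], eps)
                    r = abs(node_to_leaf(anchor, bl) - node_to_leaf(anchor, cl)) / dbc
                    const += r * r
        n_pairs = n * (n - 1) / 2
        dev = np.sqrt((sums + const) / n_pairs)
        k = int(np.argmin(dev))
        cand = (float(dev[k]), tuple(sorted(side)), float(grid[k]))
        if best is None or cand[0] < best[0]:
            best = cand
    return best[1], best[2], best[0]


# -------------------------------------------------------------- closed forms
def expected_p_distance(rate: float, path: float) -> float:
    return (19.0 / 20.0) * (1.0 - math.exp(-rate * path * 20.0 / 19.0))


def yule_expected_depth(n: int, birth_rate: float) -> float:
    return sum(1.0 / k for k in range(2, n + 1)) / birth_rate
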