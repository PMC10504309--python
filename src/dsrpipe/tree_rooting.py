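"""Root placement on unrooted trees.

Two strategies are provided.  Minimal ancestor deviation (MAD) scans every
branch and every relative position rho on it, scoring how far the induced
ancestor-descendant distances deviate from a strict molecular clock: for a
leaf pair (b, c) whose path crosses the candidate root, the relative
deviation is r_bc = |2 d(rho, b)/d(b, c) - 1|, and pairs on one side of the
branch contribute a rho-independent term through their fixed induced
ancestor.  The branch score is the root-mean-square of r_bc over all leaf
pairs, minimised over rho in closed form (the objective is quadratic in
rho).  On a perfectly clock-like tree the minimal deviation is exactly zero
at the true root.

Outgroup rooting places the root on the branch separating a designated
outgroup (e.g. a paralogous family such as AsrC against a DsrA+DsrB tree)
from the ingroup, falling back to the best-agreement branch with a
non-monophyly flag when the outgroup is scattered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DsrPipeError
from .trees import PhyloTree

__all__ = [
    "RootCandidate",
    "OutgroupRootResult",
    "RootComparison",
    "mad_root",
    "outgroup_root",
    "compare_roots",
]

_EPS = 1e-9


@dataclass(frozen=True)
class RootCandidate:
    """One candidate root branch, identified by its child-side leaf set."""

    branch: tuple[str, ...]
    rho: float
    deviation: float
    ambiguity_ratio: float  # this deviation / best deviation (>= 1)


@dataclass
class OutgroupRootResult:
    tree: PhyloTree
    monophyletic: bool
    branch: tuple[str, ...]


@dataclass
class RootComparison:
    same_branch: bool
    mad_branch: tuple[str, ...]
    outgroup_branch: tuple[str, ...]
    outgroup_monophyletic: bool
    mad_ambiguity_ratio: float


def _edge_list(tree: PhyloTree):
    """(node, branch length, child-side leaf names) for every branch."""
    edges = []
    for node in tree.root.traverse(include_self=False):
        leaves = tuple(sorted(t.name for t in node.tips()) or [node.name])
        edges.append((node, max(node.length or 0.0, _EPS), leaves))
    return edges


def _node_leaf_distances(tree: PhyloTree) -> tuple[list[str], dict[int, np.ndarray]]:
    """Distances from every node to every leaf (zero branches -> epsilon)."""
    leaves = sorted(tree.leaf_names)
    index = {name: i for i, name in enumerate(leaves)}
    adj: dict[int, list[tuple[int, float]]] = {}
    for node in tree.root.traverse(include_self=True):
        for child in node.children:
            w = max(child.length or 0.0, _EPS)
            adj.setdefault(id(node), []).append((id(child), w))
            adj.setdefault(id(child), []).append((id(node), w))
    dists: dict[int, np.ndarray] = {}
    n_leaves = len(leaves)

    tips = {id(t): t.name for t in tree.root.tips()}
    for tip_id, name in tips.items():
        # DFS from each leaf across the (acyclic) adjacency.
        seen = {tip_id: 0.0}
        stack = [tip_id]
        while stack:
            cur = stack.pop()
            for nxt, w in adj.get(cur, ()):  # pragma: no branch
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        col = index[name]
        for node_id, dist in seen.items():
            dists.setdefault(node_id, np.zeros(n_leaves))[col] = dist
    return leaves, dists


def _mad_scan(tree: PhyloTree):
    """Per-branch (rho*, deviation) over an unrooted tree."""
    leaves, dists = _node_leaf_distances(tree)
    n = len(leaves)
    if n < 3:
        raise DsrPipeError("MAD rooting needs at least three leaves")
    index = {name: i for i, name in enumerate(leaves)}
    # Leaf-to-leaf distances from the per-leaf columns at tip nodes.
    tip_ids = {t.name: id(t) for t in tree.root.tips()}
    D = np.zeros((n, n))
    for name, tid in tip_ids.items():
        D[index[name]] = dists[tid]
    if D.max() <= 0:
        raise DsrPipeError("all pairwise distances are zero; cannot root")

    results = []
    all_idx = np.arange(n)
    for node, t, side_names in _edge_list(tree):
        side = np.array([index[x] for x in side_names])
        other = np.setdiff1d(all_idx, side)
        d_child = dists[id(node)]
        d_parent = dists[id(node.parent)]

        # Spanning pairs: b on the child side, c on the other side.
        d_ib = d_child[side][:, None]  # |side| x 1
        d_bc = D[np.ix_(side, other)]  # |side| x |other|
        with np.errstate(divide="ignore", invalid="ignore"):
            inv2 = 1.0 / d_bc**2
            num = ((d_bc - 2.0 * d_ib) * inv2).sum()
            den = (2.0 * t * inv2).sum()
            rho = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else 0.0
            r_span = 2.0 * (d_ib + rho * t) / d_bc - 1.0

        sq = float((r_span**2).sum())

        # Same-side pairs have a rho-independent induced ancestor.
        for idx_set, d_node in ((side, d_child), (other, d_parent)):
            if len(idx_set) >= 2:
                dn = d_node[idx_set]
                diff = dn[:, None] - dn[None, :]
                dd = D[np.ix_(idx_set, idx_set)]
                iu = np.triu_indices(len(idx_set), k=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r_same = diff[iu] / dd[iu]
                sq += float((r_same**2).sum())

        n_pairs = n * (n - 1) // 2
        deviation = float(np.sqrt(sq / n_pairs))
        results.append((node, t, side_names, rho, deviation))
    return results


def mad_root(tree: PhyloTree) -> tuple[PhyloTree, list[RootCandidate]]:
    """Root by minimal ancestor deviation.

    Returns the rooted tree plus all candidate branches sorted by deviation
    (ties break to the branch with the lexicographically smallest child-side
    leaf set).  The second candidate's ambiguity ratio is the published
    near-tie diagnostic (second-best deviation / best deviation).
    """
    unrooted = tree.unrooted_copy()
    if unrooted.total_length() <= 0.0:
        raise DsrPipeError("all pairwise distances are zero; cannot root")
    scan = _mad_scan(unrooted)
    scan.sort(key=lambda rec: (rec[4], rec[2]))
    best_dev = scan[0][4]
    floor = best_dev if best_dev > 0 else _EPS
    candidates = [
        RootCandidate(
            branch=side,
            rho=rho,
            deviation=dev,
            ambiguity_ratio=(dev / floor) if best_dev > 0 else (1.0 if dev == 0 else np.inf),
        )
        for _, _, side, rho, dev in scan
    ]
    node, t, _, rho, _ = scan[0]
    above = float(np.clip(rho * (node.length or 0.0), 0.0, node.length or 0.0))
    rooted = unrooted.root.root_at(node, above=above, branch_attrs=[])
    return PhyloTree(rooted, rooted=True), candidates


def outgroup_root(tree: PhyloTree, outgroup_leaves: set[str]) -> OutgroupRootResult:
    """Root on the branch separating the outgroup from the ingroup.

    A non-monophyletic outgroup is flagged and the root goes to the branch
    minimising the number of misplaced leaves (ties resolved by MAD among
    the tied branches).
    """
    outgroup = set(outgroup_leaves)
    all_leaves = set(tree.leaf_names)
    if not outgroup:
        raise DsrPipeError("outgroup is empty")
    if not outgroup < all_leaves:
        unknown = sorted(outgroup - all_leaves)
        if unknown:
            raise DsrPipeError(f"outgroup leaves not in tree: {unknown}")
        raise DsrPipeError("outgroup cannot contain every leaf")

    unrooted = tree.unrooted_copy()
    edges = _edge_list(unrooted)
    scored = []
    for node, t, side_names in edges:
        side = set(side_names)
        mis = min(
            len(side ^ outgroup), len((all_leaves - side) ^ outgroup)
        )
        scored.append((mis, node, t, side_names))
    best_mis = min(s[0] for s in scored)
    tied = [s for s in scored if s[0] == best_mis]
    monophyletic = best_mis == 0

    if len(tied) > 1:
        # Resolve ties by MAD deviation restricted to the tied branches.
        mad_by_side = {rec[2]: rec[4] for rec in _mad_scan(unrooted)}
        tied.sort(key=lambda s: (mad_by_side.get(s[3], np.inf), s[3]))
    _, node, t, side_names = tied[0]
    length = node.length or 0.0
    rooted = unrooted.root.root_at(node, above=length / 2.0, branch_attrs=[])
    return OutgroupRootResult(
        tree=PhyloTree(rooted, rooted=True),
        monophyletic=monophyletic,
        branch=side_names,
    )


def candidates_to_tsv(candidates, path) -> None:
    """Write the MAD candidate table (branch, rho, deviation, ambiguity)."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("branch\trho\tdeviation\tambiguity_ratio\n")
        for c in candidates:
            fh.write(
                f"{','.join(c.branch)}\t{c.rho:.6f}\t{c.deviation:.6g}\t"
                f"{c.ambiguity_ratio:.6g}\n"
            )


def _root_bipartition(tree: PhyloTree) -> frozenset[str]:
    sides = [
        frozenset(t.name for t in child.tips()) or frozenset({child.name})
        for child in tree.root.children
    ]
    return min(sides, key=lambda s: (len(s), tuple(sorted(s))))


def compare_roots(
    tree: PhyloTree,
    mad_result: tuple[PhyloTree, list[RootCandidate]],
    outgroup_result: OutgroupRootResult,
) -> RootComparison:
    """Report whether MAD and outgroup rooting agree on the root branch."""
    mad_tree, candidates = mad_result
    all_leaves = frozenset(tree.leaf_names)
    mad_bp = _root_bipartition(mad_tree)
    out_bp = _root_bipartition(outgroup_result.tree)
    same = mad_bp in (out_bp, all_leaves - out_bp)
    ratio = (
        candidates[1].ambiguity_ratio if len(candidates) > 1 else float("inf")
    )
    return RootComparison(
        same_branch=same,
        mad_branch=tuple(sorted(mad_bp)),
        outgroup_branch=tuple(sorted(out_bp)),
        outgroup_monophyletic=outgroup_result.monophyletic,
        mad_ambiguity_ratio=ratio,
    )
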