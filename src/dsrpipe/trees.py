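"""Phylogenetic tree container used across the pipeline.

:class:`PhyloTree` is a thin wrapper around :class:`skbio.TreeNode` that adds
an explicit rooted/unrooted flag, strict leaf-label validation, and the handful
of comparisons (Robinson-Foulds distance, bipartition sets, ultrametricity
checks) the downstream rooting and evaluation stages need.  All newick
serialisation goes through scikit-bio.
"""

from __future__ import annotations

import io
from typing import Iterable

from skbio import TreeNode

from .errors import FormatError

__all__ = ["PhyloTree"]


class PhyloTree:
    """A weighted (un)rooted tree with uniquely labelled leaves.

    Parameters
    ----------
    root:
        The underlying scikit-bio node.  Ownership passes to the wrapper;
        callers should not mutate the node afterwards.
    rooted:
        Whether the basal node is a true root.  When ``None`` the flag is
        inferred: a basal bifurcation is treated as rooted, anything else as
        unrooted.
    """

    def __init__(self, root: TreeNode, rooted: bool | None = None):
        if rooted is None:
            rooted = len(root.children) == 2
        self.root = root
        self.rooted = bool(rooted)
        self._validate()

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "PhyloTree":
        try:
            node = TreeNode.read(io.StringIO(text), convert_underscores=False)
        except Exception as exc:  # skbio raises several parser error types
            raise FormatError(f"invalid newick: {exc}") from exc
        return cls(node, rooted=rooted)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip() + "\n"

    # ------------------------------------------------------------ structure
    def _validate(self) -> None:
        names = [t.name for t in self.root.tips()]
        if any(n is None or n == "" for n in names):
            raise FormatError("tree contains an unlabeled leaf")
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate leaf labels: {', '.join(dupes)}")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def __len__(self) -> int:
        return sum(1 for _ in self.root.tips())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), rooted=self.rooted)

    def find_leaf(self, name: str) -> TreeNode:
        for tip in self.root.tips():
            if tip.name == name:
                return tip
        raise KeyError(f"no leaf named {name!r}")

    # -------------------------------------------------------- manipulations
    def unrooted_copy(self) -> "PhyloTree":
        """Copy with any basal bifurcation collapsed into a trifurcation."""
        node = self.root.copy()
        if len(node.children) == 2:
            node.unroot()
        return PhyloTree(node, rooted=False)

    def restrict(self, names: Iterable[str]) -> "PhyloTree":
        """The induced subtree on ``names`` (degree-2 nodes collapsed)."""
        names = list(names)
        missing = sorted(set(names) - set(self.leaf_names))
        if missing:
            raise KeyError(f"leaves not in tree: {', '.join(missing)}")
        sheared = self.root.shear(names)
        sheared.length = None
        return PhyloTree(sheared, rooted=self.rooted)

    # ------------------------------------------------------------- metrics
    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (missing branch lengths count as 0)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length or 0.0
            if node.is_tip():
                depths[node.name] = acc
            for child in node.children:
                walk(child, acc)

        for child in self.root.children:
            walk(child, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        depths = list(self.leaf_depths().values())
        return (max(depths) - min(depths)) <= tol * max(1.0, max(depths))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised to its smaller side.

        Ties on size are broken by sorted leaf names so the representation is
        unique regardless of tree orientation.
        """
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset[str]] = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    def rf_distance(self, other: "PhyloTree") -> int:
        """Unrooted Robinson-Foulds distance (bipartition symmetric difference).

        Both trees must share an identical leaf set; restrict first otherwise.
        """
        if set(self.leaf_names) != set(other.leaf_names):
            raise ValueError("trees must share the same leaf set")
        return len(self.bipartitions() ^ other.bipartitions())

    def tip_distances(self) -> tuple[list[str], "object"]:
        """Leaf labels plus the patristic leaf-to-leaf distance matrix."""
        dm = self.root.tip_tip_distances()
        return list(dm.ids), dm.data

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.traverse(include_self=False))

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {len(self)} leaves>"
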