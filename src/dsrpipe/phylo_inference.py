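"""Self-contained multiple alignment, trimming, distance and tree inference.

The alignment stage is a deterministic progressive aligner: 3-mer count
cosine distances feed a UPGMA guide tree, and profiles are merged up the
guide tree by affine-gap profile-profile alignment under BLOSUM62
(sum-of-pairs column scoring).  Tree inference is canonical neighbor
joining on model-corrected distances; the correction inverts the uniform
20-state substitution model the simulator uses, so parameter-recovery tests
have an exact oracle.  Branch support comes from a nonparametric column
bootstrap over the same path.  For production-scale analyses an external
maximum-likelihood engine can be plugged in through
:func:`external_tree_adapter`; its trees feed the rooting stage identically.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .errors import ConfigError, DsrPipeError
from .io_formats import AMINO_ACIDS, ProteinSequence
from .trees import PhyloTree

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "progressive_align",
    "trim_alignment",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "external_tree_adapter",
]

_ALPHA = AMINO_ACIDS + "X"  # 21 scored symbols; '-' handled separately
_CODE = {c: i for i, c in enumerate(_ALPHA)}
GAP = "-"
_P_CAP = 0.95
_D_MAX = 10.0


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by protein id (input order preserved)."""

    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, protein_id: str) -> str:
        return self.rows[protein_id].replace(GAP, "")

    def to_codes(self) -> np.ndarray:
        """Integer matrix; gaps are -1."""
        out = np.empty((len(self.rows), self.n_columns), dtype=np.int8)
        for i, row in enumerate(self.rows.values()):
            out[i] = [(-1 if c == GAP else _CODE[c]) for c in row]
        return out

    def column_gap_fractions(self) -> np.ndarray:
        codes = self.to_codes()
        return (codes < 0).mean(axis=0)


# ------------------------------------------------------- progressive aligner
@njit(cache=True)
def _gotoh_profile(scores, gap_open, gap_extend):  # pragma: no cover - jitted
    """Affine-gap global DP over a precomputed column-score matrix.

    Traceback preference on ties: diagonal, then up (gap in second profile),
    then left.  Returns the traceback matrix of state choices.
    """
    n, m = scores.shape
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in profile b (moving down)
    Iy = np.full((n + 1, m + 1), neg)  # gap in profile a (moving right)
    tb = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
        tb[1, i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
        tb[2, 0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scores[i - 1, j - 1]
            # M state
            best = M[i - 1, j - 1]
            state = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                state = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                state = 2
            M[i, j] = best + s
            tb[0, i, j] = state
            # Ix: gap column in b
            o = M[i - 1, j] - gap_open
            e = Ix[i - 1, j] - gap_extend
            if o >= e:
                Ix[i, j] = o
                tb[1, i, j] = 0
            else:
                Ix[i, j] = e
                tb[1, i, j] = 1
            # Iy: gap column in a
            o = M[i, j - 1] - gap_open
            e = Iy[i, j - 1] - gap_extend
            if o >= e:
                Iy[i, j] = o
                tb[2, i, j] = 0
            else:
                Iy[i, j] = e
                tb[2, i, j] = 2
    end_state = 0
    best = M[n, m]
    if Ix[n, m] > best:
        best = Ix[n, m]
        end_state = 1
    if Iy[n, m] > best:
        end_state = 2
    return tb, end_state


def _blosum_21() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate(_ALPHA):
        for j, b in enumerate(_ALPHA):
            out[i, j] = mat[a][b]
    return out


_S21 = _blosum_21()


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies over the 21 scored symbols.

    Gap characters carry zero weight, so heavily gapped columns score low.
    """
    length = len(rows[0])
    prof = np.zeros((length, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                prof[j, _CODE[c]] += 1.0
    prof /= len(rows)
    return prof


def _merge(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    scores = pa @ _S21 @ pb.T
    tb, state = _gotoh_profile(scores, gap_open, gap_extend)
    i, j = scores.shape
    path: list[int] = []
    while i > 0 or j > 0:
        prev = tb[state, i, j]
        path.append(state)
        if state == 0:
            i -= 1
            j -= 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        state = prev
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for step in path:
        if step == 0:
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ia += 1
            ib += 1
        elif step == 1:
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
    return out_a, out_b


def _kmer_cosine_distances(seqs: list[str], k: int) -> np.ndarray:
    vocab: dict[str, int] = {}
    vecs = []
    for s in seqs:
        counts: dict[int, float] = {}
        for i in range(max(len(s) - k + 1, 0)):
            kmer = s[i : i + k]
            idx = vocab.setdefault(kmer, len(vocab))
            counts[idx] = counts.get(idx, 0.0) + 1.0
        vecs.append(counts)
    n = len(seqs)
    dense = np.zeros((n, len(vocab)))
    for i, counts in enumerate(vecs):
        for idx, v in counts.items():
            dense[i, idx] = v
    norms = np.linalg.norm(dense, axis=1)
    norms[norms == 0] = 1.0
    sim = (dense @ dense.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def progressive_align(
    sequences: Sequence[ProteinSequence],
    k: int = 3,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Deterministic progressive multiple alignment.

    UPGMA on k-mer cosine distances provides the merge order; profiles are
    merged bottom-up with affine-gap profile alignment.  Row order in the
    result is input order.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to align")
    ids = [p.protein_id for p in sequences]
    seqs = [p.residues for p in sequences]
    dist = _kmer_cosine_distances(seqs, k)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    for step, (a, b, _, _) in enumerate(z):
        ia, rows_a = clusters.pop(int(a))
        ib, rows_b = clusters.pop(int(b))
        merged_a, merged_b = _merge(rows_a, rows_b, gap_open, gap_extend)
        clusters[len(seqs) + step] = (ia + ib, merged_a + merged_b)
    order, rows = clusters.popitem()[1]
    by_input = dict(sorted(zip(order, rows)))
    aln = MultipleAlignment({ids[i]: by_input[i] for i in range(len(seqs))})
    for p in sequences:  # ungapping must recover the inputs
        assert aln.ungapped(p.protein_id) == p.residues
    return aln


# ------------------------------------------------------------------ trimming
def trim_alignment(
    aln: MultipleAlignment, gap_threshold: float = 0.95
) -> tuple[MultipleAlignment, list[int]]:
    """Keep columns whose fraction of non-gap residues is >= ``gap_threshold``.

    Returns the trimmed alignment plus the indices of retained columns in
    the input (column provenance map).
    """
    gap_frac = aln.column_gap_fractions()
    kept = [int(i) for i in np.nonzero(1.0 - gap_frac >= gap_threshold)[0]]
    if not kept:
        raise DsrPipeError(
            "trimming removed every column; lower the gap threshold"
        )
    rows = {
        pid: "".join(row[i] for i in kept) for pid, row in aln.rows.items()
    }
    return MultipleAlignment(rows), kept


# ----------------------------------------------------------------- distances
@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # model-corrected distances
    p: np.ndarray  # observed proportion of differing shared columns

    def __post_init__(self):
        self.d = np.asarray(self.d, float)
        self.p = np.asarray(self.p, float)
        if self.d.shape != (len(self.labels),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


def correct_distance(p: float | np.ndarray) -> float | np.ndarray:
    """Invert the uniform 20-state model: d = -(19/20) ln(1 - 20p/19)."""
    return -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * np.asarray(p))


def _pairwise_p(codes: np.ndarray, labels: list[str]) -> np.ndarray:
    n = codes.shape[0]
    p = np.zeros((n, n))
    valid = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            total = int(shared.sum())
            if total == 0:
                raise DsrPipeError(
                    f"no shared non-gap columns between {labels[i]} and {labels[j]}"
                )
            diff = int((codes[i, shared] != codes[j, shared]).sum())
            p[i, j] = p[j, i] = diff / total
    return p


def distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Corrected pairwise distances from a (trimmed) alignment.

    p >= 0.95 saturates the correction and is capped at d = 10 with a warning.
    """
    labels = aln.ids
    codes = aln.to_codes()
    p = _pairwise_p(codes, labels)
    d = np.zeros_like(p)
    saturated = p >= _P_CAP
    with np.errstate(invalid="ignore", divide="ignore"):
        d[~saturated] = correct_distance(p[~saturated])
    if saturated.any():
        warnings.warn(
            f"{int(saturated.sum() // 2)} saturated pairs capped at d={_D_MAX}",
            stacklevel=2,
        )
        d[saturated] = _D_MAX
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, p)


# ------------------------------------------------------------ neighbor joining
def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical NJ with deterministic tie-breaks.

    The minimal-Q pair is joined; exact Q ties break to the lexicographically
    smallest (label, label) pair, where an internal node carries the smallest
    leaf label beneath it.  Negative branch lengths are clamped to zero with
    a warning.  The result is unrooted (basal trifurcation).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    D = dm.d.copy().astype(float)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    keys: list[str] = list(dm.labels)
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                cand = (Q[i, j], *sorted((keys[i], keys[j])))
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        new = TreeNode(children=[child_i, child_j])
        new_key = min(keys[i], keys[j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [new]
        keys = [keys[x] for x in keep] + [new_key]

    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    if min(la, lb, lc) < 0:
        clamped = True
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root, rooted=False)


# ------------------------------------------------------------------ bootstrap
def nj_from_codes(codes: np.ndarray, labels: list[str]) -> PhyloTree:
    p = _pairwise_p(codes, labels)
    d = np.where(p >= _P_CAP, _D_MAX, 0.0)
    ok = p < _P_CAP
    with np.errstate(invalid="ignore"):
        d = np.where(ok, -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * np.minimum(p, 0.9499)), d)
    d[p >= _P_CAP] = _D_MAX
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamp warnings are noise inside replicates
        return neighbor_joining(DistanceMatrix(labels, d, p))


def bootstrap_support(
    aln: MultipleAlignment, n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """Felsenstein column bootstrap over the distance/NJ path.

    Resamples alignment columns with replacement; the support of each
    internal edge of the point-estimate tree is the percentage of replicate
    trees containing the same bipartition, recorded as the internal node
    label.  Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(aln.rows) < 4:
        raise ValueError("bootstrap needs at least four sequences")
    labels = aln.ids
    codes = aln.to_codes()
    point = nj_from_codes(codes, labels)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    rng = np.random.default_rng(seed)
    n_cols = codes.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, n_cols)
        rep = nj_from_codes(codes[:, cols], labels)
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = frozenset(labels)
    for node in point.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        bp = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        if bp in counts:
            support = 100.0 * counts[bp] / n_replicates
            node.name = f"{support:.1f}"
    return point


# ----------------------------------------------------------- external engine
def external_tree_adapter(
    aln: MultipleAlignment, command_template: str
) -> PhyloTree:
    """Run an external tree engine and validate its output.

    ``command_template`` contains ``{in}`` and ``{out}`` placeholders for the
    FASTA alignment and newick output paths.  The engine's tree must carry
    exactly the alignment's sequence ids; it feeds rooting identically to
    internally inferred trees.
    """
    if "{in}" not in command_template or "{out}" not in command_template:
        raise ConfigError("command template must contain {in} and {out}")
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "alignment.fasta"
        out_path = Path(tmp) / "tree.nwk"
        with in_path.open("w") as fh:
            for pid, row in aln.rows.items():
                fh.write(f">{pid}\n{row}\n")
        cmd = command_template.replace("{in}", str(in_path)).replace(
            "{out}", str(out_path)
        )
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise DsrPipeError(
                f"external engine failed (exit {proc.returncode}): "
                f"{proc.stderr.strip() or proc.stdout.strip()}"
            )
        if not out_path.exists():
            raise DsrPipeError("external engine produced no output tree")
        tree = PhyloTree.from_newick(out_path.read_text())
    if set(tree.leaf_names) != set(aln.ids):
        raise DsrPipeError(
            "external engine tree leaves do not match the alignment ids"
        )
    return tree
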