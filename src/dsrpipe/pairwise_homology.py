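"""Pairwise alignment, percent identity, and decoy-aware family assignment.

Global (Needleman-Wunsch) and local (Smith-Waterman) affine-gap alignments
are computed with Biopython's C pairwise aligner under BLOSUM62 with gap
open 10 / extend 0.5 by default, matching the EMBOSS ``needleall`` defaults
used for the all-vs-all identity matrices.  Family assignment screens every
protein against reference sequences of the target families *and* of decoy
homolog families (NarGHI-, HdrA-like, ...): a protein whose best hit is a
decoy is rejected rather than misassigned, which is how hits to related
complexes with similar domain architecture are disambiguated.

No database search engine is embedded, so the E-value filter is exercised
through a Karlin-Altschul surrogate E = K.m.n.exp(-lambda.S) with constants
calibrated for gapped BLOSUM62 scoring; externally supplied E-values from
ingested hit tables take precedence over the surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError
from .io_formats import HitRecord, ProteinSequence
from .sequence_clustering import IdentityGraph

__all__ = [
    "AlignmentResult",
    "FamilyAssignment",
    "align_global",
    "align_local",
    "all_vs_all_identity",
    "assign_families",
    "assign_from_hits",
    "surrogate_evalue",
    "surrogate_bitscore",
]

# Karlin-Altschul constants for gapped BLOSUM62 alignments.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    mode: str  # "global" | "local"
    percent_identity: float


@dataclass(frozen=True)
class FamilyAssignment:
    """Best-hit family call for one protein, or None when filtered/decoy."""

    protein_id: str
    family: str | None
    best_identity: float
    best_evalue: float
    decoy_rejected: bool = False
    best_reference: str | None = None
    best_hit_family: str | None = None  # family of the best hit before filtering


@lru_cache(maxsize=8)
def _load_matrix(matrix_name: str):
    """A named matrix, or an NCBI-format matrix text file given by path."""
    from pathlib import Path

    if Path(matrix_name).is_file():
        return substitution_matrices.read(matrix_name)
    return substitution_matrices.load(matrix_name)


@lru_cache(maxsize=8)
def _aligner(mode: str, matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _load_matrix(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _as_str(seq) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else str(seq)


def _id_of(seq, default: str) -> str:
    return seq.protein_id if isinstance(seq, ProteinSequence) else default


def _align(
    a,
    b,
    mode: str,
    matrix: str,
    gap_open: float,
    gap_extend: float,
) -> AlignmentResult:
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(mode, matrix, gap_open, gap_extend)
    alignments = aligner.align(sa, sb)
    if len(alignments) == 0:  # local mode, no positive-scoring cell
        return AlignmentResult(
            _id_of(a, "query"), _id_of(b, "target"), "", "", 0.0, mode, 0.0
        )
    best = alignments[0]
    counts = best.counts()
    length = best.length
    identity = 100.0 * counts.identities / length if length else 0.0
    return AlignmentResult(
        query_id=_id_of(a, "query"),
        target_id=_id_of(b, "target"),
        aligned_query=best[0],
        aligned_target=best[1],
        score=float(best.score),
        mode=mode,
        percent_identity=identity,
    )


def align_global(
    a,
    b,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal affine-gap global alignment.

    Percent identity counts identical columns over the full alignment length,
    gap columns included in the denominator (EMBOSS convention).
    """
    return _align(a, b, "global", substitution_matrix, gap_open, gap_extend)


def align_local(
    a,
    b,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal affine-gap local alignment; identity over the local length."""
    return _align(a, b, "local", substitution_matrix, gap_open, gap_extend)


def local_score(
    a,
    b,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score-only local alignment (no traceback); used for hit screening."""
    aligner = _aligner("local", substitution_matrix, gap_open, gap_extend)
    return float(aligner.score(_as_str(a), _as_str(b)))


def surrogate_evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value surrogate for a local score on an m x n search."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def surrogate_bitscore(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)


def all_vs_all_identity(
    sequences: Sequence[ProteinSequence],
    mode: str = "global",
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> IdentityGraph:
    """Symmetric percent-identity matrix over a protein set (diagonal 100)."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if mode != "global":
        raise ValueError("all-vs-all identity is defined for global alignments")
    ids = [p.protein_id for p in sequences]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate protein ids in identity computation")
    n = len(sequences)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = align_global(
                sequences[i], sequences[j], substitution_matrix, gap_open, gap_extend
            )
            m[i, j] = m[j, i] = res.percent_identity
    return IdentityGraph(ids, m)


def assign_families(
    proteins: Sequence[ProteinSequence],
    reference_families: Mapping[str, Sequence[ProteinSequence]],
    decoy_families: Iterable[str] = (),
    min_identity: float = 25.0,
    max_evalue: float = 1e-10,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[FamilyAssignment]:
    """Best-hit family assignment with decoy disambiguation and hit filters.

    Every protein is locally aligned against every reference; the best hit
    (highest bitscore, ties broken by lower E-value then family name) decides
    the call.  Decoy best-hits and hits failing the identity/E-value filters
    yield ``family=None``.
    """
    decoys = set(decoy_families)
    unknown = decoys - set(reference_families)
    if unknown:
        raise ConfigError(f"decoy families without references: {sorted(unknown)}")
    for fam, refs in reference_families.items():
        if not refs:
            raise ConfigError(f"family {fam!r} has no reference sequences")

    out: list[FamilyAssignment] = []
    for protein in proteins:
        best = None  # (bitscore, -evalue rank) via tuple compare below
        for family in sorted(reference_families):
            for ref in reference_families[family]:
                score = local_score(
                    protein, ref, substitution_matrix, gap_open, gap_extend
                )
                evalue = surrogate_evalue(score, len(protein), len(ref))
                bits = surrogate_bitscore(score)
                key = (-bits, evalue, family)
                if best is None or key < best[0]:
                    best = (key, family, ref, score)
        _, family, ref, score = best
        res = align_local(protein, ref, substitution_matrix, gap_open, gap_extend)
        evalue = surrogate_evalue(score, len(protein), len(ref))
        if family in decoys:
            out.append(
                FamilyAssignment(
                    protein.protein_id, None, res.percent_identity, evalue,
                    decoy_rejected=True, best_reference=ref.protein_id,
                    best_hit_family=family,
                )
            )
        elif res.percent_identity < min_identity or evalue > max_evalue:
            out.append(
                FamilyAssignment(
                    protein.protein_id, None, res.percent_identity, evalue,
                    best_reference=ref.protein_id, best_hit_family=family,
                )
            )
        else:
            out.append(
                FamilyAssignment(
                    protein.protein_id, family, res.percent_identity, evalue,
                    best_reference=ref.protein_id, best_hit_family=family,
                )
            )
    return out


def assign_from_hits(
    hits: Sequence[HitRecord],
    decoy_families: Iterable[str] = (),
    min_identity: float = 25.0,
    max_evalue: float = 1e-10,
) -> list[FamilyAssignment]:
    """Family assignment from an ingested hit table.

    Externally computed identities and E-values take precedence over the
    internal surrogate; the same best-hit and filter semantics apply.
    """
    decoys = set(decoy_families)
    by_target: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_target.setdefault(h.target_protein_id, []).append(h)
    out = []
    for target in sorted(by_target):
        best = min(
            by_target[target],
            key=lambda h: (-h.bitscore, h.e_value, h.query_family),
        )
        if best.query_family in decoys:
            out.append(
                FamilyAssignment(
                    target, None, best.percent_identity, best.e_value,
                    decoy_rejected=True, best_hit_family=best.query_family,
                )
            )
        elif best.percent_identity < min_identity or best.e_value > max_evalue:
            out.append(
                FamilyAssignment(
                    target, None, best.percent_identity, best.e_value,
                    best_hit_family=best.query_family,
                )
            )
        else:
            out.append(
                FamilyAssignment(
                    target, best.query_family, best.percent_identity, best.e_value,
                    best_hit_family=best.query_family,
                )
            )
    return out
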