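"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular formats are UTF-8, tab-delimited with a header row.  Gene
positions are 0-based ranks along a contig (the unit of every synteny
distance is "genes", not nucleotides).  Readers validate strictly and reject
malformed input with the offending file and line named; they never silently
repair.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import FormatError
from .trees import PhyloTree


def _open_text(path: Path):
    """Open a text file, transparently decompressing ``.gz``."""
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()

__all__ = [
    "GeneRecord",
    "ProteinSequence",
    "HitRecord",
    "AnnotatedGenome",
    "read_fasta",
    "write_fasta",
    "read_gene_locations",
    "write_gene_locations",
    "read_hit_table",
    "write_hit_table",
    "read_newick",
    "write_newick",
]

# 20 canonical residues plus X for anything unresolved.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}
# IUPAC ambiguity / rare residues folded into X so substitution matrices stay total.
_FOLD_TO_X = set("BZJUO")

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneRecord:
    """One gene at a 0-based rank along its contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    index: int
    strand: str
    protein_id: str

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise FormatError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.index < 0:
            raise FormatError(f"gene {self.gene_id}: negative index {self.index}")


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with genome provenance."""

    protein_id: str
    residues: str
    genome_id: str = ""
    genus: str = ""

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise FormatError(
                f"protein {self.protein_id}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HitRecord:
    """A similarity-search hit of one family query against a target protein."""

    query_family: str
    target_protein_id: str
    percent_identity: float
    e_value: float
    bitscore: float

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_family}->{self.target_protein_id}: "
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise FormatError(
                f"hit {self.query_family}->{self.target_protein_id}: "
                f"negative E-value {self.e_value}"
            )


@dataclass
class AnnotatedGenome:
    """Ordered genes per contig plus their protein sequences."""

    genome_id: str
    genus: str = ""
    complete: bool = True
    genes: list[GeneRecord] = field(default_factory=list)
    proteins: dict[str, ProteinSequence] = field(default_factory=dict)

    def genes_by_contig(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        for contig, genes in out.items():
            genes.sort(key=lambda g: g.index)
            indices = [g.index for g in genes]
            if indices != list(range(len(genes))):
                raise FormatError(
                    f"genome {self.genome_id} contig {contig}: gene indices "
                    f"not consecutive from 0"
                )
        return out


# --------------------------------------------------------------------- FASTA
def _clean_residues(raw: str, where: str) -> str:
    seq = raw.upper()
    folded = set(seq) & _FOLD_TO_X
    if folded:
        warnings.warn(
            f"{where}: ambiguous residues {sorted(folded)} mapped to X",
            stacklevel=3,
        )
        for ch in folded:
            seq = seq.replace(ch, "X")
    return seq


def _parse_description(desc: str) -> dict[str, str]:
    """key=value tokens after the sequence id, e.g. 'p1 genome=g1 genus=Ga'."""
    meta = {}
    for token in desc.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file.

    Header tokens of the form ``genome=``/``genus=`` after the id are picked
    up as metadata.  Duplicate ids and empty sequences are rejected.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        parsed = list(SeqIO.parse(handle, "fasta"))
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        meta = _parse_description(rec.description)
        records.append(
            ProteinSequence(
                protein_id=rec.id,
                residues=_clean_residues(raw, f"{path}:{rec.id}"),
                genome_id=meta.get("genome", ""),
                genus=meta.get("genus", ""),
            )
        )
    if not records:
        # Distinguish "no records" caused by a non-FASTA file from an empty file.
        with _open_text(path) as handle:
            text = handle.read()
        if text.strip() and not text.lstrip().startswith(">"):
            raise FormatError(f"{path}: not FASTA (first record lacks '>')")
    return records


def write_fasta(proteins: Iterable[ProteinSequence], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for p in proteins:
            meta = ""
            if p.genome_id:
                meta += f" genome={p.genome_id}"
            if p.genus:
                meta += f" genus={p.genus}"
            fh.write(f">{p.protein_id}{meta}\n")
            for i in range(0, len(p.residues), width):
                fh.write(p.residues[i : i + width] + "\n")


# ----------------------------------------------------------- gene locations
_TSV_COLUMNS = ["genome", "contig", "index", "strand", "gene_id", "protein_id"]


def read_gene_locations(
    path: str | Path, dialect: str = "tsv", genome_id: str | None = None
) -> list[GeneRecord]:
    """Read gene locations from the 6-column TSV dialect or a GFF3 subset.

    TSV indices are taken verbatim and must be unique and consecutive from 0
    within each contig.  For GFF3 only ``CDS`` features are consumed and
    ranks are re-derived from the coordinate sort per seqid; ``genome_id``
    defaults to the file stem.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_locations_tsv(path)
    if dialect == "gff3":
        return _read_locations_gff3(path, genome_id or path.stem)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_locations_tsv(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise FormatError(
                f"{path}:1: expected columns {_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            genome, contig, index, strand, gene_id, protein_id = parts
            try:
                idx = int(index)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: index {index!r} is not an integer")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            records.append(
                GeneRecord(gene_id, genome, contig, idx, strand, protein_id)
            )
    _validate_consecutive(records, path)
    return records


def _validate_consecutive(records: list[GeneRecord], path: Path) -> None:
    by_contig: dict[tuple[str, str], list[int]] = {}
    for r in records:
        by_contig.setdefault((r.genome_id, r.contig_id), []).append(r.index)
    for (genome, contig), indices in by_contig.items():
        if sorted(indices) != list(range(len(indices))):
            raise FormatError(
                f"{path}: genome {genome} contig {contig}: indices not "
                f"unique/consecutive from 0"
            )


def _read_locations_gff3(path: Path, genome_id: str) -> list[GeneRecord]:
    # Minimal stable subset: seqid, start, strand and a protein_id/ID attribute.
    rows: dict[str, list[tuple[int, str, str, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 fields")
            seqid, _, ftype, start, _, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start_i = int(start)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: start {start!r} is not an integer")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, _, v = item.partition("=")
                    attr_map[k.strip()] = v.strip()
            pid = attr_map.get("protein_id") or attr_map.get("ID")
            if not pid:
                raise FormatError(f"{path}:{lineno}: CDS lacks protein_id/ID attribute")
            rows.setdefault(seqid, []).append((start_i, strand, pid, lineno))
    records: list[GeneRecord] = []
    for seqid in sorted(rows):
        for rank, (start_i, strand, pid, _) in enumerate(
            sorted(rows[seqid], key=lambda t: t[0])
        ):
            records.append(
                GeneRecord(
                    gene_id=pid,
                    genome_id=genome_id,
                    contig_id=seqid,
                    index=rank,
                    strand=strand,
                    protein_id=pid,
                )
            )
    return records


def write_gene_locations(records: Iterable[GeneRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.genome_id}\t{r.contig_id}\t{r.index}\t{r.strand}\t"
                f"{r.gene_id}\t{r.protein_id}\n"
            )


# ------------------------------------------------------------------ hit TSV
_HIT_COLUMNS = ["query_family", "target", "pident", "evalue", "bitscore"]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read an externally produced (HMM/BLAST-style) hit table.

    Rows whose numeric fields fail type coercion are skipped with a warning
    naming the row; values that coerce but violate invariants (identity
    outside [0, 100], negative E-value) raise.
    """
    path = Path(path)
    records: list[HitRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HIT_COLUMNS:
            raise FormatError(f"{path}:1: expected columns {_HIT_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_HIT_COLUMNS):
                warnings.warn(f"{path}:{lineno}: rejected row (field count)", stacklevel=2)
                continue
            family, target, pident, evalue, bitscore = parts
            try:
                pid_f, ev_f, bs_f = float(pident), float(evalue), float(bitscore)
            except ValueError:
                warnings.warn(f"{path}:{lineno}: rejected row (type coercion)", stacklevel=2)
                continue
            try:
                records.append(HitRecord(family, target, pid_f, ev_f, bs_f))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_family}\t{h.target_protein_id}\t{h.percent_identity:.3f}\t"
                f"{h.e_value:.6g}\t{h.bitscore:.2f}\n"
            )


# ------------------------------------------------------------------- newick
def read_newick(path: str | Path, rooted: bool | None = None) -> PhyloTree:
    text = Path(path).read_text()
    return PhyloTree.from_newick(text, rooted=rooted)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())


# ------------------------------------------------------- dataset assembly
def load_genomes(
    fasta_path: str | Path,
    locations_path: str | Path,
    genome_meta: Mapping[str, Mapping[str, object]] | None = None,
) -> list[AnnotatedGenome]:
    """Assemble :class:`AnnotatedGenome` objects from exported artifacts.

    ``genome_meta`` optionally supplies ``genus``/``complete`` per genome id;
    FASTA header metadata fills the genus where present.
    """
    proteins = read_fasta(fasta_path)
    genes = read_gene_locations(locations_path, dialect="tsv")
    by_genome: dict[str, AnnotatedGenome] = {}
    for gene in genes:
        genome = by_genome.setdefault(gene.genome_id, AnnotatedGenome(gene.genome_id))
        genome.genes.append(gene)
    prot_index = {p.protein_id: p for p in proteins}
    for genome in by_genome.values():
        for gene in genome.genes:
            if gene.protein_id not in prot_index:
                raise FormatError(
                    f"gene {gene.gene_id} references missing protein {gene.protein_id}"
                )
            genome.proteins[gene.protein_id] = prot_index[gene.protein_id]
        genome.genes_by_contig()  # validates index consecutiveness
        genera = {p.genus for p in genome.proteins.values() if p.genus}
        if len(genera) == 1:
            genome.genus = genera.pop()
    if genome_meta:
        for gid, meta in genome_meta.items():
            if gid in by_genome:
                by_genome[gid].genus = str(meta.get("genus", by_genome[gid].genus))
                by_genome[gid].complete = bool(meta.get("complete", True))
    return [by_genome[g] for g in sorted(by_genome)]
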