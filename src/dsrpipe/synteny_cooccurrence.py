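"""Gene-neighborhood synteny clusters and presence/absence genotyping.

Synteny clusters are runs of family-assigned genes along one contig in which
consecutive hits are separated by at most ``max_gap`` genes.  The default
reading of "a maximum distance of four genes between two hit genes" counts
*intervening* non-hit genes (index difference <= max_gap + 1); the
alternative reading (index difference <= max_gap) is selectable via
``gap_rule="offset"``.

The presence/absence matrix counts assigned proteins per genome and family;
genotype calling classifies each genome by its Dsr repertoire, where the
minimal set for dissimilatory sulfite processing is DsrABCMK.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DsrPipeError
from .io_formats import AnnotatedGenome, GeneRecord
from .pairwise_homology import FamilyAssignment

__all__ = [
    "SyntenyCluster",
    "PresenceAbsenceMatrix",
    "GenotypeCall",
    "extract_synteny_clusters",
    "presence_absence",
    "call_genotypes",
    "screen_apr_qmo_without_dsr",
    "MINIMAL_SET",
    "DEFAULT_TYPE_LABELS",
    "arrangement_string",
    "write_synteny_svg",
]

MINIMAL_SET = ("DsrA", "DsrB", "DsrC", "DsrM", "DsrK")

# Reductive- vs oxidative-type marker families used for chimeric calls.
DEFAULT_TYPE_LABELS: dict[str, str] = {
    "DsrD": "reductive",
    "DsrT": "reductive",
    "QmoA": "reductive",
    "QmoB": "reductive",
    "QmoC": "reductive",
    "AprA": "reductive",
    "AprB": "reductive",
    "Sat": "reductive",
    "DsrE": "oxidative",
    "DsrF": "oxidative",
    "DsrH": "oxidative",
    "DsrL": "oxidative",
}

GENOTYPE_CLASSES = (
    "sulfite_minimal",
    "sulfate_capable",
    "oxidative",
    "chimeric",
    "partial",
    "none",
)


@dataclass
class SyntenyCluster:
    """A maximal run of co-localised family hits on one contig.

    ``genes`` covers every gene from the first to the last hit inclusive;
    intervening non-hit genes carry the label ``"cargo"``.  ``span`` is the
    half-open index interval [first hit, last hit + 1).
    """

    genome_id: str
    contig_id: str
    genes: list[tuple[int, str, str, str]]  # (index, gene_id, label, strand)
    span: tuple[int, int]

    @property
    def families(self) -> list[str]:
        return [label for _, _, label, _ in self.genes if label != "cargo"]


def extract_synteny_clusters(
    genomes: Sequence[AnnotatedGenome],
    assignments: Sequence[FamilyAssignment],
    max_gap: int = 4,
    gap_rule: str = "intervening",
) -> list[SyntenyCluster]:
    """Group family hits into neighborhood clusters per contig.

    Hits on one contig join a cluster while at most ``max_gap`` non-hit
    genes separate consecutive hits (``gap_rule="intervening"``), or while
    their rank difference is at most ``max_gap`` (``gap_rule="offset"``).
    Clusters never span contigs; singletons are allowed.
    """
    if gap_rule not in ("intervening", "offset"):
        raise ValueError(f"unknown gap_rule {gap_rule!r}")
    family_of = {
        a.protein_id: a.family for a in assignments if a.family is not None
    }
    known_proteins = {
        pid for genome in genomes for pid in genome.proteins
    }
    for pid in family_of:
        if pid not in known_proteins:
            raise DsrPipeError(f"assignment references unknown protein {pid!r}")

    max_delta = max_gap + 1 if gap_rule == "intervening" else max_gap
    clusters: list[SyntenyCluster] = []
    for genome in genomes:
        for contig, genes in sorted(genome.genes_by_contig().items()):
            hits = [g for g in genes if g.protein_id in family_of]
            if not hits:
                continue
            runs: list[list[GeneRecord]] = [[hits[0]]]
            for prev, cur in zip(hits, hits[1:]):
                if cur.index - prev.index <= max_delta:
                    runs[-1].append(cur)
                else:
                    runs.append([cur])
            by_index = {g.index: g for g in genes}
            for run in runs:
                lo, hi = run[0].index, run[-1].index
                members = []
                for idx in range(lo, hi + 1):
                    g = by_index[idx]
                    label = family_of.get(g.protein_id, "cargo")
                    members.append((idx, g.gene_id, label, g.strand))
                clusters.append(
                    SyntenyCluster(
                        genome_id=genome.genome_id,
                        contig_id=contig,
                        genes=members,
                        span=(lo, hi + 1),
                    )
                )
    return clusters


def arrangement_string(cluster: SyntenyCluster) -> str:
    """Compact per-cluster arrangement, e.g. 'DsrA-DsrB-cargo-DsrC'."""
    return "-".join(label for _, _, label, _ in cluster.genes)


@dataclass
class PresenceAbsenceMatrix:
    """Genome x family assignment counts with a boolean view."""

    counts: pd.DataFrame  # rows: genome ids, columns: family names

    @property
    def boolean(self) -> pd.DataFrame:
        return self.counts > 0

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="genome")


def presence_absence(
    genomes: Sequence[AnnotatedGenome],
    assignments: Sequence[FamilyAssignment],
    families: Sequence[str],
) -> PresenceAbsenceMatrix:
    """Count assigned proteins per genome per family.

    Genomes without a single assignment still appear as all-zero rows.
    """
    genome_of = {
        pid: genome.genome_id
        for genome in genomes
        for pid in genome.proteins
    }
    counts = pd.DataFrame(
        0,
        index=sorted(g.genome_id for g in genomes),
        columns=list(families),
        dtype=int,
    )
    for a in assignments:
        if a.family is None or a.family not in counts.columns:
            continue
        genome = genome_of.get(a.protein_id)
        if genome is None:
            raise DsrPipeError(
                f"assignment references unknown protein {a.protein_id!r}"
            )
        counts.loc[genome, a.family] += 1
    return PresenceAbsenceMatrix(counts)


@dataclass(frozen=True)
class GenotypeCall:
    genome_id: str
    has_minimal_set: bool
    genotype: str  # one of GENOTYPE_CLASSES


def call_genotypes(
    matrix: PresenceAbsenceMatrix,
    type_labels: Mapping[str, str] | None = None,
) -> list[GenotypeCall]:
    """Classify each genome's Dsr repertoire.

    Rules (precedence chimeric > oxidative > sulfate_capable >
    sulfite_minimal):

    * minimal set: all of DsrABCMK present;
    * chimeric: minimal set plus both reductive- and oxidative-type markers;
    * oxidative: minimal set plus DsrEFH (all three) or DsrL, without DsrD;
    * sulfate_capable: minimal set plus Sat, AprA, AprB and QmoA or QmoB;
    * sulfite_minimal: minimal set only;
    * partial: at least one but not all of DsrABCMK; none otherwise.
    """
    labels = DEFAULT_TYPE_LABELS if type_labels is None else dict(type_labels)
    for fam, kind in labels.items():
        if kind not in ("reductive", "oxidative"):
            raise DsrPipeError(f"unknown type label {kind!r} for family {fam!r}")
    have = matrix.boolean
    calls = []
    for genome, row in have.iterrows():
        def present(fam: str) -> bool:
            return fam in row.index and bool(row[fam])

        n_min = sum(present(f) for f in MINIMAL_SET)
        minimal = n_min == len(MINIMAL_SET)
        types_present = {
            labels[f] for f in row.index if f in labels and row[f]
        }
        if minimal:
            if {"reductive", "oxidative"} <= types_present:
                cls = "chimeric"
            elif (
                (present("DsrE") and present("DsrF") and present("DsrH"))
                or present("DsrL")
            ) and not present("DsrD"):
                cls = "oxidative"
            elif (
                present("Sat")
                and present("AprA")
                and present("AprB")
                and (present("QmoA") or present("QmoB"))
            ):
                cls = "sulfate_capable"
            else:
                cls = "sulfite_minimal"
        elif n_min >= 1:
            cls = "partial"
        else:
            cls = "none"
        calls.append(GenotypeCall(genome, minimal, cls))
    return calls


def screen_apr_qmo_without_dsr(
    genomes: Sequence[AnnotatedGenome],
    assignments: Sequence[FamilyAssignment],
) -> list[str]:
    """Genomes with Apr/Qmo assignments but no Dsr-family assignment at all."""
    genome_of = {
        pid: genome.genome_id for genome in genomes for pid in genome.proteins
    }
    apr_qmo = {"AprA", "AprB", "QmoA", "QmoB", "QmoC"}
    has_apr: set[str] = set()
    has_dsr: set[str] = set()
    for a in assignments:
        if a.family is None:
            continue
        genome = genome_of.get(a.protein_id)
        if genome is None:
            continue
        if a.family in apr_qmo:
            has_apr.add(genome)
        if a.family.startswith("Dsr"):
            has_dsr.add(genome)
    return sorted(has_apr - has_dsr)


# ------------------------------------------------------------------ exports
def clusters_to_tsv(clusters: Iterable[SyntenyCluster], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cluster_id\tgenome\tcontig\tindex\tgene_id\tlabel\tstrand\n")
        for cid, cluster in enumerate(clusters):
            for idx, gene_id, label, strand in cluster.genes:
                fh.write(
                    f"{cid}\t{cluster.genome_id}\t{cluster.contig_id}\t{idx}\t"
                    f"{gene_id}\t{label}\t{strand}\n"
                )


def write_synteny_svg(
    clusters: Sequence[SyntenyCluster], path: str | Path, box: int = 46
) -> None:
    """Minimal SVG track plot: one row per cluster, one labelled box per gene."""
    rows = len(clusters)
    width = box * (1 + max((len(c.genes) for c in clusters), default=1))
    height = 30 * rows + 10
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-size="7" font-family="monospace">'
    ]
    for r, cluster in enumerate(clusters):
        y = 5 + 30 * r
        parts.append(
            f'<text x="2" y="{y + 12}">{cluster.genome_id}:{cluster.contig_id}</text>'
        )
        for i, (idx, _, label, strand) in enumerate(cluster.genes):
            x = box + i * box
            fill = "#cccccc" if label == "cargo" else "#e07050"
            parts.append(
                f'<rect x="{x}" y="{y}" width="{box - 4}" height="18" '
                f'fill="{fill}" stroke="black"/>'
            )
            parts.append(
                f'<text x="{x + 2}" y="{y + 12}">{label}({strand})</text>'
            )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")
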