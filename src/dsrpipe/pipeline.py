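"""End-to-end orchestration: assign -> cluster -> align -> trim -> tree ->
root -> synteny -> genotype, with a machine-readable run report.

The pipeline is fully deterministic given the configured seed: every random
draw (bootstrap resampling) flows from named substreams, so re-running with
the same inputs reproduces byte-identical artifacts.  The companion
:func:`simulate_and_run` drives the pipeline over a simulated dataset and
scores the outputs against the simulator's ground truth (assignment
accuracy, clustering agreement, Robinson-Foulds distances, root recovery,
and lateral-gene-transfer discordance flags).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .errors import ConfigError, StageError
from .io_formats import AnnotatedGenome, HitRecord, ProteinSequence
from .pairwise_homology import (
    FamilyAssignment,
    all_vs_all_identity,
    assign_families,
    assign_from_hits,
)
from .phylo_inference import (
    MultipleAlignment,
    bootstrap_support,
    distance_matrix,
    external_tree_adapter,
    neighbor_joining,
    progressive_align,
    trim_alignment,
)
from .sequence_clustering import mcl_cluster, reduce_redundancy
from .synthetic_data import (
    CLASS_TO_GENOTYPE,
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
)
from .synteny_cooccurrence import (
    arrangement_string,
    call_genotypes,
    clusters_to_tsv,
    extract_synteny_clusters,
    presence_absence,
    screen_apr_qmo_without_dsr,
)
from .tree_rooting import mad_root
from .trees import PhyloTree

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "simulate_and_run"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric knob of the analysis, in one serialisable place."""

    seed: int = 0
    min_local_identity: float = 25.0
    max_evalue: float = 1e-10
    cluster_identity_threshold: float = 90.0  # strict 'above'
    mcl_inflation: float = 2.0
    trim_gap_threshold: float = 0.95
    synteny_max_gap: int = 4
    synteny_gap_rule: str = "intervening"
    n_bootstrap: int = 1000
    complete_only: bool = False
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    min_tree_size: int = 3
    engine_command: str | None = None  # external ML engine template

    def __post_init__(self):
        if not 0.0 <= self.min_local_identity <= 100.0:
            raise ConfigError("min_local_identity must be in [0, 100]")
        if self.max_evalue < 0:
            raise ConfigError("max_evalue must be >= 0")
        if not 0.0 <= self.cluster_identity_threshold <= 100.0:
            raise ConfigError("cluster_identity_threshold must be in [0, 100]")
        if not 0.0 < self.trim_gap_threshold <= 1.0:
            raise ConfigError("trim_gap_threshold must be in (0, 1]")
        if self.synteny_max_gap < 0:
            raise ConfigError("synteny_max_gap must be >= 0")
        if self.mcl_inflation <= 1.0:
            raise ConfigError("mcl_inflation must be > 1")
        if self.n_bootstrap < 0:
            raise ConfigError("n_bootstrap must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class FamilyTreeResult:
    family: str
    retained: list[str]
    tree: PhyloTree | None  # MAD-rooted
    unrooted: PhyloTree | None
    alignment: MultipleAlignment | None
    n_columns_trimmed: int
    mad_branch: tuple[str, ...] | None
    mad_rho: float | None
    mad_deviation: float | None
    mad_ambiguity: float | None
    skipped_reason: str | None = None
    mcl_clusters: list[set[str]] = field(default_factory=list)
    mad_candidates: list = field(default_factory=list)


@dataclass
class PipelineResult:
    report: dict
    assignments: list[FamilyAssignment]
    matrix: "object"
    genotypes: list
    synteny_clusters: list
    family_results: dict[str, FamilyTreeResult]


def _derived_seed(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence((seed, *key)).generate_state(1)[0] % (2**31)
    )


def load_dataset(
    datadir: str | Path,
) -> tuple[list[AnnotatedGenome], dict[str, list[ProteinSequence]], list[str]]:
    """Load an exported dataset directory.

    Expects ``proteins.faa``, ``genes.tsv``, ``references.faa``,
    ``reference_families.tsv`` and optionally ``genomes.tsv`` metadata, as
    written by :func:`dsrpipe.synthetic_data.export_dataset`.
    Returns (genomes, reference families, decoy family names).
    """
    from .io_formats import load_genomes, read_fasta

    datadir = Path(datadir)
    meta: dict[str, dict] = {}
    genomes_tsv = datadir / "genomes.tsv"
    if genomes_tsv.exists():
        for line in genomes_tsv.read_text().splitlines()[1:]:
            gid, genus, complete, *_ = line.split("\t")
            meta[gid] = {"genus": genus, "complete": bool(int(complete))}
    genomes = load_genomes(datadir / "proteins.faa", datadir / "genes.tsv", meta)
    refs = {p.protein_id: p for p in read_fasta(datadir / "references.faa")}
    references: dict[str, list[ProteinSequence]] = {}
    decoys: list[str] = []
    for line in (datadir / "reference_families.tsv").read_text().splitlines()[1:]:
        family, pid, role = line.split("\t")
        references.setdefault(family, []).append(refs[pid])
        if role == "decoy":
            decoys.append(family)
    return genomes, references, decoys


def run_pipeline(
    genomes: Sequence[AnnotatedGenome],
    reference_families: Mapping[str, Sequence[ProteinSequence]],
    decoy_families: Sequence[str],
    config: PipelineConfig,
    outdir: str | Path | None = None,
    hits: Sequence[HitRecord] | None = None,
) -> PipelineResult:
    """Run every stage over annotated genomes and reference families.

    ``hits`` optionally supplies an externally produced hit table which then
    replaces the internal similarity search.  With ``outdir`` set, every
    intermediate artifact plus a JSON and text report are written.
    """
    target_families = sorted(set(reference_families) - set(decoy_families))
    proteins = [
        p for genome in genomes for _, p in sorted(genome.proteins.items())
    ]
    completeness = {g.genome_id: g.complete for g in genomes}

    # ---- stage: assignment -------------------------------------------------
    try:
        if hits is not None:
            assignments = assign_from_hits(
                hits, decoy_families, config.min_local_identity, config.max_evalue
            )
        else:
            assignments = assign_families(
                proteins,
                reference_families,
                decoy_families,
                config.min_local_identity,
                config.max_evalue,
                config.substitution_matrix,
                config.gap_open,
                config.gap_extend,
            )
    except Exception as exc:
        raise StageError("assign", str(exc)) from exc

    assigned = [a for a in assignments if a.family is not None]
    by_family: dict[str, list[ProteinSequence]] = {f: [] for f in target_families}
    prot_index = {p.protein_id: p for p in proteins}
    for a in assigned:
        if a.family in by_family and a.protein_id in prot_index:
            by_family[a.family].append(prot_index[a.protein_id])

    # ---- stage: synteny + genotyping --------------------------------------
    try:
        synteny = extract_synteny_clusters(
            genomes, assignments, config.synteny_max_gap, config.synteny_gap_rule
        )
        matrix = presence_absence(genomes, assignments, target_families)
        genotypes = call_genotypes(matrix)
        apr_only = screen_apr_qmo_without_dsr(genomes, assignments)
    except Exception as exc:
        raise StageError("synteny", str(exc)) from exc

    # ---- stage: per-family clustering, alignment, tree, rooting -----------
    family_results: dict[str, FamilyTreeResult] = {}
    n_retained_total = 0
    for fi, family in enumerate(target_families):
        members = sorted(by_family[family], key=lambda p: p.protein_id)
        if len(members) < 2:
            family_results[family] = FamilyTreeResult(
                family, [m.protein_id for m in members], None, None, None, 0,
                None, None, None, None, skipped_reason="fewer than 2 members",
            )
            n_retained_total += len(members)
            continue
        try:
            graph = all_vs_all_identity(
                members,
                substitution_matrix=config.substitution_matrix,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            ).threshold(config.cluster_identity_threshold)
            clusters = mcl_cluster(graph, inflation=config.mcl_inflation)
            retained = reduce_redundancy(
                clusters,
                {m.protein_id: m for m in members},
                complete_only=config.complete_only,
                completeness=completeness,
            )
        except Exception as exc:
            raise StageError(f"cluster[{family}]", str(exc)) from exc
        retained = sorted(retained)
        n_retained_total += len(retained)
        retained_seqs = [prot_index[p] for p in retained]
        if len(retained) < max(3, config.min_tree_size):
            family_results[family] = FamilyTreeResult(
                family, retained, None, None, None, 0, None, None, None, None,
                skipped_reason=f"only {len(retained)} retained sequences",
                mcl_clusters=[set(c.members) for c in clusters],
            )
            continue
        try:
            aln = progressive_align(
                retained_seqs, gap_open=config.gap_open, gap_extend=config.gap_extend
            )
            trimmed, _ = trim_alignment(aln, config.trim_gap_threshold)
            if config.engine_command:
                unrooted = external_tree_adapter(trimmed, config.engine_command)
            elif config.n_bootstrap > 0 and len(retained) >= 4:
                unrooted = bootstrap_support(
                    trimmed,
                    config.n_bootstrap,
                    seed=_derived_seed(config.seed, 5, fi),
                )
            else:
                unrooted = neighbor_joining(distance_matrix(trimmed))
            rooted, candidates = mad_root(unrooted)
        except Exception as exc:
            raise StageError(f"tree[{family}]", str(exc)) from exc
        best = candidates[0]
        family_results[family] = FamilyTreeResult(
            family,
            retained,
            rooted,
            unrooted,
            trimmed,
            trimmed.n_columns,
            best.branch,
            best.rho,
            best.deviation,
            candidates[1].ambiguity_ratio if len(candidates) > 1 else float("inf"),
            mcl_clusters=[set(c.members) for c in clusters],
            mad_candidates=candidates,
        )

    # ---- report ------------------------------------------------------------
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "counts": {
            "genomes": len(genomes),
            "proteins_screened": len(proteins) if hits is None else len(
                {a.protein_id for a in assignments}
            ),
            "assigned": len(assigned),
            "decoy_rejected": sum(a.decoy_rejected for a in assignments),
            "filtered": sum(
                a.family is None and not a.decoy_rejected for a in assignments
            ),
            "retained_for_trees": n_retained_total,
            "trees_built": sum(
                1 for r in family_results.values() if r.tree is not None
            ),
            "synteny_clusters": len(synteny),
        },
        "genotypes": {g.genome_id: g.genotype for g in genotypes},
        "apr_qmo_without_dsr": apr_only,
        "root_placements": {
            fam: {
                "branch": list(r.mad_branch) if r.mad_branch else None,
                "rho": r.mad_rho,
                "deviation": r.mad_deviation,
                "ambiguity_ratio": r.mad_ambiguity,
            }
            for fam, r in family_results.items()
            if r.tree is not None
        },
        "skipped_families": {
            fam: r.skipped_reason
            for fam, r in family_results.items()
            if r.skipped_reason
        },
        "arrangements": {
            f"{c.genome_id}:{c.contig_id}:{c.span[0]}": arrangement_string(c)
            for c in synteny
        },
    }

    result = PipelineResult(
        report, assignments, matrix, genotypes, synteny, family_results
    )
    if outdir is not None:
        _write_artifacts(result, genomes, config, Path(outdir))
    return result


def _write_artifacts(
    result: PipelineResult,
    genomes: Sequence[AnnotatedGenome],
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "assignments.tsv").open("w") as fh:
        fh.write(
            "protein_id\tfamily\tbest_identity\tbest_evalue\tdecoy_rejected\t"
            "best_hit_family\n"
        )
        for a in result.assignments:
            fh.write(
                f"{a.protein_id}\t{a.family or '-'}\t{a.best_identity:.3f}\t"
                f"{a.best_evalue:.6g}\t{int(a.decoy_rejected)}\t"
                f"{a.best_hit_family or '-'}\n"
            )
    result.matrix.to_tsv(outdir / "presence_absence.tsv")
    with (outdir / "genotypes.tsv").open("w") as fh:
        fh.write("genome\thas_minimal_set\tgenotype\n")
        for g in result.genotypes:
            fh.write(f"{g.genome_id}\t{int(g.has_minimal_set)}\t{g.genotype}\n")
    clusters_to_tsv(result.synteny_clusters, outdir / "synteny_clusters.tsv")
    for fam, r in result.family_results.items():
        if r.alignment is not None:
            with (outdir / f"family_{fam}.aln.fasta").open("w") as fh:
                for pid, row in r.alignment.rows.items():
                    fh.write(f">{pid}\n{row}\n")
        if r.tree is not None:
            (outdir / f"family_{fam}.rooted.nwk").write_text(r.tree.to_newick())
        if r.mad_candidates:
            from .tree_rooting import candidates_to_tsv

            candidates_to_tsv(
                r.mad_candidates, outdir / f"family_{fam}.mad_candidates.tsv"
            )
        if r.mcl_clusters:
            kept = set(r.retained)
            with (outdir / f"family_{fam}.clusters.tsv").open("w") as fh:
                fh.write("cluster_id\tprotein_id\tkept\n")
                for ci, members in enumerate(r.mcl_clusters):
                    for pid in sorted(members):
                        fh.write(f"{ci}\t{pid}\t{int(pid in kept)}\n")
    config.to_yaml(outdir / "config.yaml")
    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True) + "\n"
    )
    lines = [f"dsrpipe {__version__} run report (seed {config.seed})"]
    for key, value in sorted(result.report["counts"].items()):
        lines.append(f"  {key}: {value}")
    lines.append("genotypes:")
    for genome, cls in sorted(result.report["genotypes"].items()):
        lines.append(f"  {genome}: {cls}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- evaluation
def _genome_of_protein(genomes: Sequence[AnnotatedGenome]) -> dict[str, str]:
    return {
        pid: genome.genome_id for genome in genomes for pid in genome.proteins
    }


def _genome_labelled(
    tree: PhyloTree, genome_of: Mapping[str, str]
) -> PhyloTree | None:
    """Relabel protein-id leaves with genome ids.

    Genomes contributing more than one leaf (paralogs or borderline false
    positives that slipped past the hit filters) are dropped, since genome-
    level tree comparisons are only defined for single-copy representation.
    Returns None when fewer than three single-copy genomes remain.
    """
    from collections import Counter

    leaf_genomes = [genome_of[p] for p in tree.leaf_names]
    counts = Counter(leaf_genomes)
    keep = [
        p for p in tree.leaf_names if counts[genome_of[p]] == 1
    ]
    if len(keep) < 3:
        return None
    out = tree.restrict(keep) if len(keep) < len(tree.leaf_names) else tree.copy()
    for tip in out.root.tips():
        tip.name = genome_of[tip.name]
    return PhyloTree(out.root, rooted=out.rooted)


def _nearest_leaf(tree: PhyloTree, leaf: str) -> str:
    ids, data = tree.tip_distances()
    i = ids.index(leaf)
    row = data[i].copy()
    row[i] = np.inf
    return ids[int(np.argmin(row))]


def simulate_and_run(
    sim_config: SimulationConfig,
    pipeline_config: PipelineConfig,
    outdir: str | Path | None = None,
) -> tuple[PipelineResult, dict]:
    """Simulate a dataset, run the pipeline, and score against ground truth."""
    genomes, truth = simulate_dataset(sim_config)
    references = {f: [truth.references[f]] for f in sorted(truth.references)}
    result = run_pipeline(
        genomes, references, truth.decoys, pipeline_config, outdir=outdir
    )
    evaluation = evaluate_against_truth(result, genomes, truth)
    if outdir is not None:
        Path(outdir, "evaluation.json").write_text(
            json.dumps(evaluation, indent=2, sort_keys=True) + "\n"
        )
    return result, evaluation


def evaluate_against_truth(
    result: PipelineResult,
    genomes: Sequence[AnnotatedGenome],
    truth: GroundTruth,
) -> dict:
    """Score pipeline outputs against the simulator ledgers."""
    genome_of = _genome_of_protein(genomes)
    truth_label: dict[str, str] = {}
    for genome_id, layout in truth.layouts.items():
        for gene_id, label in layout:
            truth_label[gene_id] = label
    assignment_by_id = {a.protein_id: a for a in result.assignments}

    # Assignment accuracy over planted (non-cargo, non-decoy) genes present.
    n_total = n_correct = 0
    n_decoy = n_decoy_rejected = 0
    for genome in genomes:
        for pid in genome.proteins:
            label = truth_label[pid]
            a = assignment_by_id.get(pid)
            if label == "cargo":
                continue
            if label in truth.decoys:
                n_decoy += 1
                n_decoy_rejected += int(a is not None and a.decoy_rejected)
                continue
            n_total += 1
            n_correct += int(a is not None and a.family == label)
    assignment_accuracy = n_correct / n_total if n_total else float("nan")

    # Genotype concordance with the planted genome classes.
    expected = {g: CLASS_TO_GENOTYPE[truth.classes[g]] for g in truth.classes}
    called = {g.genome_id: g.genotype for g in result.genotypes}
    genotype_matches = {
        g: called.get(g) == expected[g] for g in sorted(expected)
    }
    genotype_accuracy = sum(genotype_matches.values()) / len(genotype_matches)

    # Clustering agreement: the expected partition links family members whose
    # true-tree patristic distance predicts a global identity above the 90%
    # clustering cutoff (xenologous transfer pairs sit at epsilon distance in
    # the true gene tree, so they are linked automatically).  Pairs near the
    # identity boundary make this an approximate, diagnostic score.
    d_crit = -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * 0.10)
    ari_values = []
    for fam, fr in result.family_results.items():
        if not fr.mcl_clusters or fam not in truth.gene_trees:
            continue
        members = sorted(set().union(*fr.mcl_clusters))
        pred = {}
        for ci, cluster in enumerate(fr.mcl_clusters):
            for pid in cluster:
                pred[pid] = ci
        ids, data = truth.gene_trees[fam].tip_distances()
        pos = {g: i for i, g in enumerate(ids)}
        parent = {p: p for p in members}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                ga, gb = genome_of[a], genome_of[b]
                if ga in pos and gb in pos and data[pos[ga], pos[gb]] < d_crit:
                    parent[find(a)] = find(b)
        expected_group = {p: find(p) for p in members}
        keys = sorted({v for v in expected_group.values()})
        ari_values.append(
            adjusted_rand_score(
                [keys.index(expected_group[p]) for p in members],
                [pred[p] for p in members],
            )
        )
    cluster_ari = float(np.mean(ari_values)) if ari_values else float("nan")

    # Tree accuracy: RF distance of each inferred family tree to the true
    # gene tree restricted to the retained genomes.
    rf: dict[str, int] = {}
    root_recovered: dict[str, bool] = {}
    for fam, fr in result.family_results.items():
        if fr.tree is None or fam not in truth.gene_trees:
            continue
        inferred = _genome_labelled(fr.unrooted, genome_of)
        if inferred is None:
            continue
        carriers = set(inferred.leaf_names)
        true_tree = truth.gene_trees[fam]
        if not carriers <= set(true_tree.leaf_names):
            continue
        restricted = true_tree.restrict(sorted(carriers))
        rf[fam] = inferred.rf_distance(restricted.unrooted_copy())
        rooted_genomes = _genome_labelled(fr.tree, genome_of)
        if rooted_genomes is None or set(rooted_genomes.leaf_names) != carriers:
            continue
        root_bp = min(
            (
                frozenset(t.name for t in child.tips()) or frozenset({child.name})
                for child in rooted_genomes.root.children
            ),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        true_root_bp = min(
            (
                frozenset(t.name for t in child.tips()) or frozenset({child.name})
                for child in restricted.root.children
            ),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        all_g = frozenset(carriers)
        root_recovered[fam] = root_bp in (true_root_bp, all_g - true_root_bp)

    # LGT discordance: does the recipient's nearest leaf jump to the donor?
    lgt_flags = []
    for event in truth.lgt_events:
        fam, donor, recipient = event["family"], event["donor"], event["recipient"]
        per_family = {}
        for other_fam, fr in result.family_results.items():
            if fr.tree is None:
                continue
            labelled = _genome_labelled(fr.unrooted, genome_of)
            if labelled is None:
                continue
            if {donor, recipient} <= set(labelled.leaf_names):
                per_family[other_fam] = _nearest_leaf(labelled, recipient) == donor
        lgt_flags.append(
            {
                "family": fam,
                "donor": donor,
                "recipient": recipient,
                "discordant_families": sorted(
                    f for f, flag in per_family.items() if flag
                ),
                "concordant_families": sorted(
                    f for f, flag in per_family.items() if not flag
                ),
            }
        )

    return {
        "assignment_accuracy": assignment_accuracy,
        "decoy_rejection_rate": (
            n_decoy_rejected / n_decoy if n_decoy else float("nan")
        ),
        "genotype_accuracy": genotype_accuracy,
        "genotype_matches": genotype_matches,
        "cluster_ari": cluster_ari,
        "rf_distances": rf,
        "rf_zero_fraction": (
            float(np.mean([v == 0 for v in rf.values()])) if rf else float("nan")
        ),
        "root_recovered": root_recovered,
        "lgt_flags": lgt_flags,
    }
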