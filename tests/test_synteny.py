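import numpy as np
import pandas as pd
import pytest

from dsrpipe.errors import DsrPipeError
from dsrpipe.io_formats import AnnotatedGenome, GeneRecord, ProteinSequence
from dsrpipe.pairwise_homology import FamilyAssignment
from dsrpipe.synteny_cooccurrence import (
    DEFAULT_TYPE_LABELS,
    PresenceAbsenceMatrix,
    arrangement_string,
    call_genotypes,
    extract_synteny_clusters,
    presence_absence,
    screen_apr_qmo_without_dsr,
    write_synteny_svg,
)


def toy_genome(hit_indices, n_genes=25, genome_id="g1", contig="c1", offset=0):
    genome = AnnotatedGenome(genome_id=genome_id, genus="gen")
    assignments = []
    for i in range(n_genes):
        pid = f"{genome_id}_{contig}_p{i + offset}"
        genome.genes.append(
            GeneRecord(pid, genome_id, contig, i, "+" if i % 2 else "-", pid)
        )
        genome.proteins[pid] = ProteinSequence(pid, "MKVLW", genome_id, "gen")
        if i in hit_indices:
            assignments.append(FamilyAssignment(pid, "DsrA", 99.0, 1e-40))
    return genome, assignments


class TestClusterExtraction:
    def test_worked_example_gap_rule(self):
        # hits {2,4,9,15,21}, max_gap 4 -> clusters [2,4,9], [15], [21]
        genome, assignments = toy_genome({2, 4, 9, 15, 21})
        clusters = extract_synteny_clusters([genome], assignments, max_gap=4)
        spans = [
            [i for i, _, label, _ in c.genes if label != "cargo"]
            for c in clusters
        ]
        assert spans == [[2, 4, 9], [15], [21]]

    def test_offset_rule_selectable(self):
        genome, assignments = toy_genome({2, 4, 9, 15, 21})
        clusters = extract_synteny_clusters(
            [genome], assignments, max_gap=4, gap_rule="offset"
        )
        spans = [
            [i for i, _, label, _ in c.genes if label != "cargo"]
            for c in clusters
        ]
        assert spans == [[2, 4], [9], [15], [21]]

    def test_contigs_never_merge(self):
        g1, a1 = toy_genome({0, 1}, n_genes=3, contig="c1")
        g2, a2 = toy_genome({0}, n_genes=3, contig="c2", offset=100)
        genome = AnnotatedGenome(genome_id="g1", genus="gen")
        genome.genes = g1.genes + g2.genes
        genome.proteins = {**g1.proteins, **g2.proteins}
        clusters = extract_synteny_clusters([genome], a1 + a2, max_gap=4)
        assert len(clusters) == 2
        assert {c.contig_id for c in clusters} == {"c1", "c2"}

    def test_every_hit_in_exactly_one_cluster(self):
        genome, assignments = toy_genome({0, 3, 7, 8, 14, 22})
        clusters = extract_synteny_clusters([genome], assignments, max_gap=4)
        covered = [
            gid for c in clusters for _, gid, label, _ in c.genes
            if label != "cargo"
        ]
        assert sorted(covered) == sorted(a.protein_id for a in assignments)
        assert len(covered) == len(set(covered))

    def test_translation_invariance_of_splitting(self):
        base, a_base = toy_genome({2, 4, 9, 15, 21})
        shifted, a_shift = toy_genome(
            {i + 3 for i in (2, 4, 9, 15, 21)}, n_genes=28, genome_id="g2",
            offset=500,
        )
        c1 = extract_synteny_clusters([base], a_base, max_gap=4)
        c2 = extract_synteny_clusters([shifted], a_shift, max_gap=4)
        sizes1 = [len(c.families) for c in c1]
        sizes2 = [len(c.families) for c in c2]
        assert sizes1 == sizes2

    def test_unknown_protein_rejected(self):
        genome, _ = toy_genome(set())
        bad = [FamilyAssignment("ghost", "DsrA", 99.0, 1e-40)]
        with pytest.raises(DsrPipeError, match="unknown protein"):
            extract_synteny_clusters([genome], bad)

    def test_planted_block_recovered_in_order(self, small_dataset):
        # The simulator's consecutive Dsr cluster comes back as one cluster
        # with the families in planted order.
        from dsrpipe.synthetic_data import CLASS_LAYOUTS

        _, genomes, truth = small_dataset
        block = CLASS_LAYOUTS["bacterial_reductive"]["blocks"][0]
        target = next(
            g for g in genomes
            if truth.classes[g.genome_id] == "bacterial_reductive"
        )
        assignments = [
            FamilyAssignment(gid, label, 99.0, 1e-40)
            for gid, label in truth.layouts[target.genome_id]
            if label not in ("cargo",) + tuple(truth.decoys)
        ]
        clusters = extract_synteny_clusters([target], assignments, max_gap=4)
        joined = [c.families for c in clusters]
        assert any(
            "-".join(block) in "-".join(fams) for fams in joined
        )

    def test_svg_track_plot_written(self, tmp_path):
        genome, assignments = toy_genome({2, 4})
        clusters = extract_synteny_clusters([genome], assignments)
        out = tmp_path / "syn.svg"
        write_synteny_svg(clusters, out)
        text = out.read_text()
        assert text.startswith("<svg") and "DsrA" in text
        assert arrangement_string(clusters[0]).startswith("DsrA-")


def matrix_from(rows: dict[str, dict[str, int]], families) -> PresenceAbsenceMatrix:
    df = pd.DataFrame(0, index=sorted(rows), columns=list(families), dtype=int)
    for genome, fams in rows.items():
        for fam, count in fams.items():
            df.loc[genome, fam] = count
    return PresenceAbsenceMatrix(df)


ALL_FAMS = [
    "DsrA", "DsrB", "DsrC", "DsrD", "DsrE", "DsrF", "DsrH", "DsrJ", "DsrK",
    "DsrL", "DsrM", "DsrN", "DsrO", "DsrP", "DsrT",
    "QmoA", "QmoB", "QmoC", "AprA", "AprB", "Sat",
]


class TestPresenceAbsence:
    def test_counts_and_zero_rows(self):
        g1, a1 = toy_genome({2}, n_genes=5, genome_id="g1")
        g2 = AnnotatedGenome(genome_id="g2", genus="gen")
        m = presence_absence([g1, g2], a1, ["DsrA", "DsrC"])
        assert m.counts.loc["g1", "DsrA"] == 1
        assert m.counts.loc["g2"].sum() == 0

    def test_column_sums_equal_total_assignments(self, small_dataset):
        _, genomes, truth = small_dataset
        assignments = [
            FamilyAssignment(gid, label, 99.0, 1e-40)
            for g in genomes
            for gid, label in truth.layouts[g.genome_id]
            if label in ALL_FAMS
        ]
        m = presence_absence(genomes, assignments, ALL_FAMS)
        per_family = {}
        for a in assignments:
            per_family[a.family] = per_family.get(a.family, 0) + 1
        for fam in ALL_FAMS:
            assert m.counts[fam].sum() == per_family.get(fam, 0)


class TestGenotypes:
    def test_minimal_set_only_is_sulfite_minimal(self):
        m = matrix_from(
            {"g": {f: 1 for f in ("DsrA", "DsrB", "DsrC", "DsrM", "DsrK", "DsrN")}},
            ALL_FAMS,
        )
        (call,) = call_genotypes(m)
        assert call.has_minimal_set and call.genotype == "sulfite_minimal"

    def test_full_reductive_set_is_sulfate_capable(self):
        fams = ["DsrA", "DsrB", "DsrC", "DsrM", "DsrK", "DsrD", "DsrT",
                "Sat", "AprA", "AprB", "QmoA", "QmoB", "QmoC"]
        m = matrix_from({"g": {f: 1 for f in fams}}, ALL_FAMS)
        (call,) = call_genotypes(m)
        assert call.genotype == "sulfate_capable"

    def test_oxidative_requires_no_dsrd(self):
        fams = ["DsrA", "DsrB", "DsrC", "DsrM", "DsrK", "DsrE", "DsrF", "DsrH"]
        m = matrix_from({"g": {f: 1 for f in fams}}, ALL_FAMS)
        assert call_genotypes(m)[0].genotype == "oxidative"
        m2 = matrix_from({"g": {f: 1 for f in fams + ["DsrD"]}}, ALL_FAMS)
        assert call_genotypes(m2)[0].genotype == "chimeric"

    def test_chimeric_precedence_over_oxidative(self):
        fams = ["DsrA", "DsrB", "DsrC", "DsrM", "DsrK", "DsrL", "Sat",
                "AprA", "AprB", "QmoA"]
        m = matrix_from({"g": {f: 1 for f in fams}}, ALL_FAMS)
        assert call_genotypes(m)[0].genotype == "chimeric"

    def test_partial_and_none(self):
        m = matrix_from({"g1": {"DsrA": 1}, "g2": {"Sat": 1}, "g3": {}}, ALL_FAMS)
        calls = {c.genome_id: c.genotype for c in call_genotypes(m)}
        assert calls == {"g1": "partial", "g2": "none", "g3": "none"}

    def test_unknown_type_label_rejected(self):
        m = matrix_from({"g": {}}, ALL_FAMS)
        with pytest.raises(DsrPipeError):
            call_genotypes(m, {"DsrD": "sideways"})

    def test_simulator_classes_recovered_exactly(self, small_dataset):
        from dsrpipe.synthetic_data import CLASS_TO_GENOTYPE

        _, genomes, truth = small_dataset
        assignments = [
            FamilyAssignment(gid, label, 99.0, 1e-40)
            for g in genomes
            for gid, label in truth.layouts[g.genome_id]
            if label in ALL_FAMS
        ]
        m = presence_absence(genomes, assignments, ALL_FAMS)
        calls = {c.genome_id: c.genotype for c in call_genotypes(m)}
        for genome_id, cls in truth.classes.items():
            assert calls[genome_id] == CLASS_TO_GENOTYPE[cls]


class TestAprQmoScreen:
    def test_inclusion_and_exclusion(self):
        g1, _ = toy_genome(set(), n_genes=2, genome_id="g1")
        g2, _ = toy_genome(set(), n_genes=2, genome_id="g2", offset=10)
        a = [
            FamilyAssignment("g1_c1_p0", "AprA", 90.0, 1e-40),
            FamilyAssignment("g2_c1_p10", "AprA", 90.0, 1e-40),
            FamilyAssignment("g2_c1_p11", "DsrC", 90.0, 1e-40),
        ]
        assert screen_apr_qmo_without_dsr([g1, g2], a) == ["g1"]

    def test_apr_only_genomes_recovered_from_truth(self):
        from dsrpipe.synthetic_data import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(seed=31, n_genomes=20, seq_length=60)
        genomes, truth = simulate_dataset(cfg)
        assignments = [
            FamilyAssignment(gid, label, 99.0, 1e-40)
            for g in genomes
            for gid, label in truth.layouts[g.genome_id]
            if label in ALL_FAMS
        ]
        expected = sorted(
            g for g, cls in truth.classes.items() if cls == "apr_only"
        )
        assert expected  # the 20-genome default fractions include one
        assert screen_apr_qmo_without_dsr(genomes, assignments) == expected
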