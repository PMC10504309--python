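import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import AA, random_protein

from dsrpipe.errors import ConfigError, DsrPipeError
from dsrpipe.io_formats import ProteinSequence
from dsrpipe.phylo_inference import (
    DistanceMatrix,
    MultipleAlignment,
    bootstrap_support,
    correct_distance,
    distance_matrix,
    external_tree_adapter,
    neighbor_joining,
    progressive_align,
    trim_alignment,
)
from dsrpipe.trees import PhyloTree


def random_binary_tree(rng, n_taxa, min_len=0.1, max_len=1.0) -> PhyloTree:
    """Random unrooted binary topology with uniform branch lengths."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(min_len, max_len)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b],
                          length=float(rng.uniform(min_len, max_len)))
        nodes.append(parent)
    return PhyloTree(TreeNode(children=nodes), rooted=False)


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        seqs = [ProteinSequence(f"s{i}", "MKVLWAAL") for i in range(4)]
        aln = progressive_align(seqs)
        assert aln.n_columns == 8
        assert all("-" not in row for row in aln.rows.values())

    def test_ungapping_recovers_inputs(self, rng):
        seqs = [
            random_protein(rng, int(rng.integers(20, 40)), f"s{i}")
            for i in range(6)
        ]
        aln = progressive_align(seqs)
        for s in seqs:
            assert aln.ungapped(s.protein_id) == s.residues

    def test_simulator_output_aligns_gap_free(self, small_dataset):
        # Substitution-only evolution: homologous columns need no gaps.
        _, genomes, truth = small_dataset
        fam_seqs = [
            g.proteins[f"{g.genome_id}_DsrA"]
            for g in genomes
            if f"{g.genome_id}_DsrA" in g.proteins
        ]
        aln = progressive_align(fam_seqs)
        assert all("-" not in row for row in aln.rows.values())
        assert aln.n_columns == len(fam_seqs[0].residues)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            progressive_align([ProteinSequence("a", "MK")])


class TestTrim:
    def _aln(self, rows):
        return MultipleAlignment(dict(rows))

    def test_single_gap_column_removed_at_095(self):
        rows = {f"r{i}": "AC" for i in range(9)}
        rows["r9"] = "A-"
        trimmed, kept = trim_alignment(self._aln(rows), 0.95)
        assert kept == [0] and trimmed.n_columns == 1

    def test_gap_free_unchanged(self, rng):
        seqs = {f"r{i}": "MKVLW" for i in range(5)}
        trimmed, kept = trim_alignment(self._aln(seqs), 0.95)
        assert kept == list(range(5))

    def test_random_masks_match_direct_recount(self, rng):
        for _ in range(20):
            n, L = 8, 30
            mask = rng.random((n, L)) < 0.2
            rows = {}
            for i in range(n):
                rows[f"r{i}"] = "".join(
                    "-" if mask[i, j] else AA[int(rng.integers(0, 20))]
                    for j in range(L)
                )
            threshold = float(rng.choice([0.5, 0.8, 0.95, 1.0]))
            try:
                _, kept = trim_alignment(self._aln(rows), threshold)
            except DsrPipeError:
                kept = None
            expected = [
                j for j in range(L)
                if (n - mask[:, j].sum()) / n >= threshold
            ]
            assert kept == (expected or None)

    def test_idempotent(self, rng):
        rows = {
            "a": "MK-LW",
            "b": "MKVLW",
            "c": "MKVL-",
            "d": "MKVLW",
        }
        once, _ = trim_alignment(self._aln(rows), 0.9)
        twice, _ = trim_alignment(once, 0.9)
        assert once.rows == twice.rows

    def test_all_columns_removed_is_error(self):
        rows = {"a": "M-", "b": "-K"}
        with pytest.raises(DsrPipeError, match="threshold"):
            trim_alignment(self._aln(rows), 1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACW-", min_size=8, max_size=8),
            min_size=2,
            max_size=8,
        ),
        st.sampled_from([0.5, 0.75, 0.95]),
    )
    def test_retained_columns_equal_gap_recount_property(self, rows, threshold):
        aln = self._aln({f"r{i}": s for i, s in enumerate(rows)})
        n = len(rows)
        expected = [
            j for j in range(8)
            if sum(s[j] != "-" for s in rows) / n >= threshold
        ]
        if not expected:
            with pytest.raises(DsrPipeError):
                trim_alignment(aln, threshold)
        else:
            _, kept = trim_alignment(aln, threshold)
            assert kept == expected


class TestDistances:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment({"a": "MKVLW", "b": "MKVLW"})
        dm = distance_matrix(aln)
        assert dm.d[0, 1] == 0.0

    def test_stated_formula_at_p_01(self):
        assert correct_distance(0.1) == pytest.approx(
            -(19 / 20) * np.log(1 - (20 / 19) * 0.1)
        )
        assert correct_distance(0.1) == pytest.approx(0.1056643, abs=1e-6)

    def test_monotone_in_p(self):
        p = np.linspace(0.0, 0.94, 50)
        d = correct_distance(p)
        assert np.all(np.diff(d) > 0)

    def test_saturation_capped_with_warning(self):
        aln = MultipleAlignment({"a": "A" * 40, "b": "C" * 40})
        with pytest.warns(UserWarning, match="saturated"):
            dm = distance_matrix(aln)
        assert dm.d[0, 1] == 10.0

    def test_zero_shared_columns_is_error(self):
        aln = MultipleAlignment({"a": "MK--", "b": "--VL"})
        with pytest.raises(DsrPipeError, match="no shared"):
            distance_matrix(aln)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # matrix generated from ((a:1,b:2):1,(c:3,d:1))
        labels = ["a", "b", "c", "d"]
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, D, D * 0))
        ids, data = tree.tip_distances()
        order = [ids.index(l) for l in labels]
        assert np.allclose(data[np.ix_(order, order)], D, atol=1e-9)
        assert tree.bipartitions() == {frozenset({"a", "b"})}

    def test_three_taxa_star_lengths(self):
        labels = ["a", "b", "c"]
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, D, D * 0))
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_label_permutation_equivariance(self, rng):
        t = random_binary_tree(rng, 7)
        ids, data = t.tip_distances()
        perm = rng.permutation(len(ids))
        t1 = neighbor_joining(
            DistanceMatrix(list(ids), data, data * 0)
        )
        t2 = neighbor_joining(
            DistanceMatrix(
                [ids[i] for i in perm], data[np.ix_(perm, perm)], data * 0
            )
        )
        assert t1.rf_distance(t2) == 0

    def test_fifty_random_additive_matrices_recovered_exactly(self, rng):
        for _ in range(50):
            t = random_binary_tree(rng, 8)
            ids, data = t.tip_distances()
            inferred = neighbor_joining(DistanceMatrix(list(ids), data, data * 0))
            assert inferred.rf_distance(t) == 0
            ids2, data2 = inferred.tip_distances()
            order = [ids2.index(l) for l in ids]
            assert np.allclose(data2[np.ix_(order, order)], data, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), np.zeros((2, 2)))


class TestBootstrap:
    def _two_clade_alignment(self, rng, n_cols=1000):
        # two 2-leaf clades separated by a long internal branch
        base = rng.integers(0, 20, n_cols)
        other = (base + 1 + rng.integers(0, 19, n_cols)) % 20
        rows = {}
        for name, anchor in (("a1", base), ("a2", base), ("b1", other), ("b2", other)):
            s = anchor.copy()
            idx = rng.choice(n_cols, 30, replace=False)
            s[idx] = (s[idx] + 1 + rng.integers(0, 19, 30)) % 20
            rows[name] = "".join(AA[c] for c in s)
        return MultipleAlignment(rows)

    def test_clear_split_gets_high_support(self, rng):
        tree = bootstrap_support(self._two_clade_alignment(rng), 100, seed=7)
        supports = [
            float(n.name) for n in tree.root.non_tips(include_self=False)
            if n.name
        ]
        assert supports and min(supports) >= 99.0

    def test_supports_in_range_and_deterministic(self, rng):
        aln = self._two_clade_alignment(rng, 300)
        t1 = bootstrap_support(aln, 50, seed=3)
        t2 = bootstrap_support(aln, 50, seed=3)
        assert t1.to_newick() == t2.to_newick()
        for node in t1.root.non_tips(include_self=False):
            if node.name:
                assert 0.0 <= float(node.name) <= 100.0

    def test_replicate_count_validated(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(self._two_clade_alignment(rng, 100), 0)


class TestExternalAdapter:
    def test_mock_engine_roundtrip(self, tmp_path):
        aln = MultipleAlignment({"a": "MK", "b": "MV", "c": "ML"})
        script = tmp_path / "engine.sh"
        script.write_text("#!/bin/sh\necho '(a:1,b:1,c:1);' > \"$2\"\n")
        script.chmod(0o755)
        tree = external_tree_adapter(aln, f"{script} {{in}} {{out}}")
        assert sorted(tree.leaf_names) == ["a", "b", "c"]

    def test_leaf_mismatch_is_error(self, tmp_path):
        aln = MultipleAlignment({"a": "MK", "b": "MV"})
        script = tmp_path / "engine.sh"
        script.write_text("#!/bin/sh\necho '(x:1,y:1);' > \"$2\"\n")
        script.chmod(0o755)
        with pytest.raises(DsrPipeError, match="leaves"):
            external_tree_adapter(aln, f"{script} {{in}} {{out}}")

    def test_nonzero_exit_is_error(self, tmp_path):
        aln = MultipleAlignment({"a": "MK", "b": "MV"})
        script = tmp_path / "engine.sh"
        script.write_text("#!/bin/sh\necho boom >&2\nexit 3\n")
        script.chmod(0o755)
        with pytest.raises(DsrPipeError, match="exit 3"):
            external_tree_adapter(aln, f"{script} {{in}} {{out}}")

    def test_adapter_tree_feeds_rooting_like_internal_trees(self, tmp_path):
        from dsrpipe.tree_rooting import mad_root

        nwk = "((a:1,b:1):1,(c:1.5,d:1.5):0.5);"
        aln = MultipleAlignment({k: "MKVL" for k in "abcd"})
        script = tmp_path / "engine.sh"
        script.write_text(f"#!/bin/sh\necho '{nwk}' > \"$2\"\n")
        script.chmod(0o755)
        via_adapter = external_tree_adapter(aln, f"{script} {{in}} {{out}}")
        direct = PhyloTree.from_newick(nwk)
        r1, c1 = mad_root(via_adapter)
        r2, c2 = mad_root(direct)
        assert c1[0].branch == c2[0].branch
        assert r1.to_newick() == r2.to_newick()
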