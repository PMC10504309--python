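"""Synthetic annotated genomes with known evolutionary ground truth.

The generator emulates the structure of prokaryotic genome collections
carrying dissimilatory sulfite/sulfate reduction (Dsr) gene clusters:

* a clock-like (ultrametric) species tree from a seeded birth-death process;
* protein families evolved along that tree under a uniform 20-state
  substitution model (Poisson replacement events, each drawing one of the 19
  alternative residues uniformly) with optional gamma site-rate heterogeneity;
* genome classes with realistic gene content — an archaeal-style minimal
  sulfite-reduction set (DsrABCMKN), a bacterial reductive set with the
  consecutive dsrABDNCTMKJOP cluster plus the sulfate-activation arm
  (QmoABC, AprAB, Sat), an oxidative set (DsrEFH/DsrL, no DsrD/T), chimeric
  genomes carrying both, and Apr/Qmo-only genomes without any Dsr genes;
* decoy homolog families (NarG-like, HdrA-like) evolved from independent
  roots but sharing a short motif with a target family, so that best-hit
  family assignment has to disambiguate them;
* planted lateral gene transfers implemented as xenologous replacement of
  the recipient's copy with a sequence evolved from the donor lineage; and
* genome incompleteness as i.i.d. gene deletion.

Everything is deterministic under a fixed seed; every random draw flows from
named substreams of the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .errors import ConfigError
from .io_formats import (
    AMINO_ACIDS,
    AnnotatedGenome,
    GeneRecord,
    ProteinSequence,
    write_fasta,
    write_gene_locations,
)
from .trees import PhyloTree

__all__ = [
    "FamilySpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_species_tree",
    "evolve_family",
    "assemble_genomes",
    "simulate_dataset",
    "export_dataset",
    "DEFAULT_FAMILIES",
    "CLASS_LAYOUTS",
    "CLASS_TO_GENOTYPE",
]

_N_AA = 20

GENOME_CLASSES = (
    "archaeal_minimal",
    "bacterial_reductive",
    "oxidative",
    "chimeric",
    "apr_only",
)

# Planted gene-cluster layouts per genome class.  Blocks are contiguous runs
# of genes; the bacterial reductive block reproduces the consecutive
# dsrABDNCTMKJOP arrangement with dsrT adjacent to dsrM.
CLASS_LAYOUTS: dict[str, dict[str, list[list[str]] | list[str]]] = {
    "archaeal_minimal": {
        "blocks": [["DsrA", "DsrB", "DsrC", "DsrM", "DsrK", "DsrN"]],
        "scattered": [],
    },
    "bacterial_reductive": {
        "blocks": [
            ["DsrA", "DsrB", "DsrD", "DsrN", "DsrC", "DsrT",
             "DsrM", "DsrK", "DsrJ", "DsrO", "DsrP"],
            ["QmoA", "QmoB", "QmoC"],
            ["AprA", "AprB", "Sat"],
        ],
        "scattered": [],
    },
    "oxidative": {
        "blocks": [
            ["DsrA", "DsrB", "DsrC", "DsrE", "DsrF", "DsrH", "DsrL",
             "DsrM", "DsrK", "DsrJ", "DsrO", "DsrP"],
        ],
        "scattered": [],
    },
    "chimeric": {
        "blocks": [
            ["DsrA", "DsrB", "DsrD", "DsrN", "DsrC", "DsrT",
             "DsrM", "DsrK", "DsrJ", "DsrO", "DsrP"],
            ["DsrE", "DsrF", "DsrH"],
            ["QmoA", "QmoB", "QmoC"],
            ["AprA", "AprB", "Sat"],
        ],
        "scattered": ["DsrL"],
    },
    "apr_only": {
        "blocks": [["AprA", "AprB", "Sat"], ["QmoA", "QmoB", "QmoC"]],
        "scattered": [],
    },
}

# Expected pathway genotype per simulated genome class (at zero incompleteness).
CLASS_TO_GENOTYPE = {
    "archaeal_minimal": "sulfite_minimal",
    "bacterial_reductive": "sulfate_capable",
    "oxidative": "oxidative",
    "chimeric": "chimeric",
    "apr_only": "none",
}


@dataclass(frozen=True)
class FamilySpec:
    """One simulated protein family.

    ``cluster_block`` names the planted block the family belongs to for
    book-keeping ("dsr", "qmo", "apr") or "scattered"; the per-class block
    orders live in :data:`CLASS_LAYOUTS`.  Decoys list the target family
    whose root motif they share.
    """

    name: str
    genotype_classes: tuple[str, ...]
    cluster_block: str = "dsr"
    decoy_of: str | None = None


def _classes_with(family: str) -> tuple[str, ...]:
    out = []
    for cls, layout in CLASS_LAYOUTS.items():
        fams = [f for block in layout["blocks"] for f in block]
        fams += list(layout["scattered"])
        if family in fams:
            out.append(cls)
    return tuple(out)


def _default_families() -> tuple[FamilySpec, ...]:
    names = sorted(
        {
            f
            for layout in CLASS_LAYOUTS.values()
            for block in layout["blocks"]
            for f in block
        }
        | {f for layout in CLASS_LAYOUTS.values() for f in layout["scattered"]}
    )
    specs = [
        FamilySpec(
            name,
            _classes_with(name),
            cluster_block="qmo" if name.startswith("Qmo")
            else "apr" if name in ("AprA", "AprB", "Sat")
            else "scattered" if name == "DsrL"
            else "dsr",
        )
        for name in names
    ]
    # Decoy homolog families, planted scattered in every genome class.
    specs.append(
        FamilySpec("NarG_like", GENOME_CLASSES, "scattered", decoy_of="DsrA")
    )
    specs.append(
        FamilySpec("HdrA_like", GENOME_CLASSES, "scattered", decoy_of="QmoA")
    )
    return tuple(specs)


DEFAULT_FAMILIES = _default_families()

DEFAULT_CLASS_FRACTIONS = {
    "archaeal_minimal": 0.25,
    "bacterial_reductive": 0.40,
    "oxidative": 0.20,
    "chimeric": 0.10,
    "apr_only": 0.05,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All simulator parameters; the seed is mandatory.

    Branch lengths are in expected substitutions per site once multiplied by
    ``subst_rate``; ``tree_height`` rescales the species tree to a fixed
    root-to-tip depth (None keeps raw birth-death time units).
    """

    seed: int
    n_genomes: int = 20
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_height: float | None = 0.5
    seq_length: int = 300
    cargo_length: int = 200
    n_cargo: int = 8
    subst_rate: float = 1.0
    gamma_shape: float | None = None
    families: tuple[FamilySpec, ...] = DEFAULT_FAMILIES
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    min_internal_branch: float = 0.04  # after height scaling; 0 disables
    lgt_events: tuple[tuple[str, str, str], ...] = ()  # (family, donor, recipient)
    lgt_branch_length: float = 0.02
    lgt_additive: bool = False  # False: xenologous replacement
    incompleteness_prob: float = 0.0
    outgroup_branch_length: float = 0.4
    motif_length: int = 30

    def __post_init__(self):
        if self.n_genomes < 3:
            raise ConfigError("n_genomes must be >= 3")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ConfigError("birth rate must be > 0 and death rate >= 0")
        if self.seq_length < 10:
            raise ConfigError("seq_length must be >= 10")
        if not 0.0 <= self.incompleteness_prob <= 1.0:
            raise ConfigError("incompleteness_prob must be in [0, 1]")
        if self.subst_rate <= 0:
            raise ConfigError("subst_rate must be > 0")
        names = [f.name for f in self.families]
        if len(names) != len(set(names)):
            raise ConfigError("family names must be unique")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    species_tree: PhyloTree
    classes: dict[str, str]  # genome -> class
    gene_trees: dict[str, PhyloTree]  # family -> true gene tree over carriers
    layouts: dict[str, list[tuple[str, str]]]  # genome -> [(gene_id, label)]
    lgt_events: list[dict]
    deleted: list[dict]
    references: dict[str, ProteinSequence]  # family -> outgroup representative
    decoys: list[str]


# ------------------------------------------------------------------ helpers
def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _seq_to_str(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] for c in codes)


def _mutate(
    codes: np.ndarray, lam_per_site: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Apply Poisson(lam) replacement events per site, each to one of the
    19 alternative residues uniformly."""
    k = rng.poisson(lam_per_site)
    out = codes.copy()
    kmax = int(k.max()) if k.size else 0
    for round_ in range(kmax):
        idx = np.nonzero(k > round_)[0]
        out[idx] = (out[idx] + 1 + rng.integers(0, _N_AA - 1, idx.size)) % _N_AA
    return out


# -------------------------------------------------------------- species tree
class _Lineage:
    __slots__ = ("start", "node")

    def __init__(self, start: float, node: TreeNode):
        self.start = start
        self.node = node


def simulate_species_tree(config: SimulationConfig) -> PhyloTree:
    """Seeded birth-death simulation conditioned on ``n_genomes`` extant tips.

    The process starts from a single lineage and stops the first time the
    extant count reaches ``n_genomes``, extended by one further waiting time
    so the youngest split has nonzero subtending branches.  Full extinction
    is retried with derived sub-seeds, failing after 100 attempts.  The
    returned tree is rooted, binary, and ultrametric; with ``tree_height``
    set it is rescaled to that root-to-tip depth.
    """
    last_error = None
    for attempt in range(100):
        rng = _rng(config.seed, 0, attempt)
        try:
            tree = _simulate_once(config, rng)
        except _SimFailed as exc:
            last_error = exc
            continue
        return tree
    raise ConfigError(
        f"birth-death simulation failed in 100 attempts: {last_error}"
    )


class _SimFailed(Exception):
    pass


def _simulate_once(config: SimulationConfig, rng: np.random.Generator) -> PhyloTree:
    lam, mu = config.birth_rate, config.death_rate
    root = TreeNode()
    active = [_Lineage(0.0, root)]
    t = 0.0
    births: dict[int, float] = {id(root): 0.0}
    spans: dict[int, tuple[float, float | None]] = {}
    extinct: set[int] = set()
    for _ in range(100_000):
        n = len(active)
        if n == 0:
            raise _SimFailed("all lineages extinct")
        if n == config.n_genomes:
            t += rng.exponential(1.0 / (n * (lam + mu)))
            present = t
            break
        t += rng.exponential(1.0 / (n * (lam + mu)))
        i = int(rng.integers(n))
        lineage = active[i]
        if rng.random() < lam / (lam + mu):  # birth: split into two children
            spans[id(lineage.node)] = (lineage.start, t)
            left, right = TreeNode(), TreeNode()
            lineage.node.extend([left, right])
            active[i] = _Lineage(t, left)
            active.append(_Lineage(t, right))
        else:  # death
            spans[id(lineage.node)] = (lineage.start, t)
            extinct.add(id(lineage.node))
            del active[i]
    else:
        raise _SimFailed("event budget exhausted before reaching target size")

    for lineage in active:
        spans[id(lineage.node)] = (lineage.start, present)

    def build(node: TreeNode) -> TreeNode | None:
        start, end = spans[id(node)]
        if not node.children:
            if id(node) in extinct:
                return None
            return TreeNode(length=end - start)
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # collapse through an extinct sister
            kids[0].length += end - start
            return kids[0]
        new = TreeNode(length=end - start, children=kids)
        return new

    built = build(root)
    if built is None or sum(1 for _ in built.tips()) != config.n_genomes:
        raise _SimFailed("pruned tree lost extant tips")
    built.length = None
    if len(built.children) != 2:
        raise _SimFailed("root not bifurcating after pruning")
    for i, tip in enumerate(built.tips()):
        tip.name = f"g{i + 1:03d}"
    tree = PhyloTree(built, rooted=True)
    if config.tree_height is not None:
        depth = max(tree.leaf_depths().values())
        factor = config.tree_height / depth
        for node in tree.root.traverse(include_self=False):
            node.length = (node.length or 0.0) * factor
    if config.min_internal_branch > 0:
        _enforce_min_internal(tree, config.min_internal_branch)
    return tree


def _enforce_min_internal(tree: PhyloTree, delta: float) -> None:
    """Raise every internal branch to at least ``delta`` while keeping the
    tree ultrametric.

    Speciation events closer together than ``delta`` leave essentially no
    substitutions on the connecting branch, so trees with such branches test
    tree-shape luck rather than inference.  Node heights are pushed down by
    at most what the chain of descendants permits; tip branches absorb the
    remainder, so root-to-tip depths stay exactly equal.
    """
    heights: dict[int, float] = {}

    def orig_height(node) -> float:
        if node.is_tip():
            heights[id(node)] = 0.0
            return 0.0
        h = max(orig_height(c) + (c.length or 0.0) for c in node.children)
        heights[id(node)] = h
        return h

    floors: dict[int, float] = {}

    def floor_of(node) -> float:
        if node.is_tip():
            floors[id(node)] = 0.0
            return 0.0
        f = delta + max(floor_of(c) for c in node.children)
        floors[id(node)] = f
        return f

    root_h = orig_height(tree.root)
    floor_of(tree.root)
    new_h: dict[int, float] = {id(tree.root): max(root_h, floors[id(tree.root)])}

    def assign(node) -> None:
        for child in node.children:
            if child.is_tip():
                new_h[id(child)] = 0.0
            else:
                desired = min(heights[id(child)], new_h[id(node)] - delta)
                new_h[id(child)] = max(desired, floors[id(child)])
            child.length = new_h[id(node)] - new_h[id(child)]
            assign(child)

    assign(tree.root)


# ----------------------------------------------------------------- evolution
def evolve_family(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    root_codes: np.ndarray | None = None,
    seq_length: int | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Evolve one family along ``tree``.

    Returns (leaf name -> residue codes, root codes, per-site rates).  Site
    rates are Gamma(shape, mean 1) when ``gamma_shape`` is set, else 1.
    """
    length = seq_length if seq_length is not None else config.seq_length
    if length < 10:
        raise ConfigError("seq_length must be >= 10")
    if root_codes is None:
        root_codes = rng.integers(0, _N_AA, length)
    root_codes = np.asarray(root_codes)
    if config.gamma_shape is not None:
        site_rates = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, length)
    else:
        site_rates = np.ones(length)

    leaves: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, codes: np.ndarray) -> None:
        for child in node.children:
            lam = config.subst_rate * (child.length or 0.0) * site_rates
            child_codes = _mutate(codes, lam, rng)
            if child.is_tip():
                leaves[child.name] = child_codes
            else:
                walk(child, child_codes)

    walk(tree.root, root_codes)
    return leaves, root_codes, site_rates


def expected_p_distance(rate: float, path_length: float) -> float:
    """Closed-form p-distance of the uniform 20-state model after a total
    path of ``path_length`` branch-length units at ``rate`` events/site."""
    return (19.0 / 20.0) * (1.0 - np.exp(-rate * path_length * 20.0 / 19.0))


# ------------------------------------------------------------------ assembly
def _assign_classes(
    leaf_names: Sequence[str], fractions: Mapping[str, float]
) -> dict[str, str]:
    n = len(leaf_names)
    counts = {}
    total = sum(fractions.values())
    raw = {cls: n * fractions[cls] / total for cls in GENOME_CLASSES if cls in fractions}
    counts = {cls: int(np.floor(v)) for cls, v in raw.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), GENOME_CLASSES.index(c)))
    for cls in by_frac[:remainder]:
        counts[cls] += 1
    classes = {}
    i = 0
    for cls in GENOME_CLASSES:
        for _ in range(counts.get(cls, 0)):
            classes[leaf_names[i]] = cls
            i += 1
    return classes


def _restricted_gene_tree(species_tree: PhyloTree, carriers: list[str]) -> PhyloTree:
    if len(carriers) < 2:
        raise ConfigError("gene tree needs at least two carriers")
    return species_tree.restrict(carriers)


def _apply_lgt_to_tree(tree: PhyloTree, donor: str, recipient: str, eps: float) -> PhyloTree:
    """Xenologous replacement: recipient tip re-grafts as sister to the donor."""
    out = tree.copy()
    rec = out.find_leaf(recipient)
    rec.parent.remove(rec)
    root = out.root
    root.prune()  # collapse degree-2 nodes left behind
    if len(root.children) == 1:
        child = root.children[0]
        child.length = None
        root = child
    donor_tip = None
    for tip in root.tips():
        if tip.name == donor:
            donor_tip = tip
            break
    donor_tip.name = None
    donor_tip.extend(
        [TreeNode(name=donor, length=eps), TreeNode(name=recipient, length=eps)]
    )
    return PhyloTree(root, rooted=tree.rooted)


def assemble_genomes(
    species_tree: PhyloTree,
    config: SimulationConfig,
) -> tuple[list[AnnotatedGenome], GroundTruth]:
    """Evolve all families, plant gene clusters, apply LGT and incompleteness."""
    leaf_names = list(species_tree.leaf_names)
    classes = _assign_classes(leaf_names, config.class_fractions)
    specs = {f.name: f for f in config.families}
    fam_names = sorted(specs)

    carriers = {
        fam: [g for g in leaf_names if classes[g] in specs[fam].genotype_classes]
        for fam in fam_names
    }
    for fam, donor, recipient in config.lgt_events:
        if fam not in specs:
            raise ConfigError(f"LGT names unknown family {fam!r}")
        if donor not in carriers[fam] or recipient not in carriers[fam]:
            raise ConfigError(
                f"LGT for {fam}: donor/recipient must both carry the family"
            )

    # Evolve sequences family by family on deterministic substreams.  Decoy
    # roots copy a short motif from their target family's root.
    fam_root: dict[str, np.ndarray] = {}
    fam_leaves: dict[str, dict[str, np.ndarray]] = {}
    references: dict[str, ProteinSequence] = {}
    evolve_order = [f for f in fam_names if specs[f].decoy_of is None] + [
        f for f in fam_names if specs[f].decoy_of is not None
    ]
    for fam in evolve_order:
        fi = fam_names.index(fam)
        rng = _rng(config.seed, 1, fi)
        root = rng.integers(0, _N_AA, config.seq_length)
        spec = specs[fam]
        if spec.decoy_of is not None:
            target = spec.decoy_of
            if target not in fam_root:
                raise ConfigError(f"decoy {fam} targets unknown family {target!r}")
            k = min(config.motif_length, config.seq_length)
            root[:k] = fam_root[target][:k]
        fam_root[fam] = root
        leaves, _, site_rates = evolve_family(species_tree, config, rng, root)
        fam_leaves[fam] = leaves
        # Outgroup representative: the family root evolved down an outgroup branch.
        ref_codes = _mutate(
            root, config.subst_rate * config.outgroup_branch_length * site_rates, rng
        )
        references[fam] = ProteinSequence(
            protein_id=f"REF_{fam}", residues=_seq_to_str(ref_codes)
        )

    # True gene trees over carriers, then xenologous replacements.
    gene_trees: dict[str, PhyloTree] = {}
    for fam in fam_names:
        if len(carriers[fam]) >= 2:
            gene_trees[fam] = _restricted_gene_tree(species_tree, carriers[fam])
    lgt_ledger = []
    for li, (fam, donor, recipient) in enumerate(config.lgt_events):
        rng = _rng(config.seed, 4, li)
        lam = config.subst_rate * config.lgt_branch_length * np.ones(config.seq_length)
        fam_leaves[fam][recipient] = _mutate(fam_leaves[fam][donor], lam, rng)
        if fam in gene_trees:
            gene_trees[fam] = _apply_lgt_to_tree(
                gene_trees[fam], donor, recipient, config.lgt_branch_length
            )
        lgt_ledger.append(
            {"family": fam, "donor": donor, "recipient": recipient,
             "mode": "additive" if config.lgt_additive else "replacement"}
        )

    # Per-genome gene order: cargo interleaved with planted blocks.
    genomes: list[AnnotatedGenome] = []
    layouts: dict[str, list[tuple[str, str]]] = {}
    deleted_ledger: list[dict] = []
    for gi, genome_id in enumerate(leaf_names):
        cls = classes[genome_id]
        rng = _rng(config.seed, 2, gi)
        layout = CLASS_LAYOUTS[cls]
        # Units keep planted blocks contiguous: each block is inserted as one
        # atom between cargo/scattered genes, never inside another block.
        units: list[list[tuple[str, str]]] = [
            [(f"{genome_id}_cargo{i:02d}", "cargo")] for i in range(config.n_cargo)
        ]
        blocks = [
            [(f"{genome_id}_{fam}", fam) for fam in block if fam in specs]
            for block in layout["blocks"]
        ]
        scattered_fams = [f for f in layout["scattered"] if f in specs]
        scattered_fams += [
            f.name
            for f in config.families
            if f.decoy_of is not None and cls in f.genotype_classes
        ]
        for block in blocks:
            if not block:
                continue
            pos = int(rng.integers(0, len(units) + 1))
            units.insert(pos, block)
        for fam in scattered_fams:
            pos = int(rng.integers(0, len(units) + 1))
            units.insert(pos, [(f"{genome_id}_{fam}", fam)])
        order: list[tuple[str, str]] = [gene for unit in units for gene in unit]

        # Incompleteness: delete each gene independently.
        kept: list[tuple[str, str]] = []
        complete = True
        for gene_id, label in order:
            if (
                config.incompleteness_prob > 0.0
                and rng.random() < config.incompleteness_prob
            ):
                complete = False
                deleted_ledger.append(
                    {"genome": genome_id, "gene_id": gene_id, "family": label}
                )
            else:
                kept.append((gene_id, label))

        genus = f"gen_{genome_id}"
        genome = AnnotatedGenome(genome_id=genome_id, genus=genus, complete=complete)
        for idx, (gene_id, label) in enumerate(kept):
            if label == "cargo":
                codes = rng.integers(0, _N_AA, config.cargo_length)
                residues = _seq_to_str(codes)
            else:
                residues = _seq_to_str(fam_leaves[label][genome_id])
            strand = "+" if rng.random() < 0.5 else "-"
            genome.genes.append(
                GeneRecord(gene_id, genome_id, "c1", idx, strand, gene_id)
            )
            genome.proteins[gene_id] = ProteinSequence(
                protein_id=gene_id, residues=residues,
                genome_id=genome_id, genus=genus,
            )
        genomes.append(genome)
        layouts[genome_id] = list(order)

    truth = GroundTruth(
        species_tree=species_tree,
        classes=classes,
        gene_trees=gene_trees,
        layouts=layouts,
        lgt_events=lgt_ledger,
        deleted=deleted_ledger,
        references=references,
        decoys=[f.name for f in config.families if f.decoy_of is not None],
    )
    return genomes, truth


def simulate_dataset(config: SimulationConfig) -> tuple[list[AnnotatedGenome], GroundTruth]:
    """Convenience driver: species tree + assembled genomes + ground truth."""
    tree = simulate_species_tree(config)
    return assemble_genomes(tree, config)


# -------------------------------------------------------------------- export
def export_dataset(
    genomes: Sequence[AnnotatedGenome], truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write the dataset in the pipeline's on-disk formats.

    Produces ``proteins.faa``, ``genes.tsv``, ``references.faa`` plus a
    ``reference_families.tsv`` role table, ``genomes.tsv`` metadata, and
    ``ground_truth.json`` (trees as newick strings, ledgers as arrays).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.faa",
        "genes": outdir / "genes.tsv",
        "references": outdir / "references.faa",
        "reference_families": outdir / "reference_families.tsv",
        "genomes": outdir / "genomes.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    all_proteins = [p for g in genomes for _, p in sorted(g.proteins.items())]
    write_fasta(all_proteins, paths["proteins"])
    write_gene_locations([g for gnm in genomes for g in gnm.genes], paths["genes"])
    write_fasta(
        [truth.references[f] for f in sorted(truth.references)], paths["references"]
    )
    with paths["reference_families"].open("w") as fh:
        fh.write("family\tprotein_id\trole\n")
        for fam in sorted(truth.references):
            role = "decoy" if fam in truth.decoys else "target"
            fh.write(f"{fam}\t{truth.references[fam].protein_id}\t{role}\n")
    with paths["genomes"].open("w") as fh:
        fh.write("genome\tgenus\tcomplete\tclass\n")
        for g in genomes:
            fh.write(
                f"{g.genome_id}\t{g.genus}\t{int(g.complete)}\t"
                f"{truth.classes[g.genome_id]}\n"
            )
    blob = {
        "species_tree": truth.species_tree.to_newick().strip(),
        "classes": truth.classes,
        "gene_trees": {
            f: t.to_newick().strip() for f, t in sorted(truth.gene_trees.items())
        },
        "layouts": truth.layouts,
        "lgt_events": truth.lgt_events,
        "deleted": truth.deleted,
        "decoys": truth.decoys,
    }
    paths["ground_truth"].write_text(json.dumps(blob, indent=2, sort_keys=True) + "\n")
    return paths


def load_ground_truth(datadir: str | Path) -> GroundTruth:
    """Reload ``ground_truth.json`` from an exported dataset directory.

    Reference sequences live in ``references.faa`` and are not duplicated in
    the JSON, so the returned object's ``references`` mapping is empty.
    """
    blob = json.loads((Path(datadir) / "ground_truth.json").read_text())
    return GroundTruth(
        species_tree=PhyloTree.from_newick(blob["species_tree"]),
        classes=blob["classes"],
        gene_trees={
            f: PhyloTree.from_newick(nwk) for f, nwk in blob["gene_trees"].items()
        },
        layouts={
            g: [tuple(pair) for pair in pairs]
            for g, pairs in blob["layouts"].items()
        },
        lgt_events=blob["lgt_events"],
        deleted=blob["deleted"],
        references={},
        decoys=blob["decoys"],
    )
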