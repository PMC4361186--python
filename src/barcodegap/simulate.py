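"""Synthetic multi-marker barcode datasets from a multispecies coalescent.

The generator emulates the statistical structure of a recently radiated
plant clade sampled for barcoding: a shallow Yule species tree whose
internal branches are compressed toward a star phylogeny (recent
radiation), gene trees drawn per marker under the multispecies
coalescent (incomplete lineage sorting, controlled by theta),
occasional organelle-capture-like introgression events that transplant
one species' lineages into another species' clade, and sequences
evolved under the two-parameter (Kimura) substitution model so that the
K2P distance used downstream is the matching estimator.

Time is expressed directly in expected substitutions per site at the
slowest marker; faster markers scale branch lengths by a per-marker
rate multiplier.  Only these relative rates matter to the evaluation,
so no separate mutation-rate/generation-time layer exists.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so an identical configuration
yields byte-identical FASTA and Newick output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .alignments import MarkerAlignment, MultiMarkerDataset, SequenceRecord

__all__ = [
    "MarkerModel",
    "SimulationConfig",
    "SyntheticDataset",
    "DEFAULT_MARKERS",
    "simulate_species_tree",
    "simulate_gene_tree",
    "apply_introgression",
    "evolve_alignment",
    "simulate_dataset",
]


@dataclass(frozen=True)
class MarkerModel:
    """One simulated locus: name, aligned length (bp), relative rate."""

    name: str
    length: int
    rate_multiplier: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("marker length must be >= 1")
        if self.rate_multiplier < 0:
            raise ValueError("rate multiplier must be >= 0")


#: Five-marker profile mirroring a typical plastid + nuclear barcode panel:
#: aligned lengths of rbcL/matK/trnH-psbA/trnL-F/ITS-like loci, with
#: relative rates proportional to their observed mean interspecific
#: divergences (slowest marker = 1).
DEFAULT_MARKERS = (
    MarkerModel("rbcL", 1415, 1.0),
    MarkerModel("matK", 847, 2.25),
    MarkerModel("trnH-psbA", 423, 6.5),
    MarkerModel("trnL-F", 927, 1.9),
    MarkerModel("ITS", 668, 9.1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults emulate a recent radiation.

    tree_depth is the species-tree root-to-tip height in expected
    substitutions/site at the slowest marker; radiation_scale in [0, 1]
    compresses internal branches toward a star phylogeny;
    coalescent_theta sets within-branch coalescence (rate = pairs/theta,
    same time units), so theta comparable to internal branch lengths
    produces substantial incomplete lineage sorting;
    introgression_prob is the per-marker probability of one
    organelle-capture event; missing_prob drops accession x marker
    entries to emulate unequal per-marker sampling.
    """

    n_species: int = 47
    accessions_per_species: tuple[int, int] = (3, 6)
    markers: tuple[MarkerModel, ...] = DEFAULT_MARKERS
    kappa: float = 2.0
    tree_depth: float = 0.002
    radiation_scale: float = 0.5
    coalescent_theta: float = 0.00125
    introgression_prob: float = 0.2
    missing_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.accessions_per_species
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not (1 <= lo <= hi):
            raise ValueError("invalid accessions_per_species range")
        if len({m.name for m in self.markers}) != len(self.markers):
            raise ValueError("duplicate marker names")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be > 0")
        if not 0.0 <= self.radiation_scale <= 1.0:
            raise ValueError("radiation_scale must be in [0, 1]")
        if self.coalescent_theta < 0:
            raise ValueError("coalescent_theta must be >= 0")
        if not 0.0 <= self.introgression_prob <= 1.0:
            raise ValueError("introgression_prob must be in [0, 1]")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """Truth-labeled simulator output: data plus generating genealogies."""

    config: SimulationConfig
    dataset: MultiMarkerDataset
    species_tree: dendropy.Tree
    gene_trees: dict[str, dendropy.Tree]
    event_log: list[dict] = field(default_factory=list)

    def write(self, outdir) -> None:
        """Write FASTA per marker, Newick trees, species map and event log."""
        import os

        from .io import write_fasta, write_newick, write_tsv

        os.makedirs(outdir, exist_ok=True)
        for marker, aln in self.dataset.alignments.items():
            write_fasta(aln, os.path.join(outdir, f"{marker}.fasta"))
        write_newick(self.species_tree, os.path.join(outdir, "species_tree.nwk"))
        for marker, gt in self.gene_trees.items():
            write_newick(gt, os.path.join(outdir, f"gene_tree_{marker}.nwk"))
        write_tsv(
            os.path.join(outdir, "species_map.tsv"),
            ["accession", "species"],
            sorted(self.dataset.species_of.items()),
        )
        write_tsv(
            os.path.join(outdir, "events.tsv"),
            ["marker", "recipient", "donor"],
            [(e["marker"], e["recipient"], e["donor"]) for e in self.event_log],
        )


# ---------------------------------------------------------------------------
# Species tree


def _finish_tree(
    seed_node: dendropy.Node, leaf_labels: Mapping[int, str] | None = None
) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed_node)
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.new_taxon(leaf._pending_label)
        del leaf._pending_label
    tree.is_rooted = True
    return tree


def simulate_species_tree(
    n_species: int,
    tree_depth: float,
    radiation_scale: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Ultrametric Yule species tree compressed toward a recent radiation.

    A pure-birth topology is rescaled so every root-to-tip path equals
    ``tree_depth``; internal branches are then multiplied by
    ``radiation_scale`` and pendant branches re-extended so tips stay at
    depth ``tree_depth``.  radiation_scale -> 0 approaches a star
    phylogeny (simultaneous divergence of all species).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if labels is None:
        width = max(2, len(str(n_species)))
        labels = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    elif len(labels) != n_species:
        raise ValueError("labels length must equal n_species")
    rng = np.random.default_rng(seed)

    # forward Yule: start with the root split, lineages split at rate 1 each
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        pick = int(rng.integers(k))
        node, born = active.pop(pick)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / len(active))
    order = rng.permutation(len(active))
    for slot, (node, born) in enumerate(active):
        node.edge.length = t_end - born
        node._pending_label = labels[int(order[slot])]

    # rescale to requested depth
    scale = tree_depth / t_end
    for node in root.preorder_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    # compress internals, then restore tip depth (ultrametric radiation)
    for node in root.preorder_iter():
        if node is root or node.is_leaf():
            continue
        node.edge.length *= radiation_scale
    depth_of: dict[dendropy.Node, float] = {root: 0.0}
    for node in root.preorder_iter():
        if node is root:
            continue
        depth_of[node] = depth_of[node.parent_node] + node.edge.length
    for node in root.leaf_iter():
        node.edge.length += tree_depth - depth_of[node]
    return _finish_tree(root)


def _node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Age (time before the tips) of every node in an ultrametric tree."""
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    max_depth = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        max_depth = max(max_depth, depth[node])
    return {node: max_depth - d for node, d in depth.items()}


# ---------------------------------------------------------------------------
# Multispecies-coalescent gene tree


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    samples_per_species: Mapping[str, Sequence[str] | int],
    coalescent_theta: float,
    seed: int | np.random.SeedSequence = 0,
) -> dendropy.Tree:
    """Draw one gene tree under the multispecies coalescent.

    ``samples_per_species`` maps species-tree leaf labels to either the
    accession labels to sample or a count (labels are then generated as
    ``{species}a{i}``).  Within each species-tree branch, the current
    k lineages coalesce at rate ``k*(k-1)/2 / theta`` (time in the
    species tree's substitution units); uncoalesced lineages propagate
    rootward, and everything coalesces in the (unbounded) root branch.
    theta = 0 forces instantaneous within-branch coalescence, i.e.
    topological concordance with the species tree.
    """
    if coalescent_theta < 0:
        raise ValueError("coalescent_theta must be >= 0")
    rng = np.random.default_rng(seed)
    ages = _node_ages(species_tree)

    def _coalesce(
        pool: list[dendropy.Node],
        lower: float,
        upper: float,
    ) -> list[dendropy.Node]:
        time = lower
        while len(pool) > 1:
            k = len(pool)
            if coalescent_theta == 0.0:
                time = lower
            else:
                rate = k * (k - 1) / 2.0 / coalescent_theta
                time = time + rng.exponential(1.0 / rate)
                if time >= upper:
                    return pool
            i, j = sorted(rng.choice(k, size=2, replace=False))
            right = pool.pop(int(j))
            left = pool.pop(int(i))
            parent = dendropy.Node()
            for child in (left, right):
                child.edge.length = time - child._age
                parent.add_child(child)
            parent._age = time
            pool.append(parent)
        return pool

    pools: dict[dendropy.Node, list[dendropy.Node]] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            spec = samples_per_species.get(label, 0)
            if isinstance(spec, int):
                sample_labels = [f"{label}a{i + 1}" for i in range(spec)]
            else:
                sample_labels = list(spec)
            pool = []
            for lab in sample_labels:
                tip = dendropy.Node()
                tip._pending_label = lab
                tip._age = ages[node]
                pool.append(tip)
        else:
            pool = []
            for child in node.child_nodes():
                pool.extend(pools.pop(child))
        if node is species_tree.seed_node:
            root_pool = _coalesce(pool, ages[node], math.inf)
        else:
            pools[node] = _coalesce(pool, ages[node], ages[node.parent_node])

    if len(root_pool) != 1:
        raise RuntimeError("gene tree failed to fully coalesce")
    root = root_pool[0]
    # convert remaining bookkeeping
    for node in root.preorder_iter():
        if hasattr(node, "_age"):
            del node._age
    return _finish_tree(root)


# ---------------------------------------------------------------------------
# Introgression


def _remove_leaf(root: dendropy.Node, leaf: dendropy.Node) -> dendropy.Node:
    """Remove a leaf, suppressing the resulting unifurcation; return root."""
    parent = leaf.parent_node
    parent.remove_child(leaf)
    children = parent.child_nodes()
    if len(children) == 1:
        only = children[0]
        grand = parent.parent_node
        if grand is None:
            parent.remove_child(only)
            only.edge.length = None
            return only
        only.edge.length = (only.edge.length or 0.0) + (parent.edge.length or 0.0)
        grand.remove_child(parent)
        grand.add_child(only)
    return root


def apply_introgression(
    gene_tree: dendropy.Tree,
    species_of: Mapping[str, str],
    introgression_prob: float,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[dendropy.Tree, list[dict]]:
    """Transplant one species' lineages into another species' clade.

    With probability ``introgression_prob`` a recipient and a donor
    species are drawn; every recipient sample is detached and re-grafted
    as sister to a donor sample (donors cycled), attaching at a uniform
    height on the donor tip's pendant edge.  This emulates organelle
    capture: the recipient's accessions show a systematic association
    with the donor and the recipient becomes non-monophyletic on this
    gene tree whenever it has two or more samples.  The tree is
    modified in place and returned with the event log.
    """
    if not 0.0 <= introgression_prob <= 1.0:
        raise ValueError("introgression_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    events: list[dict] = []
    if rng.random() >= introgression_prob:
        return gene_tree, events

    leaves_by_species: dict[str, list[dendropy.Node]] = {}
    for leaf in gene_tree.leaf_node_iter():
        leaves_by_species.setdefault(species_of[leaf.taxon.label], []).append(leaf)
    candidates = sorted(sp for sp, lv in leaves_by_species.items() if lv)
    if len(candidates) < 2:
        return gene_tree, events
    pick = rng.choice(len(candidates), size=2, replace=False)
    recipient, donor = candidates[int(pick[0])], candidates[int(pick[1])]

    recipient_leaves = sorted(
        leaves_by_species[recipient], key=lambda lf: lf.taxon.label
    )
    donor_leaves = sorted(leaves_by_species[donor], key=lambda lf: lf.taxon.label)
    order = rng.permutation(len(donor_leaves))

    root = gene_tree.seed_node
    for idx, rleaf in enumerate(recipient_leaves):
        root = _remove_leaf(root, rleaf)
    for idx, rleaf in enumerate(recipient_leaves):
        dleaf = donor_leaves[int(order[idx % len(donor_leaves)])]
        pendant = dleaf.edge.length or 0.0
        u = float(rng.uniform(0.0, pendant)) if pendant > 0 else 0.0
        parent = dleaf.parent_node
        joint = dendropy.Node()
        parent.remove_child(dleaf)
        parent.add_child(joint)
        joint.edge.length = pendant - u
        dleaf.edge.length = u
        rleaf.edge.length = u
        joint.add_child(dleaf)
        joint.add_child(rleaf)

    events.append({"recipient": recipient, "donor": donor})
    new_tree = dendropy.Tree(
        taxon_namespace=gene_tree.taxon_namespace, seed_node=root
    )
    new_tree.is_rooted = True
    return new_tree, events


# ---------------------------------------------------------------------------
# Sequence evolution (K80)


_tv_codes = np.array([1, 3], dtype=np.uint8)


def evolve_alignment(
    gene_tree: dendropy.Tree,
    length: int,
    kappa: float,
    rate_multiplier: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    marker: str = "sim",
    species_of: Mapping[str, str] | None = None,
) -> MarkerAlignment:
    """Evolve sites independently down a gene tree under the K80 model.

    Branch lengths are multiplied by ``rate_multiplier`` and interpreted
    as expected substitutions per site; kappa is the transition /
    transversion *rate* ratio.  The root sequence is uniform over
    {A, C, G, T} (the model's stationary distribution).  Output is a
    gap-free alignment of the gene tree's leaves, in leaf-label order.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if rate_multiplier < 0:
        raise ValueError("rate_multiplier must be >= 0")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa / (kappa + 2.0)

    seqs: dict[dendropy.Node, np.ndarray] = {}
    root = gene_tree.seed_node
    seqs[root] = rng.integers(0, 4, size=length, dtype=np.uint8)
    for node in gene_tree.preorder_node_iter():
        if node is root:
            continue
        t = (node.edge.length or 0.0) * rate_multiplier
        parent_seq = seqs[node.parent_node]
        if t <= 0.0:
            seqs[node] = parent_seq
            continue
        e1 = math.exp(-4.0 * beta * t)
        e2 = math.exp(-2.0 * (alpha + beta) * t)
        p_same = 0.25 + 0.25 * e1 + 0.5 * e2
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e1
        # xor codes: 0 = identity, 2 = transition, 1/3 = the two transversions
        codes = rng.choice(
            np.array([0, 2, 1, 3], dtype=np.uint8),
            size=length,
            p=[p_same, p_ts, p_tv, p_tv],
        )
        seqs[node] = parent_seq ^ codes

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    leaves = sorted(gene_tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    for leaf in leaves:
        label = leaf.taxon.label
        residues = bases[seqs[leaf]].tobytes().decode("ascii")
        species = species_of[label] if species_of else label
        records.append(SequenceRecord(label, species, marker, residues))
    return MarkerAlignment(marker=marker, records=records)


# ---------------------------------------------------------------------------
# Full dataset


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a truth-labeled multi-marker dataset from one config.

    Per-marker missingness is decided first (so each gene tree contains
    exactly the accessions sampled for that marker), then one coalescent
    gene tree is drawn per marker, introgression is applied per marker,
    and sequences are evolved with the marker's length and rate.
    """
    master = np.random.SeedSequence(config.seed)
    n_markers = len(config.markers)
    # spawn order: species tree, accession counts, then per-marker triples
    spawned = master.spawn(2 + 3 * n_markers + 1)
    tree_seed, counts_seed = spawned[0], spawned[1]
    missing_seed = spawned[-1]

    species_tree = simulate_species_tree(
        config.n_species,
        config.tree_depth,
        config.radiation_scale,
        seed=tree_seed,
    )
    species = sorted(leaf.taxon.label for leaf in species_tree.leaf_node_iter())

    counts_rng = np.random.default_rng(counts_seed)
    lo, hi = config.accessions_per_species
    accessions_of: dict[str, list[str]] = {}
    species_of: dict[str, str] = {}
    for sp in species:
        n_acc = int(counts_rng.integers(lo, hi + 1))
        accs = [f"{sp}a{i + 1}" for i in range(n_acc)]
        accessions_of[sp] = accs
        for acc in accs:
            species_of[acc] = sp

    missing_rng = np.random.default_rng(missing_seed)
    alignments: dict[str, MarkerAlignment] = {}
    gene_trees: dict[str, dendropy.Tree] = {}
    event_log: list[dict] = []
    for mi, marker in enumerate(config.markers):
        gt_seed = spawned[2 + 3 * mi]
        intro_seed = spawned[2 + 3 * mi + 1]
        seq_seed = spawned[2 + 3 * mi + 2]

        present: dict[str, list[str]] = {}
        for sp in species:
            kept = [
                acc
                for acc in accessions_of[sp]
                if missing_rng.random() >= config.missing_prob
            ]
            if kept:
                present[sp] = kept

        gene_tree = simulate_gene_tree(
            species_tree, present, config.coalescent_theta, seed=gt_seed
        )
        gene_tree, events = apply_introgression(
            gene_tree, species_of, config.introgression_prob, seed=intro_seed
        )
        for ev in events:
            event_log.append({"marker": marker.name, **ev})
        aln = evolve_alignment(
            gene_tree,
            marker.length,
            config.kappa,
            marker.rate_multiplier,
            seed=seq_seed,
            marker=marker.name,
            species_of=species_of,
        )
        alignments[marker.name] = aln
        gene_trees[marker.name] = gene_tree

    dataset = MultiMarkerDataset(alignments, dict(species_of))
    return SyntheticDataset(
        config=config,
        dataset=dataset,
        species_tree=species_tree,
        gene_trees=gene_trees,
        event_log=event_log,
    )
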