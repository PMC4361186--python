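"""Distance trees, bootstrap supports, and species-monophyly scoring.

UPGMA (average-linkage agglomeration; rooted, ultrametric) and
neighbor-joining (Q-criterion agglomeration; unrooted, exact on additive
matrices) are built directly from a masked K2P DistanceMatrix.  Both
refuse matrices with undefined entries: imputing a masked distance would
silently corrupt downstream monophyly scores.

Species resolution follows the tree-based identification convention:
a species is *resolved* by a tree when its accessions are monophyletic —
a complete clade in a rooted tree, or one side of a single edge's
bipartition in an unrooted tree — and *resolved with support* when that
edge's nonparametric bootstrap value meets a threshold (70 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .alignments import MarkerAlignment
from .distances import DistanceMatrix, distance_matrix_from_encoded, encode_sequences
from .io import support_of

__all__ = [
    "MaskedDistanceError",
    "ResolutionReport",
    "upgma_tree",
    "nj_tree",
    "build_tree",
    "bootstrap_supports",
    "is_monophyletic",
    "resolution_rates",
    "clade_leaf_sets",
    "nontrivial_splits",
]


class MaskedDistanceError(ValueError):
    """Tree construction refused: the distance matrix has undefined entries."""


def _require_defined(dm: DistanceMatrix) -> None:
    if not dm.all_defined:
        pairs = dm.undefined_pairs()
        raise MaskedDistanceError(
            f"{len(pairs)} undefined distance(s), e.g. {pairs[:3]!r}; "
            "tree construction refuses masked matrices"
        )


def _new_tree(seed: dendropy.Node, leaves: Iterable[dendropy.Node], rooted: bool) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    for leaf in leaves:
        leaf.taxon = tns.new_taxon(leaf._pending_label)
        del leaf._pending_label
    tree.is_rooted = rooted
    return tree


def _leaf_node(label: str) -> dendropy.Node:
    node = dendropy.Node()
    node._pending_label = label
    return node


# ---------------------------------------------------------------------------
# UPGMA


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) tree; rooted and ultrametric.

    Ties in the minimum average distance are broken on the
    lexicographically smallest pair of cluster representative labels,
    making the output deterministic.
    """
    _require_defined(dm)
    n = dm.n
    if n < 2:
        raise ValueError("need at least two taxa")

    D = dm.values.astype(float).copy()
    nodes = [_leaf_node(lab) for lab in dm.labels]
    leaves = list(nodes)
    size = [1] * n
    height = [0.0] * n
    # representative = lexicographically smallest leaf label in the cluster
    rep = list(dm.labels)
    active = list(range(n))

    while len(active) > 1:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        np.fill_diagonal(sub, np.inf)
        d_min = sub.min()
        ties = np.argwhere(np.triu(sub == d_min, k=1))
        ai, aj = min(
            (tuple(t) for t in ties),
            key=lambda t: tuple(sorted((rep[idx[t[0]]], rep[idx[t[1]]]))),
        )
        i, j = int(idx[ai]), int(idx[aj])
        d = D[i, j]
        h = d / 2.0
        parent = dendropy.Node()
        for child in (i, j):
            nodes[child].edge.length = max(h - height[child], 0.0)
            parent.add_child(nodes[child])
        # size-weighted average linkage
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (size[i] * D[i, k] + size[j] * D[j, k]) / (
                size[i] + size[j]
            )
        nodes[i] = parent
        size[i] += size[j]
        height[i] = h
        rep[i] = min(rep[i], rep[j])
        active.remove(j)

    root = nodes[active[0]]
    return _new_tree(root, leaves, rooted=True)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou-Nei, Q-criterion); unrooted.

    Exact on additive matrices.  Negative branch-length estimates are
    clamped to zero and counted on the returned tree's
    ``clamped_negative_branches`` attribute.  Ties in Q are broken on
    the lexicographically smallest representative-label pair.
    """
    _require_defined(dm)
    n = dm.n
    if n < 2:
        raise ValueError("need at least two taxa")

    clamped = 0

    def _bl(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += 1
            return 0.0
        return x

    leaves = [_leaf_node(lab) for lab in dm.labels]

    if n == 2:
        seed = dendropy.Node()
        for node in leaves:
            node.edge.length = dm.values[0, 1] / 2.0
            seed.add_child(node)
        tree = _new_tree(seed, leaves, rooted=False)
        tree.clamped_negative_branches = clamped
        return tree

    D = dm.values.astype(float).copy()
    nodes = list(leaves)
    rep = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        q_min = qmat.min()
        # qmat can differ by 1 ulp across the diagonal (summation order),
        # so collect hits from both triangles and normalize the pair
        ties = {(min(t), max(t)) for t in map(tuple, np.argwhere(qmat == q_min))}
        ai, aj = min(
            ties,
            key=lambda t: tuple(sorted((rep[idx[t[0]]], rep[idx[t[1]]]))),
        )
        i, j = int(idx[ai]), int(idx[aj])
        d_ij = sub[ai, aj]
        li = d_ij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        nodes[i].edge.length = _bl(li)
        nodes[j].edge.length = _bl(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (D[i, k] + D[j, k] - d_ij) / 2.0
        nodes[i] = parent
        rep[i] = min(rep[i], rep[j])
        active.remove(j)

    a, b, c = active
    seed = dendropy.Node()
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].edge.length = _bl(lk)
        seed.add_child(nodes[k])
    tree = _new_tree(seed, leaves, rooted=False)
    tree.clamped_negative_branches = clamped
    return tree


def build_tree(dm: DistanceMatrix, method: str) -> dendropy.Tree:
    """Dispatch to :func:`upgma_tree` or :func:`nj_tree` by name."""
    method = method.lower()
    if method == "upgma":
        return upgma_tree(dm)
    if method == "nj":
        return nj_tree(dm)
    raise ValueError(f"unknown tree method {method!r} (expected 'upgma' or 'nj')")


# ---------------------------------------------------------------------------
# Bipartitions and clades


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label


def clade_leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set below every node (postorder accumulation)."""
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([_leaf_label(node)])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= out[child]
            out[node] = frozenset(acc)
    return out


def _canonical_split(
    side: frozenset[str], all_leaves: frozenset[str], ref: str
) -> frozenset[str]:
    # canonical representation: the side NOT containing the reference leaf
    return all_leaves - side if ref in side else side


def nontrivial_splits(
    tree: dendropy.Tree,
) -> dict[frozenset[str], dendropy.Node]:
    """Map canonical nontrivial bipartitions -> defining internal node.

    For rooted trees the keys are clade leaf-sets of internal non-root
    nodes; for unrooted trees they are edge bipartitions canonicalised
    to the side not containing the lexicographically smallest leaf.
    """
    clades = clade_leaf_sets(tree)
    all_leaves = clades[tree.seed_node]
    out: dict[frozenset[str], dendropy.Node] = {}
    if tree.is_rooted:
        for node, clade in clades.items():
            if node is tree.seed_node or node.is_leaf():
                continue
            out[clade] = node
        return out
    ref = min(all_leaves)
    for node, clade in clades.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        key = _canonical_split(clade, all_leaves, ref)
        if len(key) < 2 or len(key) > len(all_leaves) - 2:
            continue  # trivial split
        out[key] = node
    return out


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_supports(
    alignment: MarkerAlignment,
    method: str,
    n_reps: int,
    seed: int,
) -> dendropy.Tree:
    """Point-estimate tree with nonparametric bootstrap edge supports.

    Each replicate resamples alignment columns with replacement (same
    length), rebuilds the tree, and records its bipartitions; an edge's
    support is the percentage of successful replicates containing that
    bipartition, rounded to the nearest integer and stored as the
    internal node's label.  Replicates whose resampled matrix has
    undefined entries are skipped and counted; a warning is issued when
    more than 10% are skipped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    codes = encode_sequences([rec.residues for rec in alignment])
    labels = alignment.accession_ids
    dm = distance_matrix_from_encoded(codes, labels)
    tree = build_tree(dm, method)

    rng = np.random.default_rng(seed)
    length = codes.shape[1]
    counts: dict[frozenset[str], int] = {}
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        sub = np.ascontiguousarray(codes[:, cols])
        dm_rep = distance_matrix_from_encoded(sub, labels)
        if not dm_rep.all_defined:
            skipped += 1
            continue
        rep_tree = build_tree(dm_rep, method)
        for key in nontrivial_splits(rep_tree):
            counts[key] = counts.get(key, 0) + 1

    successful = n_reps - skipped
    if skipped > 0.1 * n_reps:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped "
            "(undefined distances)",
            stacklevel=2,
        )
    for key, node in nontrivial_splits(tree).items():
        if successful > 0:
            pct = 100.0 * counts.get(key, 0) / successful
        else:
            pct = 0.0
        node.label = str(int(round(pct)))
    tree.bootstrap_replicates = successful
    tree.bootstrap_skipped = skipped
    return tree


# ---------------------------------------------------------------------------
# Monophyly


def is_monophyletic(
    tree: dendropy.Tree, leaf_set: Iterable[str]
) -> tuple[bool, int | None]:
    """Test whether a leaf-label set is monophyletic; return its support.

    Rooted tree: true iff some node's descendant set equals the set.
    Unrooted tree: true iff some edge's bipartition has one side equal
    to the set (either side of the split qualifies).  A singleton is
    monophyletic by definition, with support ``None``.
    """
    target = frozenset(leaf_set)
    if not target:
        raise ValueError("leaf_set must be non-empty")
    clades = clade_leaf_sets(tree)
    all_leaves = clades[tree.seed_node]
    unknown = target - all_leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)!r}")
    if len(target) == 1:
        return True, None
    if target == all_leaves:
        return True, None
    if tree.is_rooted:
        for node, clade in clades.items():
            if clade == target:
                return True, support_of(node)
        return False, None
    complement = all_leaves - target
    for node, clade in clades.items():
        if node is tree.seed_node:
            continue
        if clade == target or clade == complement:
            sup = support_of(node) if not node.is_leaf() else None
            return True, sup
    return False, None


@dataclass
class ResolutionReport:
    """Per-tree species-monophyly scoring (one marker combo, one method)."""

    combo: list[str]
    method: str
    n_species_evaluated: int
    n_monophyletic: int
    n_monophyletic_supported: int
    rate: float
    rate_supported: float
    per_species: dict[str, dict] = field(default_factory=dict)


def resolution_rates(
    tree: dendropy.Tree,
    species_of: Mapping[str, str],
    support_threshold: int = 70,
    singletons_count: bool = True,
    combo: Sequence[str] | None = None,
    method: str = "",
) -> ResolutionReport:
    """Score every species' monophyly on one tree.

    A species represented by a single leaf is counted monophyletic in
    the raw rate when ``singletons_count`` (the default keeps the
    denominator at the full species count) but never enters the
    supported numerator, since it defines no internal edge.  Rates are
    percentages rounded to one decimal.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    by_species: dict[str, set[str]] = {}
    for label in leaves:
        by_species.setdefault(species_of[label], set()).add(label)

    per_species: dict[str, dict] = {}
    n_mono = 0
    n_supported = 0
    for sp in sorted(by_species):
        members = by_species[sp]
        if len(members) == 1:
            mono = singletons_count
            sup = None
            per_species[sp] = {
                "monophyletic": mono,
                "support": None,
                "singleton": True,
            }
            if mono:
                n_mono += 1
            continue
        mono, sup = is_monophyletic(tree, members)
        per_species[sp] = {
            "monophyletic": mono,
            "support": sup,
            "singleton": False,
        }
        if mono:
            n_mono += 1
            if sup is not None and sup >= support_threshold:
                n_supported += 1

    n_eval = len(by_species)
    rate = round(100.0 * n_mono / n_eval, 1) if n_eval else 0.0
    rate_sup = round(100.0 * n_supported / n_eval, 1) if n_eval else 0.0
    return ResolutionReport(
        combo=list(combo) if combo is not None else [],
        method=method,
        n_species_evaluated=n_eval,
        n_monophyletic=n_mono,
        n_monophyletic_supported=n_supported,
        rate=rate,
        rate_supported=rate_sup,
        per_species=per_species,
    )
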