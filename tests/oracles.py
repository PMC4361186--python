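"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the mathematical
definitions (per-character counting, arbitrary-precision closed forms,
exhaustive enumeration) and never calls the implementation paths it is
used to check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import mpmath
import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
UNAMBIGUOUS = PURINES | PYRIMIDINES


def k2p_brute(seq_a: str, seq_b: str):
    """Count transitions/transversions character by character and
    evaluate the K2P closed form with 50-digit arithmetic.

    Returns (distance, P, Q, n_sites, defined) with distance as float.
    """
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan, math.nan, math.nan, 0, False
    p = Fraction(ts, n)
    q = Fraction(tv, n)
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.nan, float(p), float(q), n, False
    with mpmath.workdps(50):
        d = -mpmath.mpf("0.5") * mpmath.log(
            mpmath.mpf(w1.numerator) / w1.denominator
        ) - mpmath.mpf("0.25") * mpmath.log(mpmath.mpf(w2.numerator) / w2.denominator)
        d = float(d)
    return max(d, 0.0), ts / n, tv / n, n, True


def wilcoxon_enumerate(x, y):
    """Exact two-sided rank-sum p by enumerating value assignments.

    Pools the observed values and considers every way of labelling
    ``len(x)`` of them as the first sample, recomputing mid-ranks from
    scratch for each assignment.
    """
    pooled = list(map(float, x)) + list(map(float, y))
    n = len(x)
    total = len(pooled)

    def rank_sum(indices):
        chosen = set(indices)
        order = sorted(range(total), key=lambda i: pooled[i])
        ranks = [0.0] * total
        i = 0
        while i < total:
            j = i
            while j + 1 < total and pooled[order[j + 1]] == pooled[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return sum(ranks[i] for i in chosen)

    w_obs = rank_sum(range(n))
    mu = n * (total + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = trials = 0
    for combo in itertools.combinations(range(total), n):
        trials += 1
        if abs(rank_sum(combo) - mu) >= dev - 1e-9:
            hits += 1
    return w_obs, hits / trials


def random_binary_unrooted(rng: np.random.Generator, labels):
    """Random unrooted binary topology with U(0.1, 1) branch lengths.

    Returns (edges, lengths) as an adjacency structure plus the
    leaf-to-leaf path-length matrix computed by BFS — an additive
    matrix realisable by exactly this tree.
    """
    labels = list(labels)
    n = len(labels)
    assert n >= 3
    # nodes: 0..n-1 leaves; internal nodes appended
    adj: dict[int, dict[int, float]] = {i: {} for i in range(3)}
    nxt = n

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    star = nxt
    nxt += 1
    for leaf in range(3):
        connect(leaf, star, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n):
        # pick a random existing edge and subdivide it
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = nxt
        nxt += 1
        cut = float(rng.uniform(0.25, 0.75)) * w
        connect(u, mid, cut)
        connect(mid, v, w - cut)
        connect(leaf, mid, float(rng.uniform(0.1, 1.0)))

    dist = np.zeros((n, n))
    for src in range(n):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur].items():
                if nb not in seen:
                    seen[nb] = seen[cur] + w
                    stack.append(nb)
        for dst in range(n):
            dist[src, dst] = seen[dst]
    return adj, dist


def splits_of_adjacency(adj, n_leaves):
    """Nontrivial leaf bipartitions of an adjacency-structure tree,
    canonicalised to the side not containing leaf 0."""
    splits = set()
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        seen = {v}
        stack = [v]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if (cur == v and nb == u) or nb in seen:
                    continue
                seen.add(nb)
                stack.append(nb)
        side = frozenset(x for x in seen if x < n_leaves)
        if 0 in side:
            side = frozenset(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(side)
    return splits


def random_ultrametric(rng: np.random.Generator, n: int):
    """Random strictly ultrametric distance matrix via sequential
    agglomeration at strictly increasing heights."""
    heights = np.zeros((n, n))
    clusters = [[i] for i in range(n)]
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.1, 1.0))
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                heights[a, b] = heights[b, a] = h
        clusters[i] = clusters[i] + clusters.pop(j)
    return 2.0 * heights


def classify_query_brute(query, labels, species, dist, defined, criterion, threshold):
    """Independent re-derivation of the three identification criteria
    from first principles on explicit distance lists."""
    qi = labels.index(query)
    q_sp = species[query]
    refs = [
        (lab, dist[qi][j])
        for j, lab in enumerate(labels)
        if j != qi and defined[qi][j]
    ]
    conspecifics = [lab for j, lab in enumerate(labels) if j != qi and species[lab] == q_sp]
    if not refs:
        return "no_match"
    best_d = min(d for _, d in refs)
    best = [lab for lab, d in refs if d == best_d]
    best_species = {species[lab] for lab in best}

    def bm_outcome():
        if best_species == {q_sp}:
            return "correct"
        return "ambiguous" if q_sp in best_species else "incorrect"

    if criterion == "best_match":
        return bm_outcome()
    if criterion == "best_close_match":
        if best_d > threshold:
            return "no_match"
        return bm_outcome()
    # all_species_barcodes
    if len(conspecifics) < 2:
        return "no_conspecific"
    within = {lab for lab, d in refs if d <= threshold}
    if not within:
        return "no_match"
    cons = set(conspecifics)
    if within == cons:
        return "correct"
    if within < cons:
        return "incorrect"
    return "ambiguous" if within & cons else "incorrect"
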