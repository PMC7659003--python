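"""Directed 3-/4-node motif census, identifiers and significance.

Motif identifiers follow the classic motif-detector bitmask convention: a labeled n-node
digraph is the integer whose bit of weight 2^(n^2 - (n(i-1) + j)) is set for
each edge i -> j (row-major adjacency, most-significant bit = 1 -> 1).  The
*canonical* identifier of an isomorphism class is the minimum of that
integer over all n! node relabelings; under this convention the familiar
3-node types are 36 (convergence, two edges into one node), 6 (divergence),
12 (chain), 38 (feed-forward), 98 (the 3-cycle feedback loop), 74 (a
reciprocal dyad plus one incoming edge) and 78 (a hub with reciprocal edges
to two otherwise unconnected nodes).

The census counts *induced* occurrences: every weakly connected n-node
subset contributes exactly one count, under the canonical id of its induced
subgraph, enumerated with the ESU (exact subgraph enumeration) scheme.
Significance compares the real count against a null ensemble of
degree-preserving edge switchings that also conserve the number of
reciprocal (mutual) dyads; a motif is significant when z >= 2 and its real
count is at least 4 (the published defaults of the original detector).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "MotifRecord",
    "motif_id_encode",
    "motif_id_decode",
    "motif_id_canonical",
    "all_canonical_classes",
    "census",
    "census_instances",
    "randomize_network",
    "motif_significance",
    "representative_motifs",
    "submotif_census",
    "correlated_feedback_fraction",
]


def _bit(n: int, i: int, j: int) -> int:
    """Bit weight of edge i -> j (1-based labels) in an n-node mask."""
    return 1 << (n * n - (n * (i - 1) + j))


def motif_id_encode(n: int, edges: Iterable[tuple[int, int]]) -> int:
    """Row-major adjacency bitmask of a labeled digraph on nodes 1..n."""
    if n not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    mask = 0
    for i, j in edges:
        if i == j:
            raise ValueError(f"self-loop at node {i}")
        if not (1 <= i <= n and 1 <= j <= n):
            raise ValueError(f"edge ({i}, {j}) outside 1..{n}")
        mask |= _bit(n, i, j)
    return mask


def motif_id_decode(n: int, mask: int) -> list[tuple[int, int]]:
    """Edge list (on nodes 1..n) of a bitmask; rejects diagonal bits."""
    if n not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    if not 0 <= mask < 1 << (n * n):
        raise ValueError(f"id {mask} out of range for n={n}")
    edges = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if mask & _bit(n, i, j):
                if i == j:
                    raise ValueError(f"id {mask} sets the diagonal bit ({i},{i})")
                edges.append((i, j))
    return edges


@lru_cache(maxsize=2)
def _canonical_table(n: int) -> np.ndarray:
    """canonical[mask] = min over all node relabelings, for every n-node mask."""
    nbits = n * n
    masks = np.arange(1 << nbits, dtype=np.int64)
    best = masks.copy()
    positions = [(i, j) for i in range(1, n + 1) for j in range(1, n + 1)]
    for perm in permutations(range(1, n + 1)):
        relabel = dict(zip(range(1, n + 1), perm))
        permuted = np.zeros_like(masks)
        for i, j in positions:
            src = nbits - (n * (i - 1) + j)
            dst = nbits - (n * (relabel[i] - 1) + relabel[j])
            permuted |= ((masks >> src) & 1) << dst
        np.minimum(best, permuted, out=best)
    return best


def motif_id_canonical(n: int, mask_or_edges) -> int:
    """Canonical (relabeling-minimal) id of a mask or edge list."""
    if isinstance(mask_or_edges, (int, np.integer)):
        mask = int(mask_or_edges)
        motif_id_decode(n, mask)  # validates range and diagonal
    else:
        mask = motif_id_encode(n, mask_or_edges)
    return int(_canonical_table(n)[mask])


def _connected_mask(n: int, mask: int) -> bool:
    """Weak connectivity of the digraph encoded by ``mask``."""
    adj = [0] * n
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i != j and mask & _bit(n, i, j):
                adj[i - 1] |= 1 << (j - 1)
                adj[j - 1] |= 1 << (i - 1)
    seen = 1
    frontier = [0]
    while frontier:
        v = frontier.pop()
        nxt = adj[v] & ~seen
        while nxt:
            b = nxt & -nxt
            nxt ^= b
            seen |= b
            frontier.append(b.bit_length() - 1)
    return seen == (1 << n) - 1


@lru_cache(maxsize=2)
def all_canonical_classes(n: int) -> tuple[int, ...]:
    """Sorted canonical ids of all connected n-node classes (13 / 199)."""
    table = _canonical_table(n)
    out = set()
    for mask in range(1 << (n * n)):
        if int(table[mask]) == mask and not _has_diag(n, mask) and _connected_mask(n, mask):
            out.add(mask)
    return tuple(sorted(out))


def _has_diag(n: int, mask: int) -> bool:
    return any(mask & _bit(n, i, i) for i in range(1, n + 1))


# ---------------------------------------------------------------------------
# Census (ESU enumeration of connected induced subgraphs)
# ---------------------------------------------------------------------------

def _esu_subsets(adj: Sequence[set[int]], k: int) -> Iterator[tuple[int, ...]]:
    """All weakly connected k-node subsets, each exactly once (ESU scheme)."""
    n = len(adj)

    def extend(sub: list[int], ext: set[int], v: int) -> Iterator[tuple[int, ...]]:
        if len(sub) == k:
            yield tuple(sub)
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            # exclusive neighborhood: neighbors of w not adjacent to sub
            new_ext = ext | {
                u for u in adj[w] if u > v and not any(u in adj[s] for s in sub)
            }
            yield from extend(sub + [w], new_ext, v)

    for v in range(n):
        ext0 = {u for u in adj[v] if u > v}
        yield from extend([v], ext0, v)


def _neighbor_sets(graph: nx.DiGraph, nodes: list) -> list[set[int]]:
    index = {u: i for i, u in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in nodes]
    for u, v in graph.edges():
        adj[index[u]].add(index[v])
        adj[index[v]].add(index[u])
    return adj


def _subset_mask(
    graph: nx.DiGraph, nodes: Sequence, subset: Sequence[int], n: int
) -> int:
    mask = 0
    for a, ia in enumerate(subset, start=1):
        for b, jb in enumerate(subset, start=1):
            if a != b and graph.has_edge(nodes[ia], nodes[jb]):
                mask |= _bit(n, a, b)
    return mask


def census(graph: nx.DiGraph, n: int) -> dict[int, int]:
    """Counts of connected induced n-node subgraphs by canonical id."""
    if n not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    nodes = list(graph.nodes)
    if len(nodes) < n:
        return {}
    adj = _neighbor_sets(graph, nodes)
    table = _canonical_table(n)
    counts: Counter[int] = Counter()
    for subset in _esu_subsets(adj, n):
        counts[int(table[_subset_mask(graph, nodes, subset, n)])] += 1
    return dict(counts)


def census_instances(graph: nx.DiGraph, n: int) -> dict[int, list[tuple]]:
    """Like :func:`census` but retaining the node tuple of every instance."""
    nodes = list(graph.nodes)
    if len(nodes) < n:
        return {}
    adj = _neighbor_sets(graph, nodes)
    table = _canonical_table(n)
    out: dict[int, list[tuple]] = {}
    for subset in _esu_subsets(adj, n):
        cid = int(table[_subset_mask(graph, nodes, subset, n)])
        out.setdefault(cid, []).append(tuple(nodes[i] for i in subset))
    return out


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

def randomize_network(
    graph: nx.DiGraph, seed: int | None = None, n_switches: int | None = None
) -> nx.DiGraph:
    """Degree-preserving randomization conserving reciprocal-dyad count.

    Single (non-reciprocal) edges are rewired pairwise (a->b, c->d becomes
    a->d, c->b) rejecting any switch that would create a self-loop, a
    multi-edge or a new reciprocal pair; reciprocal dyads are rewired as
    units.  Every node keeps its exact in- and out-degree.  Defaults to
    100 * |E| attempted switches; graphs with no legal switch come back
    unchanged.
    """
    if graph.number_of_edges() < 2:
        return graph.copy()
    rng = np.random.default_rng(seed)
    edges = set(graph.edges())
    mutual = {tuple(sorted((u, v), key=repr)) for u, v in edges if (v, u) in edges}
    singles = [e for e in edges if (e[1], e[0]) not in edges]
    dyads = sorted(mutual, key=repr)
    if n_switches is None:
        n_switches = 100 * len(edges)
    for _ in range(n_switches):
        n_s, n_d = len(singles), len(dyads)
        pool = n_s * (n_s > 1) + n_d * (n_d > 1)
        if pool == 0:
            break
        pick_single = rng.integers(pool) < n_s * (n_s > 1)
        if pick_single:
            i1, i2 = rng.choice(n_s, size=2, replace=False)
            a, b = singles[i1]
            c, d = singles[i2]
            if a == d or c == b or a == c or b == d:
                continue
            e1, e2 = (a, d), (c, b)
            if e1 in edges or e2 in edges:
                continue
            if (d, a) in edges or (b, c) in edges:  # would create a mutual pair
                continue
            edges.discard((a, b))
            edges.discard((c, d))
            edges.add(e1)
            edges.add(e2)
            singles[i1], singles[i2] = e1, e2
        else:
            i1, i2 = rng.choice(n_d, size=2, replace=False)
            a, b = dyads[i1]
            c, d = dyads[i2]
            if len({a, b, c, d}) < 4:
                continue
            newpairs = ((a, d), (c, b))
            conflict = False
            for u, v in newpairs:
                if (u, v) in edges or (v, u) in edges:
                    conflict = True
            if conflict:
                continue
            for u, v in ((a, b), (c, d)):
                edges.discard((u, v))
                edges.discard((v, u))
            for u, v in newpairs:
                edges.add((u, v))
                edges.add((v, u))
            dyads[i1] = tuple(sorted((a, d), key=repr))
            dyads[i2] = tuple(sorted((c, b), key=repr))
    out = nx.DiGraph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(edges)
    return out


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifRecord:
    n: int
    canonical_id: int
    count_real: int
    null_mean: float
    null_sd: float
    z: float
    significant: bool


def motif_significance(
    graph: nx.DiGraph,
    n: int,
    n_random: int = 100,
    seed: int | None = None,
    z_threshold: float = 2.0,
    min_count: int = 4,
) -> list[MotifRecord]:
    """Motif z-scores against the degree/mutual-preserving null ensemble.

    z = (count_real - null_mean) / null_sd per canonical id; a motif is
    significant iff z >= ``z_threshold`` and count_real >= ``min_count``.
    A degenerate null (sd = 0) yields z = 0 when the real count equals the
    null mean and an infinite, non-significant z otherwise.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    real = census(graph, n)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_random)
    null_counts: dict[int, list[int]] = {}
    ids = set(real)
    samples = []
    for s in seeds:
        null = census(randomize_network(graph, seed=s), n)
        samples.append(null)
        ids |= set(null)
    records = []
    for cid in sorted(ids):
        counts = np.array([s.get(cid, 0) for s in samples], dtype=float)
        mean, sd = float(counts.mean()), float(counts.std(ddof=1))
        c = real.get(cid, 0)
        if sd > 0:
            z = (c - mean) / sd
            sig = z >= z_threshold and c >= min_count
        elif c == mean:
            z, sig = 0.0, False
        else:
            z, sig = float(np.inf) if c > mean else float(-np.inf), False
        records.append(MotifRecord(n, cid, c, mean, sd, z, sig))
    return records


def representative_motifs(
    records_by_level: Mapping[object, Iterable[MotifRecord]],
    min_levels: int = 3,
) -> set[int]:
    """Motif ids significant at >= ``min_levels`` of the strength levels."""
    if len(records_by_level) < min_levels:
        raise ValueError("need records for at least min_levels strength levels")
    tally: Counter[int] = Counter()
    for recs in records_by_level.values():
        for r in recs:
            if r.significant:
                tally[r.canonical_id] += 1
    return {cid for cid, k in tally.items() if k >= min_levels}


# ---------------------------------------------------------------------------
# Containment
# ---------------------------------------------------------------------------

def submotif_census(canonical_id4: int) -> dict[int, int]:
    """Connected induced 3-node types embedded in a 4-node canonical type."""
    edges = motif_id_decode(4, canonical_id4)
    g = nx.DiGraph()
    g.add_nodes_from(range(1, 5))
    g.add_edges_from(edges)
    return census(g, 3)


def correlated_feedback_fraction(
    graph: nx.DiGraph,
    canonical_id4: int,
    correlated_taxa: set,
    require_all: bool = True,
) -> float | None:
    """Share of a 4-node motif's instances carrying a correlated feedback loop.

    Percentage of the instances of ``canonical_id4`` in ``graph`` that
    contain at least one induced 3-node subgraph of canonical type 98 (the
    feedback loop) whose nodes are all (or, with ``require_all=False``, at
    least one) in ``correlated_taxa``.  Returns None if the motif type does
    not occur.
    """
    inst = census_instances(graph, 4).get(canonical_id4)
    if not inst:
        return None
    table = _canonical_table(3)
    nodes = list(graph.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    hits = 0
    for quad in inst:
        found = False
        for triple in combinations(quad, 3):
            mask = _subset_mask(graph, nodes, [index[u] for u in triple], 3)
            if int(table[mask]) != 98:
                continue
            inside = sum(u in correlated_taxa for u in triple)
            if (require_all and inside == 3) or (not require_all and inside >= 1):
                found = True
                break
        hits += found
    return 100.0 * hits / len(inst)
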