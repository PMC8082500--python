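"""Three-node (triad) motif analysis for directed regulatory networks.

A triad is a weakly connected 3-node directed subgraph; up to isomorphism
there are exactly 13 such classes.  Classes are indexed 1..13 in the standard
triad-significance-profile order, which places the feed-forward loop (FFL) at
7, the Regulated mutual triad at 9, the Regulating mutual triad at 10 and the
Clique (all three pairs mutual) at 13:

====  =================  =========================================
 id   name               canonical arcs on nodes (A, B, C)
====  =================  =========================================
 1    V-out              A->B, A->C
 2    3-Chain            A->B, B->C
 3    V-in               A->C, B->C
 4    Mutual-in          B<->C, A->C
 5    Mutual-out         B<->C, C->A
 6    Double mutual      A<->C, B<->C
 7    FFL                A->B, A->C, B->C
 8    3-Loop             A->B, B->C, C->A
 9    Regulated mutual   A->B, A->C, B<->C
 10   Regulating mutual  A<->B, A->C, B->C
 11   Mutual chain       A<->B, B->C, C->A
 12   Semi clique        A<->B, A<->C, B->C
 13   Clique             A<->B, A<->C, B<->C
====  =================  =========================================

Motif statistics compare the observed per-class census against an ensemble of
degree-preserving randomized networks (single arcs switched among single
arcs, mutual dyads among mutual dyads), yielding per-class Z scores, the
significance profile SP = Z / ||Z||_2 and empirical p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TRIAD_CLASSES",
    "classify_triad",
    "count_classes",
    "directify",
    "triad_census",
    "find_motif_instances",
    "randomize",
    "null_ensemble",
    "significance",
    "TriadSignificance",
]

# ordered encoding of the 6 possible arcs among 3 local node slots
_PAIRS = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))
_PAIR_BIT = {p: 1 << i for i, p in enumerate(_PAIRS)}

TRIAD_CLASSES: dict[int, dict] = {
    1: {"name": "V-out", "arcs": ((0, 1), (0, 2))},
    2: {"name": "3-Chain", "arcs": ((0, 1), (1, 2))},
    3: {"name": "V-in", "arcs": ((0, 2), (1, 2))},
    4: {"name": "Mutual-in", "arcs": ((1, 2), (2, 1), (0, 2))},
    5: {"name": "Mutual-out", "arcs": ((1, 2), (2, 1), (2, 0))},
    6: {"name": "Double mutual", "arcs": ((0, 2), (2, 0), (1, 2), (2, 1))},
    7: {"name": "FFL", "arcs": ((0, 1), (0, 2), (1, 2))},
    8: {"name": "3-Loop", "arcs": ((0, 1), (1, 2), (2, 0))},
    9: {"name": "Regulated mutual", "arcs": ((0, 1), (0, 2), (1, 2), (2, 1))},
    10: {"name": "Regulating mutual", "arcs": ((0, 1), (1, 0), (0, 2), (1, 2))},
    11: {"name": "Mutual chain", "arcs": ((0, 1), (1, 0), (1, 2), (2, 0))},
    12: {"name": "Semi clique", "arcs": ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2))},
    13: {"name": "Clique", "arcs": tuple(_PAIRS)},
}

ROLES = ("A", "B", "C")


def _mask(arcs) -> int:
    m = 0
    for p in arcs:
        m |= _PAIR_BIT[p]
    return m


def _arcs_of_mask(m: int):
    return tuple(p for p in _PAIRS if m & _PAIR_BIT[p])


def _is_connected_mask(m: int) -> bool:
    arcs = _arcs_of_mask(m)
    if not arcs:
        return False
    touched = set()
    for a, b in arcs:
        touched.add(a)
        touched.add(b)
    if touched != {0, 1, 2}:
        return False
    # 3 nodes all touched by arcs => weakly connected unless one node only in
    # its own component; with 3 nodes, "all touched" plus any arc structure
    # can still be disconnected only if arcs split 1|2 - impossible when the
    # lone node is touched.  Verify via union-find for safety.
    parent = list(range(3))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in arcs:
        parent[find(a)] = find(b)
    return len({find(i) for i in range(3)}) == 1


def _permuted_mask(m: int, perm) -> int:
    # perm maps canonical slot -> new slot
    return _mask(tuple((perm[a], perm[b]) for a, b in _arcs_of_mask(m)))


def _build_tables():
    """Expand the 13 canonical representatives over all node permutations.

    Returns (mask -> class id, mask -> role permutation) where the role
    permutation maps local slot index -> role index (0=A, 1=B, 2=C), chosen
    deterministically (lexicographically minimal) among the automorphisms.
    """
    cls_of: dict[int, int] = {}
    role_of: dict[int, tuple] = {}
    for cid, info in TRIAD_CLASSES.items():
        rep = _mask(info["arcs"])
        for perm in itertools.permutations(range(3)):
            m = _permuted_mask(rep, perm)
            prev = cls_of.get(m)
            if prev is not None and prev != cid:
                raise AssertionError(
                    f"triad classes {prev} and {cid} share a labeled digraph"
                )
            cls_of[m] = cid
            inv = tuple(perm.index(i) for i in range(3))  # local slot -> role
            if m not in role_of or inv < role_of[m]:
                role_of[m] = inv
    connected = [m for m in range(64) if _is_connected_mask(m)]
    uncovered = [m for m in connected if m not in cls_of]
    if uncovered:
        raise AssertionError(f"connected triads not covered by class table: {uncovered}")
    extra = [m for m in cls_of if not _is_connected_mask(m)]
    if extra:
        raise AssertionError("class table contains disconnected digraphs")
    return cls_of, role_of


_CLASS_OF_MASK, _ROLE_OF_MASK = _build_tables()


def count_classes(connected: str = "weak") -> int:
    """Count isomorphism classes of labeled 3-node digraphs by enumeration.

    ``connected='weak'`` counts weakly connected classes (the 13 triad
    classes); ``'all'`` counts every class including empty/disconnected;
    ``'directed'`` counts connected classes without any mutual dyad.
    Independent of the canonical class table (pure brute force).
    """
    seen: set[int] = set()
    reps = []
    for m in range(64):
        if m in seen:
            continue
        orbit = {_permuted_mask(m, p) for p in itertools.permutations(range(3))}
        seen |= orbit
        reps.append(m)
    if connected == "all":
        return len(reps)
    if connected == "weak":
        return sum(_is_connected_mask(m) for m in reps)
    if connected == "directed":

        def has_mutual(m):
            return any(
                (m & _PAIR_BIT[(a, b)]) and (m & _PAIR_BIT[(b, a)])
                for a, b in ((0, 1), (0, 2), (1, 2))
            )

        return sum(_is_connected_mask(m) and not has_mutual(m) for m in reps)
    raise ValueError(f"unknown mode {connected!r}")


def classify_triad(arcs) -> int | str:
    """Classify the arc set of a 3-node digraph into a triad class id.

    ``arcs`` is an iterable of ordered pairs over exactly 3 distinct node
    labels.  Returns the class id (1..13), or ``"empty"`` / ``"disconnected"``
    for non-triads.  Self-arcs are rejected.
    """
    arcs = list(arcs)
    nodes = set()
    for a, b in arcs:
        if a == b:
            raise ValueError(f"self-arc on node {a!r}")
        nodes.add(a)
        nodes.add(b)
    if len(nodes) > 3:
        raise ValueError("more than 3 nodes in triad")
    if not arcs:
        return "empty"
    order = {n: i for i, n in enumerate(sorted(nodes, key=str))}
    m = _mask(tuple((order[a], order[b]) for a, b in set(arcs)))
    if not _is_connected_mask(m):
        return "disconnected"
    return _CLASS_OF_MASK[m]


def directify(net, collapse: bool = True) -> nx.DiGraph:
    """Convert a mixed network into a plain directed graph for the census.

    Regulation arcs are kept as-is; each undirected co-expression edge
    becomes a mutual arc pair.  With ``collapse=True`` (default) an arc plus
    a co-expression edge on the same pair yields a mutual pair; with
    ``collapse=False`` co-expression edges touching an existing arc are
    dropped, keeping the directed arc only.  Accepts a
    :class:`~triadnet.grn_assembly.MixedNetwork` or an ``nx.DiGraph``
    (returned unchanged, copied).
    """
    if isinstance(net, nx.DiGraph):
        G = nx.DiGraph()
        G.add_nodes_from(net.nodes(data=True))
        G.add_edges_from((u, v) for u, v in net.edges() if u != v)
        return G
    G = nx.DiGraph()
    for node, attrs in net.nodes.items():
        G.add_node(node, **attrs)
    for (u, v) in net.regulation:
        G.add_edge(u, v)
    for pair in net.coexpression:
        u, v = sorted(pair, key=str)
        if collapse or (not G.has_edge(u, v) and not G.has_edge(v, u)):
            G.add_edge(u, v)
            G.add_edge(v, u)
    return G


def _triple_mask(G: nx.DiGraph, x, y, z) -> int:
    order = sorted((x, y, z), key=str)
    m = 0
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i != j and G.has_edge(a, b):
                m |= _PAIR_BIT[(i, j)]
    return m


def triad_census(G: nx.DiGraph, return_instances: bool = False):
    """Census of all weakly connected triples, per triad class.

    Returns ``counts`` (dict class id -> count) and, when requested, the
    instance lists per class, each instance ordered by canonical role.
    """
    if any(u == v for u, v in G.edges()):
        raise ValueError("self-arcs are not allowed")
    counts = {cid: 0 for cid in TRIAD_CLASSES}
    instances = {cid: [] for cid in TRIAD_CLASSES} if return_instances else None
    # faster membership for the neighbor test in _connected_triples
    nbr_sets = {}
    for u, v, w in _connected_triples_fast(G, nbr_sets):
        m = _triple_mask(G, u, v, w)
        cid = _CLASS_OF_MASK.get(m)
        if cid is None:
            continue  # triple touched by arcs but not mutually connected
        counts[cid] += 1
        if return_instances:
            order = sorted((u, v, w), key=str)
            role = _ROLE_OF_MASK[m]  # local slot -> role index
            by_role = [None, None, None]
            for slot, node in enumerate(order):
                by_role[role[slot]] = node
            instances[cid].append(tuple(by_role))
    if return_instances:
        return counts, instances
    return counts


def _connected_triples_fast(G: nx.DiGraph, nbr_sets: dict):
    for u in G.nodes:
        nbr_sets[u] = (set(G.successors(u)) | set(G.predecessors(u))) - {u}
    rank = {u: i for i, u in enumerate(sorted(G.nodes, key=str))}
    for u in G.nodes:
        nu = sorted(nbr_sets[u], key=str)
        for i in range(len(nu)):
            v = nu[i]
            nv = nbr_sets[v]
            for j in range(i + 1, len(nu)):
                w = nu[j]
                # emit only from the minimal-rank valid center
                ok = True
                if rank[v] < rank[u] and w in nv:
                    ok = False
                elif rank[w] < rank[u] and v in nbr_sets[w]:
                    ok = False
                if ok:
                    yield u, v, w


def triad_census_brute(G: nx.DiGraph) -> dict[int, int]:
    """Exhaustive all-triples census (independent oracle, O(n^3))."""
    counts = {cid: 0 for cid in TRIAD_CLASSES}
    for u, v, w in itertools.combinations(sorted(G.nodes, key=str), 3):
        m = _triple_mask(G, u, v, w)
        cid = _CLASS_OF_MASK.get(m)
        if cid is not None:
            counts[cid] += 1
    return counts


def _class_instances(G: nx.DiGraph, class_id: int):
    """Enumerate one class's triples without a full census.

    Classes containing a single (non-mutual) arc are anchored on the graph's
    single arcs — typically few in co-expression-heavy networks — and
    extended by one neighbor; all-mutual classes (6, 13) are anchored on
    mutual dyads.  Coverage is complete: every instance of a class with a
    single arc contains one, and the third node is adjacent to an endpoint.
    """
    target_has_single = any(
        (b, a) not in TRIAD_CLASSES[class_id]["arcs"]
        for a, b in TRIAD_CLASSES[class_id]["arcs"]
    )
    nbrs = {u: (set(G.successors(u)) | set(G.predecessors(u))) - {u} for u in G.nodes}
    found = {}
    if target_has_single:
        anchors = [(u, v) for u, v in G.edges() if not G.has_edge(v, u)]
        for x, y in anchors:
            for z in (nbrs[x] | nbrs[y]) - {x, y}:
                key = tuple(sorted((x, y, z), key=str))
                if key in found:
                    continue
                m = _triple_mask(G, *key)
                if _CLASS_OF_MASK.get(m) == class_id:
                    found[key] = m
    else:
        mutual = [(u, v) for u, v in G.edges() if G.has_edge(v, u) and str(u) < str(v)]
        madj = {u: set() for u in G.nodes}
        for u, v in mutual:
            madj[u].add(v)
            madj[v].add(u)
        if class_id == 13:
            for u, v in mutual:
                for w in madj[u] & madj[v]:
                    key = tuple(sorted((u, v, w), key=str))
                    if key not in found:
                        m = _triple_mask(G, *key)
                        if _CLASS_OF_MASK.get(m) == class_id:
                            found[key] = m
        else:  # class 6: two mutual dyads sharing a node, no third connection
            for u, v in mutual:
                for w in (madj[u] | madj[v]) - {u, v}:
                    key = tuple(sorted((u, v, w), key=str))
                    if key not in found:
                        m = _triple_mask(G, *key)
                        if _CLASS_OF_MASK.get(m) == class_id:
                            found[key] = m
    out = []
    for key, m in found.items():
        role = _ROLE_OF_MASK[m]
        by_role = [None, None, None]
        for slot, node in enumerate(key):
            by_role[role[slot]] = node
        out.append(tuple(by_role))
    return out


def find_motif_instances(G: nx.DiGraph, class_id: int, require: dict | None = None):
    """List every instance of one triad class, with canonical role labels.

    Each instance is a tuple ``(node_A, node_B, node_C)`` per the class's
    canonical representative.  ``require`` maps a role letter to a node
    attribute name that must be truthy for the node filling that role, e.g.
    ``{"A": "is_tf", "B": "is_tf"}`` for "both regulators are TFs".
    """
    if class_id not in TRIAD_CLASSES:
        raise ValueError(f"unknown triad class {class_id}")
    result = _class_instances(G, class_id)
    if require:
        kept = []
        for inst in result:
            by_role = dict(zip(ROLES, inst))
            if all(G.nodes[by_role[r]].get(attr, False) for r, attr in require.items()):
                kept.append(inst)
        result = kept
    return sorted(result, key=lambda t: tuple(str(x) for x in t))


# ---------------------------------------------------------------------------
# degree-preserving null model


def _split_arcs(G: nx.DiGraph):
    singles, mutuals = [], []
    for u, v in G.edges():
        if G.has_edge(v, u):
            if str(u) < str(v):
                mutuals.append((u, v))
        else:
            singles.append((u, v))
    return singles, mutuals


def randomize(G: nx.DiGraph, switches_per_arc: int = 100, seed=None) -> nx.DiGraph:
    """Degree-preserving arc switching; mutual dyads are switched as units.

    Single (non-reciprocated) arcs are swapped only with single arcs, mutual
    pairs only with mutual pairs; a switch is rejected if it would create a
    self-arc, a duplicate arc, or convert a single arc into a mutual pair (or
    vice versa).  In-, out- and mutual-degree sequences are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    singles, mutuals = _split_arcs(G)
    arcs = set(G.edges())
    ns, nm = len(singles), len(mutuals)
    if ns < 2 and nm < 2:
        warnings.warn("too few switchable arcs; returning an unchanged copy")
        return G.copy()
    n_attempts = switches_per_arc * G.number_of_edges()
    weights = np.array([ns if ns >= 2 else 0, nm if nm >= 2 else 0], dtype=float)
    weights /= weights.sum()
    choices = rng.random(n_attempts) < weights[0]
    idx_s = rng.integers(0, max(ns, 1), size=(n_attempts, 2))
    idx_m = rng.integers(0, max(nm, 1), size=(n_attempts, 2))
    coin = rng.random(n_attempts)
    for a_i, pick_single in enumerate(choices):
        if pick_single:
            i, j = idx_s[a_i]
            if i == j:
                continue
            a, b = singles[i]
            c, d = singles[j]
            if a == d or c == b:
                continue
            n1, n2 = (a, d), (c, b)
            if n1 in arcs or n2 in arcs or n1 == n2:
                continue
            # creating a mutual pair is forbidden
            if (d, a) in arcs or (b, c) in arcs:
                continue
            arcs.discard((a, b))
            arcs.discard((c, d))
            arcs.add(n1)
            arcs.add(n2)
            singles[i], singles[j] = n1, n2
        else:
            i, j = idx_m[a_i]
            if i == j:
                continue
            a, b = mutuals[i]
            c, d = mutuals[j]
            if len({a, b, c, d}) < 4:
                continue
            if coin[a_i] < 0.5:
                p1, p2 = (a, d), (c, b)
            else:
                p1, p2 = (a, c), (d, b)
            bad = False
            for x, y in (p1, p2):
                if (x, y) in arcs or (y, x) in arcs:
                    bad = True
                    break
            if bad:
                continue
            for x, y in (mutuals[i], mutuals[j]):
                arcs.discard((x, y))
                arcs.discard((y, x))
            for x, y in (p1, p2):
                arcs.add((x, y))
                arcs.add((y, x))
            mutuals[i], mutuals[j] = p1, p2
    H = nx.DiGraph()
    H.add_nodes_from(G.nodes(data=True))
    H.add_edges_from(arcs)
    return H


def null_ensemble(
    G: nx.DiGraph, n_random: int = 10_000, switches_per_arc: int = 100, seed=None
) -> np.ndarray:
    """Per-class triad counts over an ensemble of randomized networks.

    Returns an array of shape (n_random, 13), column k-1 holding class k.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros((n_random, len(TRIAD_CLASSES)), dtype=float)
    for r in range(n_random):
        H = randomize(G, switches_per_arc=switches_per_arc, seed=rng.integers(2**31))
        counts = triad_census(H)
        out[r] = [counts[cid] for cid in sorted(TRIAD_CLASSES)]
    return out


@dataclass
class TriadSignificance:
    """Per-class motif significance against a randomized-network ensemble."""

    counts: np.ndarray  # observed, shape (13,)
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    sp: np.ndarray  # significance profile, Z normalized to unit length
    p_over: np.ndarray
    p_under: np.ndarray
    zero_sd: np.ndarray = field(repr=False)  # classes with degenerate null sd
    n_random: int = 0

    def as_table(self):
        import pandas as pd

        cids = sorted(TRIAD_CLASSES)
        return pd.DataFrame(
            {
                "class_id": cids,
                "name": [TRIAD_CLASSES[c]["name"] for c in cids],
                "count": self.counts,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "Z": self.z,
                "SP": self.sp,
                "p_over": self.p_over,
                "p_under": self.p_under,
            }
        )


def significance(real_counts: dict[int, int], ensemble: np.ndarray) -> TriadSignificance:
    """Z scores, unit-length significance profile and empirical p-values.

    ``Z_k = (N_k - mean_k) / sd_k`` with the sample sd over the ensemble;
    classes with zero null sd get Z = 0 and are flagged.  ``SP = Z/||Z||_2``
    (all-zero Z left as zeros).  Empirical ``p_over`` is the fraction of
    ensemble networks with count >= observed (``p_under`` analogous); the
    resolution is 1/n_random.
    """
    cids = sorted(TRIAD_CLASSES)
    obs = np.array([real_counts[c] for c in cids], dtype=float)
    mean = ensemble.mean(axis=0)
    sd = ensemble.std(axis=0, ddof=1) if len(ensemble) > 1 else np.zeros(len(cids))
    zero_sd = sd == 0
    z = np.zeros(len(cids))
    np.divide(obs - mean, sd, out=z, where=~zero_sd)
    norm = np.linalg.norm(z)
    sp = z / norm if norm > 0 else np.zeros_like(z)
    n = len(ensemble)
    p_over = (ensemble >= obs).mean(axis=0)
    p_under = (ensemble <= obs).mean(axis=0)
    return TriadSignificance(
        counts=obs,
        null_mean=mean,
        null_sd=sd,
        z=z,
        sp=sp,
        p_over=p_over,
        p_under=p_under,
        zero_sd=zero_sd,
        n_random=n,
    )
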