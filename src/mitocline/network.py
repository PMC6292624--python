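"""Median-joining haplotype networks with star contraction and MP pruning.

Pipeline (mirroring classical haplotype-network practice for mtDNA):

1. :func:`frequency_filter` — drop rare haplotypes (the "frequency > 1"
   preprocessing: keep haplotypes observed more than once).
2. :func:`star_contraction` — collapse star-like clusters of satellite
   haplotypes onto their center within a Hamming radius, summing
   multiplicities (radius 5 for large clades, 1 for small ones in the
   published analysis).
3. :func:`build_mj` — Bandelt-style median joining over binary haplotype
   vectors: iterate between (a) the epsilon-relaxed minimum spanning network
   (all links whose length is at most the bottleneck connection threshold
   plus epsilon) and (b) insertion of quasi-median (majority-per-position)
   vectors for connected triplets, until closure; degree-<=2 median nodes
   whose removal does not lengthen the minimal connection are discarded.
4. :func:`mp_postprocess` — maximum-parsimony pruning: delete every median
   node and edge that participates in no minimum-total-length spanning
   subgraph connecting all observed haplotypes (exhaustive Steiner-subset
   search up to 12 nodes, greedy pruning above, recorded in the output).

All positions carry weight 1, so epsilon is in mutation-count units.
Processing order is deterministic (lexicographic on vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

__all__ = [
    "HaplotypeSet",
    "MJGraph",
    "frequency_filter",
    "star_contraction",
    "build_mj",
    "mp_postprocess",
]

MP_EXHAUSTIVE_LIMIT = 12  # max network nodes for exhaustive MP search
MAX_NETWORK_NODES = 5000  # median-closure safety cap


@dataclass
class HaplotypeSet:
    """Distinct fixed-length binary haplotypes with multiplicities."""

    vectors: np.ndarray  # (n_hap, L) uint8 in {0, 1}
    counts: np.ndarray  # (n_hap,) positive ints
    labels: list[str] | None = None

    def __post_init__(self):
        try:
            self.vectors = np.asarray(self.vectors, dtype=np.uint8)
        except (TypeError, ValueError) as err:
            raise ValueError("haplotype vectors must form a rectangular array") from err
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array")
        if not np.isin(self.vectors, [0, 1]).all():
            raise ValueError("haplotype vectors must be binary")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 1).any():
            raise ValueError("multiplicities must be >= 1")
        if len(self.counts) != len(self.vectors):
            raise ValueError("counts and vectors length mismatch")
        keys = [v.tobytes() for v in self.vectors]
        if len(set(keys)) != len(keys):
            raise ValueError("haplotypes must be distinct")

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def length(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def from_matrix(cls, calls: np.ndarray, labels: list[str] | None = None) -> "HaplotypeSet":
        """Collapse a samples x loci 0/1 matrix into distinct haplotypes.

        MISSING (-1) calls are not representable in a binary haplotype; rows
        containing them raise a ValueError (impute or drop first).
        """
        calls = np.asarray(calls)
        if (calls == -1).any():
            raise ValueError("matrix contains MISSING calls; impute or drop first")
        uniq, inverse, counts = np.unique(
            calls.astype(np.uint8), axis=0, return_inverse=True, return_counts=True
        )
        lab = None
        if labels is not None:
            lab = []
            for i in range(len(uniq)):
                members = [labels[j] for j in np.flatnonzero(inverse == i)]
                lab.append(members[0])
        return cls(uniq, counts, lab)

    def sorted_lex(self) -> "HaplotypeSet":
        order = np.lexsort(self.vectors.T[::-1])
        return HaplotypeSet(
            self.vectors[order],
            self.counts[order],
            [self.labels[i] for i in order] if self.labels else None,
        )


@dataclass
class MJGraph:
    """Haplotype network: observed + inferred (median) haplotypes.

    Wraps a networkx Graph whose nodes are vector byte-keys with attributes
    ``vector`` (tuple), ``count`` (0 for medians), ``median`` (bool); edges
    carry ``positions`` (tuple of differing 0-based column indices) and
    ``weight`` (their number). ``params`` records the parameters used.
    """

    graph: nx.Graph
    params: dict = field(default_factory=dict)

    @property
    def n_observed(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if not d["median"])

    @property
    def median_nodes(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["median"])

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            vu = np.array(self.graph.nodes[u]["vector"])
            vv = np.array(self.graph.nodes[v]["vector"])
            diff = tuple(int(i) for i in np.flatnonzero(vu != vv))
            if not diff:
                raise ValueError("edge between identical vectors")
            if tuple(d["positions"]) != diff:
                raise ValueError(f"edge label inconsistent with endpoints: {u}-{v}")
        if self.graph.number_of_nodes() and not nx.is_connected(self.graph):
            raise ValueError("network is not connected")

    @classmethod
    def build(cls, vectors, counts, medians, edges, params=None) -> "MJGraph":
        """Assemble a graph from explicit vectors and edge index pairs."""
        g = nx.Graph()
        vecs = [np.asarray(v, dtype=np.uint8) for v in vectors]
        keys = [v.tobytes() for v in vecs]
        for k, v, c, m in zip(keys, vecs, counts, medians):
            g.add_node(k, vector=tuple(int(x) for x in v), count=int(c), median=bool(m))
        for i, j in edges:
            diff = tuple(int(x) for x in np.flatnonzero(vecs[i] != vecs[j]))
            g.add_edge(keys[i], keys[j], positions=diff, weight=len(diff))
        return cls(g, dict(params or {}))


def frequency_filter(h: HaplotypeSet, min_count: int) -> HaplotypeSet:
    """Drop haplotypes observed fewer than ``min_count`` times."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keep = h.counts >= min_count
    if not keep.any():
        raise ValueError("frequency filter removed every haplotype")
    return HaplotypeSet(
        h.vectors[keep],
        h.counts[keep],
        [h.labels[i] for i in np.flatnonzero(keep)] if h.labels else None,
    )


def _hamming(vectors: np.ndarray) -> np.ndarray:
    return (vectors[:, None, :] != vectors[None, :, :]).sum(axis=2)


def star_contraction(
    h: HaplotypeSet, max_radius: int
) -> tuple[HaplotypeSet, list[dict]]:
    """Collapse star-like clusters onto their centers, to a fixed point.

    A cluster is a center plus >= 2 satellites, each within Hamming distance
    ``max_radius`` of the center and strictly closer to the center than to any
    haplotype outside the cluster. Satellites merge into the center, summing
    multiplicities. Candidate centers are scanned in order of decreasing
    multiplicity (ties: lexicographic vector order) and the scan restarts
    after every contraction, so the result is deterministic.
    """
    if max_radius < 1:
        raise ValueError("max_radius must be >= 1")
    cur = h.sorted_lex()
    log: list[dict] = []
    while True:
        n = len(cur)
        if n < 3:
            break
        d = _hamming(cur.vectors)
        order = sorted(range(n), key=lambda i: (-cur.counts[i], i))
        merged = False
        for c in order:
            within = [
                i for i in range(n) if i != c and 0 < d[i, c] <= max_radius
            ]
            # satellites: closer to the center than to anything outside the
            # tentative cluster {center} + within
            cluster = set(within) | {c}
            sats = []
            for i in within:
                outside = [j for j in range(n) if j not in cluster]
                if all(d[i, c] < d[i, j] for j in outside):
                    sats.append(i)
            if len(sats) >= 2:
                keep = np.array([j for j in range(n) if j not in sats])
                new_counts = cur.counts.copy()
                new_counts[c] += cur.counts[sats].sum()
                log.append(
                    {
                        "center": cur.vectors[c].copy(),
                        "satellites": [cur.vectors[i].copy() for i in sats],
                        "merged_count": int(cur.counts[sats].sum()),
                    }
                )
                cur = HaplotypeSet(
                    cur.vectors[keep],
                    new_counts[keep],
                    [cur.labels[i] for i in keep] if cur.labels else None,
                )
                merged = True
                break
        if not merged:
            break
    return cur, log


def _bottleneck_thresholds(d: np.ndarray) -> np.ndarray:
    """T[u, v]: max edge weight on the minimax path between u and v.

    Computed from a minimum spanning tree of the complete distance graph;
    the minimax (bottleneck) path between two nodes is realized on any MST.
    """
    n = len(d)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    T = np.zeros((n, n), dtype=int)
    for src in range(n):
        # DFS over the MST tracking the running max edge weight
        stack = [(src, -1, 0)]
        while stack:
            node, parent, mx = stack.pop()
            T[src, node] = mx
            for nbr in mst.neighbors(node):
                if nbr != parent:
                    w = mst.edges[node, nbr]["weight"]
                    stack.append((nbr, node, max(mx, w)))
    return T


def _eps_msn_edges(vectors: np.ndarray, epsilon: int) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network."""
    d = _hamming(vectors)
    T = _bottleneck_thresholds(d)
    n = len(vectors)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= T[i, j] + epsilon
    ]


def build_mj(h: HaplotypeSet, epsilon: int = 10) -> MJGraph:
    """Median-joining network of a haplotype set.

    Iterates: form the epsilon-relaxed minimum spanning network over the
    current vector set; for every connected triplet (three nodes whose induced
    subgraph has at least two links), insert the quasi-median — the
    majority-per-position vector — if it is new; repeat until no median is
    added. Median nodes of degree <= 2 that are not needed for a minimal
    connection of the remaining set are then discarded.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(h) == 0:
        raise ValueError("need at least one haplotype")
    h = h.sorted_lex()
    observed = {v.tobytes(): (tuple(int(x) for x in v), int(c)) for v, c in
                zip(h.vectors, h.counts)}
    vec_set: dict[bytes, np.ndarray] = {v.tobytes(): v.copy() for v in h.vectors}

    max_rounds = 4 * (h.length + 1)
    for _ in range(max_rounds):
        keys = sorted(vec_set)
        vectors = np.array([vec_set[k] for k in keys], dtype=np.uint8)
        edges = _eps_msn_edges(vectors, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(keys))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        new: dict[bytes, np.ndarray] = {}
        # connected triplets: u-v and v-w linked (w > u to avoid duplicates)
        for v in range(len(keys)):
            nbrs = sorted(adj[v])
            for a, b in combinations(nbrs, 2):
                m = _majority(vectors[a], vectors[v], vectors[b])
                k = m.tobytes()
                if k not in vec_set and k not in new:
                    new[k] = m
        if not new:
            break
        vec_set.update(new)
        if len(vec_set) > MAX_NETWORK_NODES:
            raise RuntimeError(
                f"median closure exceeded {MAX_NETWORK_NODES} nodes; reduce "
                "epsilon or pre-process with star contraction / frequency filter"
            )

    keys = sorted(vec_set)
    vectors = np.array([vec_set[k] for k in keys], dtype=np.uint8)
    edges = _eps_msn_edges(vectors, epsilon)
    g = nx.Graph()
    for k, v in zip(keys, vectors):
        is_obs = k in observed
        g.add_node(
            k,
            vector=tuple(int(x) for x in v),
            count=observed[k][1] if is_obs else 0,
            median=not is_obs,
        )
    for i, j in edges:
        diff = tuple(int(x) for x in np.flatnonzero(vectors[i] != vectors[j]))
        g.add_edge(keys[i], keys[j], positions=diff, weight=len(diff))

    _prune_obsolete_medians(g, epsilon)
    return MJGraph(g, {"epsilon": int(epsilon)})


def _majority(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return ((a.astype(int) + b + c) >= 2).astype(np.uint8)


def _mst_cost(vectors: list[np.ndarray]) -> int:
    if len(vectors) <= 1:
        return 0
    arr = np.array(vectors, dtype=np.uint8)
    d = _hamming(arr)
    g = nx.Graph()
    g.add_nodes_from(range(len(arr)))
    for i in range(len(arr)):
        for j in range(i + 1, len(arr)):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def _prune_obsolete_medians(g: nx.Graph, epsilon: int) -> None:
    """Drop degree-<=2 median nodes that no minimal connection needs.

    A median node is obsolete when removing it leaves the minimum spanning
    cost of the remaining vector set unchanged. After each removal the
    epsilon-MSN over the remaining set is rebuilt.
    """
    while True:
        med = [n for n, d in g.nodes(data=True) if d["median"] and g.degree(n) <= 2]
        removed = False
        for m in sorted(med):
            rest = [np.array(g.nodes[n]["vector"], dtype=np.uint8)
                    for n in g.nodes if n != m]
            full = rest + [np.array(g.nodes[m]["vector"], dtype=np.uint8)]
            if _mst_cost(rest) <= _mst_cost(full):
                g.remove_node(m)
                removed = True
                break
        if not removed:
            break
        # rebuild MSN edges over the remaining set
        keys = sorted(g.nodes)
        vectors = np.array([g.nodes[k]["vector"] for k in keys], dtype=np.uint8)
        g.remove_edges_from(list(g.edges))
        for i, j in _eps_msn_edges(vectors, epsilon):
            diff = tuple(int(x) for x in np.flatnonzero(vectors[i] != vectors[j]))
            g.add_edge(keys[i], keys[j], positions=diff, weight=len(diff))


def _edge_in_some_mst(h: nx.Graph, u, v) -> bool:
    """Cut criterion: (u, v) is in some MST iff u, v are not connected using
    only strictly lighter edges."""
    w = h.edges[u, v]["weight"]
    light = nx.Graph()
    light.add_nodes_from(h.nodes)
    light.add_edges_from(
        (a, b) for a, b, d in h.edges(data=True) if d["weight"] < w
    )
    return not nx.has_path(light, u, v)


def mp_postprocess(g: MJGraph) -> MJGraph:
    """Maximum-parsimony pruning of a median-joining network.

    Keeps exactly the median nodes and edges that participate in at least one
    minimum-total-length spanning subgraph (Steiner subgraph) connecting all
    observed haplotypes. Exhaustive over median-node subsets when the network
    has at most ``MP_EXHAUSTIVE_LIMIT`` nodes; otherwise a greedy pruning
    heuristic runs and the output's ``params['mp_mode']`` records it.
    """
    graph = g.graph
    if graph.number_of_nodes() == 0 or not nx.is_connected(graph):
        raise ValueError("mp_postprocess requires a connected, non-empty network")
    observed = [n for n, d in graph.nodes(data=True) if not d["median"]]
    medians = sorted(n for n, d in graph.nodes(data=True) if d["median"])
    params = dict(g.params)

    if graph.number_of_nodes() <= MP_EXHAUSTIVE_LIMIT:
        params["mp_mode"] = "exhaustive"
        best_cost = None
        optimal: list[tuple[frozenset, nx.Graph]] = []
        for r in range(len(medians) + 1):
            for subset in combinations(medians, r):
                nodes = observed + list(subset)
                h = graph.subgraph(nodes)
                if len(nodes) == 0 or not nx.is_connected(h):
                    continue
                mst = nx.minimum_spanning_tree(h, weight="weight")
                cost = int(sum(d["weight"] for _, _, d in mst.edges(data=True)))
                if best_cost is None or cost < best_cost:
                    best_cost = cost
                    optimal = [(frozenset(subset), h)]
                elif cost == best_cost:
                    optimal.append((frozenset(subset), h))
        if best_cost is None:
            raise RuntimeError("observed haplotypes are disconnected")  # invariant
        keep_nodes = set(observed)
        keep_edges: set[frozenset] = set()
        for subset, h in optimal:
            keep_nodes |= subset
            for u, v in h.edges:
                if _edge_in_some_mst(h, u, v):
                    keep_edges.add(frozenset((u, v)))
        pruned = graph.subgraph(keep_nodes).copy()
        pruned.remove_edges_from(
            [(u, v) for u, v in pruned.edges if frozenset((u, v)) not in keep_edges]
        )
    else:
        params["mp_mode"] = "heuristic"
        pruned = graph.copy()
        changed = True
        while changed:
            changed = False
            meds = sorted(
                (n for n, d in pruned.nodes(data=True) if d["median"]),
                key=lambda n: pruned.degree(n),
            )
            base = _steiner_cost(pruned, observed)
            for m in meds:
                trial = pruned.copy()
                trial.remove_node(m)
                if not trial.number_of_nodes():
                    continue
                if not all(nx.has_path(trial, observed[0], o) for o in observed[1:]):
                    continue
                if _steiner_cost(trial, observed) <= base:
                    pruned = trial
                    changed = True
                    break

    if not nx.is_connected(pruned):
        raise RuntimeError("MP pruning disconnected the network")  # invariant
    return MJGraph(pruned, params)


def _steiner_cost(h: nx.Graph, observed: list) -> int:
    """MST cost over the whole graph — an upper-bound proxy for the Steiner
    cost used by the greedy heuristic."""
    mst = nx.minimum_spanning_tree(h, weight="weight")
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))
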