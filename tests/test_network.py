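"""Median-joining networks: star contraction, MJ construction, MP pruning."""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest

from mitocline import (
    HaplotypeSet,
    MJGraph,
    build_mj,
    frequency_filter,
    mp_postprocess,
    star_contraction,
)
from mitocline.tree import HaploNode, HaploTree, Variant


def hset(rows, counts=None):
    arr = np.array(rows, dtype=np.uint8)
    return HaplotypeSet(arr, counts if counts is not None else np.ones(len(arr)))


def vectors_of(g: MJGraph):
    return {tuple(d["vector"]) for _, d in g.graph.nodes(data=True)}


def median_vectors_of(g: MJGraph):
    return {
        tuple(d["vector"]) for _, d in g.graph.nodes(data=True) if d["median"]
    }


# -- brute-force oracles ----------------------------------------------------

def quasi_median_closure(vectors):
    s = {tuple(int(x) for x in v) for v in vectors}
    changed = True
    while changed:
        changed = False
        for a, b, c in combinations(sorted(s), 3):
            m = tuple(int(x + y + z >= 2) for x, y, z in zip(a, b, c))
            if m not in s:
                s.add(m)
                changed = True
                break
    return s


def mst_edges_and_cost(vectors):
    arr = np.array(vectors, dtype=int)
    g = nx.Graph()
    for i in range(len(arr)):
        for j in range(i + 1, len(arr)):
            g.add_edge(i, j, weight=int((arr[i] != arr[j]).sum()))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    cost = sum(d["weight"] for _, _, d in mst.edges(data=True))
    return set(frozenset(e) for e in mst.edges), cost


# -- frequency filter --------------------------------------------------------

def test_frequency_filter_drops_singletons():
    h = hset([[0, 0], [1, 1]], [5, 1])
    out = frequency_filter(h, 2)
    assert len(out) == 1 and out.counts[0] == 5


def test_frequency_filter_min_count_one_is_identity():
    h = hset([[0, 0], [1, 1]], [5, 1])
    out = frequency_filter(h, 1)
    assert len(out) == 2


def test_frequency_filter_rejects_empty_result():
    with pytest.raises(ValueError):
        frequency_filter(hset([[0, 1], [1, 0]], [1, 1]), 2)


# -- star contraction --------------------------------------------------------

def test_star_with_three_satellites_contracts_to_center():
    center = [0, 0, 0, 0]
    sats = [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]]
    h = hset([center] + sats, [10, 1, 1, 1])
    out, log = star_contraction(h, 1)
    assert len(out) == 1
    assert out.counts[0] == 13
    assert len(log) == 1 and log[0]["merged_count"] == 3


def test_nothing_within_radius_is_unchanged():
    h = hset([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]], [4, 4])
    out, log = star_contraction(h, 1)
    assert len(out) == 2 and not log


def test_single_haplotype_is_unchanged():
    h = hset([[0, 1]], [7])
    out, log = star_contraction(h, 3)
    assert len(out) == 1 and out.counts[0] == 7 and not log


def test_satellite_closer_to_outsider_is_not_contracted():
    """A putative satellite equidistant from the center and a non-cluster
    haplotype must stay (satellites must be strictly closer to the center)."""
    center = [0, 0, 0, 0, 0, 0]
    s1 = [1, 0, 0, 0, 0, 0]
    s2 = [0, 1, 0, 0, 0, 0]
    tug = [1, 0, 1, 0, 0, 0]  # distance 1 from s1, 2 from center
    h = hset([center, s1, s2, tug], [10, 1, 1, 5])
    out, _ = star_contraction(h, 1)
    remaining = {tuple(v) for v in out.vectors}
    assert tuple(s1) in remaining  # d(s1, tug)=1 == d(s1, center): not strictly closer
    assert tuple(tug) in remaining


# -- median joining ----------------------------------------------------------

def test_two_haplotypes_single_edge_labeled_with_both_positions():
    g = build_mj(hset([[0, 0, 0], [1, 1, 0]]), epsilon=0)
    assert g.graph.number_of_nodes() == 2
    ((_, _, d),) = g.graph.edges(data=True)
    assert d["positions"] == (0, 1)
    g.validate()


def test_triplet_gains_unique_optimal_steiner_median():
    """For 110/101/011 every candidate Steiner vector is enumerated: 111
    uniquely minimizes the total connection length, and MJ adds exactly it."""
    obs = [(1, 1, 0), (1, 0, 1), (0, 1, 1)]
    costs = {}
    for cand in product([0, 1], repeat=3):
        if cand in {tuple(o) for o in obs}:
            continue
        _, cost = mst_edges_and_cost([list(o) for o in obs] + [list(cand)])
        costs[cand] = cost
    best = min(costs.values())
    best_cands = [c for c, v in costs.items() if v == best]
    assert best_cands == [(1, 1, 1)] and best == 3

    g = build_mj(hset([list(o) for o in obs]), epsilon=0)
    assert median_vectors_of(g) == {(1, 1, 1)}
    assert g.graph.number_of_edges() == 3
    g.validate()
    # MP keeps the median: it sits on the unique minimal connection
    g2 = mp_postprocess(g)
    assert median_vectors_of(g2) == {(1, 1, 1)}


def test_single_haplotype_network():
    g = build_mj(hset([[0, 1, 0]]), epsilon=0)
    assert g.graph.number_of_nodes() == 1
    assert g.graph.number_of_edges() == 0


def _random_ancestry_closed_set(rng, n_nodes=8, n_positions=24):
    """Haplotypes = all root-to-node path vectors of a random character tree
    (a perfect phylogeny including ancestral states)."""
    positions = list(rng.permutation(n_positions))
    nodes = [HaploNode("root", None, "root", ())]
    depth = {"root": 0}
    for i in range(n_nodes):
        parent = str(rng.choice([n.name for n in nodes if depth[n.name] < 3]))
        k = int(rng.integers(1, 4))
        variants = tuple(
            Variant(int(positions.pop()) + 1, "T") for _ in range(k)
        )
        name = f"n{i}"
        nodes.append(HaploNode(name, parent, ("macro", "hg", "subhg")[depth[parent]], variants))
        depth[name] = depth[parent] + 1
    tree = HaploTree(nodes)
    vecs = []
    for name in tree.nodes:
        v = np.zeros(n_positions, dtype=np.uint8)
        for var in tree.path_variants(name):
            v[var.position - 1] = 1
        vecs.append(v)
    arr = np.unique(np.array(vecs), axis=0)
    return HaplotypeSet(arr, np.ones(len(arr), dtype=int))


@pytest.mark.parametrize("seed", range(8))
def test_perfect_phylogeny_equals_brute_force_mst(seed):
    """On ancestry-closed perfect-phylogeny inputs with epsilon 0, the MJ
    network is exactly the (unique) minimum spanning tree: no medians."""
    rng = np.random.default_rng(seed)
    h = _random_ancestry_closed_set(rng)
    g = build_mj(h, epsilon=0)
    assert not median_vectors_of(g)
    key_of = {tuple(d["vector"]): n for n, d in g.graph.nodes(data=True)}
    idx = {tuple(v): i for i, v in enumerate(h.vectors)}
    got = {
        frozenset((idx[tuple(g.graph.nodes[u]["vector"])],
                   idx[tuple(g.graph.nodes[v]["vector"])]))
        for u, v in g.graph.edges
    }
    want, _ = mst_edges_and_cost(h.vectors)
    assert got == want
    g.validate()


@pytest.mark.parametrize("seed", range(10))
def test_median_nodes_lie_in_quasi_median_closure(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(3, 6))
    L = int(rng.integers(4, 9))
    rows = np.unique(rng.integers(0, 2, size=(n, L)).astype(np.uint8), axis=0)
    h = HaplotypeSet(rows, np.ones(len(rows), dtype=int))
    eps = int(rng.choice([0, 1]))
    g = build_mj(h, epsilon=eps)
    closure = quasi_median_closure(rows)
    for vec in median_vectors_of(g):
        assert vec in closure
    # every observed haplotype survives and the network is connected
    assert {tuple(r) for r in rows} <= vectors_of(g)
    assert nx.is_connected(g.graph)
    g.validate()


@pytest.mark.parametrize("seed", range(5))
def test_build_mj_is_idempotent_on_its_own_node_set(seed):
    rng = np.random.default_rng(200 + seed)
    rows = np.unique(rng.integers(0, 2, size=(5, 8)).astype(np.uint8), axis=0)
    g1 = build_mj(HaplotypeSet(rows, np.ones(len(rows), dtype=int)), epsilon=0)
    all_vecs = sorted(vectors_of(g1))
    h2 = HaplotypeSet(np.array(all_vecs, dtype=np.uint8),
                      np.ones(len(all_vecs), dtype=int))
    g2 = build_mj(h2, epsilon=0)
    assert not median_vectors_of(g2)
    assert vectors_of(g2) == set(all_vecs)


# -- MP post-processing ------------------------------------------------------

def square_with_diagonal(median_weight_one=True):
    a, b, c, d = (0, 0, 0, 0), (1, 0, 1, 0), (1, 1, 0, 0), (0, 1, 1, 0)
    if median_weight_one:
        m = (0, 1, 0, 0)  # distance 1 from a and from c
    else:
        m = (0, 1, 0, 1)  # distance 2 from a and from c
    vectors = [a, b, c, d, m]
    edges = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (4, 2)]
    return MJGraph.build(
        vectors, [1, 1, 1, 1, 0], [False, False, False, False, True], edges
    )


def test_tree_graph_is_unchanged_by_mp():
    g = build_mj(hset([[0, 0], [1, 0], [1, 1]]), epsilon=0)
    pruned = mp_postprocess(g)
    assert vectors_of(pruned) == vectors_of(g)
    assert set(pruned.graph.edges) == set(g.graph.edges)
    assert pruned.params["mp_mode"] == "exhaustive"


def test_equal_length_median_shortcut_is_retained():
    g = square_with_diagonal(median_weight_one=True)
    pruned = mp_postprocess(g)
    assert (0, 1, 0, 0) in median_vectors_of(pruned)


def test_longer_median_shortcut_is_deleted():
    g = square_with_diagonal(median_weight_one=False)
    pruned = mp_postprocess(g)
    assert not median_vectors_of(pruned)
    assert pruned.n_observed == 4
    assert nx.is_connected(pruned.graph)


def test_mp_switches_to_heuristic_above_node_limit():
    rng = np.random.default_rng(5)
    h = _random_ancestry_closed_set(rng, n_nodes=15, n_positions=40)
    g = build_mj(h, epsilon=0)
    assert g.graph.number_of_nodes() > 12
    pruned = mp_postprocess(g)
    assert pruned.params["mp_mode"] == "heuristic"
    assert {tuple(r) for r in h.vectors} <= vectors_of(pruned)
    assert nx.is_connected(pruned.graph)


def test_mismatched_vector_lengths_rejected():
    with pytest.raises(ValueError):
        HaplotypeSet(np.array([[0, 1], [1, 0, 1]], dtype=object), [1, 1])
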