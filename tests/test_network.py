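"""Network construction, topology, power-law fit, hubs and modules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from padnet.epistasis import GenePairCandidate
from padnet.network import (
    build_network,
    component_census,
    decompose_modules,
    fit_power_law,
    hub_test,
    largest_component,
    modularity_q,
    poisson_tail,
    topology_stats,
)


def cand(a, b, n=1, p=0.01):
    return GenePairCandidate(a, b, n, p)


def ppi_frame(pairs):
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


# ------------------------------------------------------------------- build


def test_empty_ppi_gives_no_edges():
    g = build_network([cand("A", "B")], ppi_frame([]))
    assert g.number_of_edges() == 0
    assert set(g.nodes) == {"A", "B"}


def test_intersection_keeps_supported_edge_only():
    g = build_network([cand("A", "B"), cand("B", "C")], ppi_frame([("A", "B")]))
    assert set(g.edges) == {("A", "B")}
    assert "C" in g.nodes  # isolated candidate gene kept


def test_edge_set_equals_bruteforce_intersection(rng):
    genes = [f"G{i}" for i in range(20)]
    all_pairs = list(itertools.combinations(genes, 2))
    cand_idx = rng.choice(len(all_pairs), size=50, replace=False)
    ppi_idx = rng.choice(len(all_pairs), size=50, replace=False)
    candidates = [cand(*all_pairs[i]) for i in cand_idx]
    # PPI may arrive in reversed order; intersection must be orientation-free
    ppi_pairs = [
        tuple(reversed(all_pairs[i])) if k % 2 else all_pairs[i]
        for k, i in enumerate(ppi_idx)
    ]
    g = build_network(candidates, ppi_frame(ppi_pairs))
    canon = lambda pairs: {tuple(sorted(p)) for p in pairs}
    expected = canon(all_pairs[i] for i in cand_idx) & canon(
        all_pairs[i] for i in ppi_idx
    )
    assert {tuple(sorted(e)) for e in g.edges} == expected
    # invariant: edges subset of both inputs
    assert {tuple(sorted(e)) for e in g.edges} <= canon(all_pairs[i] for i in cand_idx)


# -------------------------------------------------------------- components


def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: (-len(c), c[0]))


def test_component_sizes_match_union_find(rng):
    g = nx.gnm_random_graph(200, 150, seed=4)
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    oracle = union_find_components(list(g.nodes), list(g.edges))
    giant = largest_component(g)
    assert sorted(giant.nodes) == oracle[0]
    assert sorted(len(c) for c in nx.connected_components(g)) == sorted(
        len(c) for c in oracle
    )


def test_largest_component_trivial_cases():
    g = nx.path_graph(4)
    assert set(largest_component(g).nodes) == set(g.nodes)
    h = nx.Graph()
    h.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
    h.add_edges_from([("x", "y"), ("y", "z")])
    assert set(largest_component(h).nodes) == {"a", "b", "c", "d", "e"}
    assert largest_component(nx.Graph()).number_of_nodes() == 0


# ---------------------------------------------------------------- topology


def test_path_graph_stats():
    g = nx.Graph([("A", "B"), ("B", "C")])
    node_df, graph_stats = topology_stats(g)
    row = node_df.set_index("gene")
    assert row.loc["B", "betweenness"] == 1.0
    assert row.loc["B", "degree"] == 2
    assert graph_stats["diameter"] == 2


def test_triangle_stats():
    g = nx.complete_graph(3)
    node_df, graph_stats = topology_stats(g)
    assert (node_df["clustering"] == 1.0).all()
    assert graph_stats["diameter"] == 1


def test_topology_matches_bfs_oracle(rng):
    """30-node random graph: betweenness/diameter equal all-pairs BFS oracle."""
    g = nx.gnp_random_graph(30, 0.12, seed=9)
    giant = largest_component(g)
    node_df, graph_stats = topology_stats(giant)
    # oracle diameter by BFS from every node
    ecc = []
    for s in giant.nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in giant.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        ecc.append(max(dist.values()))
    assert graph_stats["diameter"] == max(ecc)
    # oracle degrees
    for _, row in node_df.iterrows():
        assert row["degree"] == giant.degree[row["gene"]]


# --------------------------------------------------------------- power law


def test_power_law_bootstrap_deterministic():
    rng = np.random.default_rng(3)
    sample = rng.zipf(3.0, 300)
    f1 = fit_power_law(sample, n_boot=200, seed=11)
    f2 = fit_power_law(sample, n_boot=200, seed=11)
    assert f1.p_value == f2.p_value and f1.alpha == f2.alpha


def test_power_law_alpha_recovery():
    rng = np.random.default_rng(8)
    sample = rng.zipf(3.0, 500)
    fit = fit_power_law(sample, xmin=1, n_boot=300, seed=5)
    assert 2.7 <= fit.alpha <= 3.3
    assert fit.p_value > 0.1
    assert 0 <= fit.ks_D <= 1


def test_power_law_rejects_poisson_degrees():
    rng = np.random.default_rng(9)
    sample = rng.poisson(8, 500)
    fit = fit_power_law(sample, xmin=1, n_boot=300, seed=6)
    assert fit.p_value < 0.1


def test_power_law_xmin_selection_minimizes_ks():
    """Clauset-style xmin scan picks the candidate with the smallest KS D."""
    rng = np.random.default_rng(12)
    # power-law tail contaminated below k=3
    sample = np.concatenate([rng.zipf(3.0, 400) + 2, rng.integers(1, 3, 200)])
    fit = fit_power_law(sample, select_xmin=True, n_boot=50, seed=1)
    from padnet.network import _ks_D, _plfit_alpha

    for cand in np.unique(sample[sample >= 1]):
        tail = sample[sample >= cand]
        if tail.size < 10 or np.ptp(tail) == 0:
            continue
        d = _ks_D(tail, _plfit_alpha(tail, int(cand)), int(cand))
        assert fit.ks_D <= d + 1e-12


def test_power_law_degenerate_inputs():
    with pytest.raises(ValueError):
        fit_power_law(np.full(50, 3))  # all equal: MLE undefined
    with pytest.raises(ValueError):
        fit_power_law(np.array([1, 2, 3]))  # too few


# -------------------------------------------------------------------- hubs


def test_poisson_tail_matches_scipy_oracle():
    for lam in (0.3, 1.0, 2.84, 8.0):
        for d in range(0, 40):
            assert poisson_tail(d, lam) == pytest.approx(
                float(poisson.sf(d - 1, lam)), abs=1e-12
            )


def test_poisson_tail_monotone_in_degree():
    ps = [poisson_tail(d, 2.84) for d in range(0, 25)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert ps[0] == 1.0  # P(X >= 0) = 1


def test_hub_test_star_graph():
    g = nx.star_graph(11)  # hub degree 11, leaves degree 1
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    hubs = hub_test(g)
    assert hubs[0].degree == 11
    lam = 2 * g.number_of_edges() / g.number_of_nodes()
    assert hubs[0].lam == pytest.approx(lam)
    assert hubs[0].p_adjusted == pytest.approx(
        min(1.0, poisson_tail(11, lam) * g.number_of_nodes())
    )
    assert hubs[0].is_hub
    assert all(h.p_adjusted <= 1.0 for h in hubs)


# ----------------------------------------------------------------- modules


def bridged_cliques():
    g = nx.Graph()
    for base in (0, 5):
        for i, j in itertools.combinations(range(5), 2):
            g.add_edge(f"n{base + i}", f"n{base + j}")
    g.add_edge("n0", "n5")
    return g


@pytest.mark.parametrize("algorithm", ["fast_greedy", "leading_eigenvector"])
def test_bridged_cliques_split_into_cliques(algorithm):
    g = bridged_cliques()
    part = decompose_modules(g, algorithm=algorithm)
    groups = {frozenset(part.module_nodes(m["module"])) for m in part.modules}
    expected = {
        frozenset(f"n{i}" for i in range(5)),
        frozenset(f"n{i}" for i in range(5, 10)),
    }
    assert groups == expected
    # reported Q equals direct evaluation of the modularity formula
    comms = [set(part.module_nodes(m["module"])) for m in part.modules]
    assert part.modularity_q == pytest.approx(modularity_q(g, comms))


def test_bridged_cliques_match_exhaustive_oracle():
    """The clique split maximizes modularity over all <=3-block partitions."""
    g = bridged_cliques()
    nodes = sorted(g.nodes)
    best_q, best_part = -1.0, None
    # enumerate set partitions of 10 nodes into at most 3 blocks
    def partitions(seq, k):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest, k):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1 :]
            if len(part) < k:
                yield part + [[head]]
    for part in partitions(nodes, 3):
        q = modularity_q(g, [set(b) for b in part])
        if q > best_q:
            best_q, best_part = q, part
    found = decompose_modules(g)
    assert found.modularity_q == pytest.approx(best_q)
    assert {frozenset(b) for b in best_part} == {
        frozenset(found.module_nodes(m["module"])) for m in found.modules
    }


def test_single_clique_one_module():
    g = nx.complete_graph(6)
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    part = decompose_modules(g)
    assert len(part.modules) == 1
    assert part.modules[0]["n_nodes"] == 6


def test_edgeless_graph_singleton_modules():
    g = nx.Graph()
    g.add_nodes_from(["a", "b", "c"])
    part = decompose_modules(g)
    assert part.modularity_q == 0.0
    assert sorted(part.assignment.values()) == [1, 2, 3]


def test_modules_partition_nodes(small_bundle):
    g = nx.gnm_random_graph(40, 70, seed=2)
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    giant = largest_component(g)
    part = decompose_modules(giant)
    all_nodes = sorted(part.assignment)
    assert all_nodes == sorted(giant.nodes)
    sizes = sum(m["n_nodes"] for m in part.modules)
    assert sizes == giant.number_of_nodes()
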