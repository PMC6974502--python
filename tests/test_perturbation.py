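"""Start/end resolution and k/p/c-filtered all-shortest-paths search."""

import itertools
import random

import pytest

from pharmgraph import (KnowledgeGraph, find_shortest_paths,
                        max_connecting_confidence, resolve_start_nodes,
                        restrict_subnetwork)
from pharmgraph.errors import FormatError, InputError
from pharmgraph.perturbation import PerturbationParams, classify_identifier

from conftest import accession, chain_graph, fake_inchikey, random_regulatory_graph


def test_classify_identifier_syntax():
    assert classify_identifier("P42345") == "target"
    assert classify_identifier("Q9Y478") == "target"
    assert classify_identifier("QNUKRWAIZMBVCU") == "compound"
    assert classify_identifier("QNUKRWAIZMBVCU-WCIBSUBMSA-N") == "compound"
    with pytest.raises(FormatError):
        classify_identifier("not-an-id-1")


def test_resolve_start_nodes_potency_filter():
    graph, ns_key, targets = chain_graph(dti_p=6.0)
    seeds, compounds, _ = resolve_start_nodes(graph, [ns_key], p=5.0)
    assert seeds == {graph.target_handle(targets[0])}
    assert len(compounds) == 1
    seeds, compounds, _ = resolve_start_nodes(graph, [ns_key], p=7.0)
    assert seeds == set() and compounds == set()


def test_resolve_start_nodes_mixed_and_unresolved():
    graph, ns_key, targets = chain_graph()
    seeds, _, report = resolve_start_nodes(
        graph, [ns_key, targets[2], "P99999", "ZZZZZZZZZZZZZZ"], p=5.0)
    assert seeds == {graph.target_handle(targets[0]),
                     graph.target_handle(targets[2])}
    assert sorted(report["unresolved"]) == ["P99999", "ZZZZZZZZZZZZZZ"]


def test_chain_path_with_compound_attached():
    graph, ns_key, targets = chain_graph(confidences=(0.5, 0.9), dti_p=6.0)
    sub = find_shortest_paths(graph, [ns_key], [targets[2]],
                              PerturbationParams(k=5, p=5, c=0.01))
    assert [p.nodes for p in sub.paths] == [
        tuple(graph.target_handle(t) for t in targets)]
    assert graph.compound_handle(fake_inchikey(1)) in sub.nodes
    kinds = sorted(d["kind"] for _, _, _, d in sub.edges)
    assert kinds == ["REGULATES", "REGULATES", "TESTED_ON"]


def test_chain_too_long_for_k_gives_empty_subnetwork():
    graph, ns_key, targets = chain_graph()
    sub = find_shortest_paths(graph, [ns_key], [targets[2]],
                              PerturbationParams(k=1))
    assert sub.is_empty and sub.paths == []


def test_diamond_returns_all_shortest_paths():
    kg = KnowledgeGraph(seed=0)
    t1, t2a, t2b, t3 = (accession(i) for i in range(4))
    for t in (t1, t2a, t2b, t3):
        kg.add_target(t)
    for a, b in [(t1, t2a), (t1, t2b), (t2a, t3), (t2b, t3)]:
        kg.add_regulates(a, b, "binding", "up", 0.8, "x")
    sub = find_shortest_paths(kg, [t1], [t3], PerturbationParams())
    assert sorted(p.nodes for p in sub.paths) == sorted([
        (kg.target_handle(t1), kg.target_handle(t2a), kg.target_handle(t3)),
        (kg.target_handle(t1), kg.target_handle(t2b), kg.target_handle(t3))])


def test_start_equals_end_single_node_path():
    graph, _, targets = chain_graph()
    sub = find_shortest_paths(graph, [targets[1]], [targets[1]])
    assert [p.nodes for p in sub.paths] == [(graph.target_handle(targets[1]),)]
    assert sub.nodes == {graph.target_handle(targets[1])}


def test_direction_matters():
    graph, _, targets = chain_graph()
    with_flow = find_shortest_paths(graph, [targets[0]], [targets[2]])
    against_flow = find_shortest_paths(graph, [targets[2]], [targets[0]])
    assert not with_flow.is_empty and against_flow.is_empty


def test_unresolvable_end_is_input_error():
    graph, ns_key, _ = chain_graph()
    with pytest.raises(InputError):
        find_shortest_paths(graph, [ns_key], ["P99999"])


def test_max_connecting_confidence_bottleneck():
    graph, ns_key, targets = chain_graph(confidences=(0.5, 0.9))
    assert max_connecting_confidence(graph, [ns_key], [targets[2]]) == 0.5


def test_max_connecting_confidence_parallel_chains():
    kg = KnowledgeGraph(seed=0)
    s, e = accession(0), accession(5)
    for t in [accession(i) for i in range(6)]:
        kg.add_target(t)
    # chain A via node 1, min confidence 0.3; chain B via node 2, min 0.7
    for a, b, c in [(s, accession(1), 0.3), (accession(1), e, 0.9),
                    (s, accession(2), 0.7), (accession(2), e, 0.8)]:
        kg.add_regulates(a, b, "binding", "up", c, "x")
    assert max_connecting_confidence(kg, [s], [e]) == 0.7


def test_max_connecting_confidence_disconnected_is_absent():
    kg = KnowledgeGraph(seed=0)
    kg.add_target(accession(0))
    kg.add_target(accession(1))
    assert max_connecting_confidence(kg, [accession(0)], [accession(1)]) is None


def test_restrict_subnetwork_hiding():
    graph, ns_key, targets = chain_graph(dti_p=6.0)
    sub = find_shortest_paths(graph, [ns_key], [targets[2]],
                              PerturbationParams(c=0.01))
    no_compounds = restrict_subnetwork(sub, {"compound"}, graph)
    assert all(graph.g.nodes[n]["kind"] == "target" for n in no_compounds.nodes)
    assert len(no_compounds.paths) == 1  # protein path intact
    assert restrict_subnetwork(sub, set(), graph).nodes == sub.nodes
    everything_hidden = restrict_subnetwork(sub, {"compound", "target", "pattern"}, graph)
    assert everything_hidden.is_empty and everything_hidden.paths == []


# --------------------------------------------------------------- oracle tests

def _enumerate_min_paths(kg, start, end, k, c):
    """Depth-limited exhaustive enumeration of simple directed paths over
    confidence-filtered REGULATES edges; keep the minimal length <= k."""
    adjacency = {}
    for u, v, _, d in kg.g.edges(keys=True, data=True):
        if d["kind"] == "REGULATES" and d["confidence"] >= c:
            adjacency.setdefault(u, set()).add(v)
    if start == end:
        return [(start,)]
    found = []

    def dfs(node, path):
        if len(path) - 1 > k:
            return
        if node == end:
            found.append(tuple(path))
            return
        for nxt in adjacency.get(node, ()):
            if nxt not in path:
                dfs(nxt, path + [nxt])

    dfs(start, [start])
    if not found:
        return []
    shortest = min(len(p) for p in found)
    return sorted(p for p in found if len(p) == shortest)


def test_paths_match_exhaustive_enumeration_on_random_graphs():
    rng = random.Random(17)
    for trial in range(40):
        n = rng.randint(3, 10)
        kg = random_regulatory_graph(rng, n, rng.randint(2, 20), seed=trial)
        k = rng.randint(0, 4)
        c = round(rng.random(), 2)
        starts = [accession(0)]
        ends = [accession(n - 1)]
        sub = find_shortest_paths(kg, starts, ends,
                                  PerturbationParams(k=k, c=c))
        expected = _enumerate_min_paths(kg, kg.target_handle(starts[0]),
                                        kg.target_handle(ends[0]), k, c)
        assert sorted(p.nodes for p in sub.paths) == expected


def test_connectivity_monotone_in_k_p_c():
    graph, ns_key, targets = chain_graph(confidences=(0.4, 0.6, 0.8), dti_p=6.0)

    def connects(k, p, c):
        return not find_shortest_paths(graph, [ns_key], [targets[-1]],
                                       PerturbationParams(k=k, p=p, c=c)).is_empty

    for k_lo, k_hi in itertools.combinations(range(0, 6), 2):
        assert (not connects(k_lo, 5, 0)) or connects(k_hi, 5, 0)
    for c_lo, c_hi in itertools.combinations([0, 0.3, 0.5, 0.7, 0.9], 2):
        assert connects(5, 5, c_hi) <= connects(5, 5, c_lo)
    assert connects(5, 6.0, 0) and not connects(5, 7.0, 0)


def test_returned_paths_simple_and_minimal():
    rng = random.Random(23)
    for trial in range(15):
        kg = random_regulatory_graph(rng, 8, 18, seed=trial)
        sub = find_shortest_paths(kg, [accession(0)], [accession(7)],
                                  PerturbationParams(k=5, c=0.2))
        lengths = {}
        for p in sub.paths:
            assert len(set(p.nodes)) == len(p.nodes)  # simple
            lengths.setdefault((p.start, p.end), set()).add(p.length)
        for lset in lengths.values():
            assert len(lset) == 1  # only minimal-length paths per pair
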