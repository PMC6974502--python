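"""Graph assembly, pattern-frequency filter, neighbors, serialization."""

import random

import pytest

from pharmgraph import (FilterConfig, KnowledgeGraph, build_graph,
                        export_graph, filter_patterns, graphs_equal,
                        import_graph, neighbors)
from pharmgraph.chem import MoleculeRecord
from pharmgraph.errors import ConfigError, ConsistencyError, GraphLookupError
from pharmgraph.ingest import AggregatedActivity, RegulatoryRecord

from conftest import accession, fake_inchikey, random_regulatory_graph


def _two_compound_inputs():
    mols = [MoleculeRecord.build("Cc1ccccc1", fake_inchikey(1)),
            MoleculeRecord.build("CCc1ccccc1", fake_inchikey(2))]
    acts = [AggregatedActivity(m.inchikey, accession(1), "IC50", 6.0 + i, 1)
            for i, m in enumerate(mols)]
    return acts, mols


def test_build_graph_toy_counts():
    acts, mols = _two_compound_inputs()
    g = build_graph(acts, [], mols, FilterConfig(1, 100), seed=1)
    s = g.summary()
    assert s["nodes"] == {"compound": 2, "target": 1, "pattern": 1}
    assert s["edges"]["TESTED_ON"] == 2 and s["edges"]["PATTERN_OF"] == 2
    (edge,) = [d for _, _, _, d in g.g.edges(keys=True, data=True)
               if d["kind"] == "PATTERN_OF" and d["overlap"] == pytest.approx(6 / 7)]
    assert edge


def test_build_graph_default_bounds_prune_rare_pattern():
    acts, mols = _two_compound_inputs()
    g = build_graph(acts, [], mols, FilterConfig(), seed=1)  # degree 2 < 5
    assert g.nodes_of_kind("pattern") == []
    assert g.summary()["edges"]["PATTERN_OF"] == 0
    # compounds stay even without pattern edges
    assert len(g.nodes_of_kind("compound")) == 2


def test_build_graph_empty_inputs():
    g = build_graph([], [], [], FilterConfig(), seed=1)
    assert g.summary() == {"nodes": {"compound": 0, "target": 0, "pattern": 0},
                           "edges": {k: 0 for k in
                                     ("TESTED_ON", "REGULATES", "PATTERN_OF",
                                      "POTENT_PATTERN_OF")}}


def test_build_graph_unknown_structure_is_consistency_error():
    acts, mols = _two_compound_inputs()
    with pytest.raises(ConsistencyError):
        build_graph(acts, [], mols[:1], FilterConfig(1, 100))


def test_build_graph_collapses_duplicate_ppi_keeping_max_confidence():
    dup = [RegulatoryRecord("P11111", "P22222", "binding", "up", c, "x")
           for c in (0.3, 0.8, 0.5)]
    other = RegulatoryRecord("P11111", "P22222", "phosphorylation", "up", 0.2, "x")
    g = build_graph([], dup + [other], [], FilterConfig(), seed=1)
    edges = [d for _, _, _, d in g.g.edges(keys=True, data=True)
             if d["kind"] == "REGULATES"]
    assert sorted(e["confidence"] for e in edges) == [0.2, 0.8]


def _degree_graph(degrees):
    kg = KnowledgeGraph(seed=0)
    serial = 0
    for i, degree in enumerate(degrees):
        scaffold = f"scaffold_{degree}"
        kg.add_pattern(scaffold, 6)
        for _ in range(degree):
            serial += 1
            key = fake_inchikey(serial)
            kg.add_compound(key, "Cc1ccccc1")
            kg.add_pattern_of(scaffold, key, 0.5)
    return kg


def test_filter_boundary_keeps_half_open_interval():
    kg = _degree_graph([4, 5, 99, 100])
    filter_patterns(kg, 5, 100)
    kept = sorted(kg.g.nodes[n]["compound_degree"]
                  for n in kg.nodes_of_kind("pattern"))
    assert kept == [5, 99]
    # no dangling edges
    for u, v, _, _ in kg.g.edges(keys=True, data=True):
        assert u in kg.g and v in kg.g


def test_filter_patterns_idempotent_and_noop_cases():
    kg = _degree_graph([5, 7])
    before = kg.summary()
    filter_patterns(kg, 5, 100)
    assert kg.summary() == before  # all in range
    filter_patterns(kg, 1, 10 ** 9)
    assert kg.summary() == before  # permissive bounds: no-op
    filter_patterns(kg, 6, 100)
    after = kg.summary()
    filter_patterns(kg, 6, 100)
    assert kg.summary() == after  # idempotent


def test_filter_patterns_invalid_bounds():
    with pytest.raises(ConfigError):
        filter_patterns(_degree_graph([5]), 100, 100)


def test_neighbors_ignore_direction_and_filter_by_kind():
    kg = KnowledgeGraph(seed=0)
    t = accession(0)
    kg.add_target(t)
    for i in range(1, 3):
        kg.add_target(accession(i))
        kg.add_regulates(accession(i), t, "binding", "up", 0.5, "x")  # incoming
    kg.add_target(accession(3))
    kg.add_regulates(t, accession(3), "binding", "up", 0.5, "x")  # outgoing
    kg.add_compound(fake_inchikey(1), "Cc1ccccc1")
    kg.add_tested_on(fake_inchikey(1), t, {"IC50": 6.0})
    nodes, edges = neighbors(kg, t, {"target"})
    assert len(nodes) == 3 and len(edges) == 3
    nodes, _ = neighbors(kg, t, set())
    assert nodes == set()
    nodes, _ = neighbors(kg, t, {"compound", "target"})
    assert len(nodes) == 4


def test_neighbors_unknown_node():
    with pytest.raises(GraphLookupError):
        neighbors(KnowledgeGraph(), "P99999")


def test_uuid_uniqueness_and_seeded_determinism():
    acts, mols = _two_compound_inputs()
    g1 = build_graph(acts, [], mols, FilterConfig(1, 100), seed=11)
    g2 = build_graph(acts, [], mols, FilterConfig(1, 100), seed=11)
    g3 = build_graph(acts, [], mols, FilterConfig(1, 100), seed=12)
    uuids = [d["uuid"] for _, d in g1.g.nodes(data=True)]
    uuids += [d["uuid"] for _, _, _, d in g1.g.edges(keys=True, data=True)]
    assert len(set(uuids)) == len(uuids)
    assert graphs_equal(g1, g2)
    assert not graphs_equal(g1, g3)  # different uuid sequence


def test_stereoisomers_are_distinct_nodes_sharing_ns_key():
    e_key = "QQQQQQQQQQQQQQ-AAAAAAAAAB-N"
    z_key = "QQQQQQQQQQQQQQ-CCCCCCCCCD-N"
    mols = [MoleculeRecord.build("C/C=C/c1ccccc1", e_key),
            MoleculeRecord.build("C/C=C\\c1ccccc1", z_key)]
    acts = [AggregatedActivity(m.inchikey, accession(1), "IC50", 6.0, 1)
            for m in mols]
    g = build_graph(acts, [], mols, FilterConfig(1, 100), seed=1)
    assert len(g.nodes_of_kind("compound")) == 2
    assert len(g.compounds_by_ns_key("QQQQQQQQQQQQQQ")) == 2
    # stereo-stripped: both share one pattern node
    assert len(g.nodes_of_kind("pattern")) == 1


def _random_property_graph(rng, seed):
    kg = random_regulatory_graph(rng, rng.randint(2, 8), rng.randint(1, 12),
                                 seed=seed)
    for i in range(rng.randint(1, 5)):
        key = fake_inchikey(100 + i)
        kg.add_compound(key, "Cc1ccccc1")
        kg.add_tested_on(key, accession(rng.randrange(2)),
                         {"IC50": round(rng.uniform(4, 9), 3),
                          "EC50": round(rng.uniform(4, 9), 3)})
        kg.add_pattern("c1ccccc1", 6)
        kg.add_pattern_of("c1ccccc1", key, round(rng.uniform(0.2, 1.0), 3))
    return kg


@pytest.mark.parametrize("fmt,name", [("graphml", "g.graphml"),
                                      ("json_nodelink", "g.json")])
def test_round_trip_random_graphs(fmt, name, tmp_path):
    rng = random.Random(42)
    for trial in range(15):
        kg = _random_property_graph(rng, seed=trial)
        path = tmp_path / f"{trial}_{name}"
        export_graph(kg, path, fmt)
        assert graphs_equal(kg, import_graph(path, fmt))


def test_bulk_csv_emits_one_file_per_label_and_type(tmp_path):
    kg = _random_property_graph(random.Random(7), seed=7)
    files = export_graph(kg, tmp_path / "bulk", "bulk_csv")
    names = sorted(f.name for f in files)
    assert names == ["edges_pattern_of.csv", "edges_potent_pattern_of.csv",
                     "edges_regulates.csv", "edges_tested_on.csv",
                     "nodes_compound.csv", "nodes_pattern.csv",
                     "nodes_target.csv"]
    header = (tmp_path / "bulk" / "nodes_compound.csv").read_text().splitlines()[0]
    assert "uuid" in header and "inchikey" in header


def test_export_empty_graph_and_unknown_format(tmp_path):
    kg = KnowledgeGraph(seed=0)
    export_graph(kg, tmp_path / "empty.json", "json_nodelink")
    assert graphs_equal(kg, import_graph(tmp_path / "empty.json", "json_nodelink"))
    with pytest.raises(ConfigError):
        export_graph(kg, tmp_path / "x", "dot")
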