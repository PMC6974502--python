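"""Shared builders for toy knowledge graphs and synthetic identifiers."""

from __future__ import annotations

import random
import string

import pytest

from pharmgraph import FilterConfig, KnowledgeGraph
from pharmgraph.chem import MoleculeRecord
from pharmgraph.ingest import AggregatedActivity, RegulatoryRecord


def fake_inchikey(i: int) -> str:
    """Distinct, layout-valid synthetic InChIKey for toy records."""
    letters = string.ascii_uppercase
    block = []
    n = i
    for _ in range(14):
        block.append(letters[n % 26])
        n //= 26
    return "".join(reversed(block)) + "-UHFFFAOYSA-N"


def accession(i: int) -> str:
    """Layout-valid synthetic UniProt accession."""
    return f"P{20000 + i:05d}"


def empty_graph(seed: int = 0) -> KnowledgeGraph:
    return KnowledgeGraph(seed=seed)


def chain_graph(confidences=(0.5, 0.9), dti_p: float = 6.0, seed: int = 1):
    """Compound -> T1 -> T2 -> ... with given regulatory confidences.

    Returns (graph, compound ns key, target accessions).
    """
    from pharmgraph import build_graph

    mol = MoleculeRecord.build("Cc1ccccc1", fake_inchikey(1))
    targets = [accession(i) for i in range(len(confidences) + 1)]
    acts = [AggregatedActivity(mol.inchikey, targets[0], "IC50", dti_p, 1)]
    ppis = [RegulatoryRecord(targets[i], targets[i + 1], "binding",
                             "up-regulates", c, f"PMID:{i}")
            for i, c in enumerate(confidences)]
    graph = build_graph(acts, ppis, [mol], FilterConfig(1, 10 ** 9), seed=seed)
    return graph, mol.ns_inchikey, targets


def bare_target_graph(seed: int = 0) -> KnowledgeGraph:
    """Graph shell for tests that wire nodes and edges directly."""
    return KnowledgeGraph(seed=seed)


def random_regulatory_graph(rng: random.Random, n_targets: int, n_edges: int,
                            seed: int = 0) -> KnowledgeGraph:
    """Random directed confidence-weighted protein network."""
    kg = KnowledgeGraph(seed=seed)
    targets = [accession(i) for i in range(n_targets)]
    for t in targets:
        kg.add_target(t)
    pairs = [(a, b) for a in targets for b in targets if a != b]
    rng.shuffle(pairs)
    for a, b in pairs[:n_edges]:
        kg.add_regulates(a, b, "binding", "up-regulates",
                         round(rng.random(), 3), "PMID:0")
    return kg


@pytest.fixture
def toy_prediction_graph():
    """Two targets, one potent pattern, tested and untested carriers.

    T1 has potent pattern P (benzene, via tested carrier C1); C2 carries P
    but is untested on T1. C1 is also tested (weakly) on T2.
    """
    kg = KnowledgeGraph(seed=7)
    c1, c2 = fake_inchikey(1), fake_inchikey(2)
    kg.add_compound(c1, "Cc1ccccc1")
    kg.add_compound(c2, "CCc1ccccc1")
    kg.add_target(accession(1))
    kg.add_target(accession(2))
    kg.add_pattern("c1ccccc1", 6)
    kg.add_pattern_of("c1ccccc1", c1, 6 / 7)
    kg.add_pattern_of("c1ccccc1", c2, 6 / 8)
    kg.add_tested_on(c1, accession(1), {"IC50": 8.0})
    kg.add_tested_on(c1, accession(2), {"IC50": 4.0})
    return kg, c1, c2, accession(1), accession(2)
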