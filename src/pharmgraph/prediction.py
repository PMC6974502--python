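"""Bioactivity prediction through shared potent patterns.

A (compound, target) association is predicted whenever some pattern is both
a potent pattern of the target (T2P edge) and a scaffold of the compound
(C2P edge). Predictions run in either direction — untested compounds for a
target, or untested (off-)targets for a compound — and are ranked by the
pattern/compound heavy-atom overlap ratio: the larger the fraction of the
compound the shared pattern explains, the stronger the hypothesis. Pairs
with an existing measured bioactivity are excluded by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

from . import chem
from .errors import GraphLookupError
from .kgraph import KnowledgeGraph


@dataclass(frozen=True)
class Prediction:
    """One predicted compound-target association via one shared pattern."""

    inchikey: str
    uniprot: str
    via_pattern: str  # scaffold SMILES
    overlap: float
    already_tested: bool


def _tested_pairs(graph: KnowledgeGraph) -> set:
    return {(graph.node_identity(u), graph.node_identity(v))
            for u, v, _, d in graph.g.edges(keys=True, data=True)
            if d["kind"] == "TESTED_ON"}


def _sort(predictions: list[Prediction]) -> list[Prediction]:
    return sorted(predictions,
                  key=lambda p: (-p.overlap, p.inchikey, p.via_pattern, p.uniprot))


def predict_compounds_for_target(graph: KnowledgeGraph, uniprot: str,
                                 include_tested: bool = False) -> list[Prediction]:
    """Compounds predicted active on *uniprot* via its potent patterns.

    One prediction per (compound, potent pattern) pair where the compound
    carries the pattern. Ordered by overlap descending, then InChIKey, then
    pattern key.
    """
    target = graph.target_handle(uniprot)
    if not graph.has_node(target):
        raise GraphLookupError(f"unknown target: {uniprot!r}")
    tested = _tested_pairs(graph)
    out: list[Prediction] = []
    for _, pattern, _, d in graph.g.out_edges(target, keys=True, data=True):
        if d["kind"] != "POTENT_PATTERN_OF":
            continue
        for _, compound, _, c2p in graph.g.out_edges(pattern, keys=True, data=True):
            if c2p["kind"] != "PATTERN_OF":
                continue
            inchikey = graph.node_identity(compound)
            was_tested = (inchikey, uniprot) in tested
            if was_tested and not include_tested:
                continue
            out.append(Prediction(inchikey, uniprot,
                                  graph.node_identity(pattern),
                                  c2p["overlap"], was_tested))
    return _sort(out)


def predict_targets_for_compound(graph: KnowledgeGraph, inchikey: str,
                                 include_tested: bool = False) -> list[Prediction]:
    """Targets for which some scaffold of the compound is a potent pattern."""
    compound = graph.compound_handle(inchikey)
    if not graph.has_node(compound):
        raise GraphLookupError(f"unknown compound: {inchikey!r}")
    tested = _tested_pairs(graph)
    out: list[Prediction] = []
    for pattern, _, _, c2p in graph.g.in_edges(compound, keys=True, data=True):
        if c2p["kind"] != "PATTERN_OF":
            continue
        for target, _, _, t2p in graph.g.in_edges(pattern, keys=True, data=True):
            if t2p["kind"] != "POTENT_PATTERN_OF":
                continue
            uniprot = graph.node_identity(target)
            was_tested = (inchikey, uniprot) in tested
            if was_tested and not include_tested:
                continue
            out.append(Prediction(inchikey, uniprot,
                                  graph.node_identity(pattern),
                                  c2p["overlap"], was_tested))
    return _sort(out)


def resolve_by_ns_key(graph: KnowledgeGraph, ns_inchikey: str) -> list[str]:
    """All compound InChIKeys whose first block equals the query.

    Stereoisomers share the non-stereo block, so more than one node may
    match; the result may also be empty. Case-insensitive.
    """
    ns = chem.ns_inchikey(ns_inchikey)
    return sorted(graph.node_identity(h) for h in graph.compounds_by_ns_key(ns))


def predictions_to_tsv(predictions: Iterable[Prediction]) -> str:
    lines = ["inchikey\tuniprot\tpattern\toverlap\talready_tested"]
    for p in predictions:
        lines.append(f"{p.inchikey}\t{p.uniprot}\t{p.via_pattern}\t"
                     f"{p.overlap:.6f}\t{str(p.already_tested).lower()}")
    return "\n".join(lines) + "\n"


def predictions_to_json(predictions: Iterable[Prediction]) -> str:
    return json.dumps([p.__dict__ for p in predictions], sort_keys=True, indent=1)
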