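"""Typed property multigraph of compounds, targets and chemical patterns.

The knowledge graph holds three node kinds and four directed edge kinds:

* ``compound`` — identified by full standard InChIKey (the NS block is a
  non-unique lookup attribute: stereoisomers are distinct nodes sharing it);
* ``target`` — identified by UniProt accession;
* ``pattern`` — a Bemis-Murcko scaffold, identified by canonical SMILES;

* ``TESTED_ON`` (compound → target) — one edge per tested pair, carrying the
  per-activity-type map of median negative-log potencies and their maximum
  (``best_p``), plus the ``potent`` flag written by the potency stage;
* ``REGULATES`` (target → target) — a causal interaction with mechanism,
  effect and a confidence score in [0, 1]; one edge per
  (source, target, mechanism), keeping the highest confidence seen;
* ``PATTERN_OF`` (pattern → compound, "C2P") — scaffold membership with the
  heavy-atom overlap ratio;
* ``POTENT_PATTERN_OF`` (target → pattern, "T2P") — written by the potency
  stage.

Patterns attached to fewer than ``pattern_min_count`` or at least
``pattern_max_count`` compounds are pruned as too specific / too general
(defaults keep degrees in [5, 100)).

Storage is a :class:`networkx.MultiDiGraph`; every node and edge carries a
UUID (random by default, a seeded deterministic sequence when a seed is
given). Serialization: GraphML, node-link JSON (both lossless round-trip)
and a bulk-import CSV dialect (one file per node label / edge type).
"""

from __future__ import annotations

import csv
import json
import random
import uuid as _uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from . import chem
from .chem import MoleculeRecord
from .errors import ConfigError, ConsistencyError, GraphLookupError
from .ingest import AggregatedActivity, RegulatoryRecord

NODE_KINDS = ("compound", "target", "pattern")
EDGE_KINDS = ("TESTED_ON", "REGULATES", "PATTERN_OF", "POTENT_PATTERN_OF")

#: edge attributes stored as JSON strings in flat formats (GraphML, CSV)
_JSON_ATTRS = ("p_values",)


@dataclass(frozen=True)
class FilterConfig:
    """Pattern-frequency bounds: keep patterns with compound degree in
    [pattern_min_count, pattern_max_count)."""

    pattern_min_count: int = 5
    pattern_max_count: int = 100

    def validate(self) -> None:
        if self.pattern_min_count >= self.pattern_max_count:
            raise ConfigError(
                f"pattern_min_count ({self.pattern_min_count}) must be below "
                f"pattern_max_count ({self.pattern_max_count})"
            )


class _UuidFactory:
    """UUID source: seeded deterministic sequence, or random UUID4."""

    def __init__(self, seed: Optional[int] = None):
        self._rng = random.Random(seed) if seed is not None else None

    def __call__(self) -> str:
        if self._rng is None:
            return str(_uuid.uuid4())
        return str(_uuid.UUID(int=self._rng.getrandbits(128), version=4))


class KnowledgeGraph:
    """In-memory property graph with identity-key indexing.

    Node handles are strings of the form ``C:<inchikey>``, ``T:<uniprot>``
    and ``P:<scaffold smiles>``; public lookups accept bare identity keys.
    """

    def __init__(self, seed: Optional[int] = None):
        self.g = nx.MultiDiGraph(potency_labeled=False)
        self._uuid = _UuidFactory(seed)

    # ------------------------------------------------------------------ nodes

    @staticmethod
    def compound_handle(inchikey: str) -> str:
        return f"C:{inchikey}"

    @staticmethod
    def target_handle(uniprot: str) -> str:
        return f"T:{uniprot}"

    @staticmethod
    def pattern_handle(scaffold_smiles: str) -> str:
        return f"P:{scaffold_smiles}"

    def add_compound(self, inchikey: str, smiles: str,
                     ns_inchikey: Optional[str] = None) -> str:
        node = self.compound_handle(inchikey)
        if node not in self.g:
            self.g.add_node(node, kind="compound", uuid=self._uuid(),
                            inchikey=inchikey,
                            ns_inchikey=ns_inchikey or inchikey[:14],
                            smiles=smiles)
        return node

    def add_target(self, uniprot: str, gene_symbol: str = "", name: str = "") -> str:
        node = self.target_handle(uniprot)
        if node not in self.g:
            self.g.add_node(node, kind="target", uuid=self._uuid(),
                            uniprot=uniprot, gene_symbol=gene_symbol, name=name)
        return node

    def add_pattern(self, scaffold_smiles: str, heavy_atoms: int) -> str:
        node = self.pattern_handle(scaffold_smiles)
        if node not in self.g:
            self.g.add_node(node, kind="pattern", uuid=self._uuid(),
                            scaffold_smiles=scaffold_smiles,
                            heavy_atoms=int(heavy_atoms), compound_degree=0)
        return node

    # ------------------------------------------------------------------ edges

    def add_tested_on(self, inchikey: str, uniprot: str,
                      p_values: dict, potent: bool = False) -> str:
        u, v = self.compound_handle(inchikey), self.target_handle(uniprot)
        key = self._uuid()
        self.g.add_edge(u, v, key=key, kind="TESTED_ON", uuid=key,
                        p_values=dict(p_values),
                        best_p=max(p_values.values()), potent=potent)
        return key

    def add_regulates(self, source: str, target: str, mechanism: str,
                      effect: str, confidence: float, reference: str) -> str:
        u, v = self.target_handle(source), self.target_handle(target)
        key = self._uuid()
        self.g.add_edge(u, v, key=key, kind="REGULATES", uuid=key,
                        mechanism=mechanism, effect=effect,
                        confidence=float(confidence), reference=reference)
        return key

    def add_pattern_of(self, scaffold_smiles: str, inchikey: str,
                       overlap: float) -> str:
        u = self.pattern_handle(scaffold_smiles)
        v = self.compound_handle(inchikey)
        key = self._uuid()
        self.g.add_edge(u, v, key=key, kind="PATTERN_OF", uuid=key,
                        overlap=float(overlap))
        return key

    def add_potent_pattern_of(self, uniprot: str, scaffold_smiles: str) -> str:
        u = self.target_handle(uniprot)
        v = self.pattern_handle(scaffold_smiles)
        key = self._uuid()
        self.g.add_edge(u, v, key=key, kind="POTENT_PATTERN_OF", uuid=key)
        return key

    # ---------------------------------------------------------------- queries

    def has_node(self, handle: str) -> bool:
        return handle in self.g

    def resolve_node(self, identifier: str) -> str:
        """Map an identity key (or an internal handle) to a node handle."""
        for handle in (identifier,
                       self.compound_handle(identifier),
                       self.target_handle(identifier),
                       self.pattern_handle(identifier)):
            if handle in self.g:
                return handle
        raise GraphLookupError(f"unknown node: {identifier!r}")

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, k in self.g.nodes(data="kind") if k == kind]

    def edges_of_kind(self, kind: str):
        return [(u, v, key, data) for u, v, key, data in self.g.edges(keys=True, data=True)
                if data["kind"] == kind]

    def compounds_by_ns_key(self, ns_inchikey: str) -> list[str]:
        ns = chem.ns_inchikey(ns_inchikey)
        return [n for n, d in self.g.nodes(data=True)
                if d["kind"] == "compound" and d["ns_inchikey"] == ns]

    def node_identity(self, handle: str) -> str:
        """Bare identity key of a node (InChIKey / UniProt / scaffold SMILES)."""
        return handle.split(":", 1)[1]

    def pattern_compound_degree(self, pattern_handle: str) -> int:
        return sum(1 for _, _, d in self.g.out_edges(pattern_handle, data=True)
                   if d["kind"] == "PATTERN_OF")

    def refresh_pattern_degrees(self) -> None:
        for node in self.nodes_of_kind("pattern"):
            self.g.nodes[node]["compound_degree"] = self.pattern_compound_degree(node)

    def summary(self) -> dict:
        counts = {kind: 0 for kind in NODE_KINDS}
        for _, k in self.g.nodes(data="kind"):
            counts[k] += 1
        edge_counts = {kind: 0 for kind in EDGE_KINDS}
        for _, _, d in self.g.edges(data=True):
            edge_counts[d["kind"]] += 1
        return {"nodes": counts, "edges": edge_counts}


def build_graph(
    activities: Sequence[AggregatedActivity],
    ppis: Sequence[RegulatoryRecord],
    compounds: Sequence[MoleculeRecord],
    config: Optional[FilterConfig] = None,
    seed: Optional[int] = None,
) -> KnowledgeGraph:
    """Assemble the knowledge graph from aggregated tables.

    Every activity's InChIKey must have a :class:`MoleculeRecord` supplying
    its structure (otherwise :class:`ConsistencyError`). Scaffolds are
    extracted per compound; pattern nodes and C2P edges carry the heavy-atom
    overlap ratio; the pattern-frequency filter is applied at the end.
    Duplicate causal-interaction rows collapse to one edge per
    (source, target, mechanism), keeping the maximum confidence.
    """
    config = config or FilterConfig()
    config.validate()
    kg = KnowledgeGraph(seed=seed)

    structures = {rec.inchikey: rec for rec in compounds}
    for act in activities:
        if act.inchikey not in structures:
            raise ConsistencyError(
                f"activity references unknown compound structure: {act.inchikey}"
            )

    for rec in compounds:
        kg.add_compound(rec.inchikey, rec.smiles, rec.ns_inchikey)

    # one TESTED_ON edge per (compound, target) pair, per-type p-value map
    pair_values: dict[tuple[str, str], dict[str, float]] = {}
    for act in activities:
        pair_values.setdefault((act.inchikey, act.uniprot), {})[act.activity_type] = act.p_value
    for (inchikey, uniprot), p_values in pair_values.items():
        kg.add_target(uniprot)
        kg.add_tested_on(inchikey, uniprot, p_values)

    # causal interactions, deduplicated by (source, target, mechanism)
    best: dict[tuple[str, str, str], RegulatoryRecord] = {}
    for ppi in ppis:
        key = (ppi.source_uniprot, ppi.target_uniprot, ppi.mechanism)
        if key not in best or ppi.confidence > best[key].confidence:
            best[key] = ppi
    for ppi in best.values():
        kg.add_target(ppi.source_uniprot)
        kg.add_target(ppi.target_uniprot)
        kg.add_regulates(ppi.source_uniprot, ppi.target_uniprot,
                         ppi.mechanism, ppi.effect, ppi.confidence, ppi.reference)

    # scaffold patterns and C2P membership
    for rec in compounds:
        result = chem.extract_scaffold(rec.smiles)
        if not result.has_scaffold:
            continue  # acyclic compounds stay as nodes without pattern edges
        kg.add_pattern(result.scaffold_smiles, result.scaffold_heavy_atoms)
        overlap = chem.overlap_ratio(result.scaffold_smiles, rec.smiles)
        kg.add_pattern_of(result.scaffold_smiles, rec.inchikey, overlap)

    filter_patterns(kg, config.pattern_min_count, config.pattern_max_count)
    return kg


def filter_patterns(graph: KnowledgeGraph, min_count: int = 5,
                    max_count: int = 100) -> KnowledgeGraph:
    """Prune patterns attached to < *min_count* or >= *max_count* compounds.

    Idempotent; survivors satisfy min_count <= compound_degree < max_count.
    """
    if min_count >= max_count:
        raise ConfigError(f"min_count ({min_count}) must be below max_count ({max_count})")
    graph.refresh_pattern_degrees()
    doomed = [n for n in graph.nodes_of_kind("pattern")
              if not (min_count <= graph.g.nodes[n]["compound_degree"] < max_count)]
    graph.g.remove_nodes_from(doomed)  # incident edges removed with the nodes
    return graph


def neighbors(graph: KnowledgeGraph, node_id: str,
              node_type_filter: Optional[Iterable[str]] = None):
    """Adjacent nodes of the given kinds, with the edges connecting them.

    Adjacency ignores edge direction (expansion semantics). Returns
    ``(node_handles, edges)`` where edges are ``(u, v, key, attrs)`` tuples.
    """
    handle = graph.resolve_node(node_id)
    kinds = set(NODE_KINDS) if node_type_filter is None else set(node_type_filter)
    nodes: set[str] = set()
    edges = []
    for u, v, key, data in graph.g.out_edges(handle, keys=True, data=True):
        if graph.g.nodes[v]["kind"] in kinds:
            nodes.add(v)
            edges.append((u, v, key, dict(data)))
    for u, v, key, data in graph.g.in_edges(handle, keys=True, data=True):
        if graph.g.nodes[u]["kind"] in kinds:
            nodes.add(u)
            edges.append((u, v, key, dict(data)))
    return nodes, edges


# ------------------------------------------------------------- serialization

def _flatten(data: dict) -> dict:
    out = {}
    for k, v in data.items():
        if k in _JSON_ATTRS:
            out[k] = json.dumps(v, sort_keys=True)
        elif v is not None:
            out[k] = v
    return out


def _unflatten(data: dict) -> dict:
    out = dict(data)
    for k in _JSON_ATTRS:
        if k in out and isinstance(out[k], str):
            out[k] = json.loads(out[k])
    return out


def export_graph(graph: KnowledgeGraph, path, format: str = "json_nodelink") -> list[Path]:
    """Write the graph; returns the file(s) created.

    ``graphml`` and ``json_nodelink`` round-trip losslessly through
    :func:`import_graph`; ``bulk_csv`` writes one node file per label and one
    edge file per relationship type under the directory *path*, suitable for
    graph-database bulk import.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.MultiDiGraph(**graph.g.graph)
        for n, d in graph.g.nodes(data=True):
            g.add_node(n, **_flatten(d))
        for u, v, key, d in graph.g.edges(keys=True, data=True):
            g.add_edge(u, v, key=key, **_flatten(d))
        nx.write_graphml(g, path, encoding="utf-8")
        return [path]
    if format == "json_nodelink":
        payload = {
            "graph": dict(graph.g.graph),
            "nodes": [{"id": n, **d} for n, d in graph.g.nodes(data=True)],
            "edges": [{"source": u, "target": v, "key": key, **d}
                      for u, v, key, d in graph.g.edges(keys=True, data=True)],
        }
        path.write_text(json.dumps(payload, sort_keys=True, indent=1), encoding="utf-8")
        return [path]
    if format == "bulk_csv":
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for kind in NODE_KINDS:
            rows = [{"handle": n, **_flatten(d)}
                    for n, d in graph.g.nodes(data=True) if d["kind"] == kind]
            written.append(_write_csv(path / f"nodes_{kind}.csv", rows))
        for kind in EDGE_KINDS:
            rows = [{"source": u, "target": v, **_flatten(d)}
                    for u, v, _, d in graph.g.edges(keys=True, data=True)
                    if d["kind"] == kind]
            written.append(_write_csv(path / f"edges_{kind.lower()}.csv", rows))
        return written
    raise ConfigError(f"unknown export format: {format!r}")


def _write_csv(path: Path, rows: list[dict]) -> Path:
    fields = sorted({k for row in rows for k in row}) if rows else ["handle"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
    return path


def import_graph(path, format: str = "json_nodelink") -> KnowledgeGraph:
    """Read a graph written by :func:`export_graph` (graphml or json_nodelink)."""
    path = Path(path)
    kg = KnowledgeGraph()
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        kg.g = nx.MultiDiGraph(**{k: v for k, v in g.graph.items()
                                  if k not in ("node_default", "edge_default")})
        for n, d in g.nodes(data=True):
            kg.g.add_node(n, **_unflatten(d))
        for u, v, key, d in g.edges(keys=True, data=True):
            d = _unflatten(d)
            kg.g.add_edge(u, v, key=d.get("uuid", key), **d)
        return kg
    if format == "json_nodelink":
        payload = json.loads(path.read_text(encoding="utf-8"))
        kg.g = nx.MultiDiGraph(**payload.get("graph", {}))
        for node in payload["nodes"]:
            node = dict(node)
            kg.g.add_node(node.pop("id"), **node)
        for edge in payload["edges"]:
            edge = dict(edge)
            kg.g.add_edge(edge.pop("source"), edge.pop("target"),
                          key=edge.pop("key"), **edge)
        return kg
    raise ConfigError(f"unknown import format: {format!r}")


def load_graph(path) -> KnowledgeGraph:
    """Load a graph file, picking the format from its suffix."""
    path = Path(path)
    fmt = "graphml" if path.suffix == ".graphml" else "json_nodelink"
    return import_graph(path, format=fmt)


def _canonical(graph: KnowledgeGraph):
    def freeze(d):
        return tuple(sorted((k, json.dumps(v, sort_keys=True)) for k, v in d.items()))
    nodes = sorted((n, freeze(d)) for n, d in graph.g.nodes(data=True))
    edges = sorted((u, v, freeze(d)) for u, v, _, d in graph.g.edges(keys=True, data=True))
    meta = freeze(graph.g.graph)
    return nodes, edges, meta


def graphs_equal(a: KnowledgeGraph, b: KnowledgeGraph) -> bool:
    """Structural equality: same nodes, edges and attributes (edge keys
    compared through the uuid attribute, not storage keys)."""
    return _canonical(a) == _canonical(b)
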