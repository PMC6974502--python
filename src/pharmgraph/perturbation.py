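"""Start → destination network-perturbation analysis.

Given start identifiers (compound NS-InChIKeys and/or UniProt accessions)
and end targets, the analysis finds, per (seed target, end target) pair,
ALL directed shortest paths through the causal-interaction layer, subject
to three parameters:

* ``k`` — maximum shortest-path length, counted in REGULATES edges
  (default 5). The compound→target bioactivity hop is not counted toward k:
  k limits pathway propagation between proteins, while p governs the
  bioactivity hop independently.
* ``p`` — minimum potency (negative-log molar) for a compound's tested
  target to seed the search (default 5, i.e. 10 µM).
* ``c`` — minimum causal-interaction confidence; edges below c are removed
  before the search (default 0.0, no filtering).

Paths of all contributing pairs are merged into one subnetwork, together
with the seed compounds and their qualifying bioactivity edges; each path
remembers the (start, end) pair that produced it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from . import chem
from .errors import FormatError, InputError
from .kgraph import KnowledgeGraph

#: UniProt accession (6- or 10-character forms)
_UNIPROT_RE = re.compile(
    r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


@dataclass(frozen=True)
class PerturbationParams:
    """The k / p / c triple governing path discovery."""

    k: int = 5
    p: float = 5.0
    c: float = 0.0

    def validate(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be non-negative: {self.k}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must be in [0, 1]: {self.c}")


@dataclass(frozen=True)
class PathRecord:
    """One shortest path (target handles) with the seed pair it came from."""

    nodes: tuple
    start: str
    end: str

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


@dataclass
class Subnetwork:
    """Merged union of all qualifying shortest paths."""

    nodes: set = field(default_factory=set)
    edges: list = field(default_factory=list)  # (u, v, key, attrs)
    paths: list = field(default_factory=list)  # PathRecord
    params: PerturbationParams = field(default_factory=PerturbationParams)

    @property
    def is_empty(self) -> bool:
        return not self.nodes

    def to_json(self, graph: Optional[KnowledgeGraph] = None) -> str:
        ident = graph.node_identity if graph else (lambda h: h)
        return json.dumps({
            "params": {"k": self.params.k, "p": self.params.p, "c": self.params.c},
            "nodes": sorted(self.nodes),
            "edges": [{"source": u, "target": v, "key": key, **attrs}
                      for u, v, key, attrs in sorted(self.edges, key=lambda e: e[2])],
            "paths": [{"nodes": [ident(n) for n in p.nodes],
                       "start": ident(p.start), "end": ident(p.end)}
                      for p in self.paths],
        }, sort_keys=True, indent=1)


def classify_identifier(identifier: str) -> str:
    """'compound' for a 14-char NS block (or full InChIKey), 'target' for a
    UniProt accession; FormatError otherwise."""
    ident = identifier.strip()
    if _UNIPROT_RE.match(ident.upper()):
        return "target"
    try:
        chem.ns_inchikey(ident)
        return "compound"
    except FormatError:
        pass
    raise FormatError(
        f"identifier {identifier!r} is neither an NS-InChIKey nor a UniProt accession"
    )


def resolve_start_nodes(graph: KnowledgeGraph, identifiers: Sequence[str],
                        p: float = 5.0):
    """Resolve mixed start identifiers into seed targets and compounds.

    Compounds resolve through the NS-InChIKey; each resolved compound seeds
    every target it was tested on with best potency >= p. Directly named
    proteins seed themselves (no potency filter). Returns
    ``(seed_targets, seed_compounds, report)`` with handles; the report
    lists identifiers that resolved to nothing in the graph.
    """
    if not identifiers:
        raise InputError("no start identifiers given")
    seed_targets: set[str] = set()
    seed_compounds: set[str] = set()
    report = {"unresolved": [], "compound_seeds": {}, "named_targets": []}
    for identifier in identifiers:
        kind = classify_identifier(identifier)
        if kind == "target":
            handle = graph.target_handle(identifier.strip().upper())
            if graph.has_node(handle):
                seed_targets.add(handle)
                report["named_targets"].append(identifier)
            else:
                report["unresolved"].append(identifier)
            continue
        matches = graph.compounds_by_ns_key(identifier)
        if not matches:
            report["unresolved"].append(identifier)
            continue
        for compound in matches:
            seeded = []
            for _, target, _, data in graph.g.out_edges(compound, keys=True, data=True):
                if data["kind"] == "TESTED_ON" and data["best_p"] >= p:
                    seed_targets.add(target)
                    seeded.append(target)
            if seeded:
                seed_compounds.add(compound)
                report["compound_seeds"][graph.node_identity(compound)] = sorted(
                    graph.node_identity(t) for t in seeded)
    return seed_targets, seed_compounds, report


def _regulatory_view(graph: KnowledgeGraph, c: float) -> nx.DiGraph:
    """Directed protein-layer view: REGULATES edges with confidence >= c."""
    view = nx.DiGraph()
    view.add_nodes_from(graph.nodes_of_kind("target"))
    for u, v, _, data in graph.g.edges(keys=True, data=True):
        if data["kind"] == "REGULATES" and data["confidence"] >= c:
            view.add_edge(u, v)
    return view


def find_shortest_paths(graph: KnowledgeGraph, starts: Sequence[str],
                        ends: Sequence[str],
                        params: Optional[PerturbationParams] = None) -> Subnetwork:
    """All shortest paths from resolved start seeds to end targets.

    For each (seed target s, end target e): when the directed shortest-path
    length L(s, e) in the confidence-filtered protein layer is at most k,
    every path of length exactly L is collected (a pair with s == e yields
    the single-node path). Collected paths are merged; seed compounds and
    their qualifying bioactivity edges to in-subnetwork seed targets are
    attached. An empty subnetwork means nothing connects under the
    parameters.
    """
    params = params or PerturbationParams()
    params.validate()

    end_targets: set[str] = set()
    unresolved_ends = []
    for identifier in ends:
        if classify_identifier(identifier) != "target":
            raise FormatError(f"end node must be a UniProt accession: {identifier!r}")
        handle = graph.target_handle(identifier.strip().upper())
        if graph.has_node(handle):
            end_targets.add(handle)
        else:
            unresolved_ends.append(identifier)
    if not end_targets:
        raise InputError(f"no resolvable end node among {list(ends)!r}")

    seed_targets, seed_compounds, _ = resolve_start_nodes(graph, starts, params.p)

    view = _regulatory_view(graph, params.c)
    sub = Subnetwork(params=params)
    for s in sorted(seed_targets):
        for e in sorted(end_targets):
            if s == e:
                sub.paths.append(PathRecord((s,), s, e))
                sub.nodes.add(s)
                continue
            try:
                paths = list(nx.all_shortest_paths(view, s, e))
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                continue
            if len(paths[0]) - 1 > params.k:
                continue
            for path in sorted(map(tuple, paths)):
                sub.paths.append(PathRecord(path, s, e))
                sub.nodes.update(path)

    # edges along path segments: every qualifying parallel REGULATES edge
    segment_pairs = {(p.nodes[i], p.nodes[i + 1])
                     for p in sub.paths for i in range(p.length)}
    for u, v in sorted(segment_pairs):
        for key, data in graph.g.get_edge_data(u, v).items():
            if data["kind"] == "REGULATES" and data["confidence"] >= params.c:
                sub.edges.append((u, v, key, dict(data)))

    # attach seed compounds whose qualifying DTI points into the subnetwork
    for compound in sorted(seed_compounds):
        attached = False
        for _, target, key, data in graph.g.out_edges(compound, keys=True, data=True):
            if (data["kind"] == "TESTED_ON" and data["best_p"] >= params.p
                    and target in sub.nodes):
                sub.edges.append((compound, target, key, dict(data)))
                attached = True
        if attached:
            sub.nodes.add(compound)
    return sub


def max_connecting_confidence(graph: KnowledgeGraph, starts: Sequence[str],
                              ends: Sequence[str], k: int = 5,
                              p: float = 5.0) -> Optional[float]:
    """Highest confidence threshold c for which a subnetwork still exists.

    The answer is always one of the finite edge-confidence values (or 0.0
    when the graph connects only unfiltered); ``None`` when even the
    unfiltered graph connects nothing. Computed by bisection over the
    sorted confidence values — connectivity is monotone non-increasing in c.
    """
    def connects(c: float) -> bool:
        sub = find_shortest_paths(graph, starts, ends,
                                  PerturbationParams(k=k, p=p, c=c))
        return bool(sub.paths)

    if not connects(0.0):
        return None
    candidates = sorted({data["confidence"]
                         for _, _, _, data in graph.g.edges(keys=True, data=True)
                         if data["kind"] == "REGULATES"})
    if not candidates:
        return 0.0
    lo, hi = 0, len(candidates) - 1
    best = 0.0
    while lo <= hi:
        mid = (lo + hi) // 2
        if connects(candidates[mid]):
            best = candidates[mid]
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def restrict_subnetwork(subnetwork: Subnetwork, hide_types: Iterable[str],
                        graph: KnowledgeGraph) -> Subnetwork:
    """View with nodes of the hidden kinds (and their edges) removed;
    the path list keeps only paths that remain intact."""
    hidden = set(hide_types)
    keep = {n for n in subnetwork.nodes if graph.g.nodes[n]["kind"] not in hidden}
    edges = [(u, v, key, attrs) for u, v, key, attrs in subnetwork.edges
             if u in keep and v in keep]
    paths = [p for p in subnetwork.paths if all(n in keep for n in p.nodes)]
    return Subnetwork(nodes=keep, edges=edges, paths=paths, params=subnetwork.params)


def subnetwork_to_graph(subnetwork: Subnetwork, graph: KnowledgeGraph) -> KnowledgeGraph:
    """Materialize a subnetwork as a standalone knowledge graph (for export)."""
    out = KnowledgeGraph()
    out.g = nx.MultiDiGraph(**graph.g.graph)
    for n in sorted(subnetwork.nodes):
        out.g.add_node(n, **dict(graph.g.nodes[n]))
    for u, v, key, attrs in subnetwork.edges:
        out.g.add_edge(u, v, key=key, **dict(attrs))
    return out
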