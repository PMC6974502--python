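"""Potent-compound labeling and target→pattern (T2P) potent-pattern edges.

A compound is "potent" on a target when it sits in the top 20% of that
target's aggregated bioactivities, ranked in decreasing order of potency;
the ranking lumps all negative-log values across activity types. For
sparsely-tested targets (at most five aggregated values) the quantile is
unreliable and a fixed cutoff of 7 (0.1 µM) is used instead.

The quantile rule is made exact as follows: with n aggregated values, the
cutoff is the ceil(0.2·n)-th largest value, and every value tying the
cutoff is included — the potent set may therefore exceed 20% under ties,
but never falls short.

Every Bemis-Murcko pattern contained in a compound potent on a target is a
*potent pattern* of that target; the derivation writes one T2P edge per
(target, pattern) pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import StateError
from .kgraph import KnowledgeGraph


@dataclass(frozen=True)
class PotencyConfig:
    """Parameters of the potency rules.

    potent_fraction: quantile of compounds labeled potent (default 0.2).
    sparse_threshold: a target with at most this many aggregated values uses
        the fixed cutoff instead of the quantile (default 5).
    sparse_cutoff: the fixed negative-log molar cutoff, default 7.0 (0.1 µM).
    """

    potent_fraction: float = 0.2
    sparse_threshold: int = 5
    sparse_cutoff: float = 7.0

    def validate(self) -> None:
        if not 0.0 < self.potent_fraction < 1.0:
            raise ValueError(f"potent_fraction must be in (0,1): {self.potent_fraction}")
        if self.sparse_cutoff <= 0:
            raise ValueError(f"sparse_cutoff must be positive: {self.sparse_cutoff}")


@dataclass
class TargetPotencyReport:
    """Audit record of how one target's potency cutoff was chosen."""

    uniprot: str
    n_values: int
    cutoff_used: float
    rule: str  # "quantile" | "sparse"
    potent_compounds: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "uniprot": self.uniprot,
            "n_values": self.n_values,
            "cutoff_used": self.cutoff_used,
            "rule": self.rule,
            "potent_compounds": sorted(self.potent_compounds),
        }


def potency_cutoff(values: Iterable[float],
                   config: Optional[PotencyConfig] = None) -> tuple[float, str]:
    """Cutoff (negative-log molar) and the rule that produced it.

    With at most ``sparse_threshold`` values the fixed ``sparse_cutoff``
    applies; otherwise the cutoff is the ceil(potent_fraction·n)-th largest
    value of the multiset.
    """
    config = config or PotencyConfig()
    config.validate()
    values = sorted(values, reverse=True)
    if not values:
        raise ValueError("cannot compute a potency cutoff from an empty value set")
    n = len(values)
    if n <= config.sparse_threshold:
        return config.sparse_cutoff, "sparse"
    n_potent = math.ceil(config.potent_fraction * n)
    return values[n_potent - 1], "quantile"


def label_potent(graph: KnowledgeGraph,
                 config: Optional[PotencyConfig] = None
                 ) -> tuple[KnowledgeGraph, list[TargetPotencyReport]]:
    """Flag potent compounds on every target's TESTED_ON edges.

    Per target the value multiset is every aggregated (compound, type)
    p-value across its incoming TESTED_ON edges, lumped regardless of type;
    a compound is potent when any of its per-type values reaches the cutoff
    (ties included). Flags are written in place; per-target audit reports
    are returned.
    """
    config = config or PotencyConfig()
    reports: list[TargetPotencyReport] = []
    for target in graph.nodes_of_kind("target"):
        edges = [(u, key, data)
                 for u, _, key, data in graph.g.in_edges(target, keys=True, data=True)
                 if data["kind"] == "TESTED_ON"]
        if not edges:
            continue
        values = [p for _, _, data in edges for p in data["p_values"].values()]
        cutoff, rule = potency_cutoff(values, config)
        report = TargetPotencyReport(
            uniprot=graph.node_identity(target),
            n_values=len(values), cutoff_used=cutoff, rule=rule,
        )
        for compound, key, data in edges:
            potent = any(p >= cutoff for p in data["p_values"].values())
            graph.g.edges[compound, target, key]["potent"] = potent
            if potent:
                report.potent_compounds.add(graph.node_identity(compound))
        reports.append(report)
    graph.g.graph["potency_labeled"] = True
    return graph, reports


def derive_potent_patterns(graph: KnowledgeGraph) -> KnowledgeGraph:
    """Write one POTENT_PATTERN_OF (T2P) edge per (target, pattern) pair
    witnessed by a compound potent on the target and carrying the pattern.

    Requires :func:`label_potent` to have run (StateError otherwise).
    Existing T2P edges are replaced, so the operation is idempotent.
    """
    if not graph.g.graph.get("potency_labeled", False):
        raise StateError("derive_potent_patterns called before label_potent")

    stale = [(u, v, key) for u, v, key, d in graph.g.edges(keys=True, data=True)
             if d["kind"] == "POTENT_PATTERN_OF"]
    graph.g.remove_edges_from(stale)

    # compound handle -> pattern identity keys it carries
    patterns_of: dict[str, list[str]] = {}
    for p, c, _, data in graph.g.edges(keys=True, data=True):
        if data["kind"] == "PATTERN_OF":
            patterns_of.setdefault(c, []).append(graph.node_identity(p))

    for target in graph.nodes_of_kind("target"):
        t2p: set[str] = set()
        for compound, _, _, data in graph.g.in_edges(target, keys=True, data=True):
            if data["kind"] == "TESTED_ON" and data.get("potent", False):
                t2p.update(patterns_of.get(compound, ()))
        for scaffold in sorted(t2p):
            graph.add_potent_pattern_of(graph.node_identity(target), scaffold)
    return graph


def reports_to_json(reports: Sequence[TargetPotencyReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], sort_keys=True, indent=1)


def reports_to_tsv(reports: Sequence[TargetPotencyReport]) -> str:
    lines = ["uniprot\tn_values\tcutoff_used\trule\tn_potent\tpotent_compounds"]
    for r in reports:
        lines.append("\t".join([
            r.uniprot, str(r.n_values), f"{r.cutoff_used:g}", r.rule,
            str(len(r.potent_compounds)), ",".join(sorted(r.potent_compounds)),
        ]))
    return "\n".join(lines) + "\n"
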