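"""Exception hierarchy shared by all pharmgraph modules."""


class PharmGraphError(Exception):
    """Base class for all errors raised by this package."""


class StructureError(PharmGraphError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{detail}: {smiles!r}")


class FormatError(PharmGraphError, ValueError):
    """A chemical or protein identifier does not match its expected layout."""


class SchemaError(PharmGraphError):
    """An input table is missing a mapped column or its header row."""


class ConfigError(PharmGraphError):
    """Invalid configuration (e.g. inconsistent pattern-frequency bounds)."""


class ConsistencyError(PharmGraphError):
    """Cross-record inconsistency, e.g. an activity whose compound structure is
    unknown, or a pattern larger than its parent compound."""


class GraphLookupError(PharmGraphError, KeyError):
    """A node identifier is not present in the knowledge graph."""


class StateError(PharmGraphError):
    """An operation was called before its prerequisite stage ran."""


class InputError(PharmGraphError):
    """A query cannot be answered from the given inputs (e.g. no resolvable
    end node for a path search)."""
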