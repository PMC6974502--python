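"""Parsing of bioactivity (DTI) and causal-interaction (PPI) tables.

Raw activity rows are aggregated into unique (compound, target, activity
type) triples; the aggregate value is the median on the negative-log molar
scale (pIC50-style, "p-value" in the potency sense). Only dose-response
potency types (IC50 / AC50 / EC50) enter the knowledge graph; Ki and other
types are dropped at aggregation.

Tables are delimited text with a header row. Column names are mapped through
a small logical-name dictionary, with presets matching a ChEMBL activity
export and a SIGNOR TSV export.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import SchemaError

#: molar factor per supported concentration unit (case preserved except for
#: the micro sign, where several spellings circulate)
UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "um": 1e-6,
    "nM": 1e-9,
    "nm": 1e-9,
    "pM": 1e-12,
}

DEFAULT_ACTIVITY_TYPES = frozenset({"IC50", "AC50", "EC50"})

#: logical column names used internally
DTI_COLUMNS = ("compound_id", "smiles", "inchikey", "uniprot",
               "activity_type", "value", "unit")
PPI_COLUMNS = ("source_uniprot", "target_uniprot", "mechanism", "effect",
               "confidence", "reference")

#: identity mapping — files that already use the logical names
PLAIN_DTI_COLUMNS = {c: c for c in DTI_COLUMNS}
PLAIN_PPI_COLUMNS = {c: c for c in PPI_COLUMNS}

#: preset matching a ChEMBL activities export joined to target accessions
CHEMBL_DTI_COLUMNS = {
    "compound_id": "molecule_chembl_id",
    "smiles": "canonical_smiles",
    "inchikey": "standard_inchi_key",
    "uniprot": "accession",
    "activity_type": "standard_type",
    "value": "standard_value",
    "unit": "standard_units",
}

#: preset matching a SIGNOR TSV export
SIGNOR_PPI_COLUMNS = {
    "source_uniprot": "IDA",
    "target_uniprot": "IDB",
    "mechanism": "MECHANISM",
    "effect": "EFFECT",
    "confidence": "SCORE",
    "reference": "PMID",
}

DTI_PRESETS = {"plain": PLAIN_DTI_COLUMNS, "chembl": CHEMBL_DTI_COLUMNS}
PPI_PRESETS = {"plain": PLAIN_PPI_COLUMNS, "signor": SIGNOR_PPI_COLUMNS}


def to_neglog_molar(value: float, unit: str) -> float:
    """Convert a concentration to its negative log10 molar value.

    ``to_neglog_molar(10, "µM") == 5.0``; ``to_neglog_molar(0.1, "µM") == 7.0``.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric activity value: {value!r}") from None
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"activity value must be positive and finite, got {value!r}")
    factor = UNIT_TO_MOLAR.get(str(unit).strip())
    if factor is None:
        raise ValueError(f"unknown concentration unit: {unit!r}")
    return -math.log10(v * factor)


@dataclass(frozen=True)
class RawActivityRecord:
    """One measured bioactivity row, before aggregation."""

    compound_id: str
    smiles: str
    inchikey: str
    uniprot: str
    activity_type: str
    value: float
    unit: str

    @property
    def p_value(self) -> float:
        return to_neglog_molar(self.value, self.unit)


@dataclass(frozen=True)
class AggregatedActivity:
    """Median negative-log activity for one (compound, target, type) triple."""

    inchikey: str
    uniprot: str
    activity_type: str
    p_value: float
    n_observations: int


@dataclass(frozen=True)
class RegulatoryRecord:
    """One directed causal protein-protein relation with its evidence."""

    source_uniprot: str
    target_uniprot: str
    mechanism: str
    effect: str
    confidence: float
    reference: str


@dataclass
class ParseReport:
    """Row-level accounting of a table parse."""

    n_rows: int = 0
    n_records: int = 0
    dropped: dict = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.n_rows, "records": self.n_records, "dropped": self.dropped},
            sort_keys=True,
        )


def _read_table(stream, sep: Optional[str]) -> pd.DataFrame:
    if isinstance(stream, (str, Path)):
        return pd.read_csv(stream, sep=sep, engine="python", dtype=str,
                           keep_default_na=False, na_values=[""])
    return pd.read_csv(io.StringIO(stream.read()) if hasattr(stream, "read") else stream,
                       sep=sep, engine="python", dtype=str,
                       keep_default_na=False, na_values=[""])


def _check_columns(df: pd.DataFrame, column_map: Mapping[str, str],
                   required: Sequence[str]) -> None:
    missing = [column_map[c] for c in required if column_map.get(c) not in df.columns]
    if missing:
        raise SchemaError(
            f"mapped column(s) {missing} not found in header {list(df.columns)}; "
            "is the header row present and the column map correct?"
        )


def parse_dti_table(
    stream,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = "\t",
    organism: Optional[str] = None,
    taxon_column: Optional[str] = None,
) -> tuple[list[RawActivityRecord], ParseReport]:
    """Parse a delimited bioactivity table into raw activity records.

    Rows missing a value, unit, InChIKey, SMILES or target accession are
    dropped and counted in the returned :class:`ParseReport`, as are rows
    whose value carries a censoring qualifier ('>', '<', etc.) — censored
    measurements cannot enter a median meaningfully. When *organism* and
    *taxon_column* are given, rows of other organisms are dropped too.
    """
    column_map = dict(column_map or PLAIN_DTI_COLUMNS)
    df = _read_table(stream, sep)
    _check_columns(df, column_map, DTI_COLUMNS)

    report = ParseReport(n_rows=len(df))
    records: list[RawActivityRecord] = []
    for _, row in df.iterrows():
        fields = {c: row.get(column_map[c]) for c in DTI_COLUMNS}
        if any(pd.isna(fields[c]) for c in ("smiles", "inchikey", "uniprot",
                                            "activity_type", "value", "unit")):
            report.drop("missing_field")
            continue
        if organism is not None and taxon_column is not None:
            if str(row.get(taxon_column, "")).strip() != organism:
                report.drop("organism")
                continue
        raw_value = str(fields["value"]).strip()
        if raw_value and raw_value[0] in "<>~":
            report.drop("qualified_value")
            continue
        try:
            value = float(raw_value)
        except ValueError:
            report.drop("non_numeric_value")
            continue
        if value <= 0:
            report.drop("non_positive_value")
            continue
        unit = str(fields["unit"]).strip()
        if unit not in UNIT_TO_MOLAR:
            report.drop("unknown_unit")
            continue
        records.append(RawActivityRecord(
            compound_id=str(fields["compound_id"]) if not pd.isna(fields["compound_id"]) else "",
            smiles=str(fields["smiles"]).strip(),
            inchikey=str(fields["inchikey"]).strip().upper(),
            uniprot=str(fields["uniprot"]).strip(),
            activity_type=str(fields["activity_type"]).strip(),
            value=value,
            unit=unit,
        ))
    report.n_records = len(records)
    return records, report


def aggregate_bioactivities(
    records: Iterable[RawActivityRecord],
    allowed_types: Optional[Iterable[str]] = None,
) -> list[AggregatedActivity]:
    """Aggregate raw rows into unique compound-target-type triples.

    Records whose activity type is outside *allowed_types* (default
    IC50/AC50/EC50) are removed; the rest are grouped by
    (inchikey, uniprot, activity_type) and each group is reduced to the
    median of its per-record negative-log molar values. For an even group
    size the median is the mean of the two central p-values.
    """
    allowed = frozenset(allowed_types) if allowed_types is not None else DEFAULT_ACTIVITY_TYPES
    groups: dict[tuple[str, str, str], list[float]] = {}
    for rec in records:
        if rec.activity_type not in allowed:
            continue
        key = (rec.inchikey, rec.uniprot, rec.activity_type)
        groups.setdefault(key, []).append(rec.p_value)
    out = []
    for (inchikey, uniprot, activity_type), values in sorted(groups.items()):
        values.sort()
        n = len(values)
        mid = n // 2
        median = values[mid] if n % 2 else (values[mid - 1] + values[mid]) / 2.0
        out.append(AggregatedActivity(inchikey, uniprot, activity_type, median, n))
    return out


def parse_ppi_table(
    stream,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = "\t",
    allow_self_loops: bool = False,
) -> tuple[list[RegulatoryRecord], ParseReport]:
    """Parse a causal-interaction table into directed regulatory records.

    The parser is non-lossy with respect to duplicates: repeated
    (source, target, mechanism) rows are kept as parallel records and
    collapsed only at graph assembly. A confidence outside [0, 1] is an
    error naming the offending row.
    """
    column_map = dict(column_map or PLAIN_PPI_COLUMNS)
    df = _read_table(stream, sep)
    _check_columns(df, column_map, ("source_uniprot", "target_uniprot", "confidence"))

    report = ParseReport(n_rows=len(df))
    records: list[RegulatoryRecord] = []
    for idx, row in df.iterrows():
        get = lambda c: row.get(column_map.get(c, ""), None)
        source = get("source_uniprot")
        target = get("target_uniprot")
        conf = get("confidence")
        if pd.isna(source) or pd.isna(target) or pd.isna(conf):
            report.drop("missing_field")
            continue
        try:
            confidence = float(conf)
        except ValueError:
            raise ValueError(f"row {idx}: non-numeric confidence {conf!r}") from None
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"row {idx}: confidence {confidence} outside [0, 1]")
        source, target = str(source).strip(), str(target).strip()
        if source == target and not allow_self_loops:
            report.drop("self_loop")
            continue
        records.append(RegulatoryRecord(
            source_uniprot=source,
            target_uniprot=target,
            mechanism=str(get("mechanism")) if not pd.isna(get("mechanism")) else "",
            effect=str(get("effect")) if not pd.isna(get("effect")) else "",
            confidence=confidence,
            reference=str(get("reference")) if not pd.isna(get("reference")) else "",
        ))
    report.n_records = len(records)
    return records, report
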