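"""Seeded synthetic DTI/PPI fixture generator with known ground truth.

The generator emulates the two input tables of the pipeline — a bioactivity
export and a causal-interaction export — at toy scale, with a planted truth
that the downstream stages must recover:

* Compounds are built by decorating a fixed list of valid ring-containing
  template structures (benzene, pyridine, indole, ...) with acyclic
  substituents, so each compound's Bemis-Murcko scaffold equals its template
  by construction and heavy-atom overlap ratios vary.
* For every planted (scaffold, target) pair, the compounds carrying that
  scaffold ("carriers") draw potencies from a high-potency law and everyone
  else from a low-potency law (default means 8.0 vs 5.0 negative-log molar,
  spread 0.3 — a 3-log separation). Per target the tested set is balanced so
  carriers make up exactly the potent fraction (20%): after the 80/20 rule
  the potent set is exactly the tested carriers. A configurable number of
  carriers per pair is held out untested — these are the compounds the
  prediction stage must enumerate.
* Activities are emitted as concentrations in nM with replicate rows
  (exercising the median) and a configurable fraction of the planned triples
  is emitted as Ki instead (exercising activity-type filtering; the tested
  set is re-balanced afterwards so the planted truth is preserved).
* The regulatory network is a directed Erdős–Rényi draw with Beta-distributed
  confidences plus optional planted directed chains for path-recovery tests.

All sampling is driven by the config seed; identical configs produce
byte-identical tables.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem

from . import chem
from .chem import MoleculeRecord
from .errors import ConfigError
from .ingest import (CHEMBL_DTI_COLUMNS, SIGNOR_PPI_COLUMNS,
                     RawActivityRecord, RegulatoryRecord)

#: ring-containing templates, each equal to its own Bemis-Murcko framework
SCAFFOLD_TEMPLATES = (
    "c1ccccc1",               # benzene
    "c1ccncc1",               # pyridine
    "c1ccc2ccccc2c1",         # naphthalene
    "c1ccc2[nH]ccc2c1",       # indole
    "c1ccc(-c2ccccc2)cc1",    # biphenyl
    "c1ccc2ncccc2c1",         # quinoline
    "c1cncnc1",               # pyrimidine
    "c1ccsc1",                # thiophene
    "C1CCN(c2ccccc2)CC1",     # 1-phenylpiperidine
    "c1ccc2occc2c1",          # benzofuran
    "C1CN(c2ccccc2)CCO1",     # 4-phenylmorpholine
    "c1cc[nH]c1",             # pyrrole
)

#: acyclic substituents; the first atom is the attachment point
_SUBSTITUENTS = ("C", "CC", "CCC", "CC(C)C", "CO", "OC", "N", "O",
                 "F", "Cl", "CCN", "C(F)(F)F", "CCO", "C(C)O")

_MECHANISMS = ("phosphorylation", "dephosphorylation", "ubiquitination",
               "binding", "transcriptional regulation", "cleavage")
_EFFECTS = ("up-regulates", "down-regulates", "up-regulates activity",
            "down-regulates activity")
_ACTIVITY_TYPES = ("IC50", "AC50", "EC50")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic fixture.

    Defaults plant one high-potency scaffold per target with a 3-log
    separation between the carrier and background potency laws, 10 carriers
    per scaffold of which 2 are held out untested, and a tested set per
    target balanced so carriers are exactly the potent fraction.
    """

    n_scaffolds: int = 6
    compounds_per_scaffold: int = 10
    n_targets: int = 6
    ppi_edge_prob: float = 0.15
    confidence_alpha: float = 2.0
    confidence_beta: float = 2.0
    potent_mean: float = 8.0
    inactive_mean: float = 5.0
    potency_spread: float = 0.3
    potent_fraction: float = 0.2
    holdout_per_pair: int = 2
    replicates: int = 3
    ki_fraction: float = 0.1
    planted_potent_pairs: Optional[frozenset] = None  # {(scaffold_idx, target_idx)}
    planted_chains: tuple = ()  # tuples of target indices
    planted_chain_confidence: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_scaffolds < 1:
            raise ConfigError("n_scaffolds must be at least 1")
        if self.n_scaffolds > len(SCAFFOLD_TEMPLATES):
            raise ConfigError(
                f"at most {len(SCAFFOLD_TEMPLATES)} scaffolds available, "
                f"requested {self.n_scaffolds}")
        if self.compounds_per_scaffold < 1 or self.n_targets < 1:
            raise ConfigError("compounds_per_scaffold and n_targets must be positive")
        if not 0.0 <= self.ppi_edge_prob <= 1.0:
            raise ConfigError(f"ppi_edge_prob outside [0,1]: {self.ppi_edge_prob}")
        if not 0.0 <= self.ki_fraction <= 1.0:
            raise ConfigError(f"ki_fraction outside [0,1]: {self.ki_fraction}")

    def planted_pairs(self) -> frozenset:
        if self.planted_potent_pairs is not None:
            return frozenset(self.planted_potent_pairs)
        return frozenset((t % self.n_scaffolds, t) for t in range(self.n_targets))

    def target_accession(self, index: int) -> str:
        return f"P{10000 + index:05d}"


@dataclass
class LibraryResult:
    """Generated compounds with their scaffold ground truth."""

    records: list  # MoleculeRecord
    scaffold_assignment: dict  # inchikey -> scaffold index
    scaffold_smiles: list  # canonical SMILES per scaffold index
    compound_ids: dict  # inchikey -> synthetic compound id

    def carriers(self, scaffold_index: int) -> list[str]:
        return [k for k, s in sorted(self.scaffold_assignment.items())
                if s == scaffold_index]


@dataclass
class FixtureTruth:
    """What the pipeline is expected to recover."""

    scaffold_assignment: dict  # inchikey -> scaffold SMILES
    target_potent_scaffolds: dict  # uniprot -> sorted scaffold SMILES
    intended_potent: dict  # uniprot -> sorted inchikeys (tested carriers)
    untested_carriers: dict  # uniprot -> sorted inchikeys (prediction truth)
    tested: dict  # uniprot -> sorted inchikeys in the dose-response design

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=1)


def _decorate(template: Chem.Mol, rng: random.Random) -> Chem.Mol:
    """Attach 1-4 acyclic substituents to carbons bearing hydrogens."""
    mol = Chem.RWMol(template)
    for _ in range(rng.randint(1, 4)):
        sites = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1]
        if not sites:
            break
        site = rng.choice(sites)
        frag = Chem.MolFromSmiles(rng.choice(_SUBSTITUENTS))
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol, frag))
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
        mol.UpdatePropertyCache(strict=False)  # refresh implicit-H counts
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def generate_compound_library(config: FixtureConfig) -> LibraryResult:
    """Decorated-scaffold compound library; scaffold extraction on any output
    molecule recovers its template exactly."""
    config.validate()
    rng = random.Random(f"{config.seed}:library")
    scaffold_smiles = [chem.canonicalize(s)
                       for s in SCAFFOLD_TEMPLATES[:config.n_scaffolds]]
    records: list[MoleculeRecord] = []
    assignment: dict[str, int] = {}
    compound_ids: dict[str, str] = {}
    serial = 0
    for s_idx, template_smiles in enumerate(scaffold_smiles):
        template = Chem.MolFromSmiles(template_smiles)
        made = 0
        attempts = 0
        while made < config.compounds_per_scaffold:
            attempts += 1
            if attempts > 200 * config.compounds_per_scaffold:
                raise ConfigError(
                    f"could not generate {config.compounds_per_scaffold} distinct "
                    f"decorations of scaffold {template_smiles}")
            mol = _decorate(template, rng)
            smiles = Chem.MolToSmiles(mol)
            if chem.extract_scaffold(smiles).scaffold_smiles != template_smiles:
                continue  # decoration closed a ring or altered aromaticity
            inchikey = Chem.MolToInchiKey(mol)
            if not inchikey or inchikey in assignment:
                continue
            serial += 1
            records.append(MoleculeRecord.build(smiles, inchikey))
            assignment[inchikey] = s_idx
            compound_ids[inchikey] = f"SYN{serial:05d}"
            made += 1
    return LibraryResult(records, assignment, scaffold_smiles, compound_ids)


def _design_target(config: FixtureConfig, library: LibraryResult,
                   target_idx: int, rng: random.Random):
    """Tested carriers, untested carriers and non-carriers for one target,
    balanced so tested carriers are exactly the potent fraction."""
    planted = sorted(s for s, t in config.planted_pairs() if t == target_idx)
    carriers, holdout = [], []
    for s in planted:
        members = library.carriers(s)
        n_hold = min(config.holdout_per_pair, max(0, len(members) - 1))
        held = rng.sample(members, n_hold) if n_hold else []
        holdout.extend(held)
        carriers.extend(m for m in members if m not in held)
    carrier_set = set(carriers) | set(holdout)
    pool = [r.inchikey for r in library.records if r.inchikey not in carrier_set]
    if carriers:
        ratio = (1.0 - config.potent_fraction) / config.potent_fraction
        n_non = min(len(pool), int(round(len(carriers) * ratio)))
        non_carriers = rng.sample(pool, n_non)
    else:
        # unplanted target: a sparse handful of inactives (fixed-cutoff rule,
        # none reach it, so no compound is potent)
        non_carriers = rng.sample(pool, min(3, len(pool)))
    return carriers, holdout, non_carriers


def generate_bioactivity_table(config: FixtureConfig, library: LibraryResult
                               ) -> tuple[list[RawActivityRecord], FixtureTruth]:
    """Raw activity rows (nM concentrations, replicated) plus ground truth.

    A ``ki_fraction`` share of each target's planned triples is emitted as
    Ki instead of a dose-response type; the tested set is then re-balanced
    (trimming non-carriers) so the surviving carriers still occupy exactly
    the top potent fraction after aggregation.
    """
    config.validate()
    rng = random.Random(f"{config.seed}:bioactivity")
    structures = {r.inchikey: r for r in library.records}
    rows: list[RawActivityRecord] = []
    truth = FixtureTruth({k: library.scaffold_smiles[s]
                          for k, s in sorted(library.scaffold_assignment.items())},
                         {}, {}, {}, {})

    for t_idx in range(config.n_targets):
        uniprot = config.target_accession(t_idx)
        carriers, holdout, non_carriers = _design_target(config, library, t_idx, rng)

        ki_pick = lambda: rng.random() < config.ki_fraction
        ki_carriers = [c for c in carriers if ki_pick()]
        ki_non = [c for c in non_carriers if ki_pick()]
        carriers = [c for c in carriers if c not in ki_carriers]
        non_carriers = [c for c in non_carriers if c not in ki_non]
        if carriers:
            ratio = (1.0 - config.potent_fraction) / config.potent_fraction
            non_carriers = non_carriers[:int(len(carriers) * ratio)]

        planted = sorted(s for s, t in config.planted_pairs() if t == t_idx)
        truth.target_potent_scaffolds[uniprot] = (
            [library.scaffold_smiles[s] for s in planted] if carriers else [])
        truth.intended_potent[uniprot] = sorted(carriers)
        # carriers with no dose-response row on this target (held out, or
        # emitted as Ki only) are exactly what prediction must enumerate
        truth.untested_carriers[uniprot] = (
            sorted(set(holdout) | set(ki_carriers)) if carriers else [])
        truth.tested[uniprot] = sorted(carriers + non_carriers)

        def emit(inchikey: str, mean: float, activity_type: str) -> None:
            p_true = min(11.0, max(3.0, rng.gauss(mean, config.potency_spread)))
            for _ in range(config.replicates):
                p_obs = p_true + rng.uniform(-0.1, 0.1)
                rows.append(RawActivityRecord(
                    compound_id=library.compound_ids[inchikey],
                    smiles=structures[inchikey].smiles,
                    inchikey=inchikey,
                    uniprot=uniprot,
                    activity_type=activity_type,
                    value=10.0 ** (9.0 - p_obs),
                    unit="nM",
                ))

        for inchikey in carriers:
            emit(inchikey, config.potent_mean, rng.choice(_ACTIVITY_TYPES))
        for inchikey in non_carriers:
            emit(inchikey, config.inactive_mean, rng.choice(_ACTIVITY_TYPES))
        for inchikey in ki_carriers:
            emit(inchikey, config.potent_mean, "Ki")
        for inchikey in ki_non:
            emit(inchikey, config.inactive_mean, "Ki")
    return rows, truth


def generate_ppi_network(config: FixtureConfig) -> list[RegulatoryRecord]:
    """Directed Erdős–Rényi regulatory network with Beta confidences,
    plus any planted directed chains (no self-loops)."""
    config.validate()
    rng = random.Random(f"{config.seed}:ppi")
    records: list[RegulatoryRecord] = []
    seen: set[tuple[str, str]] = set()
    for i in range(config.n_targets):
        for j in range(config.n_targets):
            if i == j or rng.random() >= config.ppi_edge_prob:
                continue
            src, dst = config.target_accession(i), config.target_accession(j)
            seen.add((src, dst))
            records.append(RegulatoryRecord(
                source_uniprot=src, target_uniprot=dst,
                mechanism=rng.choice(_MECHANISMS),
                effect=rng.choice(_EFFECTS),
                confidence=round(rng.betavariate(config.confidence_alpha,
                                                 config.confidence_beta), 3),
                reference=f"PMID:{rng.randint(10000000, 39999999)}",
            ))
    for chain in config.planted_chains:
        for i, j in zip(chain, chain[1:]):
            src, dst = config.target_accession(i), config.target_accession(j)
            if (src, dst) in seen:
                continue
            seen.add((src, dst))
            records.append(RegulatoryRecord(
                source_uniprot=src, target_uniprot=dst,
                mechanism="binding", effect="up-regulates",
                confidence=config.planted_chain_confidence,
                reference="PMID:00000000",
            ))
    return records


@dataclass
class Fixture:
    """A complete synthetic study: library, tables and ground truth."""

    config: FixtureConfig
    library: LibraryResult
    activities: list
    ppis: list
    truth: FixtureTruth


def generate_fixture(config: Optional[FixtureConfig] = None) -> Fixture:
    config = config or FixtureConfig()
    library = generate_compound_library(config)
    activities, truth = generate_bioactivity_table(config, library)
    ppis = generate_ppi_network(config)
    return Fixture(config, library, activities, ppis, truth)


def write_fixture(fixture: Fixture, outdir) -> dict:
    """Write dti.tsv (ChEMBL-export column names), ppi.tsv (SIGNOR column
    names) and truth.json under *outdir*; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dti_path, ppi_path = outdir / "dti.tsv", outdir / "ppi.tsv"
    truth_path = outdir / "truth.json"

    cols = CHEMBL_DTI_COLUMNS
    header = [cols[c] for c in ("compound_id", "smiles", "inchikey", "uniprot",
                                "activity_type", "value", "unit")]
    lines = ["\t".join(header)]
    for r in fixture.activities:
        lines.append("\t".join([r.compound_id, r.smiles, r.inchikey, r.uniprot,
                                r.activity_type, f"{r.value:.6g}", r.unit]))
    dti_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    pcols = SIGNOR_PPI_COLUMNS
    pheader = [pcols[c] for c in ("source_uniprot", "target_uniprot", "mechanism",
                                  "effect", "confidence", "reference")]
    plines = ["\t".join(pheader)]
    for r in fixture.ppis:
        plines.append("\t".join([r.source_uniprot, r.target_uniprot, r.mechanism,
                                 r.effect, f"{r.confidence:g}", r.reference]))
    ppi_path.write_text("\n".join(plines) + "\n", encoding="utf-8")

    truth_path.write_text(fixture.truth.to_json() + "\n", encoding="utf-8")
    return {"dti": dti_path, "ppi": ppi_path, "truth": truth_path}
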