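"""Structure-level utilities.

Everything pattern-related in the knowledge graph rests on four small
operations implemented here: SMILES canonicalization, Bemis-Murcko scaffold
extraction, heavy-atom counting and the pattern/compound heavy-atom overlap
ratio, plus handling of the non-stereo (NS) block of standard InChIKeys.

Conventions applied throughout:

* Before scaffold extraction only the largest covalent fragment of a salt or
  mixture is kept, and stereo descriptors are stripped, so that pattern
  identity is stable at the level of molecular constitution (mirroring the
  NS-InChIKey treatment of compounds).
* The Bemis-Murcko scaffold is the classical framework: ring systems plus the
  linkers connecting them, exocyclic side chains removed, atoms and bond
  orders retained (no generic carbon-skeleton reduction).
* Acyclic molecules have no scaffold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ConsistencyError, FormatError, StructureError

RDLogger.DisableLog("rdApp.*")

#: standard InChIKey layout: 14-char skeleton block, 10-char proton/stereo
#: block, 1-char protonation flag
_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
_NS_BLOCK_RE = re.compile(r"^[A-Z]{14}$")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not isinstance(smiles, str):
        raise StructureError(str(smiles), "empty or non-string SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Idempotent; any two SMILES of the same molecule map to the same string.
    Raises :class:`StructureError` for unparseable input.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in the molecule."""
    return _mol_from_smiles(smiles).GetNumHeavyAtoms()


@dataclass(frozen=True)
class ScaffoldResult:
    """Bemis-Murcko framework of a molecule.

    ``scaffold_smiles`` is ``None`` for acyclic molecules (a framework is
    undefined without a ring); ``scaffold_heavy_atoms`` is then 0.
    """

    scaffold_smiles: Optional[str]
    scaffold_heavy_atoms: int

    @property
    def has_scaffold(self) -> bool:
        return self.scaffold_smiles is not None


def extract_scaffold(smiles: str) -> ScaffoldResult:
    """Extract the Bemis-Murcko framework of the largest fragment.

    Side chains are removed; ring systems and their connecting linkers are
    kept with original elements and bond orders. Stereochemistry is stripped
    so that stereoisomers share one pattern.
    """
    mol = _largest_fragment(_mol_from_smiles(smiles))
    Chem.RemoveStereochemistry(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumHeavyAtoms() == 0:
        return ScaffoldResult(None, 0)
    return ScaffoldResult(Chem.MolToSmiles(scaffold), scaffold.GetNumHeavyAtoms())


def overlap_ratio(pattern_smiles: str, compound_smiles: str) -> float:
    """Heavy-atom count of the pattern divided by that of the compound.

    The ratio lies in (0, 1] when the pattern is a scaffold of the compound;
    it equals 1.0 exactly when the compound is its own framework. The
    compound's heavy atoms are counted on its largest covalent fragment, the
    same structure the scaffold is extracted from.
    """
    n_pattern = heavy_atom_count(pattern_smiles)
    n_compound = _largest_fragment(_mol_from_smiles(compound_smiles)).GetNumHeavyAtoms()
    if n_pattern > n_compound:
        raise ConsistencyError(
            f"pattern has more heavy atoms ({n_pattern}) than compound "
            f"({n_compound}); not a scaffold of it"
        )
    return n_pattern / n_compound


def ns_inchikey(inchikey: str) -> str:
    """First (skeleton) block of a standard InChIKey, uppercased.

    Accepts either a full 27-character hyphenated key or an already-bare
    14-character block. The NS block encodes molecular constitution without
    stereochemistry, so stereoisomers share it.
    """
    if not isinstance(inchikey, str):
        raise FormatError(f"InChIKey must be a string, got {type(inchikey).__name__}")
    key = inchikey.strip().upper()
    if _NS_BLOCK_RE.match(key):
        return key
    if _INCHIKEY_RE.match(key):
        return key[:14]
    raise FormatError(f"malformed InChIKey: {inchikey!r}")


def is_valid_inchikey(inchikey: str) -> bool:
    """True when *inchikey* matches the standard 14-10-1 hyphenated layout."""
    return isinstance(inchikey, str) and bool(_INCHIKEY_RE.match(inchikey.strip().upper()))


@dataclass(frozen=True)
class MoleculeRecord:
    """A compound structure with its identity keys.

    ``ns_inchikey`` is always the first 14 characters of ``inchikey``;
    ``heavy_atoms`` counts non-hydrogen atoms of the full input structure.
    """

    smiles: str
    inchikey: str
    ns_inchikey: str
    heavy_atoms: int

    @classmethod
    def build(cls, smiles: str, inchikey: str) -> "MoleculeRecord":
        """Validate and canonicalize a (SMILES, InChIKey) pair."""
        key = inchikey.strip().upper()
        if not _INCHIKEY_RE.match(key):
            raise FormatError(f"malformed InChIKey: {inchikey!r}")
        canonical = canonicalize(smiles)
        return cls(
            smiles=canonical,
            inchikey=key,
            ns_inchikey=key[:14],
            heavy_atoms=heavy_atom_count(canonical),
        )
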