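"""Domain model for aaRS amino-acid recognition analysis.

Aminoacyl-tRNA synthetases (aaRSs) attach each proteinogenic amino acid to
its cognate tRNA.  This module defines the controlled vocabularies (the 22
ligand codes and synthetase labels, the two structural enzyme classes, the
seven non-covalent interaction types) and the record types shared by every
analysis stage: a single typed protein-ligand contact, a protein-ligand
complex, the editing (proofreading) table, and the analysis configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml

__all__ = [
    "LIGAND_CODES",
    "AARS_LABELS",
    "CLASS_I",
    "CLASS_II",
    "STANDARD_RESIDUES",
    "METAL_SYMBOLS",
    "InteractionType",
    "InteractionRecord",
    "StructureComplex",
    "EditingTable",
    "AnalysisConfig",
    "aars_class",
    "ligand_code_for",
    "normalize_residue_type",
    "validate_complex",
    "load_editing_table",
    "default_editing_table",
]

#: The 22 amino-acid ligand codes handled by aaRSs (20 canonical plus
#: pyrrolysine and O-phosphoserine), in fixed alphabetical order of their
#: three-letter codes.  Bit indices of the editing segment follow this order.
LIGAND_CODES: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Pyl", "Sep", "Ser", "Thr", "Trp",
    "Tyr", "Val",
)

#: Synthetase labels, one per ligand, in the same fixed order.
AARS_LABELS: tuple[str, ...] = tuple(code + "RS" for code in LIGAND_CODES)

#: Class I synthetases (Rossmann-fold catalytic domain).
CLASS_I: frozenset[str] = frozenset(
    {"ArgRS", "CysRS", "GlnRS", "GluRS", "IleRS", "LeuRS", "MetRS",
     "TrpRS", "TyrRS", "ValRS"}
)

#: Class II synthetases (antiparallel beta-sheet fold); the non-standard
#: PylRS and SepRS both belong to Class II.
CLASS_II: frozenset[str] = frozenset(
    {"AlaRS", "AsnRS", "AspRS", "GlyRS", "HisRS", "LysRS", "PheRS",
     "ProRS", "SerRS", "ThrRS", "PylRS", "SepRS"}
)

#: The 20 standard residues as three-letter codes, alphabetical; fixes the
#: bit order of the 20-dimensional binding-site composition fingerprint.
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Metal element labels accepted on the protein side of metal-complex
#: contacts (the coordinating partner is the ion itself).
METAL_SYMBOLS: frozenset[str] = frozenset(
    {"ZN", "MG", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CA", "CD"}
)

# Nonstandard residues with a known standard parent.  Anything else that is
# neither standard nor a metal maps to "UNK".
_PARENT_RESIDUE: dict[str, str] = {
    "MSE": "MET", "FME": "MET", "SEC": "CYS", "CSO": "CYS", "CME": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "HYP": "PRO", "MLY": "LYS",
    "KCX": "LYS", "PYL": "LYS",
}

KINGDOMS: tuple[str, ...] = ("bacteria", "archaea", "eukaryota", "synthetic")
REACTION_STATES: tuple[str, ...] = ("pre_activation", "post_activation")


class InteractionType(str, Enum):
    """The seven non-covalent contact types recognised by the pipeline.

    Water bridges are parsed but excluded from all statistics by default:
    water placement in crystal structures is inconsistent, so counting them
    would bias comparisons between structures solved with and without
    ordered waters.
    """

    HYDROGEN_BOND = "hydrogen_bond"
    HYDROPHOBIC = "hydrophobic"
    SALT_BRIDGE = "salt_bridge"
    PI_STACKING = "pi_stacking"
    PI_CATION = "pi_cation"
    METAL_COMPLEX = "metal_complex"
    WATER_BRIDGE = "water_bridge"


#: Interaction types entering frequency tables and fingerprints (water
#: bridges excluded).
ANALYSIS_TYPES: tuple[InteractionType, ...] = tuple(
    t for t in InteractionType if t is not InteractionType.WATER_BRIDGE
)


def aars_class(label: str) -> str:
    """Return ``"I"`` or ``"II"`` for a synthetase label."""
    if label in CLASS_I:
        return "I"
    if label in CLASS_II:
        return "II"
    raise ValueError(f"unknown aaRS label: {label!r}")


def ligand_code_for(label: str) -> str:
    """Cognate ligand code of a synthetase (``"ThrRS"`` -> ``"Thr"``)."""
    if label not in AARS_LABELS:
        raise ValueError(f"unknown aaRS label: {label!r}")
    return label[:-2]


def normalize_residue_type(code: str) -> str:
    """Map a protein-side partner label to a standard residue or metal.

    Standard three-letter codes and metal element symbols pass through;
    known nonstandard residues map to their parent; everything else becomes
    ``"UNK"``.  ``"UNK"`` never contributes to sequence-composition bits.
    """
    c = code.strip().upper()
    if c in STANDARD_RESIDUES or c in METAL_SYMBOLS:
        return c
    return _PARENT_RESIDUE.get(c, "UNK")


@dataclass(frozen=True)
class InteractionRecord:
    """One typed non-covalent contact between protein and ligand.

    ``ligand_atom_ids`` are identifiers into the complex's ligand graph.
    pi-stacking records reference all atoms of one aromatic ring.
    ``scaffold_atom_ids`` is filled by specificity assignment: the union of
    amino-acid scaffold atoms the contact maps onto over all subgraph
    isomorphisms (symmetric groups map to several atoms).
    """

    itype: InteractionType
    protein_residue_type: str
    protein_residue_number: int
    chain_id: str
    ligand_atom_ids: frozenset[str]
    midpoint: Optional[tuple[float, float, float]] = None
    scaffold_atom_ids: Optional[frozenset[str]] = None

    def with_scaffold_atoms(self, atoms: Iterable[str]) -> "InteractionRecord":
        return replace(self, scaffold_atom_ids=frozenset(atoms))

    def to_dict(self) -> dict:
        d = {
            "itype": self.itype.value,
            "protein_residue_type": self.protein_residue_type,
            "protein_residue_number": self.protein_residue_number,
            "chain_id": self.chain_id,
            "ligand_atom_ids": sorted(self.ligand_atom_ids),
        }
        if self.midpoint is not None:
            d["midpoint"] = list(self.midpoint)
        if self.scaffold_atom_ids is not None:
            d["scaffold_atom_ids"] = sorted(self.scaffold_atom_ids)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "InteractionRecord":
        return cls(
            itype=InteractionType(d["itype"]),
            protein_residue_type=d["protein_residue_type"],
            protein_residue_number=int(d["protein_residue_number"]),
            chain_id=d["chain_id"],
            ligand_atom_ids=frozenset(d["ligand_atom_ids"]),
            midpoint=tuple(d["midpoint"]) if d.get("midpoint") else None,
            scaffold_atom_ids=(
                frozenset(d["scaffold_atom_ids"])
                if d.get("scaffold_atom_ids") is not None else None
            ),
        )


@dataclass
class StructureComplex:
    """One synthetase chain with its amino-acid-bearing ligand.

    ``reaction_state`` distinguishes complexes crystallised with the free
    amino acid (pre-activation) from those with the aminoacyl-adenylate or a
    non-hydrolysable analog (post-activation).  ``cavity_volume`` is the
    volume of the specificity-conferring binding-site moiety in cubic
    angstroms, computed externally.
    """

    structure_id: str
    aars: str
    ligand_graph: "MolecularGraph"  # noqa: F821 - defined in .scaffolds
    interactions: list[InteractionRecord] = field(default_factory=list)
    reaction_state: str = "pre_activation"
    kingdom: str = "synthetic"
    cavity_volume: Optional[float] = None
    coordinates: Optional[dict[str, np.ndarray]] = None

    @property
    def aars_class(self) -> str:
        return aars_class(self.aars)

    @property
    def ligand_code(self) -> str:
        return ligand_code_for(self.aars)


def _is_single_ring(atom_ids: frozenset[str], graph) -> bool:
    """True if the atoms induce one simple cycle of size >= 5 in the graph."""
    if len(atom_ids) < 5:
        return False
    sub_edges = [b for b in graph.bonds if set(b) <= atom_ids]
    if len(sub_edges) != len(atom_ids):
        return False
    deg: dict[str, int] = {a: 0 for a in atom_ids}
    for b in sub_edges:
        for a in b:
            deg[a] += 1
    if any(d != 2 for d in deg.values()):
        return False
    # connectivity: walk the cycle
    adj: dict[str, list[str]] = {a: [] for a in atom_ids}
    for b in sub_edges:
        u, v = tuple(b)
        adj[u].append(v)
        adj[v].append(u)
    seen = set()
    stack = [next(iter(atom_ids))]
    while stack:
        a = stack.pop()
        if a in seen:
            continue
        seen.add(a)
        stack.extend(adj[a])
    return seen == set(atom_ids)


def validate_complex(c: StructureComplex) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Validation never raises: an empty list means the complex is well formed.
    """
    violations: list[str] = []
    if c.aars not in AARS_LABELS:
        violations.append(f"aars: unknown label {c.aars!r}")
    if c.reaction_state not in REACTION_STATES:
        violations.append(f"reaction_state: unknown state {c.reaction_state!r}")
    if c.kingdom not in KINGDOMS:
        violations.append(f"kingdom: unknown kingdom {c.kingdom!r}")
    if c.cavity_volume is not None and not c.cavity_volume > 0:
        violations.append(
            f"cavity_volume: must be > 0 Å³, got {c.cavity_volume}"
        )
    graph_atoms = set(c.ligand_graph.atom_ids())
    for i, rec in enumerate(c.interactions):
        if not rec.ligand_atom_ids:
            violations.append(f"interactions[{i}].ligand_atom_ids: empty set")
            continue
        missing = rec.ligand_atom_ids - graph_atoms
        if missing:
            violations.append(
                f"interactions[{i}].ligand_atom_ids: not in ligand graph: "
                f"{sorted(missing)}"
            )
            continue
        if rec.itype is InteractionType.PI_STACKING and not _is_single_ring(
            rec.ligand_atom_ids, c.ligand_graph
        ):
            violations.append(
                f"interactions[{i}]: pi_stacking must reference all atoms "
                f"of one aromatic ring, got {sorted(rec.ligand_atom_ids)}"
            )
    return violations


@dataclass(frozen=True)
class EditingTable:
    """Which ligands each synthetase hydrolytically proofreads against.

    Several aaRSs possess pre- or post-transfer editing activity that
    deacylates near-cognate amino acids.  One active editing bit per edited
    ligand enters the fingerprint's 22-bit editing segment.
    """

    mapping: Mapping[str, frozenset[str]]

    def targets(self, aars: str) -> frozenset[str]:
        return self.mapping.get(aars, frozenset())


def _parse_editing_mapping(raw: Mapping) -> EditingTable:
    mapping: dict[str, frozenset[str]] = {}
    for key, values in (raw or {}).items():
        if key not in AARS_LABELS:
            raise ValueError(f"editing table: unknown aaRS label {key!r}")
        codes = frozenset(values or ())
        bad = codes - set(LIGAND_CODES)
        if bad:
            raise ValueError(
                f"editing table entry {key}: unknown ligand codes {sorted(bad)}"
            )
        mapping[key] = codes
    return EditingTable(mapping=mapping)


def load_editing_table(path: str | Path) -> EditingTable:
    """Load an editing table from a YAML or JSON mapping file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"editing table {path}: expected a mapping at top level")
    return _parse_editing_mapping(raw)


def default_editing_table() -> EditingTable:
    """The bundled approximate editing table.

    Editing-target sets follow the proofreading literature but are an
    approximation restricted to the 22-code ligand vocabulary (e.g. the
    non-proteinogenic targets norvaline and homocysteine cannot be
    encoded); users with better curation should supply their own file.
    """
    return load_editing_table(
        Path(__file__).parent / "data" / "editing_default.yaml"
    )


@dataclass
class AnalysisConfig:
    """Tunable constants of the pipeline with the study defaults."""

    occupancy_cutoff: float = 0.1
    volume_bin_start: float = 30.0
    volume_bin_stop: float = 270.0
    volume_bin_step: float = 20.0
    hash_bits: int = 500
    n_neighbors: int = 60
    min_dist: float = 0.1
    n_components: int = 2
    identity_threshold: float = 0.95
    random_seed: int = 0

    def __post_init__(self) -> None:
        span = self.volume_bin_stop - self.volume_bin_start
        n = span / self.volume_bin_step
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ValueError(
                "volume bins: (stop - start)/step must be a positive integer"
            )

    @property
    def n_volume_bins(self) -> int:
        return round(
            (self.volume_bin_stop - self.volume_bin_start) / self.volume_bin_step
        )
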