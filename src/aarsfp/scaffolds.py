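"""Amino-acid scaffold graphs and subgraph-isomorphism matching.

Only contacts with the amino-acid substructure of the ligand confer
specificity; contacts with the adenosine/phosphate moiety of an
aminoacyl-adenylate bind the shared ATP scaffold instead.  Each amino acid
is therefore represented as a heavy-atom "scaffold" graph with the carboxyl
hydroxyl removed (that hydroxyl is cleaved during activation and absent
from reaction products), and the scaffold is matched into the full ligand
graph by subgraph isomorphism.  Matching compares elements and connectivity
only: bond orders and aromaticity flags are deliberately ignored so that
AMP esters and sulfamoyl analogs match the same scaffold despite divergent
dictionary conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

import networkx as nx
from networkx.algorithms import isomorphism

from .core import (
    LIGAND_CODES,
    InteractionRecord,
    InteractionType,
    StructureComplex,
)

__all__ = [
    "Atom",
    "MolecularGraph",
    "AtomMapping",
    "ScaffoldMatchError",
    "build_scaffold",
    "find_subgraph_isomorphisms",
    "scaffold_atom_union",
    "assign_specificity_interactions",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# Ligand code -> chemical component dictionary id for the scaffold template.
_CCD_IDS = {code: code.upper() for code in LIGAND_CODES}


@dataclass(frozen=True)
class Atom:
    atom_id: str
    element: str
    name: Optional[str] = None
    role: str = "other"  # backbone | side_chain | other


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of a ligand or amino-acid scaffold.

    Hydrogen-free; bonds are unordered atom-id pairs.  Immutable and
    hashable so matching results can be memoised per unique graph.
    """

    atoms: tuple[Atom, ...]
    bonds: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        ids = {a.atom_id for a in self.atoms}
        if len(ids) != len(self.atoms):
            raise ValueError("duplicate atom ids in graph")
        for bond in self.bonds:
            if len(bond) != 2 or not bond <= ids:
                raise ValueError(f"bond endpoints not in graph: {sorted(bond)}")

    def atom_ids(self) -> tuple[str, ...]:
        return tuple(a.atom_id for a in self.atoms)

    def element_of(self, atom_id: str) -> str:
        return self._elements()[atom_id]

    def _elements(self) -> dict[str, str]:
        return {a.atom_id: a.element for a in self.atoms}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.atom_id, element=a.element, role=a.role)
        g.add_edges_from(tuple(b) for b in self.bonds)
        return g

    @classmethod
    def from_tables(
        cls,
        atoms: Iterable[tuple],
        bonds: Iterable[tuple[str, str]],
    ) -> "MolecularGraph":
        """Build from (atom_id, element[, name[, role]]) rows and bond pairs."""
        atom_objs = []
        for row in atoms:
            atom_id, element = row[0], row[1]
            name = row[2] if len(row) > 2 else None
            role = row[3] if len(row) > 3 else "other"
            atom_objs.append(Atom(str(atom_id), str(element), name, role))
        bond_set = frozenset(frozenset((str(u), str(v))) for u, v in bonds)
        return cls(atoms=tuple(atom_objs), bonds=bond_set)


@dataclass(frozen=True)
class AtomMapping:
    """Injective, element- and bond-preserving scaffold -> ligand map."""

    assignment: tuple[tuple[str, str], ...]  # sorted (scaffold_id, ligand_id)

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)


class ScaffoldMatchError(ValueError):
    """Raised when a scaffold has no embedding in a ligand graph."""


@lru_cache(maxsize=None)
def build_scaffold(ligand_code: str) -> MolecularGraph:
    """Heavy-atom scaffold graph of an amino-acid ligand.

    Built from the chemical component dictionary entry bundled with
    biotite: hydrogens are stripped and the carboxyl hydroxyl oxygen (OXT)
    removed; the carbonyl oxygen is retained.  Backbone atoms (N, CA, C, O)
    carry the ``backbone`` role, all others ``side_chain``.
    """
    if ligand_code not in LIGAND_CODES:
        raise ValueError(f"unknown ligand code: {ligand_code!r}")
    import biotite.structure.info as struc_info

    residue = struc_info.residue(_CCD_IDS[ligand_code])
    keep = [
        i
        for i in range(residue.array_length())
        if residue.element[i] not in ("H", "D")
        and residue.atom_name[i] != "OXT"
    ]
    names = [str(residue.atom_name[i]) for i in keep]
    atoms = tuple(
        Atom(
            atom_id=name,
            element=str(residue.element[i]),
            name=name,
            role="backbone" if name in BACKBONE_ATOMS else "side_chain",
        )
        for i, name in zip(keep, names)
    )
    keep_set = set(keep)
    index_to_name = {i: str(residue.atom_name[i]) for i in keep}
    bonds = frozenset(
        frozenset((index_to_name[u], index_to_name[v]))
        for u, v, _order in residue.bonds.as_array()
        if u in keep_set and v in keep_set
    )
    return MolecularGraph(atoms=atoms, bonds=bonds)


def find_subgraph_isomorphisms(
    pattern: MolecularGraph, target: MolecularGraph
) -> list[AtomMapping]:
    """All element- and bond-preserving injections of pattern into target.

    Subgraph *monomorphisms*: every pattern bond must map onto a target
    bond, but target atoms may carry extra bonds (the scaffold sits inside
    a larger ligand).  The result is exactly deduplicated and sorted
    lexicographically by assignment, so enumeration order is deterministic.
    """
    if not pattern.atoms:
        raise ValueError("pattern graph is empty")
    matcher = isomorphism.GraphMatcher(
        target.to_networkx(),
        pattern.to_networkx(),
        node_match=isomorphism.categorical_node_match("element", None),
    )
    seen: set[tuple[tuple[str, str], ...]] = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        # networkx yields target -> pattern; invert to scaffold -> ligand
        assignment = tuple(sorted((p, t) for t, p in mapping.items()))
        seen.add(assignment)
    return [AtomMapping(a) for a in sorted(seen)]


@lru_cache(maxsize=None)
def scaffold_atom_union(
    ligand_code: str, ligand_graph: MolecularGraph
) -> dict[str, frozenset[str]]:
    """Map each ligand atom to the scaffold atoms it represents.

    The union runs over *all* isomorphisms, so ligand atoms in symmetric
    groups (e.g. the two valine methyls) map to every automorphic scaffold
    position.  Raises :class:`ScaffoldMatchError` when the scaffold does
    not embed at all.
    """
    scaffold = build_scaffold(ligand_code)
    mappings = find_subgraph_isomorphisms(scaffold, ligand_graph)
    if not mappings:
        raise ScaffoldMatchError(
            f"scaffold {ligand_code} has no embedding in the ligand graph"
        )
    union: dict[str, set[str]] = {}
    for m in mappings:
        for scaffold_atom, ligand_atom in m.assignment:
            union.setdefault(ligand_atom, set()).add(scaffold_atom)
    return {k: frozenset(v) for k, v in union.items()}


def assign_specificity_interactions(
    c: StructureComplex,
) -> list[InteractionRecord]:
    """Restrict a complex's contacts to the amino-acid substructure.

    Each retained record is annotated with the union of scaffold atoms its
    ligand atoms map onto over all subgraph isomorphisms (ambiguous matches
    on symmetric groups are assigned to multiple atoms).  Records touching
    only non-substructure atoms (adenosine/phosphate moiety) are dropped.

    Raises :class:`ScaffoldMatchError` when the cognate scaffold has no
    embedding, which signals a wrong ligand or a corrupt graph.
    """
    try:
        union = scaffold_atom_union(c.ligand_code, c.ligand_graph)
    except ScaffoldMatchError as err:
        raise ScaffoldMatchError(f"{c.structure_id}: {err}") from None
    retained: list[InteractionRecord] = []
    for rec in c.interactions:
        scaffold_atoms: set[str] = set()
        for ligand_atom in rec.ligand_atom_ids:
            scaffold_atoms |= union.get(ligand_atom, frozenset())
        if scaffold_atoms:
            retained.append(rec.with_scaffold_atoms(scaffold_atoms))
    return retained


def ensure_assigned(c: StructureComplex) -> list[InteractionRecord]:
    """Return specificity-assigned records, assigning on demand."""
    if all(r.scaffold_atom_ids is not None for r in c.interactions) and c.interactions:
        return c.interactions
    return assign_specificity_interactions(c)


def analysis_records(c: StructureComplex) -> list[InteractionRecord]:
    """Specificity-assigned records minus water bridges (default filter)."""
    return [
        r for r in ensure_assigned(c) if r.itype is not InteractionType.WATER_BRIDGE
    ]
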