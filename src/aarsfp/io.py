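"""Readers and writers for the external formats the pipeline touches.

Supported inputs: PLIP XML interaction reports (the subset of elements the
analysis needs), FASTA multiple sequence alignments, ligand coordinates
from PDB files or plain coordinate tables, and the package's own JSON
complex tables.  Residue numbering is taken verbatim from files (author
numbering); unified renumbering happens later via the curation module.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import etree

from .core import InteractionRecord, InteractionType, StructureComplex
from .scaffolds import MolecularGraph

logger = logging.getLogger(__name__)

__all__ = [
    "read_plip_report",
    "write_plip_report",
    "read_msa",
    "read_coordinates",
    "complex_to_dict",
    "complex_from_dict",
    "write_complexes",
    "read_complexes",
]

# PLIP report element -> interaction type; only these are consumed, extra
# report content is tolerated silently.
_PLIP_SECTIONS = {
    "hydrogen_bonds": ("hydrogen_bond", InteractionType.HYDROGEN_BOND),
    "hydrophobic_interactions": ("hydrophobic_interaction", InteractionType.HYDROPHOBIC),
    "salt_bridges": ("salt_bridge", InteractionType.SALT_BRIDGE),
    "pi_stacks": ("pi_stack", InteractionType.PI_STACKING),
    "pi_cation_interactions": ("pi_cation_interaction", InteractionType.PI_CATION),
    "metal_complexes": ("metal_complex", InteractionType.METAL_COMPLEX),
    "water_bridges": ("water_bridge", InteractionType.WATER_BRIDGE),
}

_KNOWN_SECTION_TAGS = frozenset(_PLIP_SECTIONS)


def _text(el, tag) -> Optional[str]:
    child = el.find(tag)
    return child.text.strip() if child is not None and child.text else None


def _ligand_atom_ids(el, itype: InteractionType) -> frozenset[str]:
    """Extract ligand atom identifiers from one PLIP contact element."""
    idx_list = el.find("lig_idx_list")
    if idx_list is not None:
        return frozenset(
            i.text.strip() for i in idx_list.findall("idx") if i.text
        )
    if itype in (InteractionType.HYDROGEN_BOND, InteractionType.WATER_BRIDGE):
        protisdon = (_text(el, "protisdon") or "").lower() == "true"
        tag = "acceptoridx" if protisdon else "donoridx"
        val = _text(el, tag)
        return frozenset({val}) if val else frozenset()
    if itype is InteractionType.HYDROPHOBIC:
        val = _text(el, "ligcarbonidx")
        return frozenset({val}) if val else frozenset()
    if itype is InteractionType.METAL_COMPLEX:
        location = (_text(el, "location") or "").lower()
        val = _text(el, "target_idx")
        if val and location in ("", "ligand"):
            return frozenset({val})
        return frozenset()
    return frozenset()


def _midpoint(el) -> Optional[tuple[float, float, float]]:
    for tag in ("ligcoo", "refcoo"):
        coo = el.find(tag)
        if coo is not None:
            try:
                return tuple(float(_text(coo, ax)) for ax in "xyz")  # type: ignore[return-value]
            except (TypeError, ValueError):
                return None
    return None


def read_plip_report(path: str | Path) -> list[InteractionRecord]:
    """Parse a PLIP XML report into interaction records.

    One record per contact.  Unknown interaction section tags are skipped
    with a logged warning; contacts without resolvable ligand atom serials
    are skipped with a warning.  Water-bridge records are returned and left
    for downstream stages to exclude by default.
    """
    tree = etree.parse(str(path))  # malformed XML raises here
    records: list[InteractionRecord] = []
    for interactions_el in tree.iter("interactions"):
        for section in interactions_el:
            if not isinstance(section.tag, str):
                continue
            if section.tag not in _KNOWN_SECTION_TAGS:
                if len(section):
                    logger.warning(
                        "PLIP report %s: skipping unknown interaction "
                        "section <%s>", path, section.tag,
                    )
                continue
            child_tag, itype = _PLIP_SECTIONS[section.tag]
            for contact in section.findall(child_tag):
                restype = _text(contact, "restype")
                resnr = _text(contact, "resnr")
                chain = _text(contact, "reschain") or ""
                if itype is InteractionType.METAL_COMPLEX:
                    metal = _text(contact, "metal_type")
                    if metal:
                        restype = metal.upper()
                atom_ids = _ligand_atom_ids(contact, itype)
                if not atom_ids:
                    logger.warning(
                        "PLIP report %s: skipping %s contact without ligand "
                        "atom serials", path, itype.value,
                    )
                    continue
                records.append(
                    InteractionRecord(
                        itype=itype,
                        protein_residue_type=(restype or "UNK").upper(),
                        protein_residue_number=int(resnr) if resnr else 0,
                        chain_id=chain,
                        ligand_atom_ids=atom_ids,
                        midpoint=_midpoint(contact),
                    )
                )
    return records


def write_plip_report(records, path: str | Path, site_name: str = "LIG:A:1") -> None:
    """Write records as a minimal PLIP-style XML report (testing aid)."""
    root = etree.Element("report")
    site = etree.SubElement(root, "bindingsite")
    etree.SubElement(site, "identifiers").text = site_name
    inter = etree.SubElement(site, "interactions")
    sections = {tag: etree.SubElement(inter, tag) for tag in _PLIP_SECTIONS}
    by_type = {itype: tag for tag, (_c, itype) in _PLIP_SECTIONS.items()}
    for rec in records:
        tag = by_type[rec.itype]
        child_tag, _ = _PLIP_SECTIONS[tag]
        el = etree.SubElement(sections[tag], child_tag)
        etree.SubElement(el, "restype").text = rec.protein_residue_type
        etree.SubElement(el, "resnr").text = str(rec.protein_residue_number)
        etree.SubElement(el, "reschain").text = rec.chain_id
        if rec.itype is InteractionType.METAL_COMPLEX:
            etree.SubElement(el, "metal_type").text = rec.protein_residue_type
        idx_list = etree.SubElement(el, "lig_idx_list")
        for atom in sorted(rec.ligand_atom_ids):
            etree.SubElement(idx_list, "idx").text = atom
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def read_msa(path: str | Path) -> MultipleSeqAlignment:
    """Read a FASTA alignment; all rows must have equal gapped length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    width = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != width:
            raise ValueError(
                f"{path}: ragged alignment, sequence {rec.id!r} has length "
                f"{len(rec.seq)} != {width}"
            )
    return MultipleSeqAlignment(
        [SeqRecord(Seq(str(r.seq)), id=r.id, description="") for r in records]
    )


def read_coordinates(
    path: str | Path, ligand_name: Optional[str] = None
) -> dict[str, np.ndarray]:
    """Read ligand atom coordinates (angstroms) keyed by atom name.

    Accepts a PDB/mmCIF file (``ligand_name`` selects the residue) or a
    CSV table with columns ``atom_id,x,y,z``.  A duplicate atom name wins
    last with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif"):
        return _read_coordinates_structure(path, ligand_name)
    import pandas as pd

    table = pd.read_csv(path)
    required = {"atom_id", "x", "y", "z"}
    if not required <= set(table.columns):
        raise ValueError(
            f"{path}: coordinate table needs columns {sorted(required)}"
        )
    coords: dict[str, np.ndarray] = {}
    for row in table.itertuples(index=False):
        atom_id = str(row.atom_id)
        if atom_id in coords:
            warnings.warn(f"{path}: duplicate atom id {atom_id!r}, last wins")
        coords[atom_id] = np.array([row.x, row.y, row.z], dtype=float)
    return coords


def _read_coordinates_structure(
    path: Path, ligand_name: Optional[str]
) -> dict[str, np.ndarray]:
    import gemmi

    structure = gemmi.read_structure(str(path))
    coords: dict[str, np.ndarray] = {}
    for model in structure:
        for chain in model:
            for residue in chain:
                if ligand_name is not None and residue.name != ligand_name:
                    continue
                for atom in residue:
                    if atom.name in coords:
                        warnings.warn(
                            f"{path}: duplicate atom name {atom.name!r}, last wins"
                        )
                    coords[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
        break  # first model only
    if not coords:
        raise ValueError(f"{path}: ligand {ligand_name!r} not found")
    return coords


# ---------------------------------------------------------------------------
# Internal tabular complex format (JSON); write -> read is the identity.

def complex_to_dict(c: StructureComplex) -> dict:
    d = {
        "structure_id": c.structure_id,
        "aars": c.aars,
        "reaction_state": c.reaction_state,
        "kingdom": c.kingdom,
        "cavity_volume": c.cavity_volume,
        "ligand_graph": {
            "atoms": [
                [a.atom_id, a.element, a.name, a.role]
                for a in c.ligand_graph.atoms
            ],
            "bonds": sorted(sorted(b) for b in c.ligand_graph.bonds),
        },
        "interactions": [r.to_dict() for r in c.interactions],
    }
    if c.coordinates is not None:
        d["coordinates"] = {
            k: [float(x) for x in v] for k, v in c.coordinates.items()
        }
    return d


def complex_from_dict(d: Mapping) -> StructureComplex:
    graph = MolecularGraph.from_tables(
        atoms=d["ligand_graph"]["atoms"], bonds=d["ligand_graph"]["bonds"]
    )
    coords = None
    if d.get("coordinates") is not None:
        coords = {k: np.asarray(v, dtype=float) for k, v in d["coordinates"].items()}
    return StructureComplex(
        structure_id=d["structure_id"],
        aars=d["aars"],
        ligand_graph=graph,
        interactions=[InteractionRecord.from_dict(r) for r in d["interactions"]],
        reaction_state=d.get("reaction_state", "pre_activation"),
        kingdom=d.get("kingdom", "synthetic"),
        cavity_volume=d.get("cavity_volume"),
        coordinates=coords,
    )


def write_complexes(complexes, path: str | Path) -> None:
    payload = [complex_to_dict(c) for c in complexes]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_complexes(path: str | Path) -> list[StructureComplex]:
    payload = json.loads(Path(path).read_text())
    return [complex_from_dict(d) for d in payload]
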