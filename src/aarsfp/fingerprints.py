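"""Segmented binary interaction fingerprints and Jaccard distances.

Each protein-ligand complex is condensed into a structure-invariant binary
vector with up to four segments:

``seq`` (20 bits)
    binding-site composition: one bit per standard residue type observed
    among interacting residues (multiplicity ignored).
``int`` (500 bits)
    hashed interaction features.  A feature is the triple (interaction
    type, interacting ligand group, protein residue type), e.g. a hydrogen
    bond between a ligand oxygen and tyrosine; the ligand group is the
    element of the contacted scaffold atom, or ``ring`` for pi-stacking.
    Features are hashed (FNV-1a 64-bit) to a bit index between 1 and 500.
``editing`` (22 bits)
    one bit per ligand the synthetase proofreads against.
``volume`` (12 bits)
    one-hot binned binding-cavity volume, 30-270 A^3 in 20 A^3 steps with
    clamping, so the full concatenation is 500 + 22 + 12 = 534 bits.

The published fingerprint design never names its hash function, so bit
*indices* here are implementation-specific while distances are not: the
Jaccard distance d(a, b) = 1 - |a AND b| / (|a| + |b| - |a AND b|) only
depends on co-activation patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    AnalysisConfig,
    EditingTable,
    InteractionType,
    LIGAND_CODES,
    METAL_SYMBOLS,
    STANDARD_RESIDUES,
    StructureComplex,
    default_editing_table,
    normalize_residue_type,
)
from .scaffolds import analysis_records, build_scaffold

__all__ = [
    "SEGMENT_WIDTHS",
    "VARIANTS",
    "Fingerprint",
    "fnv1a_64",
    "feature_bit",
    "fp_seq",
    "fp_int",
    "fp_editing",
    "fp_volume",
    "fp_concat",
    "build_fingerprint",
    "jaccard_distance",
    "distance_matrix",
    "hash_collision_diagnostic",
]

SEGMENT_WIDTHS: dict[str, int] = {"seq": 20, "int": 500, "editing": 22, "volume": 12}

# Segment concatenation order is fixed; a variant names which segments are
# present.  The "Seq, Int" family relies on the hashed 500-bit segment
# (residue type is already part of every hashed feature), while Seq_sim is
# the standalone 20-bit composition baseline.
VARIANTS: dict[str, tuple[str, ...]] = {
    "Seq_sim": ("seq",),
    "Seq+Int": ("int",),
    "Seq+Int+Ed": ("int", "editing"),
    "Seq+Int+Ed+Vol": ("int", "editing", "volume"),
    "Ed": ("editing",),
    "Vol": ("volume",),
}

_SEGMENT_ORDER = ("seq", "int", "editing", "volume")


@dataclass(frozen=True)
class Fingerprint:
    """Binary fingerprint with a named segment layout."""

    bits: np.ndarray  # bool vector
    variant: str

    def __post_init__(self) -> None:
        segments = VARIANTS.get(self.variant)
        if segments is None:
            raise ValueError(f"unknown variant {self.variant!r}")
        expected = sum(SEGMENT_WIDTHS[s] for s in segments)
        if self.bits.shape != (expected,):
            raise ValueError(
                f"variant {self.variant} needs {expected} bits, "
                f"got {self.bits.shape}"
            )
        object.__setattr__(self, "bits", self.bits.astype(bool))

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def n_active(self) -> int:
        return int(self.bits.sum())

    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def segment(self, name: str) -> np.ndarray:
        offset = 0
        for seg in VARIANTS[self.variant]:
            width = SEGMENT_WIDTHS[seg]
            if seg == name:
                return self.bits[offset:offset + width]
            offset += width
        raise KeyError(f"variant {self.variant} has no segment {name!r}")

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_bitstring(cls, s: str, variant: str) -> "Fingerprint":
        return cls(np.array([ch == "1" for ch in s]), variant)


def fnv1a_64(data: str) -> int:
    """FNV-1a 64-bit hash of a UTF-8 string."""
    h = 0xCBF29CE484222325
    for byte in data.encode("utf-8"):
        h ^= byte
        h = (h * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def feature_bit(
    itype: InteractionType, ligand_group: str, residue: str, hash_bits: int = 500
) -> int:
    """1-based bit index of one interaction feature."""
    feature = f"{itype.value}|{ligand_group}|{residue}".lower()
    return fnv1a_64(feature) % hash_bits + 1


def _interacting_residues(records) -> set[str]:
    residues = set()
    for rec in records:
        res = normalize_residue_type(rec.protein_residue_type)
        if res in STANDARD_RESIDUES:
            residues.add(res)
    return residues


def fp_seq(c: StructureComplex) -> np.ndarray:
    """20-bit binding-site composition segment.

    One bit per standard residue type among specificity-interacting
    residues; multiple occurrences of a type set the same single bit.
    Metals and unknown residues set no bit.
    """
    bits = np.zeros(SEGMENT_WIDTHS["seq"], dtype=bool)
    for res in _interacting_residues(analysis_records(c)):
        bits[STANDARD_RESIDUES.index(res)] = True
    return bits


def _record_groups(rec) -> list[str]:
    """Ligand-side group labels of a record: one per assigned scaffold atom
    (element symbol), or the pseudo-group ``ring`` for pi interactions."""
    if rec.itype in (InteractionType.PI_STACKING, InteractionType.PI_CATION):
        return ["ring"]
    scaffold = rec.scaffold_atom_ids or frozenset()
    return sorted({_SCAFFOLD_ELEMENTS[a] for a in scaffold if a in _SCAFFOLD_ELEMENTS})


# element lookup over all scaffold atom names (built lazily on first use)
class _ScaffoldElements:
    def __init__(self) -> None:
        self._table: Optional[dict[str, str]] = None

    def _build(self) -> dict[str, str]:
        table: dict[str, str] = {}
        for code in LIGAND_CODES:
            for atom in build_scaffold(code).atoms:
                table[atom.atom_id] = atom.element.lower()
        return table

    def __contains__(self, atom_id: str) -> bool:
        if self._table is None:
            self._table = self._build()
        return atom_id in self._table

    def __getitem__(self, atom_id: str) -> str:
        if self._table is None:
            self._table = self._build()
        return self._table[atom_id]


_SCAFFOLD_ELEMENTS = _ScaffoldElements()


def fp_int(c: StructureComplex, hash_bits: int = 500) -> np.ndarray:
    """Hashed 500-bit interaction segment.

    Each record contributes one feature per assigned scaffold atom
    (interaction type, atom element, residue type); duplicate features are
    idempotent.  Bit index = FNV-1a(feature) mod 500, 1-based.
    """
    bits = np.zeros(hash_bits, dtype=bool)
    for rec in analysis_records(c):
        residue = normalize_residue_type(rec.protein_residue_type).lower()
        for group in _record_groups(rec):
            bits[feature_bit(rec.itype, group, residue, hash_bits) - 1] = True
    return bits


def fp_editing(aars: str, table: Optional[EditingTable] = None) -> np.ndarray:
    """22-bit editing segment: one bit per proofread ligand."""
    if table is None:
        table = default_editing_table()
    bits = np.zeros(SEGMENT_WIDTHS["editing"], dtype=bool)
    for code in table.targets(aars):
        bits[LIGAND_CODES.index(code)] = True
    return bits


def fp_volume(volume: float, config: Optional[AnalysisConfig] = None) -> np.ndarray:
    """One-hot 12-bit cavity-volume segment.

    Half-open bins [30 + 20(k-1), 30 + 20k) A^3; volumes below 30 clamp to
    bin 1 and volumes >= 270 to bin 12, so exactly one bit is active.
    """
    if not volume > 0:
        raise ValueError(f"cavity volume must be > 0 Å³, got {volume}")
    cfg = config or AnalysisConfig()
    n_bins = cfg.n_volume_bins
    k = floor((volume - cfg.volume_bin_start) / cfg.volume_bin_step) + 1
    k = min(max(k, 1), n_bins)
    bits = np.zeros(n_bins, dtype=bool)
    bits[k - 1] = True
    return bits


def fp_concat(segments: Mapping[str, np.ndarray], variant: str) -> Fingerprint:
    """Concatenate named segments in fixed order for a variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    parts = []
    for name in VARIANTS[variant]:
        if name not in segments:
            raise ValueError(f"variant {variant} requires missing segment {name!r}")
        seg = np.asarray(segments[name], dtype=bool)
        if seg.shape != (SEGMENT_WIDTHS[name],):
            raise ValueError(
                f"segment {name} must have {SEGMENT_WIDTHS[name]} bits"
            )
        parts.append(seg)
    assert tuple(VARIANTS[variant]) == tuple(
        s for s in _SEGMENT_ORDER if s in VARIANTS[variant]
    )
    return Fingerprint(np.concatenate(parts), variant)


def build_fingerprint(
    c: StructureComplex,
    variant: str = "Seq+Int+Ed+Vol",
    editing_table: Optional[EditingTable] = None,
    config: Optional[AnalysisConfig] = None,
) -> Fingerprint:
    """Build a fingerprint of the given design for one complex."""
    needed = VARIANTS.get(variant)
    if needed is None:
        raise ValueError(f"unknown variant {variant!r}")
    segments: dict[str, np.ndarray] = {}
    if "seq" in needed:
        segments["seq"] = fp_seq(c)
    if "int" in needed:
        segments["int"] = fp_int(c, (config or AnalysisConfig()).hash_bits)
    if "editing" in needed:
        segments["editing"] = fp_editing(c.aars, editing_table)
    if "volume" in needed:
        if c.cavity_volume is None:
            raise ValueError(
                f"variant {variant} needs a cavity volume, but "
                f"{c.structure_id} has none"
            )
        segments["volume"] = fp_volume(c.cavity_volume, config)
    return fp_concat(segments, variant)


def jaccard_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard distance between two fingerprints of the same design.

    d = 1 - n_ab / (n_a + n_b - n_ab); two all-zero fingerprints are
    indistinguishable and get distance 0.
    """
    if a.variant != b.variant or len(a) != len(b):
        raise ValueError(
            f"fingerprint mismatch: {a.variant}({len(a)}) vs "
            f"{b.variant}({len(b)})"
        )
    n_ab = int(np.sum(a.bits & b.bits))
    denom = a.n_active + b.n_active - n_ab
    if denom == 0:
        return 0.0
    return 1.0 - n_ab / denom


def distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Symmetric pairwise Jaccard distance matrix."""
    variants = {fp.variant for fp in fps}
    if len(variants) > 1:
        raise ValueError(f"mixed fingerprint variants: {sorted(variants)}")
    bits = np.stack([fp.bits for fp in fps]).astype(np.float64)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dm = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(dm, 0.0)
    return np.clip(dm, 0.0, 1.0)


def _realizable_features() -> list[str]:
    """The finite vocabulary of features the pipeline can actually emit.

    Hydrogen bonds involve N/O/S ligand atoms; hydrophobic contacts carbon;
    salt bridges charged N/O groups; pi interactions the ring pseudo-group;
    metal complexes N/O/S coordination with a metal on the protein side.
    """
    residues = [r.lower() for r in STANDARD_RESIDUES]
    metals = sorted(m.lower() for m in METAL_SYMBOLS)
    combos: list[tuple[InteractionType, list[str], list[str]]] = [
        (InteractionType.HYDROGEN_BOND, ["n", "o", "s"], residues),
        (InteractionType.HYDROPHOBIC, ["c"], residues),
        (InteractionType.SALT_BRIDGE, ["n", "o"], residues),
        (InteractionType.PI_STACKING, ["ring"], residues),
        (InteractionType.PI_CATION, ["ring"], residues),
        (InteractionType.METAL_COMPLEX, ["n", "o", "s"], metals),
    ]
    features = []
    for itype, groups, partners in combos:
        for g in groups:
            for res in partners:
                features.append(f"{itype.value}|{g}|{res}")
    return features


def hash_collision_diagnostic(hash_bits: int = 500) -> dict[str, float]:
    """Hash-collision statistics over the realizable feature vocabulary.

    Reports the number of features, distinct bits used, and the fraction
    of feature pairs mapping to the same bit (the collision rate relevant
    to Jaccard distances).
    """
    features = _realizable_features()
    indices = [fnv1a_64(f) % hash_bits + 1 for f in features]
    n = len(features)
    counts: dict[int, int] = {}
    for idx in indices:
        counts[idx] = counts.get(idx, 0) + 1
    colliding_pairs = sum(c * (c - 1) // 2 for c in counts.values())
    total_pairs = n * (n - 1) // 2
    return {
        "n_features": float(n),
        "n_distinct_bits": float(len(counts)),
        "pair_collision_rate": colliding_pairs / total_pairs,
    }
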