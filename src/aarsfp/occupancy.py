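"""Occupancy profiles, class frequency tables, and group statistics.

Occupancy of a (scaffold atom, interaction type) pair is the fraction of a
synthetase's structures in which that contact is observed at least once;
sparse contacts below a cutoff (default 0.1) are treated as crystallographic
noise and dropped.  Class-level frequency tables count individual contacts
instead of structures.  Water bridges never enter either statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    ANALYSIS_TYPES,
    InteractionType,
    StructureComplex,
    normalize_residue_type,
)
from .scaffolds import BACKBONE_ATOMS, analysis_records, build_scaffold

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyProfile",
    "ClassFrequencyTable",
    "SideChainContact",
    "compute_occupancy",
    "class_frequency_table",
    "class_frequency_from_counts",
    "summarize_side_chain_recognition",
    "residue_count_ligand_size_correlation",
    "mann_whitney_u",
    "spearman_rho",
    "round_half_up",
    "PHASE_TRANSFER_DG",
    "physicochemical_distances",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (5 always rounds away from zero)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-atom contact occupancies for one synthetase.

    ``entries`` maps (scaffold atom id, interaction type) to the fraction
    of structures showing that contact; retained entries are >= the cutoff.
    """

    aars: str
    n_structures: int
    cutoff: float
    entries: Mapping[tuple[str, InteractionType], float]


def compute_occupancy(
    complexes: Sequence[StructureComplex], cutoff: float = 0.1
) -> OccupancyProfile:
    """Occupancy profile over one synthetase's structures.

    A contact is counted once per structure per (atom, type) pair, so
    duplicate records within a structure do not inflate occupancy.
    Entries with occupancy strictly below ``cutoff`` are neglected.
    """
    if not complexes:
        raise ValueError("need at least one complex")
    labels = {c.aars for c in complexes}
    if len(labels) != 1:
        raise ValueError(f"mixed aaRS labels: {sorted(labels)}")
    n = len(complexes)
    counts: dict[tuple[str, InteractionType], int] = {}
    for c in complexes:
        present: set[tuple[str, InteractionType]] = set()
        for rec in analysis_records(c):
            for atom in rec.scaffold_atom_ids or ():
                present.add((atom, rec.itype))
        for key in present:
            counts[key] = counts.get(key, 0) + 1
    entries = {
        key: cnt / n for key, cnt in counts.items() if cnt / n >= cutoff
    }
    return OccupancyProfile(
        aars=labels.pop(), n_structures=n, cutoff=cutoff, entries=entries
    )


@dataclass(frozen=True)
class ClassFrequencyTable:
    """Contact counts and relative frequencies per synthetase class.

    ``counts[class][itype]`` counts individual specificity-conferring
    contacts; ``percentages`` are count/class-total as percent, rounded
    half-up to two decimals.
    """

    counts: Mapping[str, Mapping[InteractionType, int]]
    totals: Mapping[str, int]
    percentages: Mapping[str, Mapping[InteractionType, float]]

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[InteractionType, int]]
    ) -> "ClassFrequencyTable":
        totals = {k: sum(v.values()) for k, v in counts.items()}
        percentages = {
            k: {
                t: round_half_up(100.0 * n / totals[k]) if totals[k] else 0.0
                for t, n in v.items()
            }
            for k, v in counts.items()
        }
        return cls(counts=counts, totals=totals, percentages=percentages)


def class_frequency_table(
    complexes: Sequence[StructureComplex],
) -> ClassFrequencyTable:
    """Count specificity-conferring contacts per class and type.

    Unlike occupancy, every record counts (once per record, not per
    structure); water bridges are excluded.
    """
    counts: dict[str, dict[InteractionType, int]] = {}
    for c in complexes:
        per_class = counts.setdefault(
            c.aars_class, {t: 0 for t in ANALYSIS_TYPES}
        )
        for rec in analysis_records(c):
            per_class[rec.itype] += 1
    return ClassFrequencyTable.from_counts(counts)


def class_frequency_from_counts(
    counts: Mapping[str, Mapping[InteractionType, int]],
) -> ClassFrequencyTable:
    """Frequency table straight from printed per-type contact counts."""
    return ClassFrequencyTable.from_counts(counts)


@dataclass(frozen=True)
class SideChainContact:
    position: int            # unified MSA position (or author number if unmapped)
    residue_type: str
    itype: InteractionType
    mapped: bool = True      # False when no renumbering was available


def summarize_side_chain_recognition(
    complexes_by_aars: Mapping[str, Sequence[StructureComplex]],
    renumber_maps: Mapping[str, Mapping[int, int]],
    cutoff: float = 0.1,
) -> dict[str, list[SideChainContact]]:
    """Summarise side-chain recognition per synthetase.

    Only contacts that touch side-chain atoms of the amino-acid ligand are
    included (pure backbone contacts describe the universal alpha-amino /
    carboxyl fixation instead of specificity).  Protein positions are
    reported in unified MSA numbering via ``renumber_maps`` (keyed by
    structure id); structures without a map keep author numbering and are
    flagged.  Contacts are restricted to those whose (atom, type) occupancy
    passes ``cutoff`` within the synthetase's structures.
    """
    summary: dict[str, list[SideChainContact]] = {}
    for aars, complexes in complexes_by_aars.items():
        profile = compute_occupancy(complexes, cutoff=cutoff)
        kept = set(profile.entries)
        contacts: set[SideChainContact] = set()
        for c in complexes:
            mapping = renumber_maps.get(c.structure_id)
            if mapping is None:
                logger.warning(
                    "%s: no renumbering map, keeping author numbering",
                    c.structure_id,
                )
            for rec in analysis_records(c):
                atoms = rec.scaffold_atom_ids or frozenset()
                side_atoms = atoms - BACKBONE_ATOMS
                if not side_atoms:
                    continue
                if not any((a, rec.itype) in kept for a in side_atoms):
                    continue
                if mapping is not None and rec.protein_residue_number in mapping:
                    pos, mapped = mapping[rec.protein_residue_number], True
                else:
                    pos, mapped = rec.protein_residue_number, mapping is not None
                    if mapping is not None:
                        logger.warning(
                            "%s: residue %d absent from renumbering map",
                            c.structure_id, rec.protein_residue_number,
                        )
                        mapped = False
                contacts.add(
                    SideChainContact(
                        position=pos,
                        residue_type=normalize_residue_type(
                            rec.protein_residue_type
                        ),
                        itype=rec.itype,
                        mapped=mapped if mapping is not None else False,
                    )
                )
        summary[aars] = sorted(
            contacts, key=lambda s: (s.position, s.residue_type, s.itype.value)
        )
    return summary


def residue_count_ligand_size_correlation(
    complexes: Sequence[StructureComplex],
) -> tuple[float, float]:
    """Pearson correlation of mean interacting-residue count vs ligand size.

    For each synthetase, the mean number of distinct interacting binding
    site residues per structure is correlated against the heavy-atom count
    of its amino-acid scaffold.  Requires >= 3 synthetase groups and
    non-constant values.
    """
    by_aars: dict[str, list[int]] = {}
    for c in complexes:
        residues = {
            (rec.chain_id, rec.protein_residue_number)
            for rec in analysis_records(c)
        }
        by_aars.setdefault(c.aars, []).append(len(residues))
    if len(by_aars) < 3:
        raise ValueError(f"need >= 3 aaRS groups, got {len(by_aars)}")
    labels = sorted(by_aars)
    mean_counts = np.array([np.mean(by_aars[a]) for a in labels])
    sizes = np.array(
        [len(build_scaffold(a[:-2]).atoms) for a in labels], dtype=float
    )
    if np.ptp(mean_counts) == 0 or np.ptp(sizes) == 0:
        raise ValueError("correlation undefined: zero variance in one variable")
    r, p = sps.pearsonr(mean_counts, sizes)
    return float(r), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: pairs where x < y count 1, ties count 1/2 (x-over-y)."""
    greater = np.sum(x[:, None] > y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float(greater) + 0.5 * float(ties)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For pooled sizes n + m <= 16 the null distribution is enumerated
    exactly over all label assignments of the pooled values (ties handled
    exactly); larger samples use the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u_obs = _u_statistic(x, y)
    n, m = x.size, y.size
    if n + m <= 16:
        pooled = np.concatenate([x, y])
        us = np.array(
            [
                _u_statistic(pooled[list(idx)],
                             np.delete(pooled, list(idx)))
                for idx in combinations(range(n + m), n)
            ]
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, float(p)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def spearman_rho(
    d1: Sequence[float], d2: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError(f"length mismatch: {d1.size} vs {d2.size}")
    if d1.size < 3:
        raise ValueError("need >= 3 paired values")
    rho, p = sps.spearmanr(d1, d2)
    return float(rho), float(p)


#: Side-chain analog phase-transfer free energies, water -> cyclohexane,
#: kcal/mol (Radzicka & Wolfenden 1988).  Positive values prefer the
#: nonpolar phase.  Glycine (no side chain beyond H) and proline (cyclic,
#: no analog measured) are omitted.  Used as the physicochemical reference
#: space when relating recognition distances to amino-acid properties.
PHASE_TRANSFER_DG: dict[str, float] = {
    "Ala": 1.81, "Arg": -14.92, "Asn": -6.64, "Asp": -8.72, "Cys": 1.28,
    "Gln": -5.54, "Glu": -6.81, "His": -4.66, "Ile": 4.92, "Leu": 4.92,
    "Lys": -5.55, "Met": 2.35, "Phe": 2.98, "Ser": -3.40, "Thr": -2.57,
    "Trp": 2.33, "Tyr": -0.14, "Val": 4.04,
}


def physicochemical_distances(codes: Sequence[str]) -> np.ndarray:
    """Condensed pairwise |dG_i - dG_j| over the given ligand codes."""
    missing = [c for c in codes if c not in PHASE_TRANSFER_DG]
    if missing:
        raise KeyError(
            f"no phase-transfer energy for {missing}; "
            "restrict to the tabulated amino acids"
        )
    values = np.array([PHASE_TRANSFER_DG[c] for c in codes])
    out = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            out.append(abs(values[i] - values[j]))
    return np.array(out)
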