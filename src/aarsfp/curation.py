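"""Dataset curation: identity clustering and MSA-based renumbering.

Crystal structures oversample popular proteins, so near-identical chains
are collapsed before statistics: pairwise global Needleman-Wunsch identity
(BLOSUM62) feeds single-linkage clustering at a 95% identity cutoff, and
one representative per cluster is chosen by ordered quality criteria.
Residue positions of different structures of the same synthetase are then
unified by mapping author numbering onto multiple-sequence-alignment
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "nw_identity",
    "single_linkage_clusters",
    "ChainMeta",
    "select_representative",
    "RenumberMap",
    "msa_renumber",
    "renumber_table",
]

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def nw_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch with BLOSUM62; affine gaps (the first gapped position
    costs ``gap_open``, each further one ``gap_extend``).  Identity is
    identical aligned positions divided by the full alignment length
    including gap columns (``denominator="alignment"``), or by the shorter
    sequence length (``denominator="shorter"``).
    """
    for name, seq in (("first", seq_a), ("second", seq_b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"{name} sequence has invalid characters: {sorted(bad)}"
            )
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    identical = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    if denominator == "alignment":
        denom = len(a_row)
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return identical / denom


def single_linkage_clusters(
    identities: np.ndarray,
    threshold: float = 0.95,
    labels: Optional[Sequence[str]] = None,
) -> list[set]:
    """Single-linkage clusters at an identity threshold.

    Clusters are the connected components of the graph with an edge
    wherever pairwise identity >= threshold, so chains of similar
    sequences merge transitively.  The matrix must be symmetric with unit
    diagonal.
    """
    m = np.asarray(identities, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"identity matrix must be square, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("identity matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-9):
        raise ValueError("identity matrix must have unit diagonal")
    n = m.shape[0]
    ids = list(labels) if labels is not None else list(range(n))
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adjacency = csr_matrix(m >= threshold)
    n_comp, assignment = connected_components(adjacency, directed=False)
    clusters: list[set] = [set() for _ in range(n_comp)]
    for i, comp in enumerate(assignment):
        clusters[comp].add(ids[i])
    clusters.sort(key=lambda s: min(str(x) for x in s))
    return clusters


@dataclass(frozen=True)
class ChainMeta:
    """Quality metadata used for representative selection."""

    chain_id: str
    wild_type: bool = True
    resolution: Optional[float] = None  # angstroms, lower is better


def select_representative(members: Sequence[ChainMeta]) -> str:
    """Deterministic cluster representative.

    Ordered criteria: wild type preferred, then best (lowest) resolution,
    then lexicographically smallest chain id.
    """
    if not members:
        raise ValueError("cluster is empty")
    best = min(
        members,
        key=lambda c: (
            not c.wild_type,
            c.resolution if c.resolution is not None else float("inf"),
            c.chain_id,
        ),
    )
    return best.chain_id


@dataclass(frozen=True)
class RenumberMap:
    """Author residue number -> 1-based MSA column for one structure."""

    structure_id: str
    forward: Mapping[int, int]

    @property
    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.forward.items()}

    def __getitem__(self, author_number: int) -> int:
        return self.forward[author_number]


def msa_renumber(
    aligned_row: str,
    author_numbers: Sequence[int],
    sequence: Optional[str] = None,
    structure_id: str = "",
) -> RenumberMap:
    """Map author residue numbers onto MSA columns.

    ``aligned_row`` is the structure's gapped alignment row; residue k of
    the structure maps to the column (1-based) holding the k-th non-gap
    character.  When ``sequence`` is given it must equal the row with gaps
    removed; the first disagreeing position is reported otherwise.
    """
    ungapped = aligned_row.replace("-", "")
    if sequence is not None:
        seq = sequence.upper()
        row = ungapped.upper()
        if seq != row:
            for k, (a, b) in enumerate(zip(seq, row), start=1):
                if a != b:
                    raise ValueError(
                        f"{structure_id}: sequence/alignment mismatch at "
                        f"position {k}: {a!r} != {b!r}"
                    )
            raise ValueError(
                f"{structure_id}: sequence length {len(seq)} != "
                f"alignment row residues {len(row)}"
            )
    if len(author_numbers) != len(ungapped):
        raise ValueError(
            f"{structure_id}: {len(author_numbers)} author numbers for "
            f"{len(ungapped)} residues in the alignment row"
        )
    columns = [i + 1 for i, ch in enumerate(aligned_row) if ch != "-"]
    forward = dict(zip(author_numbers, columns))
    if sorted(forward) != list(author_numbers):
        raise ValueError(f"{structure_id}: author numbers must be strictly increasing")
    return RenumberMap(structure_id=structure_id, forward=forward)


def renumber_table(maps: Sequence[RenumberMap], n_columns: int) -> pd.DataFrame:
    """Deposited-layout renumbering table.

    Rows are unified (MSA) positions, one column per structure holding the
    original author number at that position (NaN where the structure has a
    gap).
    """
    table = pd.DataFrame(
        index=pd.RangeIndex(1, n_columns + 1, name="msa_position"),
        columns=[m.structure_id for m in maps],
        dtype="float64",
    )
    for m in maps:
        for author, column in m.forward.items():
            table.loc[column, m.structure_id] = author
    return table
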