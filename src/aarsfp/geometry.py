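"""Ligand torsion angles and group comparisons of binding-site volumes.

Post-activation ligands carry the amino acid esterified to AMP; the signed
dihedral about the phosphoester bridge describes which side of the
adenosine plane the amino-acid moiety points to, and differs between
synthetase classes.  Binding-cavity volumes are consumed as numbers (grid
algorithms such as POVME compute them externally) and compared between
groups with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import StructureComplex
from .occupancy import mann_whitney_u

__all__ = [
    "TorsionSpec",
    "DEFAULT_TORSION_SPEC",
    "dihedral",
    "place_fourth_atom",
    "ligand_torsion",
    "GroupComparison",
    "group_compare",
]


@dataclass(frozen=True)
class TorsionSpec:
    """Four atom selectors (ligand atom ids) defining a dihedral."""

    selectors: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.selectors) != 4:
            raise ValueError("a torsion needs exactly 4 atom selectors")


#: Default torsion about the phosphoester bridge of an aminoacyl-adenylate:
#: ribose O5' -> phosphorus -> bridging ester oxygen -> carbonyl carbon.
#: The choice of quadruple is a package convention (recorded in output
#: metadata) and fully configurable.
DEFAULT_TORSION_SPEC = TorsionSpec(("AMP_O5'", "AMP_P", "OE", "C"))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC sign convention, (-180, 180].

    Looking along p2 -> p3, the angle is positive when the far bond
    p3 -> p4 is rotated clockwise from the near bond p2 -> p1.  Raises on
    coincident consecutive points or collinear triples.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for name, v in (("p1-p2", b1), ("p2-p3", b2), ("p3-p4", b3)):
        if np.linalg.norm(v) < 1e-12:
            raise ValueError(f"degenerate geometry: coincident points {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: collinear points")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def place_fourth_atom(
    p1, p2, p3, bond_length: float, bond_angle_deg: float, dihedral_deg: float
) -> np.ndarray:
    """Place an atom at given internal coordinates relative to p1, p2, p3.

    Natural-extension (z-matrix) construction: the returned point is at
    ``bond_length`` from p3, forming ``bond_angle_deg`` with p2-p3 and the
    prescribed signed dihedral with the p1-p2-p3 plane.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = np.radians(bond_angle_deg)
    phi = np.radians(dihedral_deg)
    d = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(phi),
            bond_length * np.sin(theta) * np.sin(phi),
        ]
    )
    basis = np.stack([bc, m, n], axis=1)
    return p3 + basis @ d


def ligand_torsion(
    c: StructureComplex, spec: TorsionSpec = DEFAULT_TORSION_SPEC
) -> float:
    """Dihedral of the resolved selector quadruple for one complex."""
    if c.coordinates is None:
        raise ValueError(f"{c.structure_id}: no coordinates available")
    points = []
    for sel in spec.selectors:
        if sel not in c.coordinates:
            raise ValueError(
                f"{c.structure_id}: torsion selector {sel!r} does not resolve"
            )
        points.append(c.coordinates[sel])
    return dihedral(*points)


@dataclass(frozen=True)
class GroupComparison:
    group_names: tuple[str, str]
    medians: tuple[float, float]
    n: tuple[int, int]
    u_statistic: float
    p_value: float


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
) -> GroupComparison:
    """Mann-Whitney U comparison of exactly two value groups."""
    if len(values_by_group) != 2:
        raise ValueError(
            f"need exactly two groups, got {sorted(values_by_group)}"
        )
    (name_x, x), (name_y, y) = sorted(values_by_group.items())
    u, p = mann_whitney_u(x, y)
    return GroupComparison(
        group_names=(name_x, name_y),
        medians=(float(np.median(x)), float(np.median(y))),
        n=(len(x), len(y)),
        u_statistic=u,
        p_value=p,
    )
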