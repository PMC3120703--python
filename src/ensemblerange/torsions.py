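"""Rotatable dihedral angles of a structure bundle.

Computes φ, ψ and the side-chain angles χ1–χ5 (standard IUPAC atom
quadruples) for every residue and conformer.  The peptide-bond angle ω is
deliberately excluded: it is not a rotatable degree of freedom in the sense
relevant for local order.  An angle is emitted only when all four defining
atoms exist (in every conformer, which the bundle topology guarantees) and,
for φ/ψ, when the neighbouring residue directly follows in sequence — chain
termini and chain breaks yield no angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bundle import StructureBundle

#: Side-chain χ atom quadruples per residue type (IUPAC).  χ1 is
#: N-CA-CB-XG; later angles follow the side chain outward.
CHI_TABLE: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ARG": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
        ("CD", "NE", "CZ", "NH1"),
    ),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ),
    "GLU": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LYS": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ),
    "MET": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}

#: Fallback γ-position atoms for χ1 of residue types not in the table
#: (e.g. modified or synthetic residues carrying a CB and one more atom).
_GENERIC_GAMMA = ("CG", "CG1", "OG", "OG1", "SG")


@dataclass
class TorsionRecord:
    """One rotatable dihedral's values across all conformers.

    ``order_param`` (the angular order parameter S, 0 ≤ S ≤ 1) is filled in
    by the domain-identification stage.
    """

    position: int  # residue position within the bundle
    name: str  # "phi", "psi", "chi1" … "chi5"
    values: np.ndarray  # degrees in (−180, 180], one per conformer
    order_param: float | None = field(default=None)


def dihedral_angles(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral angle (degrees, IUPAC convention) for batched points.

    Each input has shape (..., 3); the angle is about the p1–p2 axis and lies
    in (−180, 180].
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(-y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def _chi_quadruples(bundle: StructureBundle, pos: int):
    name = bundle.residue_name(pos).upper()
    if name in CHI_TABLE:
        return CHI_TABLE[name]
    for gamma in _GENERIC_GAMMA:
        if bundle.atom_index(pos, gamma) is not None:
            return (("N", "CA", "CB", gamma),)
    return ()


def compute_torsions(bundle: StructureBundle) -> list[TorsionRecord]:
    """All defined rotatable dihedrals of a bundle (ω excluded).

    Returns one record per (residue, angle) with the angle's value in every
    conformer.  The list may be empty, e.g. for a CA-only bundle.
    """
    records: list[TorsionRecord] = []
    coords = bundle.coords

    def angle_of(atom_idx: list[int]) -> np.ndarray:
        pts = [coords[:, i, :] for i in atom_idx]
        return dihedral_angles(*pts)

    for pos in bundle.positions():
        amap_get = lambda p, a: bundle.atom_index(p, a)  # noqa: E731
        prev_ok = pos > 0 and bundle.sequence_adjacent(pos - 1, pos)
        next_ok = (
            pos + 1 < bundle.n_residues and bundle.sequence_adjacent(pos, pos + 1)
        )
        # phi: C'(i−1), N, CA, C'
        if prev_ok:
            idx = [
                amap_get(pos - 1, "C"),
                amap_get(pos, "N"),
                amap_get(pos, "CA"),
                amap_get(pos, "C"),
            ]
            if all(i is not None for i in idx):
                records.append(TorsionRecord(pos, "phi", angle_of(idx)))
        # psi: N, CA, C', N(i+1)
        if next_ok:
            idx = [
                amap_get(pos, "N"),
                amap_get(pos, "CA"),
                amap_get(pos, "C"),
                amap_get(pos + 1, "N"),
            ]
            if all(i is not None for i in idx):
                records.append(TorsionRecord(pos, "psi", angle_of(idx)))
        # side-chain chi angles
        for k, quad in enumerate(_chi_quadruples(bundle, pos), start=1):
            idx = [amap_get(pos, a) for a in quad]
            if all(i is not None for i in idx):
                records.append(TorsionRecord(pos, f"chi{k}", angle_of(idx)))
    return records
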