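"""In-memory container for multi-conformer structure bundles.

A :class:`StructureBundle` holds an NMR-style ensemble: ``N_conf`` conformers
that share a single atom/residue topology.  Coordinates are stored as one
``(n_conformers, n_atoms, 3)`` array in Å; residues are addressed by integer
*positions* (0 … n_residues−1) that run chain by chain in author order, or by
their author :class:`ResidueKey` (chain, residue number, insertion code).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptySelection, InputError, InsufficientConformers

#: Backbone atoms used in every RMSD computation (C' is named "C" in PDB files).
BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author residue identifier: chain id, residue number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode.strip()}"


@dataclass
class AtomSelection:
    """An ordered set of atoms, grouped by the residue position each belongs to.

    ``atom_indices`` and ``residue_positions`` are parallel arrays; the
    selection is what enters a superposition / RMSD computation.
    """

    atom_indices: np.ndarray
    residue_positions: np.ndarray

    def __len__(self) -> int:
        return len(self.atom_indices)


class StructureBundle:
    """An ensemble of conformers with identical atom composition.

    Parameters
    ----------
    coords:
        Array of shape ``(n_conformers, n_atoms, 3)`` in Å.
    chain_ids, res_numbers, icodes, res_names, atom_names:
        Per-atom annotations of length ``n_atoms``.

    Atoms are re-ordered internally so that residues within a chain are
    strictly increasing by (number, insertion code); chains keep their order
    of first appearance and are never merged.
    """

    def __init__(
        self,
        coords: np.ndarray,
        chain_ids: Sequence[str],
        res_numbers: Sequence[int],
        icodes: Sequence[str],
        res_names: Sequence[str],
        atom_names: Sequence[str],
    ) -> None:
        coords = np.array(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InputError("coords must have shape (n_conformers, n_atoms, 3)")
        if coords.shape[0] < 2:
            raise InsufficientConformers(
                "insufficient conformers: a bundle needs at least 2 models"
            )
        n_atoms = coords.shape[1]
        chain_ids = [str(c) for c in chain_ids]
        res_numbers = [int(n) for n in res_numbers]
        icodes = [str(i).strip() for i in icodes]
        res_names = [str(n) for n in res_names]
        atom_names = [str(n) for n in atom_names]
        for ann in (chain_ids, res_numbers, icodes, res_names, atom_names):
            if len(ann) != n_atoms:
                raise InputError("annotation length does not match atom count")

        # Canonical atom order: chains by first appearance, residues sorted by
        # (number, icode) within each chain, atoms in first-appearance order
        # within each residue.  Duplicate (residue, atom-name) entries keep the
        # first occurrence.
        chain_order: list[str] = []
        for c in chain_ids:
            if c not in chain_order:
                chain_order.append(c)
        per_chain: dict[str, dict[tuple[int, str], list[int]]] = {
            c: {} for c in chain_order
        }
        for idx in range(n_atoms):
            res_id = (res_numbers[idx], icodes[idx])
            per_chain[chain_ids[idx]].setdefault(res_id, []).append(idx)

        order: list[int] = []
        self._residues: list[ResidueKey] = []
        self._res_names: list[str] = []
        self._atom_maps: list[dict[str, int]] = []
        self._chain_ranges: dict[str, range] = {}
        res_of_atom: list[int] = []
        for chain in chain_order:
            start = len(self._residues)
            for (num, icode) in sorted(per_chain[chain]):
                atom_idxs = per_chain[chain][(num, icode)]
                pos = len(self._residues)
                amap: dict[str, int] = {}
                for idx in atom_idxs:
                    name = atom_names[idx]
                    if name in amap:
                        continue  # duplicate atom record; keep first
                    amap[name] = len(order)
                    order.append(idx)
                    res_of_atom.append(pos)
                self._residues.append(ResidueKey(chain, num, icode))
                self._res_names.append(res_names[atom_idxs[0]])
                self._atom_maps.append(amap)
            self._chain_ranges[chain] = range(start, len(self._residues))

        order_arr = np.asarray(order, dtype=int)
        self.coords: np.ndarray = np.ascontiguousarray(coords[:, order_arr, :])
        self.chain_ids = np.asarray([chain_ids[i] for i in order])
        self.res_numbers = np.asarray([res_numbers[i] for i in order], dtype=int)
        self.icodes = np.asarray([icodes[i] for i in order])
        self.res_names = np.asarray([res_names[i] for i in order])
        self.atom_names = np.asarray([atom_names[i] for i in order])
        self._res_of_atom = np.asarray(res_of_atom, dtype=int)
        self._key_to_pos = {key: pos for pos, key in enumerate(self._residues)}

    # ------------------------------------------------------------------ sizes
    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self._residues)

    @property
    def chains(self) -> tuple[str, ...]:
        return tuple(self._chain_ranges)

    # -------------------------------------------------------------- residues
    def residue_key(self, pos: int) -> ResidueKey:
        return self._residues[pos]

    def residue_name(self, pos: int) -> str:
        return self._res_names[pos]

    def position_of(self, key: ResidueKey) -> int:
        return self._key_to_pos[key]

    def positions(self, chain: str | None = None) -> range:
        """Residue positions of one chain (or all residues)."""
        if chain is None:
            return range(self.n_residues)
        return self._chain_ranges[chain]

    def chain_of(self, pos: int) -> str:
        return self._residues[pos].chain

    def same_chain(self, p: int, q: int) -> bool:
        return self._residues[p].chain == self._residues[q].chain

    def sequence_adjacent(self, p: int, q: int) -> bool:
        """True if residue q directly follows p in the same chain.

        Consecutive positions whose author numbers differ by more than one
        indicate missing residues (a chain break): no peptide bond is assumed
        and no torsion spans the break.
        """
        if q != p + 1 or not self.same_chain(p, q):
            return False
        return self._residues[q].number - self._residues[p].number <= 1

    # ----------------------------------------------------------------- atoms
    def atom_index(self, pos: int, name: str) -> int | None:
        return self._atom_maps[pos].get(name)

    def has_backbone(self, pos: int) -> bool:
        amap = self._atom_maps[pos]
        return all(a in amap for a in BACKBONE_ATOMS)

    def residue_of_atom(self, atom_idx: int) -> int:
        return int(self._res_of_atom[atom_idx])

    def backbone_selection(self, positions: Iterable[int]) -> AtomSelection:
        """Backbone N, CA, C' atoms of the given residues, in residue order.

        Residues missing any backbone atom are silently skipped (they are
        never part of an RMSD selection).
        """
        atom_idx: list[int] = []
        res_pos: list[int] = []
        for pos in positions:
            amap = self._atom_maps[pos]
            if not all(a in amap for a in BACKBONE_ATOMS):
                continue
            for a in BACKBONE_ATOMS:
                atom_idx.append(amap[a])
                res_pos.append(pos)
        if not atom_idx:
            raise EmptySelection("empty selection")
        return AtomSelection(
            np.asarray(atom_idx, dtype=int), np.asarray(res_pos, dtype=int)
        )

    # ------------------------------------------------------------ operations
    def subset_atoms(self, mask: np.ndarray) -> "StructureBundle":
        """A new bundle restricted to the atoms selected by ``mask``."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask.astype(int)
        return StructureBundle(
            self.coords[:, idx, :],
            self.chain_ids[idx],
            self.res_numbers[idx],
            self.icodes[idx],
            self.res_names[idx],
            self.atom_names[idx],
        )

    def transformed(
        self, rotations: np.ndarray, translations: np.ndarray
    ) -> "StructureBundle":
        """Apply one rigid transform per conformer to all atoms."""
        rotations = np.asarray(rotations, dtype=float)
        translations = np.asarray(translations, dtype=float)
        new = self.coords @ rotations.transpose(0, 2, 1) + translations[:, None, :]
        return StructureBundle(
            new,
            self.chain_ids,
            self.res_numbers,
            self.icodes,
            self.res_names,
            self.atom_names,
        )
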