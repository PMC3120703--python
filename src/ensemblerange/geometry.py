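"""Rigid-body superposition and ensemble RMSD — the numerical kernel.

All superpositions use the SVD (Kabsch) solution with a reflection guard, so
the optimal orthogonal matrix is always a proper rotation.  Ensemble
precision follows the NMR convention: all conformers are superimposed onto
the first one, the mean coordinates are computed, and the reported value
``r`` is the average over conformers of each conformer's RMSD to that mean.
The mean is deliberately not re-fit iteratively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TYPE_CHECKING

import numpy as np

from .errors import UnderdeterminedFit

if TYPE_CHECKING:  # pragma: no cover
    from .bundle import AtomSelection, StructureBundle


@dataclass
class EnsembleFit:
    """Result of superimposing an ensemble selection onto its first conformer.

    Attributes
    ----------
    rotations, translations:
        Per-conformer proper rigid transforms onto conformer 1 (identity for
        conformer 1 itself).
    fitted:
        Transformed selection coordinates, shape ``(n_conf, n_atoms, 3)``.
    mean:
        Mean coordinates over conformers, shape ``(n_atoms, 3)``.
    per_conformer_rmsd:
        RMSD of each fitted conformer to the mean.
    rmsd:
        Ensemble RMSD-to-mean ``r`` (Å): the average of ``per_conformer_rmsd``.
    atom_displacements:
        Per-atom distance to the mean position, averaged over conformers.
    """

    rotations: np.ndarray
    translations: np.ndarray
    fitted: np.ndarray
    mean: np.ndarray
    per_conformer_rmsd: np.ndarray
    rmsd: float
    atom_displacements: np.ndarray


def _kabsch(reference: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Kabsch: proper rotations + translations mapping ``moving`` onto
    ``reference``.  ``moving`` has shape (..., n, 3); ``reference`` (n, 3)."""
    ref_centroid = reference.mean(axis=0)
    mov_centroid = moving.mean(axis=-2)
    ref_c = reference - ref_centroid
    mov_c = moving - mov_centroid[..., None, :]
    # H = X_mov^T X_ref per batch element
    h = np.swapaxes(mov_c, -2, -1) @ ref_c
    u, _, vt = np.linalg.svd(h)
    v = np.swapaxes(vt, -2, -1)
    d = np.sign(np.linalg.det(v @ np.swapaxes(u, -2, -1)))
    # flip the smallest singular direction when the optimum is a reflection
    flip = np.ones(h.shape[:-2] + (3,))
    flip[..., 2] = d
    rot = (v * flip[..., None, :]) @ np.swapaxes(u, -2, -1)
    trans = ref_centroid - np.einsum("...ij,...j->...i", rot, mov_centroid)
    return rot, trans


def superpose_pair(
    reference: np.ndarray, moving: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``moving`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (determinant +1) even for near-planar or reflective configurations.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape or reference.ndim != 2:
        raise UnderdeterminedFit("coordinate sets must have matching (n, 3) shapes")
    if reference.shape[0] < 3:
        raise UnderdeterminedFit("underdetermined fit: need at least 3 atoms")
    rot, trans = _kabsch(reference, moving)
    fitted = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def fit_ensemble(coords: np.ndarray) -> EnsembleFit:
    """Superpose an ``(n_conf, n_atoms, 3)`` ensemble onto its first member
    and evaluate the RMSD-to-mean and per-atom displacements."""
    coords = np.asarray(coords, dtype=float)
    n_conf, n_atoms = coords.shape[:2]
    if n_atoms < 3:
        raise UnderdeterminedFit("underdetermined fit: need at least 3 atoms")
    rot, trans = _kabsch(coords[0], coords)
    # conformer 1 is the fixed reference frame
    rot[0] = np.eye(3)
    trans[0] = 0.0
    fitted = coords @ rot.transpose(0, 2, 1) + trans[:, None, :]
    mean = fitted.mean(axis=0)
    dev = fitted - mean
    per_atom_dist = np.sqrt(np.sum(dev**2, axis=2))  # (n_conf, n_atoms)
    per_conf = np.sqrt(np.mean(per_atom_dist**2, axis=1))
    return EnsembleFit(
        rotations=rot,
        translations=trans,
        fitted=fitted,
        mean=mean,
        per_conformer_rmsd=per_conf,
        rmsd=float(per_conf.mean()),
        atom_displacements=per_atom_dist.mean(axis=0),
    )


def rmsd_to_mean(bundle: "StructureBundle", selection: "AtomSelection") -> EnsembleFit:
    """Ensemble fit of a bundle on the given atom selection."""
    return fit_ensemble(bundle.coords[:, selection.atom_indices, :])


def mean_displacements(
    bundle: "StructureBundle",
    selection: "AtomSelection",
    fit: EnsembleFit | None = None,
) -> dict[int, float]:
    """Per-residue average displacement (Å) on a backbone selection.

    The displacement of a residue is the distance between its atoms and their
    mean positions after superposition onto the first conformer, averaged
    over all conformers and over the residue's backbone atoms.
    """
    if fit is None:
        fit = rmsd_to_mean(bundle, selection)
    out: dict[int, float] = {}
    for pos in np.unique(selection.residue_positions):
        mask = selection.residue_positions == pos
        out[int(pos)] = float(fit.atom_displacements[mask].mean())
    return out
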