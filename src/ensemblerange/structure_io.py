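"""Reading and writing multi-model PDB coordinate files.

Parsing is delegated to biotite; this module normalizes the result into a
:class:`~ensemblerange.bundle.StructureBundle`:

* hydrogens (and deuteriums) are ignored;
* for alternate locations the highest-occupancy variant is kept (first on
  tie, biotite's convention);
* residues without a CA atom (waters, ligands, most hetero compounds) are
  dropped;
* atoms that are absent from any model are dropped from all models, with a
  logged warning — models must otherwise agree in composition.
"""

from __future__ import annotations

import logging
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .bundle import BACKBONE_ATOMS, StructureBundle
from .errors import EmptySelection, InconsistentModels, InputError, InsufficientConformers

logger = logging.getLogger(__name__)

_AtomKey = tuple[str, int, str, str, str]  # chain, resnum, icode, resname, atom


def _model_atoms(array: "struc.AtomArray") -> tuple[list[_AtomKey], dict[_AtomKey, int]]:
    """Ordered atom keys of one model, heavy atoms only, first duplicate kept."""
    element = np.char.upper(array.element.astype(str))
    heavy = ~np.isin(element, ("H", "D"))
    keys: list[_AtomKey] = []
    index: dict[_AtomKey, int] = {}
    ins = (
        array.ins_code.astype(str)
        if "ins_code" in array.get_annotation_categories()
        else np.full(array.array_length(), "")
    )
    for i in np.nonzero(heavy)[0]:
        key = (
            str(array.chain_id[i]),
            int(array.res_id[i]),
            str(ins[i]).strip(),
            str(array.res_name[i]).strip(),
            str(array.atom_name[i]).strip(),
        )
        if key not in index:
            index[key] = int(i)
            keys.append(key)
    return keys, index


def read_bundle(
    path: str | PathLike | Sequence[str | PathLike],
    model_limit: int | None = None,
) -> StructureBundle:
    """Read a multi-model PDB file (or several single-model files) as a bundle.

    Parameters
    ----------
    path:
        A PDB file with ≥ 2 MODEL records, or a sequence of files whose models
        are concatenated (e.g. exactly two single-model files).
    model_limit:
        Use only the first ``model_limit`` models.
    """
    if isinstance(path, (str, PathLike)):
        paths = [Path(path)]
    else:
        paths = [Path(p) for p in path]

    models: list[struc.AtomArray] = []
    for p in paths:
        try:
            pdb = PDBFile.read(str(p))
        except Exception as exc:  # malformed file
            raise InputError(f"cannot read PDB file {p}: {exc}") from exc
        n = pdb.get_model_count()
        for m in range(1, n + 1):
            try:
                arr = pdb.get_structure(model=m, altloc="occupancy")
            except Exception:
                arr = pdb.get_structure(model=m, altloc="first")
            models.append(arr)
            if model_limit is not None and len(models) >= model_limit:
                break
        if model_limit is not None and len(models) >= model_limit:
            break

    if len(models) < 2:
        raise InsufficientConformers(
            "insufficient conformers: need at least 2 models "
            f"(got {len(models)})"
        )

    per_model = [_model_atoms(m) for m in models]
    common = set(per_model[0][1])
    for keys, index in per_model[1:]:
        common &= set(index)
    if not common:
        raise InconsistentModels("inconsistent models: no common atoms")
    n_total = len(per_model[0][0])
    if len(common) < n_total:
        logger.warning(
            "dropping %d atom(s) absent from at least one model",
            n_total - len(common),
        )
    keys = [k for k in per_model[0][0] if k in common]

    # drop residues without a CA atom (hetero/non-standard compounds, waters)
    with_ca = {
        (c, n, i) for (c, n, i, _rn, atom) in keys if atom == "CA"
    }
    keys = [k for k in keys if (k[0], k[1], k[2]) in with_ca]
    if not keys:
        raise InputError("no polymer residues with CA atoms in input")

    coords = np.empty((len(models), len(keys), 3), dtype=float)
    for mi, (model, (_keys, index)) in enumerate(zip(models, per_model)):
        idx = np.asarray([index[k] for k in keys], dtype=int)
        coords[mi] = model.coord[idx]

    return StructureBundle(
        coords,
        chain_ids=[k[0] for k in keys],
        res_numbers=[k[1] for k in keys],
        icodes=[k[2] for k in keys],
        res_names=[k[3] for k in keys],
        atom_names=[k[4] for k in keys],
    )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D") or (len(stripped) > 1 and stripped[:2] in ("1H", "2H")):
        return "H"
    return stripped[0]


def to_atom_array_stack(bundle: StructureBundle) -> "struc.AtomArrayStack":
    """Convert a bundle to a biotite ``AtomArrayStack`` for serialization."""
    stack = struc.AtomArrayStack(bundle.n_conformers, bundle.n_atoms)
    stack.coord[:] = bundle.coords
    stack.chain_id = bundle.chain_ids.astype("U4")
    stack.res_id = bundle.res_numbers
    stack.ins_code = bundle.icodes.astype("U1")
    stack.res_name = bundle.res_names.astype("U5")
    stack.atom_name = bundle.atom_names.astype("U6")
    stack.element = np.asarray(
        [_guess_element(a) for a in bundle.atom_names], dtype="U2"
    )
    stack.hetero = np.zeros(bundle.n_atoms, dtype=bool)
    return stack


def write_bundle(bundle: StructureBundle, path: str | PathLike) -> None:
    """Write a bundle as a multi-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array_stack(bundle))
    pdb.write(str(path))


def write_superimposed(bundle: StructureBundle, result, path: str | PathLike) -> None:
    """Write the bundle with all conformers superimposed onto the first one,
    fitting on the backbone N/CA/C' atoms of ``result``'s selected residues.

    ``result`` is a :class:`~ensemblerange.refine.RangeResult` (or anything
    with a ``selected_positions`` attribute).
    """
    from .geometry import rmsd_to_mean  # local import avoids cycle

    positions = list(getattr(result, "selected_positions", result))
    if not positions:
        raise EmptySelection("empty selection")
    selection = bundle.backbone_selection(positions)
    fit = rmsd_to_mean(bundle, selection)
    write_bundle(bundle.transformed(fit.rotations, fit.translations), path)
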