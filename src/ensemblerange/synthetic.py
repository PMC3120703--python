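"""Seeded generator of synthetic structure bundles with known ground truth.

Bundles are serine-like polypeptides (atoms N, CA, C', O, CB, OG per
residue) built from ideal internal coordinates, so that φ, ψ and χ1 are all
defined and the order-parameter machinery is fully exercised.  A bundle is
described region by region:

* ``rigid``  — fixed template torsions; small isotropic Cartesian noise σ;
* ``noisy``  — same construction with a (typically large) σ, emulating a
  disordered loop that stays attached to the rigid frame;
* ``tail`` / ``linker`` — φ, ψ, χ1 resampled uniformly per conformer,
  emulating random-coil ends and flexible inter-domain connections.

Maximal runs of rigid/noisy regions form *blocks*; with the "independent"
motion policy every block additionally receives an independent random
rotation and translation per conformer, producing multi-domain bundles with
random inter-domain orientations.  Every conformer finally gets one global
random rigid motion so that nothing is pre-superimposed.  All randomness
derives from the spec's seed.

The generator emulates ensemble disorder, not protein physics: there is no
sequence realism, no sterics, and tails may clash with the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bundle import StructureBundle

# ideal backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.5
_B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB = 1.530, 110.5, -122.0
_B_CB_OG, _A_CA_CB_OG = 1.417, 110.8

HELIX = (-57.0, -47.0)
EXTENDED = (-139.0, 135.0)

#: Cartesian noise below this σ (Å) still counts as "ordered" ground truth.
ORDERED_SIGMA_MAX = 0.5


@dataclass(frozen=True)
class Region:
    """One contiguous sequence region of a bundle blueprint."""

    kind: str  # "rigid" | "noisy" | "tail" | "linker"
    length: int
    sigma: float = 0.0  # isotropic Cartesian noise, Å (rigid/noisy kinds)
    phi_psi: tuple[float, float] = HELIX

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "noisy", "tail", "linker"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.length < 1 or self.sigma < 0:
            raise ValueError("invalid region")


@dataclass(frozen=True)
class BundleSpec:
    """Blueprint of a synthetic bundle; regions tile the sequence."""

    regions: tuple[Region, ...]
    n_conformers: int = 20
    seed: int = 0
    motion_policy: str = "shared"  # "shared" | "independent" block motions
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.motion_policy not in ("shared", "independent"):
            raise ValueError("motion_policy must be 'shared' or 'independent'")
        if self.n_conformers < 2:
            raise ValueError("need at least 2 conformers")

    @property
    def n_residues(self) -> int:
        return sum(r.length for r in self.regions)


@dataclass
class GroundTruth:
    """Expected ordered residues and domain partition of a blueprint."""

    ordered_positions: tuple[int, ...]
    domains: tuple[tuple[int, ...], ...]


# ----------------------------------------------------------------- geometry
def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position of atom D with bond C–D, angle B-C-D and torsion A-B-C-D."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


_ATOMS_PER_RES = ("N", "CA", "C", "O", "CB", "OG")


def _build_chain(torsions: np.ndarray) -> np.ndarray:
    """Build one conformer from per-residue (φ, ψ, χ1) torsions.

    Returns coordinates of shape (n_residues * 6, 3) in the order of
    ``_ATOMS_PER_RES`` per residue.  ω is fixed at 180°.
    """
    n_res = torsions.shape[0]
    coords = np.empty((n_res, len(_ATOMS_PER_RES), 3))
    # seed frame for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords[0, 0], coords[0, 1], coords[0, 2] = n0, ca0, c0
    for i in range(1, n_res):
        phi_i = torsions[i, 0]
        psi_prev = torsions[i - 1, 1]
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_i)
        coords[i, 0], coords[i, 1], coords[i, 2] = n_i, ca_i, c_i
    for i in range(n_res):
        n_i, ca_i, c_i = coords[i, 0], coords[i, 1], coords[i, 2]
        psi_i = torsions[i, 1]
        chi1_i = torsions[i, 2]
        coords[i, 3] = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi_i + 180.0)
        cb_i = _place_atom(c_i, n_i, ca_i, _B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB)
        coords[i, 4] = cb_i
        coords[i, 5] = _place_atom(n_i, ca_i, cb_i, _B_CB_OG, _A_CA_CB_OG, chi1_i)
    return coords.reshape(-1, 3)


# ------------------------------------------------------------------ regions
def _region_positions(spec: BundleSpec) -> list[tuple[Region, range]]:
    out = []
    start = 0
    for region in spec.regions:
        out.append((region, range(start, start + region.length)))
        start += region.length
    return out


def _blocks(spec: BundleSpec) -> list[range]:
    """Maximal runs of consecutive rigid/noisy regions (the rigid blocks)."""
    blocks: list[range] = []
    current: list[int] = []
    for region, span in _region_positions(spec):
        if region.kind in ("rigid", "noisy"):
            current.extend(span)
        elif current:
            blocks.append(range(current[0], current[-1] + 1))
            current = []
    if current:
        blocks.append(range(current[0], current[-1] + 1))
    return blocks


# --------------------------------------------------------------------- main
def make_bundle(spec: BundleSpec) -> StructureBundle:
    """Generate the bundle described by ``spec`` (reproducible from its seed)."""
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_residues
    regions = _region_positions(spec)

    template = np.empty((n_res, 3))
    for region, span in regions:
        template[list(span), 0] = region.phi_psi[0]
        template[list(span), 1] = region.phi_psi[1]
        template[list(span), 2] = -60.0  # χ1

    flexible = np.zeros(n_res, dtype=bool)
    sigma = np.zeros(n_res)
    for region, span in regions:
        if region.kind in ("tail", "linker"):
            flexible[list(span)] = True
        else:
            sigma[list(span)] = region.sigma

    blocks = _blocks(spec)
    conformers = np.empty((spec.n_conformers, n_res * len(_ATOMS_PER_RES), 3))
    for k in range(spec.n_conformers):
        torsions = template.copy()
        n_flex = int(flexible.sum())
        if n_flex:
            torsions[flexible] = rng.uniform(-180.0, 180.0, size=(n_flex, 3))
        coords = _build_chain(torsions).reshape(n_res, len(_ATOMS_PER_RES), 3)
        if spec.motion_policy == "independent":
            for block in blocks:
                idx = list(block)
                rot = _random_rotation(rng)
                shift = rng.normal(0.0, 5.0, size=3)
                centroid = coords[idx].reshape(-1, 3).mean(axis=0)
                coords[idx] = (coords[idx] - centroid) @ rot.T + centroid + shift
        noise_sigma = np.repeat(sigma, len(_ATOMS_PER_RES)).reshape(n_res, -1)
        coords += rng.normal(0.0, 1.0, size=coords.shape) * noise_sigma[..., None]
        # one global rigid motion per conformer: nothing is pre-superimposed
        rot = _random_rotation(rng)
        shift = rng.normal(0.0, 10.0, size=3)
        conformers[k] = coords.reshape(-1, 3) @ rot.T + shift

    atom_names = list(_ATOMS_PER_RES) * n_res
    res_numbers = np.repeat(np.arange(1, n_res + 1), len(_ATOMS_PER_RES))
    return StructureBundle(
        conformers,
        chain_ids=[spec.chain] * (n_res * len(_ATOMS_PER_RES)),
        res_numbers=res_numbers,
        icodes=[""] * (n_res * len(_ATOMS_PER_RES)),
        res_names=["SER"] * (n_res * len(_ATOMS_PER_RES)),
        atom_names=atom_names,
    )


def ground_truth(spec: BundleSpec) -> GroundTruth:
    """Expected ordered residue set and domain partition of a blueprint."""
    ordered: list[int] = []
    for region, span in _region_positions(spec):
        if region.kind in ("rigid", "noisy") and region.sigma <= ORDERED_SIGMA_MAX:
            ordered.extend(span)
    ordered_set = set(ordered)
    if spec.motion_policy == "independent":
        domains = tuple(
            tuple(p for p in block if p in ordered_set)
            for block in _blocks(spec)
            if any(p in ordered_set for p in block)
        )
    else:
        domains = (tuple(sorted(ordered_set)),) if ordered_set else ()
    return GroundTruth(ordered_positions=tuple(sorted(ordered_set)), domains=domains)


def strip_to_ca(bundle: StructureBundle) -> StructureBundle:
    """A CA-only copy of a bundle (no torsions definable)."""
    return bundle.subset_atoms(bundle.atom_names == "CA")


# ------------------------------------------------------- common blueprints
def rigid_spec(
    n_residues: int = 40, n_conformers: int = 20, sigma: float = 0.0, seed: int = 0
) -> BundleSpec:
    """A single rigid helix; with σ = 0 the conformers are congruent."""
    return BundleSpec(
        regions=(Region("rigid", n_residues, sigma),),
        n_conformers=n_conformers,
        seed=seed,
    )


def helix_with_tails_spec(
    n_tail: int = 12,
    n_core: int = 36,
    n_conformers: int = 20,
    sigma_core: float = 0.1,
    seed: int = 0,
) -> BundleSpec:
    """An ordered helix flanked by two random-coil tails."""
    return BundleSpec(
        regions=(
            Region("tail", n_tail),
            Region("rigid", n_core, sigma_core),
            Region("tail", n_tail),
        ),
        n_conformers=n_conformers,
        seed=seed,
    )


def two_domain_spec(
    n_block: int = 40,
    n_linker: int = 10,
    n_conformers: int = 20,
    sigma_core: float = 0.1,
    seed: int = 0,
) -> BundleSpec:
    """Two rigid blocks joined by a flexible linker, independent motions."""
    return BundleSpec(
        regions=(
            Region("rigid", n_block, sigma_core),
            Region("linker", n_linker),
            Region("rigid", n_block, sigma_core),
        ),
        n_conformers=n_conformers,
        seed=seed,
        motion_policy="independent",
    )


def interior_loop_spec(
    n_flank: int = 25,
    n_loop: int = 6,
    n_conformers: int = 20,
    sigma_core: float = 0.1,
    sigma_loop: float = 4.0,
    seed: int = 0,
) -> BundleSpec:
    """One domain with a disordered interior loop (flanks share one frame)."""
    return BundleSpec(
        regions=(
            Region("rigid", n_flank, sigma_core),
            Region("noisy", n_loop, sigma_loop),
            Region("rigid", n_flank, sigma_core),
        ),
        n_conformers=n_conformers,
        seed=seed,
    )


def random_coil_spec(
    n_residues: int = 10, n_conformers: int = 20, seed: int = 0
) -> BundleSpec:
    """A fully disordered bundle: no ordered residues, no domains."""
    return BundleSpec(
        regions=(Region("tail", n_residues),),
        n_conformers=n_conformers,
        seed=seed,
    )
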