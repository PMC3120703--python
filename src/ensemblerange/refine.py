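"""Residue-range refinement: gap-penalized iterative residue removal.

The right branch of the pipeline.  Starting from a boundary-extended domain,
residues are removed one at a time until the set no longer changes:

1. fit the ensemble on the current selection → RMSD ``r`` and per-residue
   displacements;
2. drop residues whose both sequence neighbours are unselected (isolated
   residues; a missing neighbour — chain terminus — counts as unselected);
3. find the largest-displacement residue whose removal opens no new gap
   (a range endpoint) and the largest-displacement one whose removal does
   (an interior residue);
4. compute the gap-weighted RMSD decreases Δr^nogap = r − r^nogap and
   Δr^gap = γ·(r − r^gap) by refitting without each candidate;
5. remove the candidate with the larger Δr if Δr ≥ δ_abs·n/N and
   Δr/r ≥ δ_rel·n/N with δ_rel = δ + 3/M (n: the residue's atoms in the
   step-1 fit; N: all fitted atoms; M: selected residues), then restart;
6. if step 5 removed nothing, scan *all* selected residues for the largest
   gap-weighted decrease and retry the same test;
7. after convergence, fill gaps shorter than g residues (once).

The inflation of δ_rel at small M guarantees termination; the reported RMSD
is recomputed on the final, post-fill selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bundle import StructureBundle
from .errors import EmptySelection
from .geometry import EnsembleFit, mean_displacements, rmsd_to_mean


@dataclass
class RefinementParams:
    """Tunable parameters of the pipeline (defaults as published).

    mu:        minimal cluster size for a domain (residues).
    m:         domain boundary extension (residues).
    gamma:     gap penalty in [0, 1]: 0 forbids new gaps, 1 ignores them.
    delta:     base of the relative-decrease threshold δ_rel = δ + 3/M.
    delta_abs: absolute RMSD-decrease threshold (Å).
    g:         gaps shorter than g residues are filled at the end.
    """

    mu: int = 8
    m: int = 3
    gamma: float = 0.4
    delta: float = 1.2
    delta_abs: float = 1.6
    g: int = 3
    variance_normalization: str = "population"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.delta_abs <= 0:
            raise ValueError("delta_abs must be positive")
        if self.g < 1:
            raise ValueError("g must be at least 1")


@dataclass
class SelectionState:
    """The refinement loop's working state."""

    selected: tuple[int, ...]  # sorted residue positions
    r: float | None = None
    displacements: dict[int, float] | None = None

    @property
    def m_count(self) -> int:
        return len(self.selected)


@dataclass
class RangeResult:
    """Final residue ranges of one domain.

    ``ranges`` holds inclusive (chain, first_key, last_key) triples in
    sequence order; ``rmsd`` is the backbone RMSD-to-mean on the final
    selection; ``history`` records every accepted removal as
    (step, position, r_before, delta_r).
    """

    ranges: list[tuple[str, str, str]]
    selected_positions: tuple[int, ...]
    n_residues: int
    n_gaps: int
    rmsd: float
    history: list[tuple[int, int, float, float]] = field(default_factory=list)
    iterations: int = 0


# ------------------------------------------------------------------ topology
def selection_runs(
    selected: Sequence[int], bundle: StructureBundle
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive selected positions within one chain."""
    runs: list[tuple[int, int]] = []
    sel = sorted(selected)
    if not sel:
        return runs
    start = prev = sel[0]
    for p in sel[1:]:
        if p == prev + 1 and bundle.same_chain(prev, p):
            prev = p
            continue
        runs.append((start, prev))
        start = prev = p
    runs.append((start, prev))
    return runs


def _endpoints_and_interior(
    selected: Sequence[int], bundle: StructureBundle
) -> tuple[set[int], set[int]]:
    endpoints: set[int] = set()
    for start, stop in selection_runs(selected, bundle):
        endpoints.add(start)
        endpoints.add(stop)
    interior = set(selected) - endpoints
    return endpoints, interior


# --------------------------------------------------------------------- steps
def remove_isolated(
    state: SelectionState, bundle: StructureBundle
) -> SelectionState:
    """Step 2: drop residues whose both sequence neighbours are unselected.

    A neighbour that does not exist (chain terminus or chain break) counts as
    unselected, so lone terminal residues are removed as well.
    """
    sel = set(state.selected)

    def neighbour_selected(p: int, q: int) -> bool:
        return (
            0 <= q < bundle.n_residues
            and q in sel
            and bundle.same_chain(p, q)
        )

    keep = tuple(
        p
        for p in state.selected
        if neighbour_selected(p, p - 1) or neighbour_selected(p, p + 1)
    )
    return SelectionState(selected=keep)


def displacement_candidates(
    state: SelectionState, bundle: StructureBundle
) -> tuple[int | None, int | None]:
    """Step 3: the max-displacement endpoint (no new gap on removal) and the
    max-displacement interior residue (removal opens a new gap)."""
    assert state.displacements is not None
    endpoints, interior = _endpoints_and_interior(state.selected, bundle)
    disp = state.displacements

    def argmax(cands: set[int]) -> int | None:
        if not cands:
            return None
        return max(sorted(cands), key=lambda p: disp[p])

    return argmax(endpoints), argmax(interior)


def _fit_state(bundle: StructureBundle, selected: Sequence[int]) -> tuple[EnsembleFit, dict[int, float]]:
    selection = bundle.backbone_selection(selected)
    fit = rmsd_to_mean(bundle, selection)
    disp = mean_displacements(bundle, selection, fit)
    return fit, disp


def _rmsd_without(
    bundle: StructureBundle, selected: Sequence[int], removed: int
) -> float | None:
    remaining = [p for p in selected if p != removed]
    if not remaining:
        return None
    return rmsd_to_mean(bundle, bundle.backbone_selection(remaining)).rmsd


def gap_weighted_decreases(
    state: SelectionState,
    bundle: StructureBundle,
    candidates: tuple[int | None, int | None],
    gamma: float,
) -> tuple[float, float]:
    """Step 4: Δr^nogap = r − r^nogap and Δr^gap = γ·(r − r^gap).

    An absent candidate yields −inf so it can never win the comparison.
    """
    assert state.r is not None
    cand_nogap, cand_gap = candidates
    d_nogap = -np.inf
    d_gap = -np.inf
    if cand_nogap is not None:
        r_nogap = _rmsd_without(bundle, state.selected, cand_nogap)
        if r_nogap is not None:
            d_nogap = state.r - r_nogap
    if cand_gap is not None:
        r_gap = _rmsd_without(bundle, state.selected, cand_gap)
        if r_gap is not None:
            d_gap = gamma * (state.r - r_gap)
    return d_nogap, d_gap


def removal_decision(
    delta_r: float,
    r: float,
    n_res_atoms: int,
    n_sel_atoms: int,
    m_count: int,
    delta: float,
    delta_abs: float,
) -> bool:
    """Step 5 test: Δr ≥ δ_abs·n/N and Δr/r ≥ (δ + 3/M)·n/N."""
    if r <= 0.0:
        return False
    frac = n_res_atoms / n_sel_atoms
    delta_rel = delta + 3.0 / m_count
    return delta_r >= delta_abs * frac and delta_r / r >= delta_rel * frac


def fill_gaps(
    state: SelectionState, bundle: StructureBundle, g: int
) -> SelectionState:
    """Step 7: add every all-selectable gap strictly shorter than g residues
    lying between two selected residues of the same chain.  Gaps containing
    residues without a complete backbone are never filled."""
    sel = sorted(state.selected)
    filled = set(sel)
    for p, q in zip(sel, sel[1:]):
        if q - p <= 1 or not bundle.same_chain(p, q):
            continue
        gap = range(p + 1, q)
        if len(gap) < g and all(bundle.has_backbone(x) for x in gap):
            filled.update(gap)
    return SelectionState(selected=tuple(sorted(filled)))


def count_gaps(selected: Sequence[int], bundle: StructureBundle) -> int:
    """Number of intra-domain gaps: unselected stretches between consecutive
    selected residues of one chain."""
    sel = sorted(selected)
    gaps = 0
    for p, q in zip(sel, sel[1:]):
        if bundle.same_chain(p, q) and q - p > 1:
            gaps += 1
    return gaps


# ---------------------------------------------------------------- main loop
def refine_domain(
    bundle: StructureBundle,
    initial_positions: Iterable[int],
    params: RefinementParams,
) -> RangeResult:
    """Run steps 1–7 on an extended domain and report its residue ranges."""
    selectable = [p for p in sorted(set(initial_positions)) if bundle.has_backbone(p)]
    if not selectable:
        raise EmptySelection("empty selection")
    state = SelectionState(selected=tuple(selectable))
    history: list[tuple[int, int, float, float]] = []
    max_iter = 4 * len(selectable) + 8
    iterations = 0

    while True:
        iterations += 1
        if iterations > max_iter:  # defensive; the thresholds guarantee exit
            raise RuntimeError("refinement failed to terminate")
        if not state.selected:
            break
        # step 1
        fit, disp = _fit_state(bundle, state.selected)
        state.r = fit.rmsd
        state.displacements = disp
        n_sel_atoms = 3 * state.m_count

        # step 2
        after = remove_isolated(state, bundle)
        if after.m_count != state.m_count:
            state = after
            continue
        if state.m_count <= 1:
            break

        # steps 3–5
        cand_nogap, cand_gap = displacement_candidates(state, bundle)
        d_nogap, d_gap = gap_weighted_decreases(
            state, bundle, (cand_nogap, cand_gap), params.gamma
        )
        if d_nogap >= d_gap:  # ties prefer the no-gap candidate
            best_delta, best_pos = d_nogap, cand_nogap
        else:
            best_delta, best_pos = d_gap, cand_gap
        if best_pos is not None and removal_decision(
            best_delta,
            state.r,
            3,
            n_sel_atoms,
            state.m_count,
            params.delta,
            params.delta_abs,
        ):
            history.append((5, best_pos, state.r, best_delta))
            state = SelectionState(
                selected=tuple(p for p in state.selected if p != best_pos)
            )
            continue

        # step 6: full scan
        endpoints, _interior = _endpoints_and_interior(state.selected, bundle)
        best_delta, best_pos = -np.inf, None
        for p in state.selected:
            r_p = _rmsd_without(bundle, state.selected, p)
            if r_p is None:
                continue
            weight = 1.0 if p in endpoints else params.gamma
            d = weight * (state.r - r_p)
            if d > best_delta:
                best_delta, best_pos = d, p
        if best_pos is not None and removal_decision(
            best_delta,
            state.r,
            3,
            n_sel_atoms,
            state.m_count,
            params.delta,
            params.delta_abs,
        ):
            history.append((6, best_pos, state.r, best_delta))
            state = SelectionState(
                selected=tuple(p for p in state.selected if p != best_pos)
            )
            continue
        break  # steps 1–6 converged

    # step 7 (once), then the reported RMSD is recomputed on the final set
    state = fill_gaps(state, bundle, params.g)
    if not state.selected:
        return RangeResult([], (), 0, 0, float("nan"), history, iterations)
    final_fit, _ = _fit_state(bundle, state.selected)

    ranges = [
        (
            bundle.chain_of(start),
            str(bundle.residue_key(start).number) + bundle.residue_key(start).icode,
            str(bundle.residue_key(stop).number) + bundle.residue_key(stop).icode,
        )
        for start, stop in selection_runs(state.selected, bundle)
    ]
    return RangeResult(
        ranges=ranges,
        selected_positions=state.selected,
        n_residues=state.m_count,
        n_gaps=count_gaps(state.selected, bundle),
        rmsd=final_fit.rmsd,
        history=history,
        iterations=iterations,
    )
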