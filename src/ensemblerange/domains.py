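"""Domain identification: order parameters, core atoms, variance clustering.

The left branch of the pipeline.  Local order of each rotatable dihedral is
summarized by the angular order parameter

    S = | (1/N) Σ_k (cos θ_k, sin θ_k) |,          0 ≤ S ≤ 1,

the length of the mean unit resultant of the angle over the N conformers.
An automatic cutoff S^cut separates ordered from disordered torsions: with
the s order parameters ranked ascending (rank 1 = smallest), S^cut is the
S_i maximizing

    Q_i = (r_i / s) · (S^max − S_i) / (S^max − S^min),

a rank-weighted elbow criterion that peaks at the top of the disordered
population.  Core atoms are the CA atoms of residues carrying at least one
torsion with S strictly above S^cut.

Core atoms are clustered agglomeratively on the distance-variance matrix
V_ij (variance over conformers of the intra-conformer CA–CA distance): at
each stage the two clusters whose merge gives the lowest intra-cluster
variance of the V_ij entries are joined (for a two-atom merge, the single
V_ij value itself).  Stage quality combines the average cluster spread

    A_i = (1/c_i) Σ_j |cluster_j| · RMSD_j      (clusters with > 1 member)

with the cluster count n_i in the penalty

    P_i = 1 + (C − 2)·(A_i − A^min)/(A^max − A^min) + n_i ,

both terms spanning 1 … C−1.  The stage minimizing P is accepted provided
the mean size of clusters with ≥ μ members exceeds ⌈C/8⌉; otherwise the
minimum is re-sought among later stages.  Qualifying clusters become
domains, whose residue ranges are extended by m residues at every boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .bundle import StructureBundle
from .errors import DegenerateOrderParameters, NoCoreAtoms, NoDomainsFound
from .geometry import fit_ensemble
from .torsions import TorsionRecord


# --------------------------------------------------------------------- Eq. 1
def order_parameter(values_deg: np.ndarray) -> float:
    """Angular order parameter S of one torsion across the conformers."""
    theta = np.radians(np.asarray(values_deg, dtype=float))
    if theta.size < 2:
        raise ValueError("order parameter needs at least 2 angle values")
    c = np.cos(theta).mean()
    s = np.sin(theta).mean()
    return float(np.hypot(c, s))


def annotate_order_parameters(records: Sequence[TorsionRecord]) -> None:
    """Fill the ``order_param`` field of every torsion record in place."""
    for rec in records:
        rec.order_param = order_parameter(rec.values)


@dataclass
class OrderParameterTable:
    """Ranked angular order parameters and the derived cutoff quantities."""

    records: list[TorsionRecord]
    s_values: np.ndarray  # ascending
    ranks: np.ndarray  # rank (1…s) of each record, ascending-S order
    q_values: np.ndarray | None = None
    cutoff: float | None = None

    @classmethod
    def from_records(cls, records: Sequence[TorsionRecord]) -> "OrderParameterTable":
        records = list(records)
        s = np.asarray([r.order_param for r in records], dtype=float)
        if np.any(np.isnan(s)):
            raise ValueError("order parameters must be computed first")
        order = np.argsort(s, kind="stable")
        ranks = np.empty(len(records), dtype=int)
        ranks[order] = np.arange(1, len(records) + 1)
        return cls(records=records, s_values=s[order], ranks=ranks)

    @property
    def s(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------- Eq. 2
def select_order_cutoff(table: OrderParameterTable, tol: float = 1e-9) -> float:
    """The automatic order-parameter cutoff S^cut.

    Scans all s candidates exhaustively; ties are broken toward the smallest
    rank for determinism.  Raises :class:`DegenerateOrderParameters` when all
    S values coincide within ``tol`` (no cutoff definable, e.g. an exactly
    rigid bundle where every S is 1 up to rounding).
    """
    s = table.s
    if s < 2:
        raise DegenerateOrderParameters("need at least 2 order parameters")
    s_min = float(table.s_values[0])
    s_max = float(table.s_values[-1])
    if not s_max - s_min > tol:
        raise DegenerateOrderParameters(
            "degenerate order parameters: all S values are equal"
        )
    ranks = np.arange(1, s + 1, dtype=float)
    q = (ranks / s) * (s_max - table.s_values) / (s_max - s_min)
    table.q_values = q
    best = int(np.argmax(q))  # argmax returns the first (smallest-rank) tie
    table.cutoff = float(table.s_values[best])
    return table.cutoff


@dataclass
class CoreAtomSet:
    """Residue positions whose CA atoms act as core atoms."""

    positions: tuple[int, ...]  # sorted residue positions
    cutoff: float | None

    @property
    def count(self) -> int:
        return len(self.positions)


def find_core_atoms(
    bundle: StructureBundle,
    records: Sequence[TorsionRecord],
    cutoff: float | None,
) -> CoreAtomSet:
    """CA atoms of residues with at least one torsion S strictly above the
    cutoff.  ``cutoff=None`` (degenerate order parameters, e.g. an exactly
    rigid bundle) accepts every torsion-bearing residue."""
    chosen: set[int] = set()
    for rec in records:
        if cutoff is None or (rec.order_param is not None and rec.order_param > cutoff):
            chosen.add(rec.position)
    positions = tuple(
        sorted(p for p in chosen if bundle.atom_index(p, "CA") is not None)
    )
    if not positions:
        raise NoCoreAtoms("no core atoms")
    return CoreAtomSet(positions=positions, cutoff=cutoff)


# --------------------------------------------------------------------- Eq. 3
def distance_variance_matrix(
    bundle: StructureBundle,
    core: CoreAtomSet,
    normalization: str = "population",
) -> np.ndarray:
    """C×C matrix of variances (Ų) of inter-core-atom distances.

    ``normalization`` is "population" (divide by N) or "sample" (N−1); the
    choice uniformly rescales the matrix and leaves all clustering decisions
    unchanged.
    """
    idx = np.asarray(
        [bundle.atom_index(p, "CA") for p in core.positions], dtype=int
    )
    ca = bundle.coords[:, idx, :]  # (N, C, 3)
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))  # (N, C, C)
    ddof = 0 if normalization == "population" else 1
    v = d.var(axis=0, ddof=ddof)
    np.fill_diagonal(v, 0.0)
    return v


# ---------------------------------------------------------------- clustering
@dataclass
class ClusteringStage:
    """One level of the agglomerative merge history (1-based ``index``)."""

    index: int
    clusters: list[tuple[int, ...]]  # sorted member tuples (core-atom indices)
    merged: tuple[int, int] | None  # which previous-stage clusters merged
    spread: float | None = None  # A_i (Å); None at stage 1
    penalty: float | None = None  # P_i


@dataclass
class ClusteringTrace:
    """Full merge history plus the spread/penalty values per stage."""

    stages: list[ClusteringStage]
    core: CoreAtomSet
    a_min: float | None = None
    a_max: float | None = None
    chosen_stage: int | None = None


class _PairStats:
    """Running count/sum/sum-of-squares of intra-cluster V entries."""

    __slots__ = ("n", "s1", "s2")

    def __init__(self, n: float = 0.0, s1: float = 0.0, s2: float = 0.0):
        self.n = n
        self.s1 = s1
        self.s2 = s2


def _merge_cost(
    v: np.ndarray,
    a: tuple[int, ...],
    b: tuple[int, ...],
    sa: _PairStats,
    sb: _PairStats,
) -> tuple[float, _PairStats]:
    block = v[np.ix_(a, b)]
    n = sa.n + sb.n + block.size
    s1 = sa.s1 + sb.s1 + float(block.sum())
    s2 = sa.s2 + sb.s2 + float((block**2).sum())
    if n == 1:
        cost = s1  # two-atom cluster: the single V value itself
    else:
        cost = max(s2 / n - (s1 / n) ** 2, 0.0)
    return cost, _PairStats(n, s1, s2)


def cluster_core_atoms(v: np.ndarray) -> ClusteringTrace:
    """Agglomerative merge history over the distance-variance matrix.

    Stage 1 holds C singleton clusters; each stage merges the pair with the
    lowest post-merge intra-cluster V-value variance; stage C is a single
    cluster.  Cost ties are resolved toward the lexicographically smallest
    member indices.
    """
    c = v.shape[0]
    if c < 2:
        raise ValueError("clustering needs at least 2 core atoms")
    clusters: list[tuple[int, ...]] = [(i,) for i in range(c)]
    stats: list[_PairStats] = [_PairStats() for _ in range(c)]
    stages = [ClusteringStage(index=1, clusters=list(clusters), merged=None)]
    cost_cache: dict[tuple[tuple[int, ...], tuple[int, ...]], tuple[float, _PairStats]] = {}

    while len(clusters) > 1:
        best: tuple[float, int, int] | None = None
        # clusters are kept sorted by smallest member, so scanning i<j with a
        # strict comparison realizes the lexicographic tie-break
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                key = (clusters[i], clusters[j])
                entry = cost_cache.get(key)
                if entry is None:
                    entry = _merge_cost(v, clusters[i], clusters[j], stats[i], stats[j])
                    cost_cache[key] = entry
                if best is None or entry[0] < best[0]:
                    best = (entry[0], i, j)
        assert best is not None
        _, bi, bj = best
        merged_members = tuple(sorted(clusters[bi] + clusters[bj]))
        merged_stats = cost_cache[(clusters[bi], clusters[bj])][1]
        merged_src = (bi, bj)
        new_clusters = [cl for k, cl in enumerate(clusters) if k not in (bi, bj)]
        new_stats = [st for k, st in enumerate(stats) if k not in (bi, bj)]
        # insert keeping order by smallest member
        insert_at = 0
        while insert_at < len(new_clusters) and new_clusters[insert_at][0] < merged_members[0]:
            insert_at += 1
        new_clusters.insert(insert_at, merged_members)
        new_stats.insert(insert_at, merged_stats)
        clusters, stats = new_clusters, new_stats
        stages.append(
            ClusteringStage(
                index=len(stages) + 1, clusters=list(clusters), merged=merged_src
            )
        )

    return ClusteringTrace(stages=stages, core=CoreAtomSet(tuple(range(c)), None))


# --------------------------------------------------------------------- Eq. 4
def average_cluster_spread(
    clusters: Sequence[tuple[int, ...]],
    cluster_rmsd: Callable[[tuple[int, ...]], float],
) -> float | None:
    """Size-weighted mean ensemble RMSD over the multi-member clusters.

    ``cluster_rmsd`` maps a cluster (core-atom index tuple) to the backbone
    RMSD-to-mean of its residues.  Returns None when every cluster is a
    singleton (stage 1 only).
    """
    total_atoms = 0
    acc = 0.0
    for cl in clusters:
        if len(cl) < 2:
            continue
        r = cluster_rmsd(cl)
        acc += len(cl) * r
        total_atoms += len(cl)
    if total_atoms == 0:
        return None
    return acc / total_atoms


def evaluate_trace(
    trace: ClusteringTrace,
    bundle: StructureBundle,
    core: CoreAtomSet,
    spread_tol: float = 1e-9,
) -> None:
    """Fill A_i and P_i for stages 2…C of a merge history.

    Cluster RMSDs are memoized: clusters propagate unchanged between stages,
    so each distinct cluster is evaluated once.  When the spread range is
    below ``spread_tol`` (effectively rigid bundles) the normalized spread
    term is zero for every stage.
    """
    trace.core = core
    cache: dict[tuple[int, ...], float] = {}

    def cluster_rmsd(cl: tuple[int, ...]) -> float:
        r = cache.get(cl)
        if r is None:
            positions = [core.positions[i] for i in cl]
            sel = bundle.backbone_selection(positions)
            r = fit_ensemble(bundle.coords[:, sel.atom_indices, :]).rmsd
            cache[cl] = r
        return r

    for stage in trace.stages[1:]:
        stage.spread = average_cluster_spread(stage.clusters, cluster_rmsd)

    spreads = [s.spread for s in trace.stages[1:] if s.spread is not None]
    if not spreads:
        return
    a_min = min(spreads)
    a_max = max(spreads)
    trace.a_min, trace.a_max = a_min, a_max
    c = core.count
    for stage in trace.stages[1:]:
        if stage.spread is None:
            continue
        if a_max - a_min > spread_tol:
            norm = (stage.spread - a_min) / (a_max - a_min)
        else:
            norm = 0.0
        n_i = len(stage.clusters)
        stage.penalty = 1.0 + (c - 2) * norm + n_i


# --------------------------------------------------------------------- Eq. 5
def select_clustering_stage(trace: ClusteringTrace, mu: int) -> int:
    """Index (1-based) of the optimal clustering stage.

    Minimizes P_i over stages 2…C; a stage is accepted only if the average
    size of its clusters with ≥ μ members strictly exceeds ⌈C/8⌉, otherwise
    the minimum is re-sought over the later stages.  Raises
    :class:`NoDomainsFound` when no stage qualifies.
    """
    c = trace.core.count
    threshold = math.ceil(c / 8)
    lo = 2
    while lo <= len(trace.stages):
        candidates = [
            s for s in trace.stages[lo - 1 :] if s.penalty is not None
        ]
        if not candidates:
            break
        best = min(candidates, key=lambda s: (s.penalty, s.index))
        sizes = [len(cl) for cl in best.clusters if len(cl) >= mu]
        if sizes and sum(sizes) / len(sizes) > threshold:
            trace.chosen_stage = best.index
            return best.index
        lo = best.index + 1
    raise NoDomainsFound("no domains found")


# ------------------------------------------------------------------- domains
@dataclass
class Domain:
    """A qualifying cluster with its boundary-extended residue set."""

    core_positions: tuple[int, ...]
    extended_positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.core_positions)


def extract_domains(
    trace: ClusteringTrace,
    stage_index: int,
    mu: int,
    m: int,
    bundle: StructureBundle,
) -> list[Domain]:
    """Domains at the chosen stage: clusters with ≥ μ core atoms, their
    residue ranges extended by ``m`` residues at every boundary (clipped at
    chain termini)."""
    stage = trace.stages[stage_index - 1]
    domains: list[Domain] = []
    for cl in stage.clusters:
        if len(cl) < mu:
            continue
        core_pos = tuple(sorted(trace.core.positions[i] for i in cl))
        extended: set[int] = set()
        for start, stop in _runs(core_pos, bundle):
            chain_range = bundle.positions(bundle.chain_of(start))
            lo = max(start - m, chain_range.start)
            hi = min(stop + m, chain_range.stop - 1)
            extended.update(range(lo, hi + 1))
        domains.append(
            Domain(core_positions=core_pos, extended_positions=tuple(sorted(extended)))
        )
    if not domains:
        raise NoDomainsFound("no domains found")
    domains.sort(key=lambda d: d.core_positions[0])
    return domains


def _runs(positions: Sequence[int], bundle: StructureBundle):
    """Maximal runs of consecutive same-chain positions as (start, stop)."""
    runs = []
    it = iter(positions)
    start = prev = next(it)
    for p in it:
        if p == prev + 1 and bundle.same_chain(prev, p):
            prev = p
            continue
        runs.append((start, prev))
        start = prev = p
    runs.append((start, prev))
    return runs
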