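# Methods

## Model and procedure

`ensemblerange` treats a structure bundle as N conformers sharing one
atom/residue topology.  The question it answers is global, not local: which
residue set can be *simultaneously* superimposed with a low backbone
RMSD-to-mean, and how many rigid units (domains) does the bundle contain?
The procedure has two stages.

### Local order and core atoms

Each rotatable dihedral (φ, ψ, χ1–χ5; ω is a partial double bond and is
excluded) contributes an angular order parameter

    S = | (1/N) Σₖ (cos θₖ, sin θₖ) |,

the resultant length of the angle treated as a unit vector — 1 for a
perfectly reproducible angle, near 1/√N for uniformly random ones.  Because
the absolute degree of order differs between bundles, the cutoff separating
ordered from disordered torsions is chosen per bundle: with the s values
ranked ascending (rank 1 = smallest),

    Q_i = (r_i / s) · (S^max − S_i) / (S^max − S^min)

is maximized over all i.  Within a disordered population Q grows with rank
while (S^max − S_i) stays large, and it collapses once S approaches S^max,
so the maximum sits at the top of the disordered population; the strict
requirement S > S^cut then selects exactly the well-ordered torsions.  Core
atoms are the CA atoms of residues holding at least one such torsion.  Using
all rotatable dihedrals (rather than φ/ψ/χ1 only, available via
`torsion_mode="phipsichi1"`) yields a broader core-atom base; both modes are
exposed because they occasionally disagree at domain boundaries.

### Clustering and stage selection

The distance-variance matrix V_ij = Var_k(d_ijk) over core-atom pairs is
invariant under per-conformer rigid motions: atoms of one rigid unit have
near-zero mutual variance regardless of how the unit tumbles between
conformers.  Variance is computed with population normalization (divide by
N); a `variance_normalization="sample"` switch exists, and since the choice
rescales the matrix uniformly it provably never changes a clustering
decision (asserted in the tests).

Agglomerative clustering starts from singletons and at each stage merges
the two clusters whose union has the lowest variance of its V entries (for
a two-atom union, the single V value itself — which makes cross-domain
pairs expensive from the first merge on).  Ties are broken toward the
lexicographically smallest member indices, making the trace deterministic.
There are exactly C stages for C core atoms.

Stage quality combines homogeneity and parsimony.  The average cluster
spread A_i is the size-weighted mean, over clusters with more than one
member, of the cluster's backbone (N/CA/C') RMSD-to-mean; the weighting
follows from defining the normalizer c_i as the total number of core atoms
in multi-member clusters.  The penalty

    P_i = 1 + (C − 2)·(A_i − A^min)/(A^max − A^min) + n_i

normalizes both the spread term and the cluster count n_i to the range
1…C−1.  The stage with minimal P is accepted only if the mean size of its
clusters with ≥ μ members strictly exceeds ⌈C/8⌉; otherwise the minimum is
re-sought among later stages, and if the search exhausts all stages the
bundle has no domains (typical for short, largely disordered peptides whose
core set is smaller than μ).  Qualifying clusters become domains and their
residue ranges are extended by m residues per boundary so that the
refinement stage starts from a generous superset.

### Refinement

Per domain, residues are removed one at a time (steps repeat until the set
is stable): ensemble fit on the current selection (all conformers onto the
first; the mean is not re-fit iteratively), removal of isolated residues,
then removal of the largest-displacement candidate — endpoint candidates
(no new gap) compete against interior candidates (new gap, decrease
weighted by γ) — provided the decrease passes both an absolute and a
relative threshold scaled by the residue's share n/N of the fitted atoms.
The relative threshold δ_rel = δ + 3/M inflates as the selection M shrinks,
which guarantees termination.  If the two displacement-ranked candidates
fail, every selected residue is retried exhaustively; displacement ranking
exists purely to keep the number of RMSD evaluations low.  After
convergence, gaps shorter than g are filled once, and the reported RMSD is
recomputed on the post-fill selection (so the printed number always belongs
to the printed ranges; filling may raise it slightly).

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| μ (`mu`) | 8 | core atoms | minimal cluster size to count as a domain |
| m | 3 | residues | boundary extension before refinement |
| γ (`gamma`) | 0.4 | — | gap penalty; 0 forbids new gaps, 1 ignores them |
| δ (`delta`) | 1.2 | — | base of relative decrease threshold δ + 3/M |
| δ_abs (`delta_abs`) | 1.6 | Å | absolute decrease threshold |
| g | 3 | residues | gaps shorter than g are filled |

All are overridable per run (CLI flags or `RefinementParams`).  On the
synthetic fixtures the result is flat over μ ∈ [6,10], m ∈ [1,5] and
g ∈ [1,5]; only γ meaningfully steers the output, trading gaps against
coverage.

## Numerical choices and degenerate inputs

* Superpositions use the Kabsch SVD solution with a reflection guard (the
  smallest singular direction is flipped when the orthogonal optimum is
  improper), so rotations are always proper even for near-planar
  selections.  The kernel is cross-checked against an independent
  quaternion-method (Kearsley) oracle to 1e-8 Å.
* For a two-conformer bundle the RMSD-to-mean is exactly half the pairwise
  RMSD; this identity is asserted to 1e-9 Å.
* If every order parameter is equal within 1e-9 (an exactly rigid bundle),
  the cutoff is undefined and every torsion-bearing residue is taken as
  core.  If the spread range A^max − A^min is below 1e-9 Å (again the rigid
  case), the normalized spread term is set to 0 for all stages rather than
  amplifying floating-point noise; the penalty then reduces to 1 + n_i and
  the single-cluster stage wins, as it should.
* Cost and penalty ties are broken toward smaller indices/residue numbers;
  identical input and parameters give byte-identical structured reports.
* Residues missing any backbone atom are never selectable and behave as
  pre-existing gaps: they are not "new" gaps when a neighbour is removed,
  and gaps containing them are never filled.  Chains are never merged; a
  chain boundary acts as an unfillable gap, and author numbering gaps
  (missing residues) break φ/ψ computation like chain breaks.
* Cluster RMSDs are memoized per distinct cluster during trace evaluation
  (clusters propagate unchanged between merges), reducing O(C²) ensemble
  fits to O(C) with identical results.

## The synthetic generator

`ensemblerange.synthetic` builds serine-like chains (N, CA, C', O, CB, OG)
from ideal internal coordinates so that φ, ψ and χ1 all exist.  Regions are
`rigid`/`noisy` (template torsions plus isotropic Cartesian noise σ) or
`tail`/`linker` (φ, ψ, χ1 resampled uniformly per conformer).  Consecutive
rigid/noisy regions form blocks; under the `independent` motion policy each
block receives a uniformly random rotation and a translation per conformer,
emulating flexibly linked domains.  Every conformer finally gets one global
random rigid motion.  Default conditions used throughout the tests:
20 conformers, σ_core = 0.1 Å (a tight NMR bundle), disordered loops at
σ = 4 Å, and fixture sizes of 40–90 residues — small enough that the full
suite runs in well under a minute per fixture on one CPU, large enough that
C ≫ μ for every ordered fixture.  The fully-random "no domains" fixture is
10 residues, mirroring the observation that this failure mode arises for
short disordered peptides: for larger random bundles the final clustering
stage always offers one cluster of C ≥ μ core atoms, so a (high-RMSD)
domain is still reported.

What the generator does *not* emulate: side-chain diversity, sterics,
realistic loop ensembles, coordinate errors correlated along the chain, or
experimental restraint structure.  Passing tests therefore demonstrate the
algorithmic properties (invariances, recovery of planted order/domain
structure, parameter plateaus, failure modes), not performance on
experimental depositions.

## Design choices where the design was open

* Superposition target is always the first conformer, and the mean is not
  re-fit; the reported r is the mean over conformers of each conformer's
  RMSD to the mean coordinates.
* "Opens a new gap" is decided purely by run topology: endpoints (including
  singletons) never open gaps, interior residues always do; ties between
  the no-gap and gap candidates prefer the no-gap removal.
* A lone residue at a chain terminus counts as isolated (a missing
  neighbour is "unselected"), so one-residue islands cannot survive.
* One residue may serve as both step-3 candidates when it is simultaneously
  the global displacement maximum and an endpoint.
* Every RMSD evaluated during refinement is a fresh fit of the reduced
  selection (no reuse of the previous superposition).
* Gap filling runs exactly once, after convergence, and does not re-enter
  the loop.
* Alternate locations keep the highest-occupancy variant; hydrogens are
  ignored; hetero residues without CA are dropped; atoms missing from some
  model are dropped from all models with a warning.

## Limitations

* Bundles that mix alternative conformations *within* individual models are
  not handled and will produce unreliable ranges.
* No structure repair or hydrogen handling; insertion codes are supported
  but unusual author numbering (decreasing within a chain) is rejected.
* Very small ordered cores (< μ residues) are reported as "no domains
  found" by construction; lowering μ is the only recourse.
* The method optimizes global superimposability, not local order: a loop
  that is locally well-defined but mobile relative to the core is excluded,
  by design.
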