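# ensemblerange

Objective selection of amino-acid residue ranges for the superposition of
protein structure ensembles (NMR-style bundles).

## The problem

An NMR structure is deposited as a bundle of conformers calculated from the
same experimental data.  Its precision is quoted as the average RMSD between
the conformers and their mean coordinates — but that number, and the visual
quality of any superposition, depend entirely on *which residues* enter the
fit.  Including disordered tails or flexible linkers inflates the RMSD and
obscures well-defined structure; manual range selection is subjective and
irreproducible.  `ensemblerange` determines those ranges automatically, with
one fixed parameter set, for single-domain proteins, multi-domain proteins
connected by flexible linkers, symmetric multimers and complexes.

## The method

Two stages operate on the Cartesian coordinates of ≥ 2 conformers:

**Domain identification.**  For every rotatable dihedral θ (φ, ψ, χ1–χ5; ω
excluded) the angular order parameter

    S = | (1/N) Σₖ (cos θₖ, sin θₖ) | ,   0 ≤ S ≤ 1,

is computed over the N conformers.  A cutoff S^cut is chosen automatically
by ranking the s order parameters ascending and maximizing
Q_i = (r_i/s)·(S^max − S_i)/(S^max − S^min); the CA atoms of residues with at
least one torsion S > S^cut are the *core atoms*.  Core atoms are clustered
agglomeratively on the distance-variance matrix V_ij = Var_k(d_ijk), merging
at each stage the pair of clusters with the lowest intra-cluster variance of
V entries.  The optimal stage minimizes the penalty
P_i = 1 + (C−2)·(A_i − A^min)/(A^max − A^min) + n_i, where A_i is the
size-weighted mean backbone RMSD-to-mean of the multi-member clusters and
n_i the cluster count, subject to the average qualifying-cluster size
exceeding ⌈C/8⌉.  Clusters with ≥ μ core atoms become domains; their residue
ranges are extended by m residues at each boundary.

**Residue-range refinement.**  Each domain is then shrunk one residue at a
time: fit the ensemble (all conformers onto the first, RMSD r to the mean
coordinates of backbone N/CA/C'), drop isolated residues, and remove the
largest-displacement residue whose gap-weighted RMSD decrease
(Δr^nogap = r − r^nogap, Δr^gap = γ·(r − r^gap)) passes both
Δr ≥ δ_abs·n/N and Δr/r ≥ (δ + 3/M)·n/N.  When the displacement-ranked
candidates fail, an exhaustive scan retries every residue; at convergence,
gaps shorter than g residues are filled.  Defaults: μ = 8, m = 3, γ = 0.4,
δ = 1.2, δ_abs = 1.6 Å, g = 3.

The gap penalty γ steers simplicity: γ = 0 yields a contiguous range,
γ = 1 ignores gap formation entirely.

## Worked example

The bundled generator builds ensembles with known ground truth.  Here, two
40-residue rigid helices joined by a 10-residue flexible linker, with
independent random inter-domain orientations in each of 20 conformers:

```sh
python -c "
from ensemblerange import synthetic as syn
from ensemblerange.structure_io import write_bundle
write_bundle(syn.make_bundle(syn.two_domain_spec(seed=5)), 'two_domain.pdb')"
ensemblerange run two_domain.pdb
```

prints

```
Input: two_domain.pdb
Conformers: 20   Residues: 90   Core atoms: 82
Domain 1: A:1..40 (40 residues, RMSD 0.17 Å)
Domain 2: A:51..90 (40 residues, RMSD 0.17 Å)
Coverage: 88.9%   Domains: 2   Intra-domain gaps: 0
```

Both rigid blocks are recovered exactly, the linker is excluded, and each
domain's backbone RMSD-to-mean (0.17 Å) reflects the 0.1 Å coordinate noise
of the generator.  `--out report.json` writes the same result as stable
JSON; `--write-superimposed out.pdb` writes each domain's conformers
superimposed onto the first; `--batch DIR` aggregates a directory of
bundles into a coverage/domain/gap/RMSD table.  Exit codes: 0 success,
1 input error, 2 no core atoms (e.g. CA-only files), 3 no domains found.

As a library:

```python
from ensemblerange import run, RefinementParams
report = run("two_domain.pdb", RefinementParams(gamma=0.0))
print(report.n_domains, report.coverage, [d.ranges for d in report.domains])
```

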