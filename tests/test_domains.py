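"""Distance-variance matrix, variance-Ward clustering, stage selection."""

import math

import numpy as np
import pytest

from ensemblerange import StructureBundle
from ensemblerange.domains import (
    ClusteringStage,
    ClusteringTrace,
    CoreAtomSet,
    average_cluster_spread,
    cluster_core_atoms,
    distance_variance_matrix,
    evaluate_trace,
    extract_domains,
    find_core_atoms,
    select_clustering_stage,
)
from ensemblerange.errors import NoCoreAtoms, NoDomainsFound
from ensemblerange.torsions import TorsionRecord, compute_torsions
from ensemblerange import synthetic as syn

from tests.conftest import random_rigid_motion


def _ca_bundle(ca_coords):
    """Bundle with one CA per residue from an (n_conf, n_res, 3) array."""
    n_res = ca_coords.shape[1]
    return StructureBundle(
        ca_coords,
        chain_ids=["A"] * n_res,
        res_numbers=np.arange(1, n_res + 1),
        icodes=[""] * n_res,
        res_names=["GLY"] * n_res,
        atom_names=["CA"] * n_res,
    )


class TestVarianceMatrix:
    def test_two_conformer_hand_value(self):
        # distances between atoms 0 and 1: 3 Å and 5 Å
        coords = np.array(
            [[[0, 0, 0], [3, 0, 0]], [[0, 0, 0], [5, 0, 0]]], dtype=float
        )
        bundle = _ca_bundle(coords)
        core = CoreAtomSet(positions=(0, 1), cutoff=None)
        v_pop = distance_variance_matrix(bundle, core, "population")
        v_smp = distance_variance_matrix(bundle, core, "sample")
        assert v_pop[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert v_smp[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_rigid_bundle_vanishes(self, rigid_bundle):
        core = CoreAtomSet(positions=tuple(range(rigid_bundle.n_residues)), cutoff=None)
        v = distance_variance_matrix(rigid_bundle, core)
        assert v.max() < 1e-10

    def test_invariant_under_per_conformer_rigid_motions(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 8, 3)) * 4
        bundle = _ca_bundle(coords)
        core = CoreAtomSet(positions=tuple(range(8)), cutoff=None)
        v0 = distance_variance_matrix(bundle, core)
        moved = coords.copy()
        for k in range(5):
            rot, shift = random_rigid_motion(rng)
            moved[k] = coords[k] @ rot.T + shift
        v1 = distance_variance_matrix(_ca_bundle(moved), core)
        assert np.allclose(v0, v1, atol=1e-10)

    def test_normalization_choice_does_not_change_clustering(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(6, 10, 3)) * 3
        bundle = _ca_bundle(coords)
        core = CoreAtomSet(positions=tuple(range(10)), cutoff=None)
        t_pop = cluster_core_atoms(distance_variance_matrix(bundle, core, "population"))
        t_smp = cluster_core_atoms(distance_variance_matrix(bundle, core, "sample"))
        for s_pop, s_smp in zip(t_pop.stages, t_smp.stages):
            assert s_pop.clusters == s_smp.clusters


class TestCoreAtoms:
    def test_all_rigid_residues_are_core(self, rigid_bundle):
        records = compute_torsions(rigid_bundle)
        core = find_core_atoms(rigid_bundle, records, None)
        assert core.count == rigid_bundle.n_residues

    def test_ca_only_input_has_no_core_atoms(self, rigid_bundle):
        ca_only = syn.strip_to_ca(rigid_bundle)
        records = compute_torsions(ca_only)
        assert records == []
        with pytest.raises(NoCoreAtoms):
            find_core_atoms(ca_only, records, None)

    def test_cutoff_comparison_is_strict(self):
        bundle = _ca_bundle(np.zeros((2, 2, 3)) + np.arange(2)[None, :, None])
        records = [
            TorsionRecord(position=0, name="phi", values=np.zeros(2), order_param=0.5),
            TorsionRecord(position=1, name="phi", values=np.zeros(2), order_param=0.8),
        ]
        core = find_core_atoms(bundle, records, 0.5)
        assert core.positions == (1,)


class TestClustering:
    def test_two_atoms(self):
        v = np.array([[0.0, 2.0], [2.0, 0.0]])
        trace = cluster_core_atoms(v)
        assert len(trace.stages) == 2
        assert trace.stages[1].clusters == [(0, 1)]

    def test_block_structure_merges_within_blocks_first(self):
        # two rigid pairs (tiny V within), large cross-block variances
        v = np.array(
            [
                [0.0, 0.01, 9.0, 8.0],
                [0.01, 0.0, 8.5, 9.5],
                [9.0, 8.5, 0.0, 0.02],
                [8.0, 9.5, 0.02, 0.0],
            ]
        )
        trace = cluster_core_atoms(v)
        assert trace.stages[1].clusters == [(0, 1), (2,), (3,)]
        assert trace.stages[2].clusters == [(0, 1), (2, 3)]

    def test_trace_length_equals_core_atom_count(self):
        rng = np.random.default_rng(2)
        for c in (2, 5, 9):
            m = rng.uniform(0, 5, size=(c, c))
            v = (m + m.T) / 2
            np.fill_diagonal(v, 0.0)
            trace = cluster_core_atoms(v)
            assert len(trace.stages) == c
            assert trace.stages[0].clusters == [(i,) for i in range(c)]
            assert len(trace.stages[-1].clusters) == 1

    def test_each_merge_minimizes_post_merge_variance(self):
        # brute-force re-evaluation of every candidate merge at every stage
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 4, size=(7, 7))
        v = (m + m.T) / 2
        np.fill_diagonal(v, 0.0)

        def cost(cluster):
            vals = [
                v[a, b] for i, a in enumerate(cluster) for b in cluster[i + 1 :]
            ]
            return vals[0] if len(vals) == 1 else float(np.var(vals))

        trace = cluster_core_atoms(v)
        for prev, cur in zip(trace.stages, trace.stages[1:]):
            merged = next(c for c in cur.clusters if c not in prev.clusters)
            best = min(
                cost(tuple(sorted(a + b)))
                for i, a in enumerate(prev.clusters)
                for b in prev.clusters[i + 1 :]
            )
            assert cost(merged) == pytest.approx(best, abs=1e-12)


class TestSpreadAndStageSelection:
    def test_spread_hand_value(self):
        # clusters of 4 and 4 atoms with RMSD 0.2 / 0.4 → A = 0.3
        rmsds = {(0, 1, 2, 3): 0.2, (4, 5, 6, 7): 0.4}
        a = average_cluster_spread(
            [(0, 1, 2, 3), (4, 5, 6, 7), (8,)], lambda cl: rmsds[cl]
        )
        assert a == pytest.approx(0.3, abs=1e-12)
        # size weighting: 2 atoms at 0.2, 6 atoms at 0.4
        a2 = average_cluster_spread(
            [(0, 1), (2, 3, 4, 5, 6, 7)], lambda cl: 0.2 if len(cl) == 2 else 0.4
        )
        assert a2 == pytest.approx((2 * 0.2 + 6 * 0.4) / 8, abs=1e-12)

    def test_all_singletons_except_pair(self):
        a = average_cluster_spread([(0, 1), (2,), (3,)], lambda cl: 1e-8)
        assert a < 1e-6

    def test_full_cluster_spread_matches_rmsd_to_mean(self, rigid_bundle):
        from ensemblerange.geometry import fit_ensemble

        core = CoreAtomSet(positions=tuple(range(rigid_bundle.n_residues)), cutoff=None)
        v = distance_variance_matrix(rigid_bundle, core)
        trace = cluster_core_atoms(v)
        evaluate_trace(trace, rigid_bundle, core)
        sel = rigid_bundle.backbone_selection(core.positions)
        full = fit_ensemble(rigid_bundle.coords[:, sel.atom_indices, :]).rmsd
        assert trace.stages[-1].spread == pytest.approx(full, abs=1e-9)

    @staticmethod
    def _fake_trace(stage_specs, c):
        """Build a trace from (clusters, spread) pairs for stages 2…C."""
        stages = [ClusteringStage(index=1, clusters=[(i,) for i in range(c)], merged=None)]
        for k, (clusters, spread) in enumerate(stage_specs, start=2):
            stages.append(
                ClusteringStage(index=k, clusters=clusters, merged=None, spread=spread)
            )
        trace = ClusteringTrace(stages=stages, core=CoreAtomSet(tuple(range(c)), None))
        spreads = [s for _, s in stage_specs]
        a_min, a_max = min(spreads), max(spreads)
        for st, (_, spread) in zip(stages[1:], stage_specs):
            norm = 0.0 if a_max == a_min else (spread - a_min) / (a_max - a_min)
            st.penalty = 1.0 + (c - 2) * norm + len(st.clusters)
        return trace

    def test_constraint_hand_case(self):
        # sizes {12, 3} at the P-minimal stage, μ = 8, C = 40:
        # only the 12-cluster qualifies; 12 > ceil(40/8) = 5 → accepted
        c = 40
        clusters_a = [tuple(range(12)), tuple(range(12, 15))] + [
            (i,) for i in range(15, c)
        ]
        trace = self._fake_trace(
            [(clusters_a, 0.1), ([tuple(range(c))], 5.0)], c
        )
        assert select_clustering_stage(trace, mu=8) == 2

    def test_constraint_failure_restarts_above_minimum(self):
        # P-minimal stage has only sub-μ clusters → search continues upward
        c = 16
        small = [tuple(range(4 * i, 4 * i + 4)) for i in range(4)]
        trace = self._fake_trace(
            [(small, 0.05), ([tuple(range(c))], 0.2)], c
        )
        assert select_clustering_stage(trace, mu=8) == 3

    def test_no_stage_satisfies_constraint(self):
        c = 6  # a single 6-atom cluster can never reach μ = 8
        trace = self._fake_trace([([tuple(range(c))], 0.3)], c)
        with pytest.raises(NoDomainsFound):
            select_clustering_stage(trace, mu=8)

    def test_matches_exhaustive_rescan(self, helix_tails_bundle):
        from ensemblerange.domains import (
            OrderParameterTable,
            annotate_order_parameters,
            select_order_cutoff,
        )

        records = compute_torsions(helix_tails_bundle)
        annotate_order_parameters(records)
        cutoff = select_order_cutoff(OrderParameterTable.from_records(records))
        core = find_core_atoms(helix_tails_bundle, records, cutoff)
        v = distance_variance_matrix(helix_tails_bundle, core)
        trace = cluster_core_atoms(v)
        evaluate_trace(trace, helix_tails_bundle, core)
        chosen = select_clustering_stage(trace, mu=8)
        # independent rescan with the same constraint loop, plain python
        threshold = math.ceil(core.count / 8)
        lo = 2
        expected = None
        while expected is None:
            cands = [s for s in trace.stages[lo - 1 :] if s.penalty is not None]
            best = min(cands, key=lambda s: (s.penalty, s.index))
            sizes = [len(cl) for cl in best.clusters if len(cl) >= 8]
            if sizes and sum(sizes) / len(sizes) > threshold:
                expected = best.index
            else:
                lo = best.index + 1
        assert chosen == expected


class TestExtractDomains:
    def test_extension_and_clipping(self):
        bundle = syn.make_bundle(syn.rigid_spec(n_residues=60, n_conformers=2, seed=0))
        core = CoreAtomSet(positions=tuple(range(19, 50)), cutoff=None)
        stages = [
            ClusteringStage(index=1, clusters=[(i,) for i in range(31)], merged=None),
            ClusteringStage(index=2, clusters=[tuple(range(31))], merged=None),
        ]
        trace = ClusteringTrace(stages=stages, core=core)
        domains = extract_domains(trace, 2, mu=8, m=3, bundle=bundle)
        # residues 20–50 (positions 19–49) extended by 3 → positions 16–52
        assert domains[0].extended_positions == tuple(range(16, 53))

    def test_sub_mu_cluster_yields_no_domain(self):
        bundle = syn.make_bundle(syn.rigid_spec(n_residues=10, n_conformers=2, seed=0))
        core = CoreAtomSet(positions=tuple(range(7)), cutoff=None)
        stages = [
            ClusteringStage(index=1, clusters=[(i,) for i in range(7)], merged=None),
            ClusteringStage(index=2, clusters=[tuple(range(7))], merged=None),
        ]
        trace = ClusteringTrace(stages=stages, core=core)
        with pytest.raises(NoDomainsFound):
            extract_domains(trace, 2, mu=8, m=3, bundle=bundle)
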