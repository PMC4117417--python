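"""LFA/IDS, commute times, interaction graphs, pathways and hubs."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from allodyn import (CommGraph, Trajectory, build_comm_graph, build_ids,
                     calibrate_ctcut, calibrate_pcut, classify_pathways,
                     commute_time_matrix, compute_pca,
                     efficient_partner_counts, export_graph, find_hubs,
                     grow_pathways, interaction_graph, lfa_transform,
                     modes_for_fraction, select, synth, verify_pathways)
from allodyn.network import LFAResult, communication_partners
from conftest import ca_selection


class TestLfaTransform:
    def test_rigid_block_correlations(self):
        top, mean = synth.helix_mean_structure(60)
        block = list(range(10, 20))
        spec = synth.GaussianEnsembleSpec(
            topology=top, mean_coords=mean, sigma=0.3,
            blocks=[(block, 0.97)], n_frames=1500, seed=0)
        traj = synth.sample_gaussian_trajectory(spec)
        ms = compute_pca(traj, ca_selection(top))
        lfa = lfa_transform(ms, modes_for_fraction(ms, 0.8),
                            residue_numbers=top.residues)
        pos = [r - 1 for r in block]
        inside = lfa.correlations[np.ix_(pos, pos)]
        iu = np.triu_indices(len(pos), 1)
        outside = lfa.correlations[np.ix_(pos, [40, 45, 50, 55])]
        assert inside[iu].min() > 0.8
        assert np.abs(outside).max() < 0.3

    def test_diagonal_dominance(self, planted_traj):
        traj, spec, _ = planted_traj
        ms = compute_pca(traj, ca_selection(traj.topology))
        lfa = lfa_transform(ms, 10)
        p = lfa.correlations
        for i in range(p.shape[0]):
            assert p[i, i] >= p[i].max() - 1e-9

    def test_independent_blocks_have_no_cross_correlation(self):
        top, mean = synth.helix_mean_structure(60)
        b1, b2 = list(range(5, 15)), list(range(35, 45))
        spec = synth.GaussianEnsembleSpec(
            topology=top, mean_coords=mean, sigma=0.3,
            blocks=[(b1, 0.95), (b2, 0.95)], n_frames=1500, seed=1)
        traj = synth.sample_gaussian_trajectory(spec)
        ms = compute_pca(traj, ca_selection(top))
        lfa = lfa_transform(ms, modes_for_fraction(ms, 0.8),
                            residue_numbers=top.residues)
        cross = lfa.correlations[np.ix_([r - 1 for r in b1],
                                        [r - 1 for r in b2])]
        assert np.abs(cross).max() < 0.3

    def test_mode_count_validation(self, planted_traj):
        traj, _, _ = planted_traj
        ms = compute_pca(traj, ca_selection(traj.topology))
        with pytest.raises(ValueError):
            lfa_transform(ms, 0)


class TestCalibratePcut:
    def test_fraction_in_band(self, planted_traj):
        traj, _, _ = planted_traj
        ms = compute_pca(traj, ca_selection(traj.topology))
        lfa = lfa_transform(ms, modes_for_fraction(ms, 0.8))
        calibrate_pcut(lfa)
        assert 0.010 <= lfa.fraction_above <= 0.012

    def test_expected_count_above(self):
        rng = np.random.default_rng(0)
        n = 46  # 1035 off-diagonal pairs
        m = rng.random((n, n))
        corr = (m + m.T) / 2
        np.fill_diagonal(corr, 1.0)
        lfa = LFAResult(n_modes=5, residues=np.arange(n), kernel=corr,
                        correlations=corr, output_matrix=np.zeros((1, 1)))
        p_cut = calibrate_pcut(lfa)
        iu = np.triu_indices(n, 1)
        above = (np.abs(corr[iu]) > p_cut).sum()
        assert above == round(0.011 * len(iu[0]))

    def test_degenerate_correlations_rejected(self):
        corr = np.ones((20, 20))
        lfa = LFAResult(n_modes=2, residues=np.arange(20), kernel=corr,
                        correlations=corr, output_matrix=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            calibrate_pcut(lfa)


class TestBuildIds:
    def test_planted_blocks_recovered(self, planted_traj):
        traj, spec, truth = planted_traj
        ms = compute_pca(traj, ca_selection(traj.topology))
        lfa = lfa_transform(ms, modes_for_fraction(ms, 0.8),
                            residue_numbers=traj.topology.residues)
        calibrate_pcut(lfa)
        segments = build_ids(lfa)
        for block in truth["blocks"]:
            want = set(block)
            jac = max(len(want & set(s.members)) /
                      len(want | set(s.members)) for s in segments)
            assert jac >= 0.8

    def test_no_correlated_partners_gives_singletons(self):
        n = 20
        corr = np.eye(n)
        kernel = np.eye(n) * np.linspace(2.0, 1.0, n)
        lfa = LFAResult(n_modes=4, residues=np.arange(100, 100 + n),
                        kernel=kernel, correlations=corr,
                        output_matrix=np.zeros((1, 1)))
        segments = build_ids(lfa, p_cut=0.5)
        assert all(len(s.members) == 1 for s in segments)
        assert all(s.members[0] == s.seed for s in segments)

    def test_uniform_motion_spans_most_residues(self):
        n = 30
        corr = np.full((n, n), 0.9)
        np.fill_diagonal(corr, 1.0)
        lfa = LFAResult(n_modes=1, residues=np.arange(n), kernel=corr,
                        correlations=corr, output_matrix=np.zeros((1, 1)))
        segments = build_ids(lfa, p_cut=0.5)
        assert len(segments[0].members) == n


class TestCommuteTime:
    def test_matches_bruteforce_variance(self, rng):
        top = synth.make_topology(4)
        coords = rng.normal(scale=2.0, size=(30, top.n_atoms, 3))
        traj = Trajectory(top, coords)
        sel = ca_selection(top)
        ct = commute_time_matrix(traj, sel, chunk=7)
        for i in range(4):
            for j in range(4):
                d = np.linalg.norm(coords[:, sel.array[i]] -
                                   coords[:, sel.array[j]], axis=1)
                assert ct[i, j] == pytest.approx(d.var(), rel=1e-10,
                                                 abs=1e-12)

    def test_rigid_pair_has_zero_ct(self, helix60):
        top, mean = helix60
        shift = np.random.default_rng(0).normal(size=(40, 1, 3))
        coords = mean[None] + shift  # global translation only
        ct = commute_time_matrix(Trajectory(top, coords),
                                 ca_selection(top))
        assert np.abs(ct).max() < 1e-10

    def test_symmetric_zero_diagonal(self, planted_traj):
        traj, _, _ = planted_traj
        ct = commute_time_matrix(Trajectory(traj.topology,
                                            traj.coords[:100]),
                                 ca_selection(traj.topology))
        np.testing.assert_allclose(ct, ct.T)
        assert np.all(np.diag(ct) == 0)


class TestCalibrateCtcut:
    def test_planted_stiff_block_reaches_target(self):
        top, mean = synth.helix_mean_structure(100)
        block = list(range(30, 50))  # 20 residues = 20%
        spec = synth.GaussianEnsembleSpec(
            topology=top, mean_coords=mean, sigma=0.5,
            stiff_chains=[(block, 0.02)], n_frames=1500, seed=2)
        traj = synth.sample_gaussian_trajectory(spec)
        ct = commute_time_matrix(traj, ca_selection(top))
        cut = calibrate_ctcut(ct, target_fraction=0.20)
        counts = efficient_partner_counts(ct, cut)
        assert abs(counts.max() - 20) <= 2
        # the block is what the calibrated threshold separates
        best = int(np.argmax(counts))
        assert best + 1 in block

    def test_fixed_mode_is_a_passthrough(self):
        # fixed thresholds skip calibration entirely: build_comm_graph
        # accepts the constant directly
        ct = np.array([[0.0, 0.05], [0.05, 0.0]])
        counts = efficient_partner_counts(ct, 0.09)
        assert counts.max() == 1

    def test_degenerate_ct_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ctcut(np.zeros((10, 10)))


class TestInteractionGraph:
    def _traj(self, persistence_frames, total=10):
        """Residues 1 and 3 in contact for the given number of frames."""
        top = synth.make_topology(4)
        base = synth.ideal_backbone_coords([synth.ALPHA_PHI_PSI] * 4)
        far = base.copy()
        far[8:12] += np.array([0, 30.0, 0])   # residue 3 far
        near = base.copy()
        near[8:12] = base[0:4] + np.array([0, 0, 3.0])  # residue 3 close to 1
        frames = [near] * persistence_frames + \
            [far] * (total - persistence_frames)
        return Trajectory(top, np.array(frames))

    def test_permanent_contact_is_an_edge(self):
        traj = self._traj(10)
        edges = interaction_graph(traj)
        assert edges[0, 2]

    def test_40_percent_contact_is_not_an_edge(self):
        traj = self._traj(4)
        edges = interaction_graph(traj)
        assert not edges[0, 2]

    def test_sequence_neighbors_excluded(self, helix60):
        top, mean = helix60
        traj = Trajectory(top, np.repeat(mean[None], 2, axis=0))
        edges = interaction_graph(traj)
        n = edges.shape[0]
        assert not np.any(np.diag(edges, 1))
        assert not np.any(np.diag(edges))
        # helix contacts at |i-j| >= 2 do exist
        assert edges.sum() > 0


class TestGrowPathways:
    def test_planted_chain_recovered(self):
        # 5-residue chain with contacts along it and low pairwise CT
        n = 12
        chain = [2, 4, 6, 8, 10]
        inter = np.zeros((n, n), dtype=bool)
        for a, b in zip(chain[:-1], chain[1:]):
            inter[a, b] = inter[b, a] = True
        ct = np.full((n, n), 5.0)
        np.fill_diagonal(ct, 0.0)
        for a in chain:
            for b in chain:
                if a != b:
                    ct[a, b] = 0.01
        pws = grow_pathways(inter, ct, ct_cut=0.1)
        assert pws == [tuple(chain)]

    def test_no_interactions_no_pathways(self):
        n = 6
        assert grow_pathways(np.zeros((n, n), dtype=bool),
                             np.zeros((n, n)), 1.0) == []

    def test_all_ct_above_cut_no_pathways(self):
        n = 6
        inter = np.ones((n, n), dtype=bool)
        ct = np.full((n, n), 10.0)
        assert grow_pathways(inter, ct, ct_cut=0.1) == []

    def test_outputs_satisfy_growth_constraints(self, planted_traj):
        traj, _, _ = planted_traj
        sel = ca_selection(traj.topology)
        graph = build_comm_graph(traj, sel, stride=5, with_neighbors=False)
        verify_pathways(graph)  # raises on violation
        assert len(graph.pathways) > 0


class TestClassifyPathways:
    def _graph(self, pathways, n=20):
        ct = np.zeros((n, n))
        inter = np.ones((n, n), dtype=bool)
        return CommGraph(residues=np.arange(1, n + 1), ct=ct, ct_cut=1.0,
                         interactions=inter, pathways=pathways)

    def test_length_classes(self):
        coords = np.zeros((20, 3))
        coords[:, 0] = np.arange(20) * 1.0
        g = self._graph([(0, 1, 2), (0, 1, 2, 3, 4), (0, 1, 2, 3, 4, 5)])
        table = classify_pathways(g, coords)
        assert list(table["length_class"]) == ["short", "intermediate",
                                               "long"]

    def test_span_classes_with_10A_boundary(self):
        coords = np.zeros((20, 3))
        coords[:, 0] = np.arange(20) * 2.0
        g = self._graph([(0, 1, 2), (0, 3, 6), (0, 2, 5)])
        table = classify_pathways(g, coords)
        # end-to-end: 4 Å (local), 12 Å (extended), 10 Å exactly (extended)
        assert list(table["span_class"]) == ["local", "extended", "extended"]

    def test_short_pathway_rejected(self):
        g = self._graph([(3,)])
        with pytest.raises(ValueError):
            classify_pathways(g, np.zeros((20, 3)))


class TestFindHubs:
    def _graph(self, pathways, n):
        ct = np.zeros((n, n))
        inter = np.ones((n, n), dtype=bool)
        return CommGraph(residues=np.arange(1, n + 1), ct=ct, ct_cut=1.0,
                         interactions=inter, pathways=pathways)

    def test_complete_coverage_makes_all_hubs(self):
        n = 10
        g = self._graph([tuple(range(n))], n)
        hubs, table = find_hubs(g)
        assert len(hubs) == n

    def test_no_pathways_no_hubs(self):
        g = self._graph([], 10)
        hubs, table = find_hubs(g)
        assert hubs == []
        assert np.all(table["n_pathways"] == 0)

    def test_star_center_is_the_only_hub(self):
        # center 0 shares 2-residue pathways with 15% of a 100-residue
        # protein; leaves each reach only the center
        n = 100
        pathways = [(0, leaf) for leaf in range(1, 16)]
        g = self._graph(pathways, n)
        hubs, table = find_hubs(g)
        assert hubs == [1]  # author number of residue position 0
        assert table.loc[0, "n_connected"] == 15
        assert np.all(table["n_connected"][1:16] == 1)

    def test_enumeration_order_invariance(self):
        n = 30
        pathways = [(0, 5, 9), (2, 6), (9, 12, 15, 18)]
        g1 = self._graph(list(pathways), n)
        g2 = self._graph(list(pathways[::-1]), n)
        assert find_hubs(g1)[0] == find_hubs(g2)[0]

    def test_direct_mode_counts_ct_partners(self):
        n = 10
        ct = np.full((n, n), 5.0)
        np.fill_diagonal(ct, 0.0)
        ct[0, 1] = ct[1, 0] = 0.01
        g = CommGraph(residues=np.arange(1, n + 1), ct=ct, ct_cut=0.1,
                      interactions=np.zeros((n, n), dtype=bool),
                      pathways=[])
        hubs, table = find_hubs(g, threshold=0.05, mode="direct")
        assert set(hubs) == {1, 2}


class TestExportGraph:
    def test_round_trip_and_attributes(self, tmp_path, planted_traj):
        traj, _, _ = planted_traj
        sub = Trajectory(traj.topology, traj.coords[:150])
        graph = build_comm_graph(sub, ca_selection(traj.topology),
                                 stride=10, with_neighbors=False)
        gml = tmp_path / "net.graphml"
        tsv = tmp_path / "net.tsv"
        export_graph(graph, gml, tsv)
        g = nx.read_graphml(gml)
        assert g.number_of_nodes() == len(graph.residues)
        edges = pd.read_csv(tsv, sep="\t")
        assert g.number_of_edges() == len(edges)
        # pathway steps are a subset of graph edges with the right type
        for pw in graph.pathways:
            for a, b in zip(pw[:-1], pw[1:]):
                u = str(graph.residues[a])
                v = str(graph.residues[b])
                assert g.has_edge(u, v)

    def test_empty_graph_is_valid(self, tmp_path):
        n = 5
        graph = CommGraph(residues=np.arange(1, n + 1),
                          ct=np.zeros((n, n)), ct_cut=0.1,
                          interactions=np.zeros((n, n), dtype=bool),
                          pathways=[])
        gml = tmp_path / "empty.graphml"
        export_graph(graph, gml)
        g = nx.read_graphml(gml)
        assert g.number_of_nodes() == n
        assert g.number_of_edges() == 0
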