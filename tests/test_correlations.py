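"""DCCM, LMI, loop-pair averaging, network building, Girvan–Newman."""

import itertools

import numpy as np
import networkx as nx
import pytest
from networkx.algorithms.community import modularity as nx_modularity

from loopdyn.correlations import (CorrelationMatrix, build_network, dccm,
                                  girvan_newman, lmi, loop_pair_average)
from loopdyn.ensembles import Ensemble, EnsembleError, LoopDefinition, SelectionMask
from loopdyn.synthetic import GaussianEnsembleSpec, gaussian_ensemble


def gaussian(n_res, rho, n_frames, seed, sigma=1.0, ca_coords=None):
    return gaussian_ensemble(GaussianEnsembleSpec(
        n_res, np.full(n_res, sigma), n_frames=n_frames, seed=seed, rho=rho,
        ca_coords=ca_coords,
    ))


class TestDccm:
    def test_perfectly_coupled_pair_is_plus_one(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 1.0
        ens = gaussian(3, rho, 200, seed=1)
        mat = dccm(ens, SelectionMask.alpha_carbons(ens.topology))
        assert mat.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_anticoupled_pair_is_minus_one(self):
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = -1.0
        ens = gaussian(2, rho, 200, seed=2)
        mat = dccm(ens, SelectionMask.alpha_carbons(ens.topology))
        assert mat.matrix[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_residues_decorrelate(self):
        ens = gaussian(5, None, 20000, seed=3)
        mat = dccm(ens, SelectionMask.alpha_carbons(ens.topology))
        off = mat.matrix[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_zero_variance_residue_reported_missing(self, caplog):
        ens = gaussian_ensemble(GaussianEnsembleSpec(
            3, np.array([1.0, 0.0, 1.0]), n_frames=100, seed=4
        ))
        with caplog.at_level("WARNING"):
            mat = dccm(ens, SelectionMask.alpha_carbons(ens.topology))
        assert np.isnan(mat.matrix[0, 1]) and np.isnan(mat.matrix[1, 2])
        assert mat.matrix[0, 2] == mat.matrix[0, 2]  # defined


class TestLoopPairAverage:
    def make_matrix(self, values):
        n = values.shape[0]
        residues = [("A", i + 1) for i in range(n)]
        return CorrelationMatrix(residues, values, "dccm")

    def loop(self, name, res_ids):
        return LoopDefinition(name, "A", np.array(res_ids), "A" * len(res_ids))

    def test_constant_rectangle(self):
        m = np.eye(4)
        m[0:2, 2:4] = m[2:4, 0:2] = 0.42
        table = loop_pair_average(
            self.make_matrix(m), [self.loop("x", [1, 2]), self.loop("y", [3, 4])]
        )
        assert table.loc["x", "y"] == pytest.approx(0.42)

    def test_hand_computed_rectangle(self):
        m = np.eye(4)
        m[0:2, 2:4] = np.array([[0.2, 0.4], [0.6, 0.8]])
        m[2:4, 0:2] = m[0:2, 2:4].T
        table = loop_pair_average(
            self.make_matrix(m), [self.loop("x", [1, 2]), self.loop("y", [3, 4])]
        )
        assert table.loc["x", "y"] == pytest.approx(0.5)

    def test_same_loop_uses_off_diagonal_only(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.6
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.4
        table = loop_pair_average(self.make_matrix(m),
                                  [self.loop("x", [1, 2, 3])])
        assert table.loc["x", "x"] == pytest.approx((0.6 + 0.2 + 0.4) / 3)

    def test_planted_block_mean_recovered(self):
        # two 6-residue loops with inter-loop correlation 0.42 planted
        n = 12
        rho = np.eye(n)
        a, b = np.arange(0, 6), np.arange(6, 12)
        for i in a:
            for j in a:
                if i != j:
                    rho[i, j] = 0.9
        for i in b:
            for j in b:
                if i != j:
                    rho[i, j] = 0.9
        rho[np.ix_(a, b)] = 0.42
        rho[np.ix_(b, a)] = 0.42
        ens = gaussian(n, rho, 20000, seed=5)
        mat = dccm(ens, SelectionMask.alpha_carbons(ens.topology))
        table = loop_pair_average(
            mat, [self.loop("la", list(range(1, 7))),
                  self.loop("lb", list(range(7, 13)))]
        )
        assert table.loc["la", "lb"] == pytest.approx(0.42, abs=0.02)


class TestLmi:
    def test_independent_residues_near_zero(self):
        ens = gaussian(4, None, 50000, seed=6)
        mat = lmi(ens, SelectionMask.alpha_carbons(ens.topology))
        off = mat.matrix[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.01

    @pytest.mark.parametrize("r", [0.2, 0.5, 0.8])
    def test_gaussian_closed_form(self, r):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = r
        ens = gaussian(3, rho, 50000, seed=int(10 * r))
        mat = lmi(ens, SelectionMask.alpha_carbons(ens.topology))
        assert mat.matrix[0, 1] == pytest.approx(
            -1.5 * np.log(1 - r * r), abs=0.03
        )

    def test_perfect_coupling_flagged_infinite(self):
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = 1.0
        ens = gaussian(2, rho, 500, seed=7)
        mat = lmi(ens, SelectionMask.alpha_carbons(ens.topology))
        assert np.isinf(mat.matrix[0, 1])

    def test_companion_distances_are_frame_averaged(self):
        ens = gaussian(3, None, 100, seed=8)
        mask = SelectionMask.alpha_carbons(ens.topology)
        mat = lmi(ens, mask)
        sub = ens.coords[:, mask.indices, :]
        expected = np.linalg.norm(sub[:, 0] - sub[:, 1], axis=1).mean()
        assert mat.distances[0, 1] == pytest.approx(expected)


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


class TestGirvanNewman:
    def two_cliques(self, k):
        g = nx.Graph()
        a = [f"a{i}" for i in range(k)]
        b = [f"b{i}" for i in range(k)]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        g.add_edge(a[0], b[0])
        return g, a, b

    def test_two_cliques_with_bridge_split_at_bridge(self):
        g, a, b = self.two_cliques(5)
        part = girvan_newman(g)
        groups = {}
        for node, c in part.assignment.items():
            groups.setdefault(c, set()).add(node)
        assert set(map(frozenset, groups.values())) == \
               {frozenset(a), frozenset(b)}
        assert part.edge_weights == {(0, 1): 1.0}

    def test_matches_brute_force_max_modularity(self):
        """Exhaustive modularity over all partitions confirms the result."""
        g, a, b = self.two_cliques(4)
        nodes = sorted(g.nodes)
        best_q, best = -np.inf, None
        for part in set_partitions(nodes):
            q = nx_modularity(g, [set(p) for p in part])
            if q > best_q:
                best_q, best = q, part
        got = girvan_newman(g)
        got_groups = {}
        for node, c in got.assignment.items():
            got_groups.setdefault(c, set()).add(node)
        assert set(map(frozenset, got_groups.values())) == \
               set(frozenset(p) for p in best)

    def test_single_clique_is_one_community(self):
        g = nx.complete_graph(6)
        assert girvan_newman(g).n_communities == 1

    def test_disconnected_components_stay_separate(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (10, 11), (11, 12)])
        part = girvan_newman(g)
        assert part.assignment[0] != part.assignment[10]

    def test_edgeless_graph_gives_singletons(self, caplog):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        with caplog.at_level("WARNING"):
            part = girvan_newman(g)
        assert part.n_communities == 3
        assert "no edges" in caplog.text


class TestBuildNetwork:
    def hand_matrix(self, lmi_vals, dists):
        n = lmi_vals.shape[0]
        residues = [("A", i + 1) for i in range(n)]
        np.fill_diagonal(lmi_vals, np.inf)
        return CorrelationMatrix(residues, lmi_vals, "lmi", dists)

    def test_tie_selects_larger_cutoff(self):
        # two triangles, all edges short: identical communities at every cutoff
        lmi_vals = np.zeros((6, 6))
        dists = np.full((6, 6), 50.0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        lmi_vals[i, j] = 1.0
                        dists[i, j] = 5.0
        _, part = build_network(self.hand_matrix(lmi_vals, dists))
        assert part.selected_cutoff == pytest.approx(10.0)
        assert part.n_communities == 2

    def test_cutoff_minimising_community_count_wins(self):
        # two triangles, each with a pendant node whose only edge sits at
        # 8.5 Å: 4 communities at 8 Å, 2 at 9/10 Å → select 10 Å
        n = 8
        lmi_vals = np.zeros((n, n))
        dists = np.full((n, n), 50.0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        lmi_vals[i, j] = 1.0
                        dists[i, j] = 5.0
        for pendant, anchor in ((6, 0), (7, 3)):
            lmi_vals[pendant, anchor] = lmi_vals[anchor, pendant] = 1.0
            dists[pendant, anchor] = dists[anchor, pendant] = 8.5
        mat = self.hand_matrix(lmi_vals, dists)
        _, part = build_network(mat)
        assert part.selected_cutoff == pytest.approx(10.0)
        assert part.n_communities == 2

        # brute-force scan over the same cutoffs confirms the selection
        counts = {}
        for cutoff in np.arange(8.0, 10.25, 0.5):
            g = nx.Graph()
            g.add_nodes_from(mat.residues)
            for i in range(n):
                for j in range(i + 1, n):
                    if lmi_vals[i, j] >= 0.4 and dists[i, j] <= cutoff:
                        g.add_edge(mat.residues[i], mat.residues[j])
            counts[cutoff] = girvan_newman(g).n_communities
        expected = max(
            (c for c in counts if counts[c] == min(counts.values()))
        )
        assert part.selected_cutoff == pytest.approx(expected)

    def test_all_below_threshold_is_error(self):
        lmi_vals = np.full((4, 4), 0.1)
        dists = np.full((4, 4), 5.0)
        with pytest.raises(EnsembleError, match="no edges"):
            build_network(self.hand_matrix(lmi_vals, dists))

    def test_planted_two_block_partition_recovered_exactly(self):
        # two spatially separated blocks, high intra-block correlation
        n = 12
        coords = np.zeros((n, 3))
        for k in range(n):
            block, pos = k // 6, k % 6
            angle = np.pi * pos / 3.0
            coords[k] = [2.5 * np.cos(angle), 2.5 * np.sin(angle),
                         40.0 * block]
        rho = np.eye(n)
        for blk in (range(0, 6), range(6, 12)):
            for i in blk:
                for j in blk:
                    if i != j:
                        rho[i, j] = 0.9
        ens = gaussian(n, rho, 5000, seed=9, ca_coords=coords)
        mask = SelectionMask.alpha_carbons(ens.topology)
        mat = lmi(ens, mask)
        _, part = build_network(mat)
        labels = [part.assignment[("A", i + 1)] for i in range(n)]
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
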