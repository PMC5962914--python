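"""Connectome construction and network measures against independent oracles."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from svdnet.connectome import (
    Connectome,
    assign_endpoints,
    build_connectome,
    global_efficiency,
    local_efficiency_mean,
    network_summaries,
)
from svdnet.phantom import Parcellation
from svdnet.tracking import Streamline, StreamlineSet

from conftest import floyd_warshall_efficiency, floyd_warshall_local_efficiency_mean


def random_weighted_graph(rng, n, p=0.3, wmax=3.0):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < p
    vals = rng.uniform(0.1, wmax, size=len(iu[0])) * mask
    w[iu] = vals
    return w + w.T


def straightline(x0, x1, y, z):
    n = max(2, int(abs(x1 - x0) / 0.5) + 1)
    xs = np.linspace(x0, x1, n)
    return Streamline(np.column_stack([xs, np.full(n, y), np.full(n, z)]))


@pytest.fixture(scope="module")
def small_parcellation():
    labels = np.zeros((20, 4, 4), dtype=np.int32)
    labels[:2] = 5     # x in [0, 5) mm
    labels[-2:] = 12   # x in [45, 50) mm
    labels[9:11, :2] = 7
    return Parcellation(labels, [5, 7, 12], np.diag([2.5, 2.5, 2.5, 1.0]))


class TestAssignEndpoints:
    def test_pair_normalized(self, small_parcellation):
        s = straightline(1.0, 48.0, 5.0, 5.0)
        assert assign_endpoints(s, small_parcellation) == (5, 12)
        s_rev = Streamline(s.points[::-1])
        assert assign_endpoints(s_rev, small_parcellation) == (5, 12)

    def test_background_endpoint_unassigned(self, small_parcellation):
        s = straightline(1.0, 30.0, 5.0, 5.0)  # ends at label 0
        assert assign_endpoints(s, small_parcellation) is None

    def test_self_connection_unassigned(self, small_parcellation):
        s = straightline(0.5, 4.0, 5.0, 5.0)  # both ends in label 5
        assert assign_endpoints(s, small_parcellation) is None

    def test_outside_volume_unassigned(self, small_parcellation):
        pts = np.array([[1.0, 5.0, 5.0], [30.0, 5.0, 5.0], [60.0, 5.0, 5.0]])
        assert assign_endpoints(Streamline(pts), small_parcellation) is None


class TestBuildConnectome:
    def test_hand_computed_weights_and_threshold(self, small_parcellation):
        # 90 streamlines of 45 mm between labels 5 and 12 -> w = 0.5*90/45 = 1.0
        ss = StreamlineSet([straightline(2.5, 47.5, 5.0, 5.0) for _ in range(90)])
        conn = build_connectome(ss, small_parcellation)
        i, j = conn.node_ids.index(5), conn.node_ids.index(12)
        assert conn.weights[i, j] == pytest.approx(1.0)

        # 10 streamlines of 40 mm -> w = 0.125 < 1 -> removed
        ss = StreamlineSet([straightline(4.0, 44.0, 5.0, 5.0) for _ in range(10)])
        conn = build_connectome(ss, small_parcellation)
        assert conn.weights.sum() == 0.0

        # mixed lengths 20 and 25 mm -> raw w = 0.5*(1/20 + 1/25) = 0.045
        ss = StreamlineSet([straightline(4.0, 24.0, 5.0, 5.0),
                            straightline(4.0, 29.0, 5.0, 5.0)])
        # (endpoints at 24/29 are background here, so place within labels)
        conn = build_connectome(ss, small_parcellation, weight_threshold=0.0)
        assert conn.weights.sum() == 0.0  # background endpoints: unassigned

        labels = np.zeros((20, 4, 4), dtype=np.int32)
        labels[:2] = 1
        labels[8:] = 2
        parc = Parcellation(labels, [1, 2], np.diag([2.5, 2.5, 2.5, 1.0]))
        ss = StreamlineSet([straightline(2.0, 22.0, 5.0, 5.0),
                            straightline(1.0, 26.0, 5.0, 5.0)])
        conn = build_connectome(ss, parc, weight_threshold=0.0)
        assert conn.weights.max() == pytest.approx(0.5 * (1 / 20 + 1 / 25))

    def test_symmetry_zero_diagonal(self, small_parcellation):
        ss = StreamlineSet([straightline(2.5, 47.5, 5.0, 5.0)])
        conn = build_connectome(ss, small_parcellation, weight_threshold=0.0)
        assert np.allclose(conn.weights, conn.weights.T)
        assert np.all(np.diag(conn.weights) == 0)

    def test_csv_roundtrip(self, tmp_path, small_parcellation):
        ss = StreamlineSet([straightline(2.5, 47.5, 5.0, 5.0) for _ in range(90)])
        conn = build_connectome(ss, small_parcellation)
        path = tmp_path / "conn.csv"
        conn.save_csv(path)
        back = Connectome.load_csv(path)
        assert np.allclose(back.weights, conn.weights)
        assert back.node_ids == conn.node_ids
        edges = conn.to_edge_list()
        assert len(edges) == 1 and edges.iloc[0]["weight"] == pytest.approx(1.0)


class TestGlobalEfficiency:
    def test_complete_three_node_graph(self):
        for w in (0.5, 1.0, 2.0):
            m = np.full((3, 3), w)
            np.fill_diagonal(m, 0.0)
            assert global_efficiency(m) == pytest.approx(w)

    def test_three_node_path_closed_form(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = m[1, 2] = m[2, 1] = 1.0
        assert global_efficiency(m) == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        assert global_efficiency(np.zeros((2, 2))) == 0.0

    def test_complete_unit_graph_exactly_one(self):
        m = 1.0 - np.eye(6)
        assert global_efficiency(m) == 1.0

    def test_monotone_in_added_edges(self):
        rng = np.random.default_rng(3)
        w = random_weighted_graph(rng, 12, p=0.2)
        e0 = global_efficiency(w)
        w2 = w.copy()
        zeros = np.argwhere((w2 == 0) & ~np.eye(12, dtype=bool))
        i, j = zeros[0]
        w2[i, j] = w2[j, i] = 1.5
        assert global_efficiency(w2) >= e0 - 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        w = random_weighted_graph(rng, n, p=float(rng.uniform(0.1, 0.9)))
        assert global_efficiency(w) == pytest.approx(
            floyd_warshall_efficiency(w), abs=1e-10)

    def test_matches_networkx_on_unit_weights(self):
        # independent library cross-check for the unweighted special case
        rng = np.random.default_rng(7)
        w = (random_weighted_graph(rng, 10, p=0.4) > 0).astype(float)
        g = nx.from_numpy_array(w)
        assert global_efficiency(w) == pytest.approx(nx.global_efficiency(g))


class TestLocalEfficiency:
    def test_triangle_all_ones(self):
        m = 1.0 - np.eye(3)
        assert local_efficiency_mean(m) == pytest.approx(1.0)

    def test_star_graph_zero(self):
        m = np.zeros((5, 5))
        m[0, 1:] = m[1:, 0] = 1.0
        assert local_efficiency_mean(m) == 0.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_neighbourhood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, 10, p=0.4)
        assert local_efficiency_mean(w) == pytest.approx(
            floyd_warshall_local_efficiency_mean(w), abs=1e-10)


class TestNetworkSummaries:
    def test_single_edge_counts(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        s = network_summaries(Connectome(w, [1, 2, 3, 4]))
        assert s.n_edges == 1
        assert s.mean_edge_weight == 2.0
        assert s.total_strength == 4.0  # both row entries counted

    def test_complete_k4_unit(self):
        w = 1.0 - np.eye(4)
        s = network_summaries(Connectome(w, [1, 2, 3, 4]))
        assert s.n_edges == 6
        assert s.global_efficiency == 1.0
        assert s.local_efficiency_mean == pytest.approx(
            floyd_warshall_local_efficiency_mean(w))

    def test_empty_network_flags(self):
        s = network_summaries(Connectome(np.zeros((5, 5)), list(range(5))))
        assert s.n_edges == 0
        assert s.mean_edge_weight is None
        assert s.global_efficiency == 0.0

    def test_random_graph_all_fields_match_oracle(self):
        rng = np.random.default_rng(11)
        w = random_weighted_graph(rng, 20, p=0.25)
        s = network_summaries(Connectome(w, list(range(20))))
        iu = np.triu_indices(20, k=1)
        present = w[iu][w[iu] > 0]
        assert s.n_edges == len(present)
        assert s.mean_edge_weight == pytest.approx(present.mean())
        assert s.total_strength == pytest.approx(w.sum())
        assert s.global_efficiency == pytest.approx(
            floyd_warshall_efficiency(w), abs=1e-10)


class TestConfigOptions:
    def test_unweighted_variant_equals_binarized(self):
        rng = np.random.default_rng(21)
        w = random_weighted_graph(rng, 12, p=0.3)
        binarized = (w > 0).astype(float)
        assert (global_efficiency(w, weighted=False)
                == pytest.approx(global_efficiency(binarized)))
        assert (local_efficiency_mean(w, weighted=False)
                == pytest.approx(local_efficiency_mean(binarized)))

    def test_endpoint_dilation_rescues_near_miss(self):
        labels = np.zeros((20, 4, 4), dtype=np.int32)
        labels[:2] = 1
        labels[-2:] = 2
        parc = Parcellation(labels, [1, 2], np.diag([2.5, 2.5, 2.5, 1.0]))
        # one endpoint one voxel short of label 2 (in background)
        s = straightline(2.5, 42.5, 5.0, 5.0)
        assert assign_endpoints(s, parc) is None
        assert assign_endpoints(s, parc, dilation_voxels=1) == (1, 2)
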