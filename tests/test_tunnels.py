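"""Clearance field, start optimization, Dijkstra search, clustering."""

import math

import numpy as np
import pytest

import smdroutes as sr
from smdroutes.tunnels import (ClearanceGrid, Tunnel, TunnelSearchParams,
                               _path_distance, resample_path, voxel_dijkstra)


def single_atom_structure(radius=1.5):
    return sr.SphereStructure(names=["C"], resnames=["SPH"], resids=np.array([1]),
                              coords=np.zeros((1, 3)), radii=np.array([radius]))


class TestClearanceField:
    def test_single_atom_matches_analytic_distance(self):
        r = 1.5
        params = TunnelSearchParams(grid_spacing=0.5)
        grid = sr.clearance_field(single_atom_structure(r), params)
        for point in [(3.0, 0.0, 0.0), (0.0, 0.0, 0.0), (-2.0, 1.0, 0.5)]:
            idx = grid.nearest_voxel(point)
            center = grid.voxel_center(idx)
            assert grid.clearance[idx] == pytest.approx(
                np.linalg.norm(center) - r, abs=1e-9)
        # inside the atom the clearance is negative
        assert grid.clearance[grid.nearest_voxel((0.0, 0.0, 0.0))] < 0

    def test_midpoint_between_equal_atoms(self):
        d, r = 6.0, 1.2
        s = sr.SphereStructure(
            names=["C1", "C2"], resnames=["SPH"] * 2, resids=np.array([1, 2]),
            coords=np.array([[-d / 2, 0, 0], [d / 2, 0, 0]]),
            radii=np.array([r, r]))
        grid = sr.clearance_field(s, TunnelSearchParams(grid_spacing=0.5))
        mid = grid.nearest_voxel((0.0, 0.0, 0.0))
        center = grid.voxel_center(mid)
        expected = min(np.linalg.norm(center - s.coords[0]),
                       np.linalg.norm(center - s.coords[1])) - r
        assert grid.clearance[mid] == pytest.approx(expected, abs=1e-9)


class TestOptimizeStart:
    def _grid_with_pocket(self):
        # synthetic clearance field: a clearance bump away from the origin
        n = 21
        clearance = np.full((n, n, n), 2.0)
        clearance[14, 10, 10] = 4.0     # (2, 0, 0) at spacing 0.5, origin −5
        return ClearanceGrid(origin=np.array([-5.0, -5.0, -5.0]), spacing=0.5,
                             clearance=clearance)

    def test_moves_to_higher_clearance(self):
        grid = self._grid_with_pocket()
        params = TunnelSearchParams(grid_spacing=0.5, start_point=(1.0, 0.0, 0.0))
        assert np.allclose(sr.optimize_start(grid, params), [2.0, 0.0, 0.0])

    def test_local_max_unchanged(self):
        grid = self._grid_with_pocket()
        params = TunnelSearchParams(grid_spacing=0.5, start_point=(2.0, 0.0, 0.0),
                                    start_max_shift=1.0)
        assert np.allclose(sr.optimize_start(grid, params), [2.0, 0.0, 0.0])

    def test_desired_clearance_clamp_prefers_nearest(self):
        n = 21
        clearance = np.full((n, n, n), 1.0)
        clearance[12, 10, 10] = 5.0      # (1, 0, 0): exactly the clamp
        clearance[16, 10, 10] = 6.0      # (3, 0, 0): farther, above the clamp
        grid = ClearanceGrid(origin=np.array([-5.0, -5.0, -5.0]), spacing=0.5,
                             clearance=clearance)
        params = TunnelSearchParams(grid_spacing=0.5, start_point=(0.0, 0.0, 0.0))
        assert np.allclose(sr.optimize_start(grid, params), [1.0, 0.0, 0.0])

    def test_buried_start_raises(self):
        clearance = np.full((9, 9, 9), -1.0)
        grid = ClearanceGrid(origin=np.zeros(3), spacing=0.5, clearance=clearance)
        params = TunnelSearchParams(start_point=(2.0, 2.0, 2.0), start_max_shift=1.0)
        with pytest.raises(ValueError, match="buried"):
            sr.optimize_start(grid, params)


class TestDijkstraOracles:
    def test_2d_grid_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        clearance = rng.uniform(0.5, 5.0, size=(30, 30))
        spacing, probe, desired = 0.5, 0.9, 5.0
        clearance[0, 0] = max(clearance[0, 0], probe)
        cost, _, _ = voxel_dijkstra(clearance, spacing, (0, 0), probe, desired)

        g = nx.Graph()
        free = clearance >= probe
        n0, n1 = clearance.shape
        for i in range(n0):
            for j in range(n1):
                if not free[i, j]:
                    continue
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        a, b = i + di, j + dj
                        if 0 <= a < n0 and 0 <= b < n1 and free[a, b]:
                            step = spacing * math.hypot(di, dj)
                            cmid = min(0.5 * (clearance[i, j] + clearance[a, b]),
                                       desired)
                            g.add_edge((i, j), (a, b), weight=step / cmid ** 2)
        lengths = nx.single_source_dijkstra_path_length(g, (0, 0))
        for node, d in lengths.items():
            assert cost[node] == pytest.approx(d, rel=1e-10)

    def test_tiny_grid_matches_exhaustive_enumeration(self):
        # brute force: enumerate every simple path on a 3×4 grid
        rng = np.random.default_rng(5)
        clearance = rng.uniform(1.0, 4.0, size=(3, 4))
        spacing, probe, desired = 1.0, 0.5, 5.0
        cost, _, _ = voxel_dijkstra(clearance, spacing, (0, 0), probe, desired)

        def neighbors(node):
            i, j = node
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < 3 and 0 <= b < 4:
                        yield (a, b)

        def edge_cost(u, v):
            step = spacing * math.hypot(u[0] - v[0], u[1] - v[1])
            return step / min(0.5 * (clearance[u] + clearance[v]), desired) ** 2

        best = {}

        def dfs(node, visited, acc):
            if node in best and best[node] <= acc:
                pass
            else:
                best[node] = min(best.get(node, np.inf), acc)
            for nxt in neighbors(node):
                if nxt not in visited:
                    c = acc + edge_cost(node, nxt)
                    if c < best.get(nxt, np.inf):
                        dfs(nxt, visited | {nxt}, c)

        dfs((0, 0), {(0, 0)}, 0.0)
        for node, d in best.items():
            assert cost[node] == pytest.approx(d, rel=1e-10)


@pytest.fixture(scope="module")
def carved_single():
    structure = sr.carve_tunnel_structure(3.0, [((1, 0, 0), 2.0, 5.0)],
                                          cavity_radius=4.0)
    params = TunnelSearchParams()
    return structure, params, sr.find_tunnels(structure, params)


class TestFindTunnels:
    def test_carved_bottleneck_recovered(self, carved_single):
        _, params, tunnels = carved_single
        assert len(tunnels) == 1
        t = tunnels[0]
        assert t.bottleneck_radius == pytest.approx(2.0, abs=params.grid_spacing)
        # exit along the carved +x axis
        assert t.path[-1][0] > 5.0
        assert 0.0 < t.priority <= 1.0
        assert t.bottleneck_radius <= t.avg_radius <= params.start_desired_clearance

    def test_sealed_cavity_yields_no_tunnels(self):
        structure = sr.carve_tunnel_structure(3.0, [], cavity_radius=4.0)
        assert sr.find_tunnels(structure, TunnelSearchParams()) == []

    def test_wide_short_ranked_before_narrow_long(self):
        structure = sr.carve_tunnel_structure(
            2.9, [((1, 0, 0), 4.23, 2.90), ((-1, 0, 0), 1.35, 15.65)],
            cavity_radius=6.5)
        tunnels = sr.find_tunnels(structure, TunnelSearchParams(grid_spacing=0.5))
        assert len(tunnels) == 2
        assert tunnels[0].path[-1][0] > 0 > tunnels[1].path[-1][0]
        assert tunnels[0].priority > tunnels[1].priority

    def test_grid_refinement_consistency(self):
        structure = sr.carve_tunnel_structure(3.0, [((0, 0, 1), 2.0, 5.0)],
                                              cavity_radius=4.0)
        coarse = sr.find_tunnels(structure, TunnelSearchParams(grid_spacing=0.5))
        fine = sr.find_tunnels(structure, TunnelSearchParams(grid_spacing=0.25))
        assert abs(coarse[0].bottleneck_radius - fine[0].bottleneck_radius) <= 0.5


class TestPriorityProperties:
    def test_extension_lowers_priority(self):
        # cost additivity: appending path at equal clearance adds cost
        base = np.column_stack([np.linspace(0, 5, 11), np.zeros(11), np.zeros(11)])
        ext = np.column_stack([np.linspace(0, 8, 17), np.zeros(17), np.zeros(17)])
        clearance = 2.0
        cost_base = 5.0 / clearance ** 2
        cost_ext = 8.0 / clearance ** 2
        assert math.exp(-cost_ext) < math.exp(-cost_base) <= 1.0


def make_toy_tunnel(x_offset, snapshot_id=0, priority=0.5):
    path = np.column_stack([np.full(10, x_offset), np.zeros(10),
                            np.linspace(0, 9, 10)])
    return Tunnel(tunnel_id=0, snapshot_id=snapshot_id, path=path,
                  clearance=np.full(10, 2.0), bottleneck_radius=2.0,
                  bottleneck_position=path[5], length=9.0, avg_radius=2.0,
                  cost=-math.log(priority), priority=priority)


class TestClusterTunnels:
    def test_identical_tunnels_form_one_full_cluster(self):
        snaps = [[make_toy_tunnel(0.0, snapshot_id=i)] for i in range(5)]
        clusters = sr.cluster_tunnels(snaps, TunnelSearchParams())
        assert len(clusters) == 1
        assert clusters[0].occurrence_fraction == 1.0

    def test_distant_channels_split(self):
        snaps = [[make_toy_tunnel(0.0, i), make_toy_tunnel(20.0, i)]
                 for i in range(10)]
        clusters = sr.cluster_tunnels(snaps, TunnelSearchParams())
        assert len(clusters) == 2
        assert all(c.occurrence_fraction == 1.0 for c in clusters)

    def test_single_snapshot_passthrough(self):
        snaps = [[make_toy_tunnel(0.0), make_toy_tunnel(30.0)]]
        clusters = sr.cluster_tunnels(snaps, TunnelSearchParams())
        assert len(clusters) == 2

    def test_representative_is_highest_priority(self):
        snaps = [[make_toy_tunnel(0.0, 0, priority=0.4)],
                 [make_toy_tunnel(0.1, 1, priority=0.9)]]
        clusters = sr.cluster_tunnels(snaps, TunnelSearchParams())
        assert clusters[0].representative.priority == 0.9

    def test_resample_path_preserves_endpoints(self):
        path = np.array([[0, 0, 0], [1, 0, 0], [1, 2, 0]], float)
        rs = resample_path(path, 16)
        assert np.allclose(rs[0], path[0]) and np.allclose(rs[-1], path[-1])
        assert _path_distance(rs, rs) == 0.0


class TestBottleneckResidues:
    def _structure_with_flanks(self):
        # two atoms flanking a constriction at the origin, plus a far atom
        coords = np.array([[0.0, 3.2, 0.0], [0.0, -3.2, 0.0], [30.0, 0.0, 0.0]])
        return sr.SphereStructure(
            names=["C", "C", "C"], resnames=["TRP", "TYR", "GLY"],
            resids=np.array([490, 475, 1]), coords=coords,
            radii=np.array([1.2, 1.2, 1.2]))

    def _member(self, snapshot_id=0):
        path = np.column_stack([np.linspace(-3, 3, 7), np.zeros(7), np.zeros(7)])
        return Tunnel(tunnel_id=0, snapshot_id=snapshot_id, path=path,
                      clearance=np.full(7, 2.0), bottleneck_radius=2.0,
                      bottleneck_position=np.zeros(3), length=6.0,
                      avg_radius=2.0, cost=1.0, priority=math.exp(-1.0))

    def test_flanking_residues_equal_frequency(self):
        structure = self._structure_with_flanks()
        cluster = sr.TunnelCluster(cluster_id=0, members={0: self._member()},
                                   representative=self._member(),
                                   occurrence_fraction=1.0)
        table = sr.bottleneck_residue_table(cluster, structure)
        assert table == [("TRP490", 1.0), ("TYR475", 1.0)] or \
               table == [("TYR475", 1.0), ("TRP490", 1.0)]
        assert len(table) == 2   # the far GLY does not appear

    def test_partial_frequency_counting(self):
        structure = self._structure_with_flanks()
        near = self._member(0)
        far = self._member(1)
        far.bottleneck_position = np.array([40.0, 0.0, 0.0])
        far.bottleneck_radius = 8.8   # touches GLY1's surface at 30+1.2
        cluster = sr.TunnelCluster(cluster_id=0, members={0: near, 1: far},
                                   representative=near, occurrence_fraction=1.0)
        table = dict(sr.bottleneck_residue_table(cluster, structure))
        assert table["TRP490"] == 0.5
        assert table["GLY1"] == 0.5
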