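"""Skeletonization, node-link graph extraction, measurement, subdivision,
radius estimation, metrics, and CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselflow import network
from vesselflow.imaging import BinaryMask
from vesselflow.network import (Link, Node, VesselGraph, measure_links,
                                neighbor_counts, subdivide_tortuous)


def mask_of(vox):
    return BinaryMask(np.asarray(vox, bool), (1.0, 1.0, 1.0))


def solid_cylinder(radius=6, length=60, pad=4):
    """Tube along z with its axis through a voxel center (offset 0.5)."""
    n = 2 * (radius + pad)
    c = n / 2 + 0.5
    x = np.arange(n) + 0.5
    X, Y = np.meshgrid(x, x, indexing="ij")
    disc = (X - c) ** 2 + (Y - c) ** 2 <= radius**2
    vox = np.zeros((n, n, length), bool)
    vox[disc] = True
    return vox


def solid_torus(R=12, r=4, n=40):
    c = n / 2
    i = np.arange(n) + 0.5
    X, Y, Z = np.meshgrid(i, i, i, indexing="ij")
    rho = np.sqrt((X - c) ** 2 + (Y - c) ** 2)
    return (rho - R) ** 2 + (Z - c) ** 2 <= r**2


def skeleton_cycles(skel):
    """Independent cycles of the 26-connectivity skeleton graph."""
    import networkx as nx

    coords = [tuple(c) for c in np.argwhere(skel.voxels)]
    G = nx.Graph()
    G.add_nodes_from(coords)
    cs = set(coords)
    for c in coords:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    nb = (c[0] + dx, c[1] + dy, c[2] + dz)
                    if nb in cs:
                        G.add_edge(c, nb)
    return G.number_of_edges() - G.number_of_nodes() + \
        nx.number_connected_components(G)


class TestSkeletonize:
    def test_cylinder_thins_to_open_curve(self):
        skel = network.skeletonize(mask_of(solid_cylinder()))
        counts = neighbor_counts(skel.voxels)
        endpoints = np.count_nonzero(counts == 1)
        assert endpoints == 2
        assert skeleton_cycles(skel) == 0

    def test_torus_thins_to_closed_loop(self):
        skel = network.skeletonize(mask_of(solid_torus()))
        counts = neighbor_counts(skel.voxels)
        assert np.count_nonzero(counts == 1) == 0
        assert skeleton_cycles(skel) == 1

    def test_topology_two_disjoint_tubes(self):
        from scipy import ndimage

        a = solid_cylinder(radius=4, length=40)     # (16, 16, 40)
        vox = np.zeros((36, 16, 40), bool)
        vox[:16] = a
        vox[20:] = a
        skel = network.skeletonize(mask_of(vox))
        s26 = np.ones((3, 3, 3))
        assert ndimage.label(skel.voxels, s26)[1] == \
            ndimage.label(vox, s26)[1] == 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            network.skeletonize(mask_of(np.zeros((5, 5, 5))))


def draw_line(vox, p0, p1):
    n = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]),
                abs(p1[2] - p0[2]))) + 1
    for t in np.linspace(0, 1, n):
        i, j, k = (round(p0[a] + t * (p1[a] - p0[a])) for a in range(3))
        vox[i, j, k] = True


class TestSkeletonToGraph:
    def test_straight_chain(self):
        vox = np.zeros((40, 5, 5), bool)
        vox[5:35, 2, 2] = True
        g = network.skeleton_to_graph(network.Skeleton(vox, np.ones(3)))
        assert g.count("terminal") == 2 and g.count("branch") == 0
        assert len(g.links) == 1

    def test_y_junction(self):
        vox = np.zeros((40, 40, 5), bool)
        draw_line(vox, (20, 20, 2), (20, 5, 2))
        draw_line(vox, (20, 20, 2), (5, 32, 2))
        draw_line(vox, (20, 20, 2), (35, 32, 2))
        g = network.skeleton_to_graph(network.Skeleton(vox, np.ones(3)))
        assert g.count("branch") == 1
        assert g.count("terminal") == 3
        assert len(g.links) == 3

    def test_binary_tree_three_bifurcations(self):
        """Stem + three bifurcation nodes: 7 links, enumerated by hand."""
        vox = np.zeros((64, 64, 5), bool)
        draw_line(vox, (2, 32, 2), (14, 32, 2))          # stem
        draw_line(vox, (14, 32, 2), (30, 16, 2))
        draw_line(vox, (14, 32, 2), (30, 48, 2))
        for y in (16, 48):
            draw_line(vox, (30, y, 2), (46, y - 8, 2))
            draw_line(vox, (30, y, 2), (46, y + 8, 2))
        g = network.skeleton_to_graph(network.Skeleton(vox, np.ones(3)))
        assert g.count("branch") == 3
        assert g.count("terminal") == 5                  # root + 4 leaves
        assert len(g.links) == 7

    def test_polylines_end_on_nodes(self):
        vox = np.zeros((40, 40, 5), bool)
        draw_line(vox, (20, 20, 2), (20, 5, 2))
        draw_line(vox, (20, 20, 2), (5, 32, 2))
        draw_line(vox, (20, 20, 2), (35, 32, 2))
        g = network.skeleton_to_graph(network.Skeleton(vox, np.ones(3)))
        g.validate()                       # raises if endpoints mismatch

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            network.skeleton_to_graph(
                network.Skeleton(np.zeros((4, 4, 4), bool), np.ones(3)))


def simple_graph(poly, radius=5.0):
    poly = np.asarray(poly, float)
    nodes = {0: Node(0, poly[0], "terminal"), 1: Node(1, poly[-1], "terminal")}
    return VesselGraph(nodes, [Link(0, 0, 1, poly, radius=radius)])


class TestMeasure:
    def test_straight_tortuosity_one(self):
        g = measure_links(simple_graph([[0, 0, 0], [10, 0, 0]]))
        assert g.links[0].tortuosity == pytest.approx(1.0)
        assert g.links[0].path_length == pytest.approx(10.0)

    @pytest.mark.parametrize("n_pts,tol", [(20, 0.01), (200, 1e-4)])
    def test_semicircle_converges_to_half_pi(self, n_pts, tol):
        theta = np.linspace(0, np.pi, n_pts)
        poly = np.column_stack([np.cos(theta), np.sin(theta),
                                np.zeros(n_pts)]) * 50
        g = measure_links(simple_graph(poly))
        assert g.links[0].tortuosity == pytest.approx(np.pi / 2, rel=tol)

    def test_ratio_arithmetic(self):
        # zig-zag with path 1.2 L over chord L
        L = 10.0
        h = np.sqrt((1.2 * L / 2) ** 2 - (L / 2) ** 2)
        g = measure_links(simple_graph([[0, 0, 0], [L / 2, h, 0], [L, 0, 0]]))
        assert g.links[0].tortuosity == pytest.approx(1.2)

    def test_closed_link_flagged_infinite(self):
        theta = np.linspace(0, 2 * np.pi, 30)
        poly = np.column_stack([np.cos(theta), np.sin(theta),
                                np.zeros_like(theta)])
        poly[-1] = poly[0]
        nodes = {0: Node(0, poly[0], "branch")}
        g = VesselGraph(nodes, [Link(0, 0, 0, poly, radius=1.0)])
        measure_links(g)
        assert np.isinf(g.links[0].tortuosity)
        assert g.links[0].degenerate

    def test_short_polyline_rejected(self):
        g = simple_graph([[0, 0, 0], [1, 0, 0]])
        g.links[0].polyline = g.links[0].polyline[:1]
        with pytest.raises(ValueError):
            measure_links(g)


class TestSubdivide:
    def wavy(self, amp=0.3):
        t = np.linspace(0, 1, 60)
        poly = np.column_stack([t * 100, amp * 100 * np.sin(np.pi * t),
                                np.zeros_like(t)])
        return measure_links(simple_graph(poly))

    def test_tortuous_link_split_into_five(self):
        g = self.wavy()
        assert g.links[0].tortuosity > 1.15
        parent_length = g.links[0].path_length
        out = subdivide_tortuous(g)
        assert len(out.links) == 5
        assert sum(1 for n in out.nodes.values() if n.kind == "through") == 4
        total = sum(lk.path_length for lk in out.links)
        assert total == pytest.approx(parent_length, rel=1e-12)

    def test_children_concatenate_to_parent(self):
        g = self.wavy()
        parent = g.links[0].polyline.copy()
        out = subdivide_tortuous(g)
        chain = out.links[0].polyline
        for lk in out.links[1:]:
            chain = np.vstack([chain, lk.polyline[1:]])
        # every parent vertex appears on the concatenated child polyline
        d = np.abs(chain[None, :, :] - parent[:, None, :]).sum(axis=2)
        assert d.min(axis=1).max() < 1e-9

    def test_threshold_is_strict(self):
        t = np.linspace(0, 1, 50)
        # amplitude tuned to land exactly on tortuosity 1.15 is brittle;
        # instead check a mildly wavy link below threshold is untouched
        g = self.wavy(amp=0.1)
        assert g.links[0].tortuosity <= 1.15
        out = subdivide_tortuous(g)
        assert len(out.links) == 1
        np.testing.assert_array_equal(out.links[0].polyline,
                                      g.links[0].polyline)

    def test_exactly_at_threshold_untouched(self):
        g = self.wavy()
        thr = g.links[0].tortuosity         # use the link's own value
        out = subdivide_tortuous(g, threshold=thr)
        assert len(out.links) == 1

    def test_invalid_parts(self):
        with pytest.raises(ValueError):
            subdivide_tortuous(self.wavy(), parts=1)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=30),
           st.integers(2, 7))
    def test_path_length_conserved_for_random_polylines(self, ys, parts):
        xs = np.arange(len(ys), dtype=float) * 5
        poly = np.column_stack([xs, ys, np.zeros(len(ys))])
        g = measure_links(simple_graph(poly))
        out = subdivide_tortuous(g, threshold=1.0 - 1e-9, parts=parts)
        if len(out.links) > 1:
            total = sum(lk.path_length for lk in out.links)
            assert total == pytest.approx(g.links[0].path_length, rel=1e-9)


class TestRadii:
    def test_cylinder_radius_recovered(self):
        vox = solid_cylinder(radius=10, length=60, pad=4)
        mask = mask_of(vox)
        c = vox.shape[0] / 2 + 0.5
        poly = np.array([[c, c, 10.0], [c, c, 50.0]])
        g = simple_graph(poly)
        measure_links(g)
        network.estimate_radii(g, mask)
        assert 9.5 <= g.links[0].radius <= 10.5

    def test_cone_per_point_radii_monotone(self):
        n = 80
        vox = np.zeros((44, 44, n), bool)
        x = np.arange(44) + 0.5
        X, Y = np.meshgrid(x, x, indexing="ij")
        for k in range(n):
            r = 5 + 10 * k / (n - 1)
            vox[:, :, k] = (X - 22) ** 2 + (Y - 22) ** 2 <= r**2
        poly = np.column_stack([np.full(n - 20, 22.0),
                                np.full(n - 20, 22.0),
                                np.arange(10, n - 10, dtype=float)])
        g = simple_graph(poly)
        measure_links(g)
        network.estimate_radii(g, mask_of(vox))
        r = g.links[0].point_radii
        assert np.all(np.diff(r) >= -0.51)     # non-decreasing after median
        assert r[-1] > r[0] + 5

    def test_single_voxel_line_subvoxel_convention(self):
        vox = np.zeros((5, 5, 30), bool)
        vox[2, 2, 2:28] = True
        poly = np.column_stack([np.full(20, 2.5), np.full(20, 2.5),
                                np.arange(5, 25, dtype=float)])
        g = simple_graph(poly)
        measure_links(g)
        network.estimate_radii(g, mask_of(vox))
        assert 0.5 <= g.links[0].radius <= 1.0

    def test_centerline_outside_mask_rejected(self):
        vox = solid_cylinder(radius=5, length=30)
        poly = np.array([[1.0, 1.0, 5.0], [1.0, 1.0, 25.0]])  # outside tube
        g = simple_graph(poly)
        measure_links(g)
        with pytest.raises(ValueError):
            network.estimate_radii(g, mask_of(vox))

    def test_perimeter_variant_close_to_edt(self):
        """The nearest-perimeter-voxel association agrees with the EDT
        estimator within a voxel (differing half-voxel conventions)."""
        vox = solid_cylinder(radius=8, length=50)
        c = vox.shape[0] / 2 + 0.5
        poly = np.array([[c, c, 10.0], [c, c, 40.0]])
        g1, g2 = simple_graph(poly), simple_graph(poly)
        measure_links(g1), measure_links(g2)
        network.estimate_radii(g1, mask_of(vox), method="edt")
        network.estimate_radii(g2, mask_of(vox), method="perimeter")
        assert abs(g1.links[0].radius - g2.links[0].radius) <= 1.0


class TestMetrics:
    def test_coverage_arithmetic(self):
        vox = np.zeros((100, 100, 100), bool)
        vox[:10] = True                        # 1e5 voxels of (1 um)^3
        g = measure_links(simple_graph([[5, 50, 50], [5, 50, 99]]))
        m = network.network_metrics(g, mask_of(vox), 0.001)
        assert m.volumetric_coverage == pytest.approx(0.1)
        assert m.vessel_density == pytest.approx(1000.0)

    def test_branch_terminal_ratio_y(self):
        nodes = {0: Node(0, np.zeros(3), "branch"),
                 1: Node(1, np.array([1., 0, 0]), "terminal"),
                 2: Node(2, np.array([0, 1., 0]), "terminal"),
                 3: Node(3, np.array([0, 0, 1.]), "terminal")}
        links = [Link(i, 0, i + 1,
                      np.array([nodes[0].position, nodes[i + 1].position]),
                      radius=2.0) for i in range(3)]
        g = measure_links(VesselGraph(nodes, links))
        m = network.network_metrics(g, mask_of(np.ones((5, 5, 5))), 1.0)
        assert m.branch_terminal_ratio == pytest.approx(1 / 3)

    def test_empty_graph_nan_ratio_with_warning(self):
        g = VesselGraph({}, [])
        with pytest.warns(UserWarning):
            m = network.network_metrics(g, mask_of(np.ones((4, 4, 4))), 1.0)
        assert np.isnan(m.branch_terminal_ratio)
        assert m.vessel_density == 0

    def test_zero_volume_rejected(self):
        g = VesselGraph({}, [])
        with pytest.raises(ValueError):
            network.network_metrics(g, mask_of(np.ones((4, 4, 4))), 0.0)


class TestCsvRoundtrip:
    def roundtrip(self, g, tmp_path, points=True):
        n, l_, p = (tmp_path / "n.csv", tmp_path / "l.csv",
                    (tmp_path / "p.csv") if points else None)
        network.export_graph_csv(g, n, l_, p)
        return network.import_graph_csv(n, l_, p)

    def test_lossless_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        nodes, links = {}, []
        for i in range(6):
            nodes[i] = Node(i, rng.uniform(0, 300, 3),
                            "branch" if i < 2 else "terminal")
        for i in range(5):
            a, b = i % 2, 2 + (i % 4)
            poly = np.vstack([nodes[a].position,
                              rng.uniform(0, 300, (3, 3)),
                              nodes[b].position])
            links.append(Link(i, a, b, poly, radius=rng.uniform(3, 15)))
        g = measure_links(VesselGraph(nodes, links))
        back = self.roundtrip(g, tmp_path)
        assert len(back.links) == 5
        for lk, bk in zip(g.links, back.links):
            assert (lk.node_a, lk.node_b) == (bk.node_a, bk.node_b)
            assert bk.radius == pytest.approx(lk.radius, rel=1e-9)
            assert bk.path_length == pytest.approx(lk.path_length, rel=1e-9)
            assert bk.tortuosity == pytest.approx(lk.tortuosity, rel=1e-9)
            np.testing.assert_allclose(bk.polyline, lk.polyline, atol=1e-4)
        for nid, node in g.nodes.items():
            np.testing.assert_allclose(back.nodes[nid].position,
                                       node.position, atol=1e-4)

    def test_row_count_matches_links(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(3)
        nodes = {i: Node(i, rng.uniform(0, 100, 3), "terminal")
                 for i in range(8)}
        links = [Link(i, i, i + 1, np.array([nodes[i].position,
                                             nodes[i + 1].position]),
                      radius=5.0) for i in range(7)]
        g = measure_links(VesselGraph(nodes, links))
        network.export_graph_csv(g, tmp_path / "n.csv", tmp_path / "l.csv")
        assert len(pd.read_csv(tmp_path / "l.csv")) == 7
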