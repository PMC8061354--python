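"""Centerline extraction, diameters, generations and bifurcation angles."""

import networkx as nx
import numpy as np
import pytest

from pulmovox import morphometry
from pulmovox.morphometry import CenterlineGraph
from pulmovox.phantom import make_bifurcation_phantom, rasterize_tube_mask
from pulmovox.types import SegmentationMask


def _tube_mask(segments, radius, shape, vs=(1, 1, 1)):
    m = rasterize_tube_mask(np.asarray(segments), radius, shape, vs)
    return SegmentationMask(m, vs)


class TestSkeletonize:
    def test_straight_cylinder_single_branch(self):
        mask = _tube_mask([[(10.5, 10.5, 5), (10.5, 10.5, 65)]], 4.0, (21, 21, 70))
        g = morphometry.skeletonize_airway(mask, prune_length=8)
        assert g.n_branches == 1
        assert len(g.endpoints()) == 2
        assert not g.bifurcations()

    def test_y_tube_single_bifurcation(self):
        mask, truth = make_bifurcation_phantom(60.0, radius_um=4)
        g = morphometry.skeletonize_airway(mask, prune_length=10,
                                           root_hint_um=truth["root_hint_um"])
        assert len(g.bifurcations()) == 1
        assert len(g.endpoints()) == 3
        assert g.n_branches == 3

    def test_short_spur_pruned(self):
        mask, truth = make_bifurcation_phantom(
            60.0, radius_um=4, daughter_length_um=70.0
        )
        g_keep = morphometry.skeletonize_airway(mask, prune_length=5,
                                                root_hint_um=truth["root_hint_um"])
        # pruning threshold longer than the daughters removes them entirely
        g_pruned = morphometry.skeletonize_airway(mask, prune_length=100.0,
                                                  root_hint_um=truth["root_hint_um"])
        assert g_keep.n_branches > g_pruned.n_branches

    def test_multiple_components_rejected(self):
        data = np.zeros((20, 20, 20), dtype=bool)
        data[2:6, 2:6, 2:6] = True
        data[12:18, 12:18, 12:18] = True
        with pytest.raises(ValueError, match="connected component"):
            morphometry.skeletonize_airway(SegmentationMask(data, (1, 1, 1)))

    def test_skeleton_inside_mask(self):
        mask, truth = make_bifurcation_phantom(50.0, radius_um=4)
        g = morphometry.skeletonize_airway(mask, prune_length=10,
                                           root_hint_um=truth["root_hint_um"])
        vs = np.asarray(mask.voxel_size)
        for _, _, d in g.graph.edges(data=True):
            vox = (d["points"] / vs).astype(int)
            assert mask.data[vox[:, 0], vox[:, 1], vox[:, 2]].all()


class TestDiameters:
    def test_cylinder_diameter(self):
        mask = _tube_mask([[(10.5, 10.5, 5), (10.5, 10.5, 65)]], 5.0, (21, 21, 70))
        g = morphometry.skeletonize_airway(mask, prune_length=8)
        g = morphometry.inner_diameter_profile(g, mask)
        (_, _, d), = g.graph.edges(data=True)
        pts = d["points"]
        core = (pts[:, 2] > 15) & (pts[:, 2] < 55)  # away from the tube ends
        diam = 2.0 * d["radii_um"][core]
        assert np.all(np.abs(diam - 10.0) <= 1.0)

    def test_anisotropic_tube_diameter_in_physical_units(self):
        vs = (1.0, 0.35, 0.35)
        # tube along z, physical radius 3.5 µm, centred on a voxel centre
        c = (50.5 * 0.35, 50.5 * 0.35)
        mask = _tube_mask([[(4, c[0], c[1]), (76, c[0], c[1])]], 3.5, (80, 101, 101), vs)
        g = morphometry.skeletonize_airway(mask, prune_length=5)
        g = morphometry.inner_diameter_profile(g, mask)
        (_, _, d), = g.graph.edges(data=True)
        pts = d["points"]
        core = (pts[:, 0] > 15) & (pts[:, 0] < 65)
        diam = 2.0 * d["radii_um"][core]
        assert np.all(np.abs(diam - 7.0) <= 0.7)

    def test_cone_diameter_monotone(self):
        """Stacked shrinking tube: diameters decrease along the axis."""
        segs, radii = [], []
        for i, r in enumerate([6.0, 5.0, 4.0, 3.0]):
            segs.append([(14.5, 14.5, 5 + 20 * i), (14.5, 14.5, 5 + 20 * (i + 1))])
            radii.append(r)
        m = np.zeros((29, 29, 90), dtype=bool)
        for s, r in zip(segs, radii):
            m |= rasterize_tube_mask(np.array([s]), r, m.shape, (1, 1, 1))
        mask = SegmentationMask(m, (1, 1, 1))
        g = morphometry.skeletonize_airway(mask, prune_length=8)
        g = morphometry.inner_diameter_profile(g, mask)
        (_, _, d), = g.graph.edges(data=True)
        pts, radii_um = d["points"], d["radii_um"]
        order = np.argsort(pts[:, 2])
        core = radii_um[order][5:-5]
        # windowed means strictly decrease along the axis
        w = len(core) // 4
        means = [core[i * w : (i + 1) * w].mean() for i in range(4)]
        assert all(a > b for a, b in zip(means, means[1:]))


def _hand_graph(edges, positions, radii=None):
    """Build a CenterlineGraph directly (nodes: id -> position µm)."""
    g = nx.Graph()
    for n, p in positions.items():
        g.add_node(n, pos=np.asarray(p, dtype=float))
    for u, v in edges:
        p0, p1 = positions[u], positions[v]
        pts = np.linspace(p0, p1, 12)
        d = {"points": pts, "length_um": float(np.linalg.norm(np.subtract(p1, p0)))}
        if radii is not None:
            d["radii_um"] = np.full(len(pts), radii[(u, v)])
        g.add_edge(u, v, **d)
    return CenterlineGraph(graph=g, root=0, voxel_size=(1, 1, 1))


class TestGenerations:
    def test_single_branch_is_generation_zero(self):
        g = _hand_graph([(0, 1)], {0: (0, 0, 0), 1: (0, 0, 50)})
        g = morphometry.assign_generations(g)
        assert g.graph.edges[0, 1]["generation"] == 0

    def test_binary_tree_depth_three(self):
        pos = {0: (0, 0, 0), 1: (0, 0, 40)}
        edges = [(0, 1)]
        nid = 2
        frontier = [(1, np.array([0.0, 0.0, 40.0]), 1)]
        while frontier:
            node, p, depth = frontier.pop()
            if depth > 3:
                continue
            for sign in (+1, -1):
                q = p + [0, sign * 30 / depth, 25]
                pos[nid] = tuple(q)
                edges.append((node, nid))
                if depth < 3:
                    frontier.append((nid, q, depth + 1))
                nid += 1
        g = morphometry.assign_generations(_hand_graph(edges, pos))
        gens = sorted({d["generation"] for _, _, d in g.graph.edges(data=True)})
        assert gens == [0, 1, 2, 3]

    def test_monopodial_main_stem_keeps_generation(self):
        pos = {0: (0, 0, 0), 1: (0, 0, 40), 2: (0, 0, 80), 3: (0, 30, 55)}
        edges = [(0, 1), (1, 2), (1, 3)]
        radii = {(0, 1): 6.0, (1, 2): 5.5, (1, 3): 2.0}
        g = _hand_graph(edges, pos, radii)
        g = morphometry.assign_generations(g, monopodial=True)
        assert g.graph.edges[0, 1]["generation"] == 0
        assert g.graph.edges[1, 2]["generation"] == 0  # wide daughter continues G0
        assert g.graph.edges[1, 3]["generation"] == 1
        strict = morphometry.assign_generations(_hand_graph(edges, pos, radii))
        assert strict.graph.edges[1, 2]["generation"] == 1


class TestBranchAngles:
    def test_orthogonal_construction(self):
        """Daughters along +y and +x from a parent along -y: alpha 90,
        betas 180 and 90."""
        pos = {0: (20.5, 5.0, 20.5), 1: (20.5, 45.0, 20.5),
               2: (20.5, 85.0, 20.5), 3: (20.5, 45.0, 60.0)}
        g = _hand_graph([(0, 1), (1, 2), (1, 3)], pos)
        angles = morphometry.branch_angles(g, fit_length=30)
        assert len(angles) == 1
        a = angles[0]
        assert a.alpha_deg == pytest.approx(90.0, abs=1e-6)
        assert sorted(np.round(a.beta_deg, 6)) == [90.0, 180.0]

    def test_collinear_pass_through_zero_alpha(self):
        pos = {0: (0, 0, 0), 1: (0, 0, 40), 2: (0, 0, 80), 3: (0, 0.5, 81)}
        g = _hand_graph([(0, 1), (1, 2), (1, 3)], pos)
        angles = morphometry.branch_angles(g, fit_length=30)
        assert angles[0].alpha_deg < 3.0

    def test_voxelized_y_branch_recovers_truth_angle(self):
        mask, truth = make_bifurcation_phantom(47.7, radius_um=4,
                                               daughter_length_um=70.0)
        g = morphometry.skeletonize_airway(mask, prune_length=10,
                                           root_hint_um=truth["root_hint_um"])
        angles = morphometry.branch_angles(g, fit_length=50.0)
        assert len(angles) == 1
        assert angles[0].alpha_deg == pytest.approx(47.7, abs=2.0)
        assert angles[0].reliable

    def test_rotation_invariance(self):
        """Rotating the Y 30 degrees in-plane moves alpha by < 1 degree."""

        def build(rot_deg):
            half = np.deg2rad(47.7) / 2.0
            rot = np.deg2rad(rot_deg)

            def rotz(v):
                y, x = v[1], v[2]
                return np.array([v[0],
                                 y * np.cos(rot) - x * np.sin(rot),
                                 y * np.sin(rot) + x * np.cos(rot)])

            dy = rotz([0, 1, 0])
            d1 = rotz([0, np.cos(half), np.sin(half)])
            d2 = rotz([0, np.cos(half), -np.sin(half)])
            node = np.array([14.5, 90.5, 90.5])
            segs = [[node - 60 * dy, node], [node, node + 70 * d1], [node, node + 70 * d2]]
            mask = _tube_mask(segs, 4.0, (29, 181, 181))
            g = morphometry.skeletonize_airway(mask, prune_length=10,
                                               root_hint_um=node - 60 * dy)
            a = morphometry.branch_angles(g, fit_length=50.0)
            return a[0].alpha_deg

        assert abs(build(0.0) - build(30.0)) < 1.0

    def test_short_branch_flagged_unreliable(self):
        mask, truth = make_bifurcation_phantom(60.0, radius_um=4,
                                               daughter_length_um=18.0)
        g = morphometry.skeletonize_airway(mask, prune_length=5,
                                           root_hint_um=truth["root_hint_um"])
        angles = morphometry.branch_angles(g, fit_length=50.0)
        if angles:  # daughters may prune entirely; if measured, must be flagged
            assert not angles[0].reliable
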