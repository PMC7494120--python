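"""Graph annotation: sides, roles, subgraph partition, root paths."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from voromorph.geometry import FRAME_BOUNDARY
from voromorph.voronoi import RZERO


def test_side_conservation_and_disk_sides(disk_fixture):
    im, bs, g, ann, _ = disk_fixture
    vs = g.vertex_side
    n_in = int((vs == "in").sum())
    n_out = int((vs == "out").sum())
    n_frame = int((vs == "frame").sum())
    assert n_in + n_out + n_frame == g.n_vertices
    assert n_frame == 4  # the corner clip terminals
    # vertices strictly inside the disk are 'in'
    c = (im.shape[0] - 1) / 2
    r2 = (g.positions[:, 0] - c) ** 2 + (g.positions[:, 1] - c) ** 2
    strict = (r2 < 20.0**2) & (g.clearance > 1.0)
    assert all(vs[v] == "in" for v in np.nonzero(strict)[0])


def test_annulus_material_is_in_hole_is_out(annulus_fixture):
    im, bs, g, ann, truth = annulus_fixture
    c = (im.shape[0] - 1) / 2
    r = np.hypot(g.positions[:, 0] - c, g.positions[:, 1] - c)
    hole = (r < 15.0) & (g.clearance > 1.0)
    assert all(g.vertex_side[v] == "out" for v in np.nonzero(hole)[0])
    ring = (r > 22.0) & (r < 28.0) & (g.clearance > 1.0)
    assert all(g.vertex_side[v] == "in" for v in np.nonzero(ring)[0])


def test_annulus_bridge_loop_and_subgraph_counts(annulus_fixture):
    _, bs, g, ann, _ = annulus_fixture
    keys = sorted(ann.subgraphs.keys())
    assert keys == [(0, "in"), (0, "out"), (1, "in"), (1, "out")]
    sub = ann.subgraphs[(0, "in")]
    assert sub.root_cyclic and sub.bridged
    # the material root path is a looped bridge equidistant to both boundaries
    for v in sub.root_path:
        assert g.vertex_boundaries(v) == frozenset({0, 1})
        assert g.vertex_role[v] == "bridge"
    in_hubs = [
        v
        for v in range(g.n_vertices)
        if g.vertex_side[v] == "in" and g.vertex_role[v] == "hub"
    ]
    assert in_hubs == []


def test_three_disks_out_graph_has_hub(three_disks_fixture):
    _, bs, g, ann = three_disks_fixture
    hubs = [
        v
        for v in range(g.n_vertices)
        if g.vertex_role[v] == "hub" and g.vertex_side[v] == "out"
    ]
    assert len(hubs) >= 1
    # a hub is equidistant to three or more distinct boundaries
    assert all(len(g.vertex_boundaries(v)) >= 3 for v in hubs)


def test_single_convex_object_has_no_in_bridges(disk_fixture):
    _, bs, g, ann, _ = disk_fixture
    in_bridges = [
        v
        for v in range(g.n_vertices)
        if g.vertex_side[v] == "in" and g.vertex_role[v] == "bridge"
    ]
    assert in_bridges == []
    sub = ann.subgraphs[(0, "in")]
    assert not sub.bridged and not sub.root_cyclic


def test_partition_covers_all_content_edges(annulus_fixture):
    _, bs, g, ann, _ = annulus_fixture
    owned = []
    for sub in ann.subgraphs.values():
        owned.extend(sub.edge_ids)
    assert len(owned) == len(set(owned))  # disjoint ownership
    content = [
        eid
        for eid, e in enumerate(g.edges)
        if e.side != "frame"
        and any(b != FRAME_BOUNDARY for b in g.edge_boundaries(e))
    ]
    assert sorted(owned) == sorted(content)


def test_bridge_roles_match_independent_distance_recomputation(annulus_fixture):
    """Equidistant-boundary sets recomputed with shapely polyline distances."""
    _, bs, g, ann, _ = annulus_fixture
    rings = {b.boundary_id: LineString(np.vstack([b.points, b.points[:1]])) for b in bs}
    rng = np.random.default_rng(0)
    cand = [v for v in range(g.n_vertices) if g.clearance[v] > 0.5]
    for v in rng.choice(cand, size=40):
        p = Point(g.positions[v])
        dists = {bid: ring.distance(p) for bid, ring in rings.items()}
        dmin = min(dists.values())
        near = {bid for bid, d in dists.items() if d <= dmin + 1e-6}
        tangent = {
            b for b in g.vertex_boundaries(v) if b != FRAME_BOUNDARY
        }
        assert tangent >= near or dmin > g.clearance[v] + 1e-6


def test_root_path_vertices_are_bridges_or_connectors_when_bridged(annulus_fixture):
    _, _, g, ann, _ = annulus_fixture
    for sub in ann.subgraphs.values():
        if sub.bridged:
            for v in sub.root_path:
                assert g.vertex_role[v] in ("bridge", "hub", "connector")


def test_removing_root_path_leaves_boundary_touching_components(annulus_fixture):
    """Branches hanging off the root path are trees reaching the boundary."""
    import networkx as nx

    _, _, g, ann, _ = annulus_fixture
    sub = ann.subgraphs[(0, "in")]
    nxg = sub.nx_graph()
    nxg.remove_nodes_from(sub.root_path)
    for comp in nx.connected_components(nxg):
        assert any(g.clearance[v] <= RZERO for v in comp)


def test_bar_root_path_is_the_midline(bar_fixture):
    im, bs, g, ann, truth = bar_fixture
    sub = ann.subgraphs[(0, "in")]
    from voromorph.profiles import width_profile

    wp = width_profile(sub)
    assert wp.positions[-1] == pytest.approx(30.0, abs=2.0)
    ys = g.positions[sub.root_path, 1]
    assert np.allclose(ys, (im.shape[0] - 1) / 2, atol=0.5)
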