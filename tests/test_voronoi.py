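"""Generalized Voronoi construction: examples, invariants, oracle checks."""

import numpy as np
import pytest
from scipy import ndimage

from voromorph.oracle import (
    match_graphs,
    oracle_graph_from_sites,
    random_site_instance,
)
from voromorph.raster import RasterImage, trace_binary_boundaries
from voromorph.synth import make_primitive
from voromorph.voronoi import (
    GeometryError,
    build_graph,
    build_graph_from_sites,
    default_frame,
)


def test_point_triangle_circumcircle():
    g = build_graph_from_sites(points=[(0, 0), (4, 0), (0, 3)])
    assert g.n_vertices == 1
    assert g.positions[0] == pytest.approx([2.0, 1.5])
    assert g.clearance[0] == pytest.approx(2.5)


def test_cocircular_square_splits_into_degree3_pair():
    g = build_graph_from_sites(points=[(0, 0), (1, 0), (1, 1), (0, 1)])
    assert g.n_vertices == 2
    assert np.allclose(g.positions, [[0.5, 0.5], [0.5, 0.5]])
    assert np.allclose(g.clearance, np.sqrt(0.5))
    assert len(g.edges) == 1 and g.edges[0].length == 0.0


def test_square_inradius(annulus_fixture=None):
    arr = np.pad(np.ones((11, 11), int), 2)
    img = RasterImage(arr)
    bs = trace_binary_boundaries(img)
    g = build_graph(bs, frame=default_frame(img.shape))
    assert g.clearance.max() == pytest.approx(5.5, abs=1e-9)


def test_crossing_boundaries_rejected():
    from voromorph.raster import Boundary

    sq1 = Boundary(0, np.array([[0.0, 0], [4, 0], [4, 4], [0, 4]]), "exterior", 1)
    sq2 = Boundary(1, np.array([[2.0, 2], [6, 2], [6, 6], [2, 6]]), "exterior", 2)
    with pytest.raises(GeometryError, match="0 and 1"):
        build_graph([sq1, sq2], frame=(-2, -2, 8, 8))


@pytest.mark.parametrize("fixture_name", ["disk_fixture", "annulus_fixture", "bar_fixture", "three_disks_fixture"])
def test_vertex_emptiness_invariant(fixture_name, request):
    """Every vertex's clearance equals its distance to the nearest site."""
    _, _, g, _ = request.getfixturevalue(fixture_name)[:4]
    d = g.sites.all_distances(g.positions)
    mind = np.where(np.isfinite(d), d, np.inf).min(axis=1)
    assert np.max(np.abs(mind - g.clearance)) < 1e-6


@pytest.mark.parametrize("fixture_name", ["disk_fixture", "annulus_fixture", "bar_fixture", "three_disks_fixture"])
def test_degree_three_on_fixtures(fixture_name, request):
    _, _, g, _ = request.getfixturevalue(fixture_name)[:4]
    deg = g.degrees()
    clip = g.frame_corner_terminals()
    assert np.all(deg[~clip] == 3)


def test_oracle_equivalence_random_segments():
    """Construction matches the exhaustive tangent-circle search."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        pts, segs = random_site_instance(rng, max_sites=40)
        frame = (0.0, 0.0, 20.0, 20.0)
        g = build_graph_from_sites(points=pts, segments=segs, frame=frame)
        o = oracle_graph_from_sites(points=pts, segments=segs, frame=frame)
        vm, em = match_graphs(g, o)
        assert vm < 1e-6
        assert em < 1e-5


def test_resolution_scaling_doubles_geometry():
    """Doubling the raster resolution of the same content doubles vertex
    clearances within rasterization error."""
    maxima = []
    for scale in (1, 2):
        img, _ = make_primitive("disk", (32 * scale, 32 * scale), radius=10.0 * scale)
        bs = trace_binary_boundaries(img)
        g = build_graph(bs, frame=default_frame(img.shape))
        maxima.append(g.clearance.max())
    assert maxima[1] / maxima[0] == pytest.approx(2.0, abs=0.1)


def test_medial_axis_maximum_matches_distance_transform(disk_fixture):
    """The in-graph's maximal-clearance vertex sits on the distance
    transform's ridge maximum (within the half-pixel convention offset)."""
    im, bs, g, _, truth = disk_fixture
    edt = ndimage.distance_transform_edt(im.values > 0)
    inside = [
        v
        for v in range(g.n_vertices)
        if g.vertex_side is not None and g.vertex_side[v] == "in"
    ]
    best = max(inside, key=lambda v: g.clearance[v])
    pos = g.positions[best]
    at_vertex = ndimage.map_coordinates(edt, [[pos[1]], [pos[0]]], order=1)[0]
    assert at_vertex >= edt.max() - 0.5
    assert abs(g.clearance[best] - edt.max()) <= 0.5


def test_graph_exports_roundtrip(tmp_path, bar_fixture):
    _, _, g, _, _ = bar_fixture
    g.save_graphml(tmp_path / "g.graphml")
    import networkx as nx

    h = nx.read_graphml(tmp_path / "g.graphml")
    assert h.number_of_nodes() == g.n_vertices
    assert h.number_of_edges() == len(g.edges)
    vf, ef = g.vertices_frame(), g.edges_frame()
    assert len(vf) == g.n_vertices and len(ef) == len(g.edges)


def test_construction_is_deterministic(bar_fixture):
    im, bs, g, _, _ = bar_fixture
    g2 = build_graph(bs, frame=default_frame(im.shape))
    assert np.array_equal(g.positions, g2.positions)
    assert np.array_equal(g.clearance, g2.clearance)
    assert [(e.v1, e.v2, e.sites) for e in g.edges] == [
        (e.v1, e.v2, e.sites) for e in g2.edges
    ]
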