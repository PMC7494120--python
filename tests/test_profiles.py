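"""Width/boundary profiles and the 40-metric vector."""

import numpy as np
import pytest
from scipy import ndimage

from voromorph.profiles import (
    FEATURE_NAMES,
    N_FEATURES,
    boundary_features,
    boundary_profile,
    features_table,
    width_profile,
)


def _edt_at(arr, positions):
    edt = ndimage.distance_transform_edt(arr > 0)
    return ndimage.map_coordinates(edt, [positions[:, 1], positions[:, 0]], order=1)


@pytest.mark.parametrize(
    "fixture_name", ["disk_fixture", "annulus_fixture", "bar_fixture"]
)
def test_width_profile_matches_distance_transform(fixture_name, request):
    im, bs, g, ann = request.getfixturevalue(fixture_name)[:4]
    sub = ann.subgraphs[(0, "in")]
    wp = width_profile(sub)
    order = [v for v in sub.root_path if g.clearance[v] > 1e-9]
    edtv = _edt_at(im.values, g.positions[order])
    assert np.max(np.abs(g.clearance[order] - edtv)) <= 0.5
    assert wp.positions.shape == wp.radii.shape
    assert np.all(np.diff(wp.positions) >= 0)
    assert wp.radii.min() <= wp.radii.mean() <= wp.radii.max()


def test_annulus_mean_width(annulus_fixture):
    _, _, _, ann, truth = annulus_fixture
    wp = width_profile(ann.subgraphs[(0, "in")])
    assert wp.radii.mean() == pytest.approx(truth["inradius"], abs=0.5)


def test_bar_max_width_is_bar_height(bar_fixture):
    _, _, _, ann, _ = bar_fixture
    wp = width_profile(ann.subgraphs[(0, "in")])
    assert 2 * wp.radii.max() == pytest.approx(10.0, abs=1e-6)


def test_one_pixel_line_has_width_one():
    from tests.conftest import build_annotated

    a = np.zeros((7, 11), int)
    a[3, 3:8] = 1
    _, _, g, ann = build_annotated(a)
    wp = width_profile(ann.subgraphs[(0, "in")])
    assert 2 * wp.radii.max() == pytest.approx(1.0, abs=1e-9)


def test_disk_boundary_profile_is_flat(disk_fixture):
    _, bs, _, ann, _ = disk_fixture
    bp = boundary_profile(ann.subgraphs[(0, "in")], bs[0])
    assert bp.height.max() <= 2.0  # pixelation only
    assert bp.height.min() >= -1e-6
    assert bp.arc.shape == bp.height.shape
    assert np.all(np.diff(bp.arc) > 0)


def test_spike_raises_boundary_profile_by_its_length(spiked_fixtures):
    _, bs0, _, ann0 = spiked_fixtures["baseline"]
    base = boundary_profile(ann0.subgraphs[(0, "in")], bs0[0]).height.max()
    assert base < 3.0  # convex shape: no protrusions
    for L in (5, 10, 20):
        _, bs, _, ann = spiked_fixtures[L]
        hmax = boundary_profile(ann.subgraphs[(0, "in")], bs[0]).height.max()
        assert hmax - base == pytest.approx(L, rel=0.15)


def test_boundary_profile_matches_bruteforce_dijkstra(bar_fixture):
    """Heights equal an independent networkx recomputation on the same
    edge list."""
    import networkx as nx

    _, bs, g, ann, _ = bar_fixture
    sub = ann.subgraphs[(0, "in")]
    bp = boundary_profile(sub, bs[0])
    nxg = sub.nx_graph()
    wg = nx.Graph()
    for u, v, d in nxg.edges(data=True):
        w = d.get("length", 0.0)
        if not wg.has_edge(u, v) or wg[u][v]["length"] > w:
            wg.add_edge(u, v, length=w)
    sources = sub.root_path if sub.bridged else [sub.root_vertex]
    best = {}
    for u in sources:
        dist = nx.single_source_dijkstra_path_length(wg, u, weight="length")
        for v, d in dist.items():
            val = d - g.clearance[u]
            if v not in best or val < best[v]:
                best[v] = val
    # recompute heights for the vertices the profile attached to
    from voromorph.profiles import _boundary_feet

    feet_arc, feet_vert = _boundary_feet(sub, bs[0])
    for arc, h in zip(bp.arc, bp.height):
        k = np.argmin(np.minimum(np.abs(feet_arc - arc), bs[0].perimeter - np.abs(feet_arc - arc)))
        v = int(feet_vert[k])
        assert h == pytest.approx(g.clearance[v] + best[v], abs=1e-9)


def test_feature_vector_layout_and_consistency(annulus_fixture):
    _, bs, _, ann, _ = annulus_fixture
    b = bs[0]
    vec = boundary_features(
        ann.subgraphs.get((0, "in")), ann.subgraphs.get((0, "out")), b
    )
    assert len(vec) == N_FEATURES == 40
    names = dict(zip(FEATURE_NAMES, vec))
    # AUC monotone over the four quantiles, both sides
    for side in ("in", "out"):
        aucs = [names[f"{side}_auc_q{q}"] for q in (0, 25, 50, 75)]
        assert all(a >= b2 - 1e-9 for a, b2 in zip(aucs, aucs[1:]))
    # area/perimeter repeat the tracing values exactly; flag identical
    for side in ("in", "out"):
        assert names[f"{side}_area"] == b.enclosed_area
        assert names[f"{side}_perimeter"] == b.perimeter
    assert names["in_exterior_flag"] == names["out_exterior_flag"] == 1.0


def test_missing_side_yields_sentinel_zeros(disk_fixture, caplog):
    import logging

    _, bs, _, ann, _ = disk_fixture
    with caplog.at_level(logging.WARNING):
        vec = boundary_features(None, ann.subgraphs.get((0, "out")), bs[0])
    assert np.all(vec[:17] == 0.0)
    assert "no in-side subgraph" in caplog.text


def test_features_table_shape(annulus_fixture):
    _, _, _, ann, _ = annulus_fixture
    tab = features_table(ann, image_id="ann")
    assert list(tab.columns[:2]) == ["image_id", "boundary_id"]
    assert tab.shape == (2, 2 + N_FEATURES)
    assert set(tab["boundary_id"]) == {0, 1}
    # interior boundary flagged 0, exterior 1
    assert tab.set_index("boundary_id").loc[0, "in_exterior_flag"] == 1.0
    assert tab.set_index("boundary_id").loc[1, "in_exterior_flag"] == 0.0
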