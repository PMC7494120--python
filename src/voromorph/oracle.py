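"""Brute-force tangent-circle oracle for the generalized Voronoi diagram.

Enumerates every triple of sites, solves for their mutually tangent
circles in closed form, discards circles that contain any site, and
assembles the surviving centres into a graph with the same conventions as
the fast builder.  O(n^3): intended only for verifying the expansion
construction on small instances.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .geometry import SiteSet, bisector_events, pair_bisectors, validate_events
from .voronoi import ShapeGraph, SizeError, _Builder, _corner_seeds

__all__ = [
    "oracle_graph",
    "oracle_graph_from_sites",
    "match_graphs",
    "random_site_instance",
]

DEFAULT_CAP = 200


def _oracle(ss: SiteSet, frame, cap: int, spacing: float) -> ShapeGraph:
    if ss.nsites > cap:
        raise SizeError(f"oracle capped at {cap} sites, got {ss.nsites}")
    builder = _Builder(ss, spacing=spacing)
    n = ss.nsites
    for i, j in combinations(range(n), 2):
        # try every triple from all three of its pairs: a single pair's
        # closed-form solve can be too ill-conditioned to pass the
        # tangency tolerance
        cand = np.arange(n)
        cand = cand[(cand != i) & (cand != j)]
        if len(cand) == 0:
            continue
        for bis in pair_bisectors(ss, i, j):
            t, third = bisector_events(ss, bis, cand)
            t, third, X, r = validate_events(ss, bis, t, third)
            if len(t) == 0:
                continue
            # loose pre-filter on the unrefined solutions; add_cluster
            # re-checks emptiness tightly at the refined position
            dmat = ss.all_distances(X)
            empty = np.nanmin(np.where(np.isfinite(dmat), dmat, np.inf), axis=1) >= (
                r - 1e-6
            )
            for m in np.nonzero(empty)[0]:
                builder.add_cluster(X[m], float(r[m]), {i, j, int(third[m])})
    # corner contact vertices (r = 0) are tangency triples too, but make
    # sure they are present even when the solver returns them marginally
    for pos, rr, sids in _corner_seeds(ss):
        builder.add_cluster(pos, rr, sids)
    return builder.assemble(frame)


def oracle_graph(
    boundaries,
    frame=None,
    *,
    cap: int = DEFAULT_CAP,
    merge_collinear: bool = True,
    spacing: float = 0.75,
) -> ShapeGraph:
    ss = SiteSet.from_boundaries(list(boundaries), frame=frame, merge_collinear=merge_collinear)
    return _oracle(ss, frame, cap, spacing)


def oracle_graph_from_sites(
    points=None, segments=None, frame=None, *, cap: int = DEFAULT_CAP, spacing: float = 0.75
) -> ShapeGraph:
    ss = SiteSet.from_raw(points, segments, frame=frame)
    return _oracle(ss, frame, cap, spacing)


def random_site_instance(
    rng: np.random.Generator,
    max_sites: int = 30,
    box: float = 20.0,
    min_sep: float = 0.05,
):
    """Random mutually disjoint points and segments inside a box.

    Segment endpoints count as point sites, so the total site count is
    about ``n_segments * 3 + n_points`` and is kept below ``max_sites``.
    """
    from shapely.geometry import LineString, Point

    n_seg = int(rng.integers(2, max(3, max_sites // 5)))
    n_pt = int(rng.integers(2, max(3, max_sites // 5)))
    segs, geoms = [], []
    tries = 0
    while len(segs) < n_seg and tries < 4000:
        tries += 1
        a = rng.uniform(1, box - 1, 2)
        ang = rng.uniform(0, 2 * np.pi)
        L = rng.uniform(0.5, 3.0)
        b = a + L * np.array([np.cos(ang), np.sin(ang)])
        if not (1 <= b[0] <= box - 1 and 1 <= b[1] <= box - 1):
            continue
        ls = LineString([a, b])
        if any(ls.distance(g) < min_sep for g in geoms):
            continue
        geoms.append(ls)
        segs.append((a, b))
    pts = []
    while len(pts) < n_pt and tries < 8000:
        tries += 1
        p = rng.uniform(1, box - 1, 2)
        if all(Point(p).distance(g) > min_sep for g in geoms):
            pts.append(p)
            geoms.append(Point(p))
    return pts, segs


def match_graphs(
    a: ShapeGraph, b: ShapeGraph, tol: float = 1e-6
) -> tuple[float, float]:
    """Compare two diagrams as geometric vertex/edge multisets.

    Returns ``(max_vertex_mismatch, max_edge_mismatch)``: the worst
    distance between matched vertices (position + clearance, after
    canonical sorting of coincident groups) and the worst unmatched edge
    discrepancy measured on (endpoint positions, length).  Values above
    ``tol`` indicate disagreement; ``inf`` means different cardinality.
    """

    def vkeys(g: ShapeGraph):
        return sorted(
            (round(g.positions[v, 0], 9), round(g.positions[v, 1], 9), round(g.clearance[v], 9))
            for v in range(g.n_vertices)
        )

    ka, kb = vkeys(a), vkeys(b)
    if len(ka) != len(kb):
        return np.inf, np.inf
    vmis = max(
        (abs(x1 - x2) + abs(y1 - y2) + abs(r1 - r2))
        for (x1, y1, r1), (x2, y2, r2) in zip(ka, kb)
    ) if ka else 0.0

    def ekeys(g: ShapeGraph):
        keys = []
        for e in g.edges:
            p1 = g.positions[e.v1]
            p2 = g.positions[e.v2]
            pts = sorted([(round(p1[0], 9), round(p1[1], 9)), (round(p2[0], 9), round(p2[1], 9))])
            keys.append((pts[0], pts[1], round(e.length, 6)))
        return sorted(keys)

    ea, eb = ekeys(a), ekeys(b)
    if len(ea) != len(eb):
        return vmis, np.inf
    emis = 0.0
    for k1, k2 in zip(ea, eb):
        d = (
            abs(k1[0][0] - k2[0][0])
            + abs(k1[0][1] - k2[0][1])
            + abs(k1[1][0] - k2[1][0])
            + abs(k1[1][1] - k2[1][1])
            + abs(k1[2] - k2[2])
        )
        emis = max(emis, d)
    return vmis, emis
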