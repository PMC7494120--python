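"""Width profiles, boundary profiles and the 40 per-boundary metrics.

Each boundary owns a subgraph on both sides (foreground and background),
and each subgraph yields two curves:

* the *width profile* — inscribed-circle radii at the vertices of the root
  path, against cumulative arc length along the path.  Inside an object it
  measures local thickness, in the background local sparsity.
* the *boundary profile* — for every point along the boundary, the
  shortest along-graph distance from the root path to the graph vertex
  attached at that point, minus the clearance of the root vertex where the
  path starts.  Protrusions and bumps show up as local maxima whose height
  approximates their geodesic length.

From the two profiles (plus area, perimeter and the exterior/interior
flag) twenty metrics per side are derived, forty per boundary:
moments and extrema of the width profile; mean, standard deviation and
maximum of the boundary profile; area under the boundary profile above its
0/25/50/75% quantiles and the number of (cyclic, upward) crossings of each
quantile — for the 0th quantile, the number of contiguous runs at the
minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .annotate import Annotation, SubGraph
from .raster import Boundary
from .voronoi import RZERO

logger = logging.getLogger(__name__)

__all__ = [
    "WidthProfile",
    "BoundaryProfile",
    "width_profile",
    "boundary_profile",
    "boundary_features",
    "features_table",
    "SIDE_FEATURE_NAMES",
    "FEATURE_NAMES",
    "N_FEATURES",
]

SIDE_FEATURE_NAMES = [
    "width_mean",
    "width_std",
    "width_m3",
    "width_m4",
    "width_min",
    "width_max",
    "bprof_mean",
    "bprof_std",
    "bprof_max",
    "auc_q0",
    "ncross_q0",
    "auc_q25",
    "ncross_q25",
    "auc_q50",
    "ncross_q50",
    "auc_q75",
    "ncross_q75",
    "area",
    "perimeter",
    "exterior_flag",
]
FEATURE_NAMES = [f"in_{n}" for n in SIDE_FEATURE_NAMES] + [
    f"out_{n}" for n in SIDE_FEATURE_NAMES
]
N_FEATURES = len(FEATURE_NAMES)  # 40


@dataclass
class WidthProfile:
    positions: np.ndarray  # cumulative arc length along the root path, px
    radii: np.ndarray  # clearance radii, px
    cyclic: bool


@dataclass
class BoundaryProfile:
    arc: np.ndarray  # boundary arc positions, px
    height: np.ndarray  # normalized heights, px
    root_assignment: np.ndarray  # root-path vertex where each path begins


def _consecutive_lengths(sub: SubGraph, order: list[int], cyclic: bool) -> np.ndarray:
    """Shortest connecting edge length between consecutive root-path vertices."""
    g = sub.graph
    best: dict[tuple[int, int], float] = {}
    for eid in sub.path_edge_ids:
        e = g.edges[eid]
        k = (min(e.v1, e.v2), max(e.v1, e.v2))
        if k not in best or e.length < best[k]:
            best[k] = e.length
    pairs = list(zip(order, order[1:]))
    if cyclic and len(order) > 1:
        pairs.append((order[-1], order[0]))
    out = []
    for u, v in pairs:
        k = (min(u, v), max(u, v))
        if k in best:
            out.append(best[k])
        else:  # connector jumps may skip over an intermediate vertex
            out.append(float(np.hypot(*(g.positions[u] - g.positions[v]))))
    return np.array(out)


def width_profile(sub: SubGraph) -> WidthProfile:
    """Inscribed-circle radii along the root path (one sample per vertex)."""
    if not sub.root_path:
        raise ValueError("subgraph has no root path")
    order = sub.root_path
    g = sub.graph
    lens = _consecutive_lengths(sub, order, sub.root_cyclic)
    positions = np.concatenate([[0.0], np.cumsum(lens[: max(len(order) - 1, 0)])])
    radii = g.clearance[order].astype(float)
    keep = radii > RZERO
    if keep.any() and not keep.all():
        positions, radii = positions[keep], radii[keep]
    return WidthProfile(positions=positions, radii=radii, cyclic=sub.root_cyclic)


def _boundary_feet(sub: SubGraph, boundary: Boundary) -> tuple[np.ndarray, np.ndarray]:
    """(arc position, vertex id) of every tangency of subgraph vertices on
    the boundary."""
    g = sub.graph
    ss = g.sites
    bid = boundary.boundary_id
    arcs, verts = [], []
    for v in sub.vertex_ids:
        x = g.positions[v]
        for s in g.tangent_sites[v]:
            if ss.boundary_of[s] != bid:
                continue
            if s < ss.npts:
                arcs.append(float(ss.pt_arc[s]))
            else:
                k = s - ss.npts
                u = float((x - ss.seg_a[k]) @ ss.seg_dir[k])
                u = min(max(u, 0.0), float(ss.seg_len[k]))
                arcs.append(float(ss.seg_arc0[k]) + u)
            verts.append(int(v))
    if not arcs:
        return np.empty(0), np.empty(0, np.int64)
    arcs = np.array(arcs)
    verts = np.array(verts, np.int64)
    # deterministic tie-break at equal arcs: lower clearance, lower id
    order = np.lexsort((verts, g.clearance[verts], arcs))
    return arcs[order], verts[order]


def _root_distances(sub: SubGraph) -> tuple[np.ndarray, np.ndarray, dict[int, int]]:
    """Multi-source shortest path from the root set, offset by -clearance.

    Returns (D, source_vertex, index map): ``D[v] = min_u (d(u, v) - r_u)``
    over root vertices u, along the subgraph edges.
    """
    g = sub.graph
    verts = [int(v) for v in sub.vertex_ids]
    idx = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    if sub.bridged:
        roots = [v for v in sub.root_path if v in idx]
    else:
        # bridgeless subgraph: paths start at the single max-clearance root
        # (the diameter-shaped root path serves the width profile only)
        roots = [sub.root_vertex] if sub.root_vertex in idx else []
    if not roots:
        raise ValueError("subgraph has no root vertices")
    rows, cols, data = [], [], []
    for eid in sub.path_edge_ids:
        e = g.edges[eid]
        if e.v1 in idx and e.v2 in idx:
            rows.append(idx[e.v1])
            cols.append(idx[e.v2])
            data.append(max(e.length, 0.0))
    rmax = float(np.max(g.clearance[roots]))
    vs = n  # virtual source
    for u in roots:
        rows.append(vs)
        cols.append(idx[u])
        data.append(rmax - float(g.clearance[u]))
    m = csr_matrix((data, (rows, cols)), shape=(n + 1, n + 1))
    dist, pred = dijkstra(m, directed=False, indices=vs, return_predecessors=True)
    D = dist[:n] - rmax
    # trace each vertex back to the root where its path begins
    src = np.full(n, -1, np.int64)
    for i in range(n):
        j = i
        guard = 0
        while pred[j] != vs and pred[j] >= 0 and guard <= n:
            j = pred[j]
            guard += 1
        src[i] = verts[j] if pred[j] == vs else -1
    return D, src, idx


def boundary_profile(sub: SubGraph, boundary: Boundary) -> BoundaryProfile:
    """Normalized root-to-boundary path lengths sampled along the boundary."""
    if not sub.root_path:
        raise ValueError("subgraph has no root path")
    D, src, idx = _root_distances(sub)
    feet_arc, feet_vert = _boundary_feet(sub, boundary)
    if len(feet_arc) == 0:
        raise ValueError(
            f"boundary {boundary.boundary_id} has no tangent vertices in this subgraph"
        )
    arc = boundary.arc_positions
    P = boundary.perimeter
    # nearest tangency foot in cyclic arc distance
    pos = np.searchsorted(feet_arc, arc)
    cand_idx = np.stack([(pos - 1) % len(feet_arc), pos % len(feet_arc)], axis=1)
    cand_arc = feet_arc[cand_idx]
    gap = np.abs(cand_arc - arc[:, None])
    gap = np.minimum(gap, P - gap)
    choice = np.argmin(gap, axis=1)
    vmap = feet_vert[cand_idx[np.arange(len(arc)), choice]]
    g = sub.graph
    # total path length = attachment gap (the tangent vertex's own radius)
    # + along-graph distance to the nearest root, minus that root's radius
    h = np.array([g.clearance[int(v)] + D[idx[int(v)]] for v in vmap])
    srcs = np.array([src[idx[int(v)]] for v in vmap])
    return BoundaryProfile(arc=arc, height=h, root_assignment=srcs)


def _cyclic_trapz(arc: np.ndarray, y: np.ndarray, perimeter: float) -> float:
    a = np.concatenate([arc, [perimeter]])
    yy = np.concatenate([y, [y[0]]])
    return float(np.trapezoid(yy, a))


def _upcrossings(h: np.ndarray, q: float) -> int:
    above = h > q
    if above.all() or not above.any():
        return 0
    prev = np.roll(above, 1)
    return int(np.sum(above & ~prev))


def _runs_at_min(h: np.ndarray, tol: float = 1e-9) -> int:
    at = h <= h.min() + tol
    if at.all():
        return 1
    prev = np.roll(at, 1)
    return int(np.sum(at & ~prev))


def _side_features(
    sub: SubGraph | None, boundary: Boundary, side: str
) -> np.ndarray:
    out = np.zeros(len(SIDE_FEATURE_NAMES))
    flag = 1.0 if boundary.kind == "exterior" else 0.0
    if sub is None or not sub.root_path:
        logger.warning(
            "boundary %d has no %s-side subgraph; side features set to 0",
            boundary.boundary_id,
            side,
        )
        return out
    wp = width_profile(sub)
    bp = boundary_profile(sub, boundary)
    r = wp.radii
    mu = float(np.mean(r))
    out[0] = mu
    out[1] = float(np.std(r))
    out[2] = float(np.mean((r - mu) ** 3))
    out[3] = float(np.mean((r - mu) ** 4))
    out[4] = float(np.min(r))
    out[5] = float(np.max(r))
    h = bp.height
    out[6] = float(np.mean(h))
    out[7] = float(np.std(h))
    out[8] = float(np.max(h))
    P = boundary.perimeter
    qs = np.quantile(h, [0.0, 0.25, 0.5, 0.75])
    for m, q in enumerate(qs):
        out[9 + 2 * m] = _cyclic_trapz(bp.arc, np.maximum(h - q, 0.0), P)
        if m == 0:
            out[10 + 2 * m] = _runs_at_min(h)
        else:
            out[10 + 2 * m] = _upcrossings(h, q)
    out[17] = boundary.enclosed_area
    out[18] = P
    out[19] = flag
    return out


def boundary_features(
    in_sub: SubGraph | None, out_sub: SubGraph | None, boundary: Boundary
) -> np.ndarray:
    """The 40-vector of per-boundary metrics (in-side block then out-side)."""
    fin = _side_features(in_sub, boundary, "in")
    fout = _side_features(out_sub, boundary, "out")
    return np.concatenate([fin, fout])


def features_table(ann: Annotation, image_id: str = "image"):
    """One feature row per boundary of an annotated image."""
    import pandas as pd

    rows = []
    for b in ann.boundaries:
        fin = ann.subgraphs.get((b.boundary_id, "in"))
        fout = ann.subgraphs.get((b.boundary_id, "out"))
        vec = boundary_features(fin, fout, b)
        rows.append([image_id, b.boundary_id, *vec])
    return pd.DataFrame(rows, columns=["image_id", "boundary_id", *FEATURE_NAMES])
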