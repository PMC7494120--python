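"""Generalized Voronoi diagram (shape graph) of boundary sites.

The diagram of all boundary corners and segments, clipped by the image
frame, is the central object of the pipeline: its vertices are centres of
maximal empty circles tangent to at least three sites, its edges are the
bisector arcs between two sites.  The medial axis of every object is a
subset of the part of the graph inside the foreground.

Construction is a deterministic *clearance expansion*: every boundary
corner is a known degree-3 vertex of the diagram with clearance 0 (the
convex-side angle bisector plus the two reflex-side perpendiculars meet
there), and every edge can be walked from a vertex along its bisector to
the next tangency event, which is found by closed-form quadratic solves
against spatially pruned candidate sites.  Breadth-first expansion from
the corner seeds therefore reaches the whole (connected, frame-bounded)
diagram; an exhaustive O(n^3) tangent-circle oracle (:mod:`.oracle`)
verifies the result on small instances.

Conventions:

* vertices tangent to four or more cocircular sites are split into
  coincident degree-3 vertices chained by zero-length edges (fan
  triangulation of the angularly sorted tangencies, anchored at the
  lowest site id);
* the frame rectangle participates as four point and four segment sites;
  the four frame-corner clip terminals keep only their interior diagonal
  edge (their two other edges lie outside the frame), every other vertex
  has degree exactly 3.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    FEET_TOL,
    FRAME_BOUNDARY,
    ONLINE_TOL,
    LineBis,
    ParaBis,
    SiteSet,
    bisector_events,
    pair_bisectors,
    validate_events,
)

__all__ = [
    "ShapeGraph",
    "GraphEdge",
    "GeometryError",
    "SizeError",
    "build_graph",
    "build_graph_from_sites",
    "default_frame",
]

RZERO = 1e-9  # clearance below this = boundary-contact vertex
MERGE_TOL = 1e-6  # coincident-vertex clustering tolerance, px
STEP_TOL = 5e-7  # minimum parameter advance when walking an edge
EMPTY_TOL = 1e-9  # emptiness slack at refined vertex positions, px
CLUSTER_TOL = 2e-9  # extra-tangency collection at refined vertices, px


class GeometryError(ValueError):
    pass


class SizeError(ValueError):
    pass


@dataclass
class GraphEdge:
    v1: int
    v2: int
    sites: tuple[int, int]
    curve_kind: str  # "line" | "parabolic"
    length: float
    side: str = ""  # filled by annotation: "in" | "out" | "frame"
    owner: int = -2  # owning boundary of the subgraph partition (annotation)


@dataclass
class ShapeGraph:
    sites: SiteSet
    positions: np.ndarray  # (V, 2)
    clearance: np.ndarray  # (V,)
    tangent_sites: list[tuple[int, ...]]
    cluster_id: np.ndarray  # geometric (pre-split) vertex id
    edges: list[GraphEdge]
    frame: tuple[float, float, float, float] | None = None
    vertex_side: np.ndarray | None = None  # filled by annotation
    vertex_role: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for e in self.edges:
            deg[e.v1] += 1
            deg[e.v2] += 1
        return deg

    def vertex_boundaries(self, vid: int) -> frozenset:
        return frozenset(int(self.sites.boundary_of[s]) for s in self.tangent_sites[vid])

    def frame_corner_terminals(self) -> np.ndarray:
        """The (up to four) frame-corner clip terminals (degree-1 by design)."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        for v in range(self.n_vertices):
            if self.clearance[v] <= RZERO and all(
                self.sites.boundary_of[s] == FRAME_BOUNDARY for s in self.tangent_sites[v]
            ):
                mask[v] = True
        return mask

    def edge_boundaries(self, e: GraphEdge) -> tuple[int, int]:
        b = self.sites.boundary_of
        return int(b[e.sites[0]]), int(b[e.sites[1]])

    # -- exports ----------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for v in range(self.n_vertices):
            side = "" if self.vertex_side is None else str(self.vertex_side[v])
            role = "" if self.vertex_role is None else str(self.vertex_role[v])
            g.add_node(
                v,
                x=float(self.positions[v, 0]),
                y=float(self.positions[v, 1]),
                clearance=float(self.clearance[v]),
                side=side,
                role=role,
            )
        for k, e in enumerate(self.edges):
            b1, b2 = self.edge_boundaries(e)
            g.add_edge(
                e.v1,
                e.v2,
                key=k,
                length=e.length,
                curve_kind=e.curve_kind,
                side=e.side,
                owner=e.owner,
                boundary_1=b1,
                boundary_2=b2,
            )
        return g

    def save_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def vertices_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "vertex": np.arange(self.n_vertices),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "clearance": self.clearance,
                "side": self.vertex_side if self.vertex_side is not None else "",
                "role": self.vertex_role if self.vertex_role is not None else "",
            }
        )

    def edges_frame(self):
        import pandas as pd

        rows = [
            (
                e.v1,
                e.v2,
                e.sites[0],
                e.sites[1],
                e.curve_kind,
                e.length,
                e.side,
                e.owner,
            )
            for e in self.edges
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "v1",
                "v2",
                "site_1",
                "site_2",
                "curve_kind",
                "length",
                "side",
                "owner",
            ],
        )


# ---------------------------------------------------------------------------


def default_frame(
    shape: tuple[int, int], margin: float = 0.5
) -> tuple[float, float, float, float]:
    """Frame rectangle for an image of given (H, W).

    Placed ``margin`` px outside the pixel-corner domain so that boundary
    runs of edge-touching objects never coincide with frame sites.
    """
    H, W = shape
    return (-0.5 - margin, -0.5 - margin, W - 0.5 + margin, H - 0.5 + margin)


class _Builder:
    """Shared machinery: spatial pruning, emptiness tests, walking, assembly."""

    def __init__(self, ss: SiteSet, spacing: float = 0.75):
        self.ss = ss
        self.spacing = spacing
        self.samples, self.owner = ss.samples(spacing)
        self.tree = cKDTree(self.samples)
        lo = self.samples.min(axis=0)
        hi = self.samples.max(axis=0)
        self.rmax = 2.0 * float(np.hypot(*(hi - lo))) + 16.0
        # clusters: geometric vertices before degenerate splitting
        self.cpos: list[np.ndarray] = []
        self.crad: list[float] = []
        self.csites: list[set[int]] = []
        self._grid: dict[tuple[int, int], list[int]] = {}

    # -- cluster bookkeeping ----------------------------------------------

    def _cells(self, x: np.ndarray):
        cx, cy = int(np.floor(x[0] / 1e-5)), int(np.floor(x[1] / 1e-5))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                yield (cx + dx, cy + dy)

    def find_cluster(self, x: np.ndarray, r: float, sids: set[int] | None = None) -> int | None:
        for cell in self._cells(x):
            for cid in self._grid.get(cell, ()):
                if (
                    abs(self.cpos[cid][0] - x[0]) <= MERGE_TOL
                    and abs(self.cpos[cid][1] - x[1]) <= MERGE_TOL
                    and abs(self.crad[cid] - r) <= MERGE_TOL
                ):
                    if sids is not None:
                        cs = self.csites[cid]
                        # merge only rediscoveries of the same circle;
                        # near-coincident vertices of *different* tangent
                        # triples (a collapsed triangle of true vertices)
                        # stay distinct degree-3 vertices
                        if not (sids <= cs or cs <= sids):
                            continue
                    return cid
        return None

    def refine_vertex(
        self, x: np.ndarray, r: float, sids: set[int]
    ) -> tuple[np.ndarray, float]:
        """Gauss-Newton polish of (centre, clearance) on all tangency residuals.

        Makes the vertex coordinates independent of which bisector pair
        discovered it (closed-form solves of grazing tangencies carry
        sqrt(eps)-level error).
        """
        if r <= RZERO or len(sids) < 3:
            return np.asarray(x, float), float(r)
        ss = self.ss
        x = np.asarray(x, float).copy()
        sl = sorted(int(s) for s in sids)

        def constraints(x, r):
            """Linearized tangency system.

            A segment tangent at one of its own endpoints (a grazing
            contact, recognized by the foot location) contributes the
            perpendicular-at-endpoint constraint instead of the flat
            distance residual, which cannot pin the position.
            """
            rows, res = [], []
            for s in sl:
                if s < ss.npts:
                    d = x - ss.pts[s]
                    dist = float(np.hypot(d[0], d[1]))
                    if dist < 1e-12:
                        continue
                    rows.append([d[0] / dist, d[1] / dist, -1.0])
                    res.append(dist - r)
                else:
                    k = s - ss.npts
                    u = float((x - ss.seg_a[k]) @ ss.seg_dir[k])
                    L = float(ss.seg_len[k])
                    ep = None
                    if abs(u) <= 1e-5 and ss.seg_p0[k] in sids:
                        ep = ss.pts[ss.seg_p0[k]]
                    elif abs(u - L) <= 1e-5 and ss.seg_p1[k] in sids:
                        ep = ss.pts[ss.seg_p1[k]]
                    if ep is not None:
                        ud = ss.seg_dir[k]
                        rows.append([ud[0], ud[1], 0.0])
                        res.append(float((x - ep) @ ud))
                    else:
                        sgn = 1.0 if float(ss.seg_nrm[k] @ x) - ss.seg_c[k] >= 0 else -1.0
                        rows.append([sgn * ss.seg_nrm[k, 0], sgn * ss.seg_nrm[k, 1], -1.0])
                        res.append(abs(float(ss.seg_nrm[k] @ x) - ss.seg_c[k]) - r)
            return rows, res

        for _ in range(3):
            rows, res = constraints(x, r)
            if len(rows) < 3:
                break
            if float(np.max(np.abs(res))) < 1e-12:
                break
            A = np.array(rows)
            b = -np.array(res)
            delta, *_ = np.linalg.lstsq(A, b, rcond=None)
            if not np.all(np.isfinite(delta)):
                break
            delta = np.clip(delta, -1e-4, 1e-4)
            x = x + delta[:2]
            r = r + float(delta[2])
            if float(np.max(np.abs(delta))) < 1e-13:
                break
        return x, float(r)

    def add_cluster(self, x: np.ndarray, r: float, sids: set[int]) -> tuple[int, bool]:
        sids = set(sids)
        # fast path: rediscovery of an already-refined cluster
        cid = self.find_cluster(np.asarray(x, float), float(r), sids)
        if cid is not None and sids <= self.csites[cid]:
            return cid, False
        x, r = self.refine_vertex(x, r, sids)
        # collect further exactly-tangent sites at the refined position; the
        # tight tolerance keeps genuinely distinct near-degenerate vertices
        # apart while still merging exact (lattice) cocircularities
        for _ in range(2):
            more = self.tangent_set(x, r, tol=CLUSTER_TOL)
            if more <= sids:
                break
            sids |= more
            x, r = self.refine_vertex(x, r, sids)
        if not self.empty_ok(x, r):
            return -1, False
        cid = self.find_cluster(x, r, sids)
        if cid is not None:
            self.csites[cid] |= sids
            return cid, False
        cid = len(self.cpos)
        self.cpos.append(np.asarray(x, float))
        self.crad.append(float(r))
        self.csites.append(set(sids))
        cell = (int(np.floor(x[0] / 1e-5)), int(np.floor(x[1] / 1e-5)))
        self._grid.setdefault(cell, []).append(cid)
        return cid, True

    # -- geometric predicates ---------------------------------------------

    def nearby_sites(self, x: np.ndarray, R: float) -> np.ndarray:
        idx = self.tree.query_ball_point(x, R)
        if not idx:
            return np.empty(0, np.int64)
        return np.unique(self.owner[idx])

    def _dists(self, x: np.ndarray, ids: np.ndarray) -> np.ndarray:
        from ._kernels import dists_to_sites

        ss = self.ss
        return dists_to_sites(
            float(x[0]),
            float(x[1]),
            np.ascontiguousarray(ids, np.int64),
            ss.npts,
            ss.pts,
            ss.seg_a,
            ss.seg_dir,
            ss.seg_nrm,
            ss.seg_len,
            FEET_TOL,
        )

    def tangent_set(self, x: np.ndarray, r: float, tol: float = CLUSTER_TOL) -> set[int]:
        """Sites tangent to the circle (x, r).

        Transversal contacts are judged by the distance residual at the
        tight tolerance.  Grazing contacts (tangency at a segment endpoint,
        where the residual is quadratically flat and cannot separate nearby
        vertices) are judged positionally: the tangency foot must lie within
        ``MERGE_TOL`` of the endpoint.
        """
        ss = self.ss
        x = np.asarray(x, float)
        ids = self.nearby_sites(x, r + self.spacing + 1e-6)
        if len(ids) == 0:
            return set()
        d = self._dists(x, ids)
        out: set[int] = set()

        segm = ids >= ss.npts
        kacc = np.empty(0, np.int64)
        if segm.any():
            sid_s = ids[segm]
            ds = d[segm]
            k = sid_s - ss.npts
            u = np.einsum("ij,ij->i", x[None, :] - ss.seg_a[k], ss.seg_dir[k])
            end_gap = np.minimum(np.abs(u), np.abs(u - ss.seg_len[k]))
            resid = np.abs(ds - r)
            graze = end_gap <= MERGE_TOL
            acc = np.isfinite(ds) & np.where(graze, resid <= 1e-6, resid <= tol)
            out.update(int(s) for s in sid_s[acc])
            kacc = k[acc]
        if (~segm).any():
            sid_p = ids[~segm]
            dp = d[~segm]
            q = ss.pts[sid_p]
            ok = np.abs(dp - r) <= tol
            if len(kacc):
                # a point on an accepted segment's carrier line grazes: its
                # tangency requires the foot of x on that segment to be at
                # the point itself (residuals are quadratically flat there)
                online = (
                    np.abs(q @ ss.seg_nrm[kacc].T - ss.seg_c[kacc][None, :])
                    <= 10 * ONLINE_TOL
                )
                foot_gap = np.abs(
                    np.einsum("mj,kj->mk", x[None, :] - q, ss.seg_dir[kacc])
                )
                any_online = online.any(axis=1)
                pass_graze = np.where(online, foot_gap <= MERGE_TOL, True).all(axis=1)
                ok = np.where(
                    any_online,
                    (np.abs(dp - r) <= 1e-6) & pass_graze,
                    ok,
                )
            out.update(int(s) for s in sid_p[ok])
        return out

    def empty_ok(self, x: np.ndarray, r: float, tol: float = EMPTY_TOL) -> bool:
        x = np.asarray(x, float)
        ids = self.nearby_sites(x, r + self.spacing + 1e-6)
        if len(ids) == 0:
            return True
        return bool(np.min(self._dists(x, ids)) >= r - tol)

    # -- edge walking ------------------------------------------------------

    def walk(
        self,
        bis: LineBis | ParaBis,
        t0: float,
        sign: float,
        pos: np.ndarray,
        r0: float,
    ) -> tuple[np.ndarray, float, int] | None:
        """Next tangency event along a bisector, or None (clipped direction)."""
        ss = self.ss
        i, j = bis.pair
        # initial gather: nearest samples (cheap, adaptive); later rounds
        # use radius balls sized by the verification bound
        k0 = min(48, len(self.samples))
        dk, ik = self.tree.query(pos, k=k0)
        dk = np.atleast_1d(dk)
        ik = np.atleast_1d(ik)
        cand0 = np.unique(self.owner[ik])
        R = float(dk[-1]) - 1e-9  # radius certainly covered by the k-NN set
        use_first = True
        while True:
            cand = cand0 if use_first else self.nearby_sites(pos, R)
            use_first = False
            cand = cand[(cand != i) & (cand != j)]
            if len(cand):
                t, third = bisector_events(ss, bis, cand)
                dt = sign * (t - t0)
                keep = dt > STEP_TOL
                tc, thc, Xc, rc = validate_events(ss, bis, t[keep], third[keep])
                regather = False
                accepted = None
                for k in np.argsort(sign * (tc - t0)):
                    tb, xb, rb = float(tc[k]), Xc[k], float(rc[k])
                    Rneed = bis.arclen(t0, tb) + max(r0, rb) + self.spacing + 1.0
                    if Rneed > R:
                        R = Rneed
                        regather = True
                        break
                    # A grossly non-empty first event proves this is not an
                    # edge direction (an intruding site would have produced
                    # an earlier accepted tangency); an event non-empty only
                    # at the tight tolerance is a micro-degenerate contact
                    # to skip past.
                    if not self.empty_ok(xb, rb, tol=1e-4):
                        return None
                    xe, re = self.refine_vertex(xb, rb, {i, j, int(thc[k])})
                    if self.empty_ok(xe, re):
                        return xe, re, int(thc[k])
                if regather:
                    continue
                if len(tc):
                    # valid events existed but none terminated the walk
                    if R >= self.rmax:
                        return None
                    R = min(2.0 * R, self.rmax)
                    continue
            if R >= self.rmax:
                return None
            R = min(2.0 * R, self.rmax)

    # -- discovery ---------------------------------------------------------

    def adjacent_pairs(self, cid: int) -> list[tuple[int, int]]:
        sids = sorted(self.csites[cid])
        r = self.crad[cid]
        pos = self.cpos[cid]
        if r <= RZERO or len(sids) <= 3:
            return [tuple(sorted(p)) for p in combinations(sids, 2)]
        order = self._angular_order(pos, sids)
        k = len(order)
        return [tuple(sorted((order[m], order[(m + 1) % k]))) for m in range(k)]

    def _angular_order(self, pos: np.ndarray, sids: list[int]) -> list[int]:
        """Cyclic order of tangency points around the circle.

        A point site and a segment tangent exactly at that point (foot at
        the segment's endpoint) share the same tangency angle; the segment
        is then placed on the side of the tie towards its own interior,
        which is the order in which the two cells actually appear around
        the vertex.
        """
        ss = self.ss
        keys = []
        for s in sids:
            f = ss.tangency_foot(pos, s)
            th = float(np.arctan2(f[1] - pos[1], f[0] - pos[0]))
            sub = 0.0
            if s >= ss.npts:
                k = s - ss.npts
                rad = f - pos
                rn = float(np.hypot(rad[0], rad[1]))
                if rn > 0:
                    that = np.array([-rad[1], rad[0]]) / rn  # CCW tangent dir
                    for e, other in (
                        (ss.seg_a[k], ss.seg_b[k]),
                        (ss.seg_b[k], ss.seg_a[k]),
                    ):
                        if np.hypot(*(f - e)) < 1e-7:
                            v = other - e
                            v = v / np.hypot(v[0], v[1])
                            sub = 0.5 if float(v @ that) > 0 else -0.5
                            break
            keys.append((th, sub, s))
        keys.sort()
        # merge angular ties (including the wrap-around at +-pi)
        groups: list[list[tuple[float, float, int]]] = []
        for k3 in keys:
            if groups and abs(k3[0] - groups[-1][-1][0]) <= 1e-6:
                groups[-1].append(k3)
            else:
                groups.append([k3])
        if len(groups) > 1 and abs((groups[0][0][0] + 2 * np.pi) - groups[-1][-1][0]) <= 1e-6:
            merged = groups.pop() + groups[0]
            groups[0] = sorted(merged, key=lambda k3: (k3[1], k3[2]))
        out: list[int] = []
        for gr in groups:
            out.extend(s for _, _, s in sorted(gr, key=lambda k3: (k3[1], k3[2])))
        return out

    def direction_valid(
        self,
        bis: LineBis | ParaBis,
        t0: float,
        sign: float,
        sids,
        i: int,
        j: int,
        delta: float = 1e-4,
    ) -> bool:
        """Probe whether (pair, sign) is locally a Voronoi edge direction.

        Along a genuine edge the pair stays tangent with valid feet and no
        other tangent site of the vertex intrudes; wrong bisector branches
        and continuations into a third site's cell fail within ``delta``.
        """
        import math

        ss = self.ss
        tp = t0 + sign * delta
        xp = bis.point(tp)
        x0, y0 = float(xp[0]), float(xp[1])
        rp = float(bis.radius(tp))

        def sdist(s: int) -> float:
            if s < ss.npts:
                return math.hypot(x0 - ss.pts[s, 0], y0 - ss.pts[s, 1])
            k = s - ss.npts
            rx, ry = x0 - ss.seg_a[k, 0], y0 - ss.seg_a[k, 1]
            u = rx * ss.seg_dir[k, 0] + ry * ss.seg_dir[k, 1]
            if u < -FEET_TOL or u > ss.seg_len[k] + FEET_TOL:
                return math.inf
            return abs(rx * ss.seg_nrm[k, 0] + ry * ss.seg_nrm[k, 1])

        for s in (i, j):
            d = sdist(s)
            if not math.isfinite(d) or abs(d - rp) > 1e-5:
                return False
        for s in sids:
            if s != i and s != j and sdist(s) < rp - 1e-9:
                return False
        return True

    def discover(self, seeds: list[tuple[np.ndarray, float, set[int]]]) -> None:
        frontier: deque[int] = deque()
        for pos, r, sids in seeds:
            cid, new = self.add_cluster(pos, r, sids)
            if new:
                frontier.append(cid)
        explored: set = set()
        while frontier:
            cid = frontier.popleft()
            pos, r = self.cpos[cid], self.crad[cid]
            for i, j in self.adjacent_pairs(cid):
                for bidx, bis in enumerate(pair_bisectors(self.ss, i, j)):
                    tV = bis.param(pos)
                    if float(np.hypot(*(bis.point(tV) - pos))) > 10 * MERGE_TOL:
                        continue  # vertex not on this bisector branch
                    for sign in (1.0, -1.0):
                        key = (cid, i, j, bidx, sign)
                        if key in explored:
                            continue
                        explored.add(key)
                        if not self.direction_valid(bis, tV, sign, self.csites[cid], i, j):
                            continue
                        ev = self.walk(bis, tV, sign, pos, r)
                        if ev is None:
                            continue
                        xb, rb, third = ev
                        ncid, new = self.add_cluster(xb, rb, {i, j, third})
                        if ncid == cid or ncid < 0:
                            continue
                        explored.add((ncid, i, j, bidx, -sign))
                        if new:
                            frontier.append(ncid)

    # -- assembly ----------------------------------------------------------

    def assemble(
        self, frame: tuple[float, float, float, float] | None
    ) -> ShapeGraph:
        ss = self.ss
        vpos: list[np.ndarray] = []
        vrad: list[float] = []
        vtang: list[tuple[int, ...]] = []
        vclu: list[int] = []
        registry: dict[tuple[int, int], list[tuple[int, np.ndarray, float]]] = {}
        zero_edges: list[tuple[int, int, tuple[int, int]]] = []

        def new_vertex(pos, r, tang, cid) -> int:
            vid = len(vpos)
            vpos.append(np.asarray(pos, float))
            vrad.append(float(r))
            vtang.append(tuple(sorted(int(s) for s in tang)))
            vclu.append(cid)
            return vid

        def register(pair, vid):
            registry.setdefault(tuple(sorted(pair)), []).append(
                (vid, vpos[vid], vrad[vid])
            )

        for cid in range(len(self.cpos)):
            pos, r = self.cpos[cid], self.crad[cid]
            sids = sorted(self.csites[cid])
            k = len(sids)
            if k < 3:
                continue  # spurious cluster (cannot be a vertex)
            if k == 3 or r <= RZERO:
                vid = new_vertex(pos, r, sids, cid)
                for pair in combinations(sids, 2):
                    register(pair, vid)
                continue
            order = self._angular_order(pos, sids)
            # rotate so the smallest site id leads (deterministic fan anchor)
            a_idx = int(np.argmin(order))
            order = order[a_idx:] + order[:a_idx]
            sub: list[int] = []
            for m in range(1, k - 1):
                tri = (order[0], order[m], order[m + 1])
                sub.append(new_vertex(pos, r, tri, cid))
            for m in range(len(sub) - 1):
                zero_edges.append((sub[m], sub[m + 1], tuple(sorted((order[0], order[m + 2])))))
            register((order[0], order[1]), sub[0])
            register((order[k - 1], order[0]), sub[-1])
            for m in range(1, k - 1):
                register((order[m], order[m + 1]), sub[m - 1])

        edges: list[GraphEdge] = []
        for v1, v2, pair in zero_edges:
            edges.append(GraphEdge(v1, v2, pair, "line", 0.0))
        for pair, entries in registry.items():
            if len(entries) < 2:
                continue
            i, j = pair
            for bis in pair_bisectors(ss, i, j):
                on = []
                for vid, pos, r in entries:
                    t = bis.param(pos)
                    if float(np.hypot(*(bis.point(t) - pos))) > 10 * MERGE_TOL:
                        continue
                    if abs(float(bis.radius(t)) - r) > 1e-4:
                        continue
                    on.append((t, vid))
                on.sort()
                for (t1, u1), (t2, u2) in zip(on, on[1:]):
                    if t2 - t1 <= 1e-9 or u1 == u2:
                        continue
                    tm = 0.5 * (t1 + t2)
                    xm = bis.point(tm)
                    rm = float(bis.radius(tm))
                    dm = ss.distances(xm[None, :], np.array([i, j]))[0]
                    if not np.all(np.isfinite(dm)) or np.max(np.abs(dm - rm)) > 1e-5:
                        continue
                    if not self.empty_ok(xm, rm):
                        continue
                    edges.append(
                        GraphEdge(u1, u2, pair, bis.kind, float(bis.arclen(t1, t2)))
                    )

        # canonical vertex order for reproducibility
        order = sorted(
            range(len(vpos)),
            key=lambda v: (vpos[v][0], vpos[v][1], vrad[v], vtang[v]),
        )
        remap = {old: new for new, old in enumerate(order)}
        positions = np.array([vpos[v] for v in order]).reshape(-1, 2)
        clearance = np.array([vrad[v] for v in order])
        tangent_sites = [vtang[v] for v in order]
        cluster_id = np.array([vclu[v] for v in order], dtype=np.int64)
        for e in edges:
            e.v1, e.v2 = remap[e.v1], remap[e.v2]
            if e.v1 > e.v2:
                e.v1, e.v2 = e.v2, e.v1
        edges.sort(key=lambda e: (e.v1, e.v2, e.sites))
        return ShapeGraph(
            sites=ss,
            positions=positions,
            clearance=clearance,
            tangent_sites=tangent_sites,
            cluster_id=cluster_id,
            edges=edges,
            frame=frame,
        )


# ---------------------------------------------------------------------------


def _corner_seeds(ss: SiteSet) -> list[tuple[np.ndarray, float, set[int]]]:
    return [
        (ss.pts[i].copy(), 0.0, {i, sprev, snext})
        for (i, sprev, snext) in ss.corner_triples()
    ]


def _bruteforce_seeds(builder: _Builder, cap: int = 400):
    """Empty tangent circles by exhaustive triple search (raw inputs only)."""
    ss = builder.ss
    if ss.nsites > cap:
        raise SizeError(
            f"{ss.nsites} sites without boundary corners: brute-force seeding "
            f"is capped at {cap}; provide a frame or boundary input"
        )
    seeds = []
    for i, j in combinations(range(ss.nsites), 2):
        for bis in pair_bisectors(ss, i, j):
            cand = np.array([k for k in range(ss.nsites) if k > j and k != i], np.int64)
            if len(cand) == 0:
                continue
            t, third = bisector_events(ss, bis, cand)
            t, third, X, r = validate_events(ss, bis, t, third)
            for m in range(len(t)):
                if builder.empty_ok(X[m], float(r[m])):
                    seeds.append((X[m], float(r[m]), {i, j, int(third[m])}))
    return seeds


def _check_boundaries(boundaries) -> None:
    from shapely import STRtree
    from shapely.geometry import LinearRing

    rings = []
    for b in boundaries:
        ring = LinearRing(np.asarray(b.points))
        if not ring.is_simple:
            raise GeometryError(f"boundary {b.boundary_id} self-intersects")
        rings.append(ring)
    if len(rings) > 1:
        tree = STRtree(rings)
        for a_idx, ring in enumerate(rings):
            for b_idx in tree.query(ring, predicate="intersects"):
                if int(b_idx) > a_idx:
                    raise GeometryError(
                        f"boundaries {boundaries[a_idx].boundary_id} and "
                        f"{boundaries[int(b_idx)].boundary_id} intersect"
                    )


def build_graph(
    boundaries,
    frame: tuple[float, float, float, float] | None = None,
    *,
    merge_collinear: bool = True,
    spacing: float = 0.75,
    validate_input: bool = True,
) -> ShapeGraph:
    """Generalized Voronoi graph of traced boundaries plus the frame."""
    boundaries = list(boundaries)
    if validate_input and boundaries:
        _check_boundaries(boundaries)
    ss = SiteSet.from_boundaries(boundaries, frame=frame, merge_collinear=merge_collinear)
    builder = _Builder(ss, spacing=spacing)
    seeds = _corner_seeds(ss)
    if not seeds:
        seeds = _bruteforce_seeds(builder)
    builder.discover(seeds)
    return builder.assemble(frame)


def build_graph_from_sites(
    points=None,
    segments=None,
    frame: tuple[float, float, float, float] | None = None,
    *,
    spacing: float = 0.75,
) -> ShapeGraph:
    """Diagram of loose point/segment sites (testing interface)."""
    ss = SiteSet.from_raw(points, segments, frame=frame)
    builder = _Builder(ss, spacing=spacing)
    seeds = _corner_seeds(ss)
    if frame is None or not seeds:
        seeds = seeds + _bruteforce_seeds(builder)
    builder.discover(seeds)
    return builder.assemble(frame)
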