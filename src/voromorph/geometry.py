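"""Sites and exact bisector algebra for the generalized Voronoi diagram.

The diagram's input ("sites") is the decomposition of every boundary
polyline into corner *points* and open *segments* between consecutive
corners, plus the frame rectangle.  Runs of collinear boundary vertices are
merged into single segments: the union of sites is the same point set, so
the diagram is unchanged geometrically, while the measure-zero degenerate
cells of run-interior vertices disappear.

Distance conventions
--------------------
The distance from ``x`` to a segment site is the perpendicular distance if
the foot of ``x`` falls inside the segment (up to a small tolerance) and
infinite otherwise; segment endpoints are always separate point sites, so
the minimum over all sites still equals the true distance to the boundary
geometry.  This convention makes the bisector between a segment and its own
endpoint the perpendicular line at the endpoint — a genuine 1-D bisector —
instead of a degenerate half-plane.

Bisectors between two sites are straight lines (point/point,
segment/segment, point/segment with the point on the segment's carrier
line) or parabolic arcs (point/segment otherwise).  Each bisector is
parameterized 1-D; a Voronoi vertex is a parameter value where a third
site reaches the running clearance radius.  Those "events" reduce to
quadratics solved in closed form, batched over candidate third sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SiteSet", "LineBis", "ParaBis", "pair_bisectors", "FRAME_BOUNDARY"]

FRAME_BOUNDARY = -1

FEET_TOL = 1e-7  # px beyond a segment end still counted as "inside"
TANGENT_TOL = 1e-7  # |d - r| below this = tangency
ONLINE_TOL = 1e-9  # point-on-carrier-line threshold (degenerate parabola)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


class SiteSet:
    """Immutable arrays describing all point and segment sites.

    Site ids: ``0..npts-1`` are points, ``npts..npts+nsegs-1`` are segments.
    """

    def __init__(
        self,
        pts: np.ndarray,
        pt_boundary: np.ndarray,
        pt_arc: np.ndarray,
        seg_a: np.ndarray,
        seg_b: np.ndarray,
        seg_boundary: np.ndarray,
        seg_arc0: np.ndarray,
    ):
        self.pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        self.pt_boundary = np.asarray(pt_boundary, dtype=np.int64)
        self.pt_arc = np.asarray(pt_arc, dtype=float)
        self.seg_a = np.asarray(seg_a, dtype=float).reshape(-1, 2)
        self.seg_b = np.asarray(seg_b, dtype=float).reshape(-1, 2)
        self.seg_boundary = np.asarray(seg_boundary, dtype=np.int64)
        self.seg_arc0 = np.asarray(seg_arc0, dtype=float)
        d = self.seg_b - self.seg_a
        self.seg_len = np.hypot(d[:, 0], d[:, 1])
        if self.seg_len.size and self.seg_len.min() <= 0:
            raise ValueError("degenerate zero-length segment site")
        self.seg_dir = d / self.seg_len[:, None]
        self.seg_nrm = np.stack([-self.seg_dir[:, 1], self.seg_dir[:, 0]], axis=1)
        self.seg_c = np.einsum("ij,ij->i", self.seg_nrm, self.seg_a)
        self.npts = len(self.pts)
        self.nsegs = len(self.seg_a)
        self.nsites = self.npts + self.nsegs
        self.boundary_of = np.concatenate([self.pt_boundary, self.seg_boundary])
        # point-site ids of segment endpoints (-1 where the endpoint is not
        # a registered point site; boundary decompositions always register)
        coord2pt = {(float(x), float(y)): i for i, (x, y) in enumerate(self.pts)}
        self.seg_p0 = np.array(
            [coord2pt.get((float(a[0]), float(a[1])), -1) for a in self.seg_a],
            dtype=np.int64,
        )
        self.seg_p1 = np.array(
            [coord2pt.get((float(b[0]), float(b[1])), -1) for b in self.seg_b],
            dtype=np.int64,
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_boundaries(
        cls,
        boundaries: Sequence,
        frame: tuple[float, float, float, float] | None = None,
        merge_collinear: bool = True,
    ) -> "SiteSet":
        """Decompose boundaries (and optionally the frame rectangle) into sites."""
        P, Pb, Pa = [], [], []
        Sa, Sb, Sbnd, Sarc = [], [], [], []

        def add_loop(pts: np.ndarray, arc: np.ndarray, bid: int) -> None:
            n = len(pts)
            if merge_collinear:
                prev = pts[np.arange(n) - 1]
                nxt = pts[(np.arange(n) + 1) % n]
                d1 = pts - prev
                d2 = nxt - pts
                cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
                corner = np.abs(cross) > 1e-9
                if not corner.any():
                    raise ValueError(f"boundary {bid} has no corners")
                idx = np.nonzero(corner)[0]
            else:
                idx = np.arange(n)
            cpts = pts[idx]
            carc = arc[idx]
            P.extend(cpts)
            Pb.extend([bid] * len(idx))
            Pa.extend(carc)
            m = len(idx)
            for k in range(m):
                a = cpts[k]
                b = cpts[(k + 1) % m]
                Sa.append(a)
                Sb.append(b)
                Sbnd.append(bid)
                Sarc.append(carc[k])

        for b in boundaries:
            add_loop(np.asarray(b.points, float), b.arc_positions, b.boundary_id)

        if frame is not None:
            x0, y0, x1, y1 = frame
            fpts = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)
            seg = np.roll(fpts, -1, axis=0) - fpts
            arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))[:-1]])
            add_loop(fpts, arc, FRAME_BOUNDARY)

        return cls(
            np.array(P, float).reshape(-1, 2),
            np.array(Pb, np.int64),
            np.array(Pa, float),
            np.array(Sa, float).reshape(-1, 2),
            np.array(Sb, float).reshape(-1, 2),
            np.array(Sbnd, np.int64),
            np.array(Sarc, float),
        )

    @classmethod
    def from_raw(
        cls,
        points: np.ndarray | None = None,
        segments: np.ndarray | None = None,
        frame: tuple[float, float, float, float] | None = None,
    ) -> "SiteSet":
        """Build from loose points and segments (each its own 'boundary').

        Segment endpoints are added as point sites automatically.  Intended
        for tests and the oracle; image pipelines use ``from_boundaries``.
        """
        pts = [] if points is None else [np.asarray(p, float) for p in points]
        segs = [] if segments is None else [np.asarray(s, float) for s in segments]
        P, Pb = [], []
        bid = 0
        for p in pts:
            P.append(p)
            Pb.append(bid)
            bid += 1
        Sa, Sb, Sbnd = [], [], []
        for s in segs:
            a, b = s[0], s[1]
            for e in (a, b):
                if not any(np.allclose(e, q, atol=1e-12) for q in P):
                    P.append(np.asarray(e, float))
                    Pb.append(bid)
            Sa.append(a)
            Sb.append(b)
            Sbnd.append(bid)
            bid += 1
        ss = cls(
            np.array(P, float).reshape(-1, 2),
            np.array(Pb, np.int64),
            np.zeros(len(P)),
            np.array(Sa, float).reshape(-1, 2),
            np.array(Sb, float).reshape(-1, 2),
            np.array(Sbnd, np.int64),
            np.zeros(len(Sa)),
        )
        if frame is not None:
            frame_ss = cls.from_boundaries([], frame=frame)
            ss = _concat_sitesets(ss, frame_ss)
        return ss

    # -- queries -----------------------------------------------------------

    def is_point(self, sid: int) -> bool:
        return sid < self.npts

    def is_frame_site(self, sid) -> np.ndarray | bool:
        return self.boundary_of[sid] == FRAME_BOUNDARY

    def site_geometry_point(self, sid: int) -> np.ndarray:
        """Representative point (point itself / segment midpoint)."""
        if sid < self.npts:
            return self.pts[sid]
        k = sid - self.npts
        return 0.5 * (self.seg_a[k] + self.seg_b[k])

    def dist_points(self, X: np.ndarray, ids: np.ndarray) -> np.ndarray:
        d = X[:, None, :] - self.pts[ids][None, :, :]
        return np.hypot(d[..., 0], d[..., 1])

    def dist_segs(self, X: np.ndarray, ks: np.ndarray) -> np.ndarray:
        """Feet-clamped distances from rows of X to segments ks (inf outside)."""
        rel = X[:, None, :] - self.seg_a[ks][None, :, :]
        u = np.einsum("mkj,kj->mk", rel, self.seg_dir[ks])
        perp = np.abs(np.einsum("mkj,kj->mk", rel, self.seg_nrm[ks]))
        L = self.seg_len[ks][None, :]
        out = (u < -FEET_TOL) | (u > L + FEET_TOL)
        perp = np.where(out, np.inf, perp)
        return perp

    def distances(self, X: np.ndarray, sids: np.ndarray) -> np.ndarray:
        """(m, len(sids)) feet-clamped distance matrix."""
        X = np.atleast_2d(np.asarray(X, float))
        sids = np.asarray(sids, np.int64)
        out = np.empty((len(X), len(sids)))
        pm = sids < self.npts
        if pm.any():
            out[:, pm] = self.dist_points(X, sids[pm])
        if (~pm).any():
            out[:, ~pm] = self.dist_segs(X, sids[~pm] - self.npts)
        return out

    def all_distances(self, X: np.ndarray) -> np.ndarray:
        return self.distances(X, np.arange(self.nsites))

    def pairwise_distance(self, X: np.ndarray, sids: np.ndarray) -> np.ndarray:
        """Elementwise distance of ``X[m]`` to site ``sids[m]`` (feet-clamped)."""
        X = np.atleast_2d(np.asarray(X, float))
        sids = np.asarray(sids, np.int64)
        out = np.full(len(sids), np.inf)
        pm = sids < self.npts
        if pm.any():
            d = X[pm] - self.pts[sids[pm]]
            out[pm] = np.hypot(d[:, 0], d[:, 1])
        sm = ~pm
        if sm.any():
            k = sids[sm] - self.npts
            rel = X[sm] - self.seg_a[k]
            u = np.einsum("ij,ij->i", rel, self.seg_dir[k])
            perp = np.abs(np.einsum("ij,ij->i", rel, self.seg_nrm[k]))
            L = self.seg_len[k]
            bad = (u < -FEET_TOL) | (u > L + FEET_TOL)
            out[sm] = np.where(bad, np.inf, perp)
        return out

    def tangency_foot(self, x: np.ndarray, sid: int) -> np.ndarray:
        """Closest point of site ``sid`` to ``x`` (assumed tangent/valid)."""
        if sid < self.npts:
            return self.pts[sid]
        k = sid - self.npts
        u = float(np.dot(x - self.seg_a[k], self.seg_dir[k]))
        u = min(max(u, 0.0), float(self.seg_len[k]))
        return self.seg_a[k] + u * self.seg_dir[k]

    def samples(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        """Dense points on all sites plus owner site ids (for KD pruning)."""
        xs = [self.pts]
        owners = [np.arange(self.npts)]
        for k in range(self.nsegs):
            m = max(1, int(np.ceil(self.seg_len[k] / spacing)))
            t = (np.arange(m) + 0.5) / m * self.seg_len[k]
            xs.append(self.seg_a[k] + t[:, None] * self.seg_dir[k][None, :])
            owners.append(np.full(m, self.npts + k))
        return np.concatenate(xs, axis=0), np.concatenate(owners)

    def corner_triples(self) -> list[tuple[int, int, int]]:
        """(point, incoming segment, outgoing segment) for every boundary corner."""
        res = []
        # segments are emitted boundary-wise in order: segment k starts at the
        # k-th corner of its boundary, so the segment ending at point i is the
        # previous one cyclically within the boundary.
        by_bnd: dict[int, list[int]] = {}
        for k in range(self.nsegs):
            by_bnd.setdefault(int(self.seg_boundary[k]), []).append(k)
        pt_of: dict[tuple[int, float, float], int] = {}
        for i in range(self.npts):
            pt_of[(int(self.pt_boundary[i]), self.pts[i, 0], self.pts[i, 1])] = i
        for bid, ks in by_bnd.items():
            m = len(ks)
            for idx, k in enumerate(ks):
                a = self.seg_a[k]
                i = pt_of.get((bid, a[0], a[1]))
                if i is None:  # raw sitesets: endpoints may be unshared
                    continue
                k_prev = ks[(idx - 1) % m]
                res.append((i, self.npts + k_prev, self.npts + k))
        return res


def _concat_sitesets(a: SiteSet, b: SiteSet) -> SiteSet:
    return SiteSet(
        np.concatenate([a.pts, b.pts]),
        np.concatenate([a.pt_boundary, b.pt_boundary]),
        np.concatenate([a.pt_arc, b.pt_arc]),
        np.concatenate([a.seg_a, b.seg_a]),
        np.concatenate([a.seg_b, b.seg_b]),
        np.concatenate([a.seg_boundary, b.seg_boundary]),
        np.concatenate([a.seg_arc0, b.seg_arc0]),
    )


# ---------------------------------------------------------------------------
# bisector descriptors


@dataclass
class LineBis:
    """Straight bisector ``x(t) = o + t e`` with ``r(t)^2 = qa t^2 + qb t + qc``."""

    o: np.ndarray
    e: np.ndarray
    qa: float
    qb: float
    qc: float
    pair: tuple[int, int]
    kind: str = "line"

    def point(self, t: float) -> np.ndarray:
        return self.o + t * self.e

    def radius(self, t) -> float:
        return np.sqrt(np.maximum(self.qa * t * t + self.qb * t + self.qc, 0.0))

    def param(self, x: np.ndarray) -> float:
        return float(np.dot(np.asarray(x) - self.o, self.e))

    def arclen(self, t0: float, t1: float) -> float:
        return abs(t1 - t0)


@dataclass
class ParaBis:
    """Parabolic bisector of a point (focus) and a segment's carrier line.

    Parameterized by the foot coordinate ``s`` along the carrier line:
    ``x(s) = o + s u + y(s) n`` with ``y(s) = ((s-sp)^2 + h^2) / (2h)``,
    the focus at ``o + sp u + h n`` (``h > 0``), and clearance ``r = y``.
    """

    o: np.ndarray
    u: np.ndarray
    n: np.ndarray
    sp: float
    h: float
    pair: tuple[int, int]
    kind: str = "parabolic"

    def y(self, s):
        return ((s - self.sp) ** 2 + self.h**2) / (2.0 * self.h)

    def point(self, s: float) -> np.ndarray:
        return self.o + s * self.u + self.y(s) * self.n

    def radius(self, s) -> float:
        return self.y(s)

    def param(self, x: np.ndarray) -> float:
        return float(np.dot(np.asarray(x) - self.o, self.u))

    def arclen(self, s0: float, s1: float) -> float:
        # arc length of y = (s^2 + h^2)/(2h) in local coords: slope s/h
        a = self.h

        def F(s):
            t = (s - self.sp) / a
            return 0.5 * a * (t * np.sqrt(1 + t * t) + np.arcsinh(t))

        return abs(F(s1) - F(s0))


def pair_bisectors(ss: SiteSet, i: int, j: int) -> list[LineBis | ParaBis]:
    """All bisector branches of sites ``i`` and ``j`` (0, 1 or 2 curves)."""
    if i > j:
        i, j = j, i
    pair = (i, j)
    ip, jp = ss.is_point(i), ss.is_point(j)
    if ip and jp:
        p, q = ss.pts[i], ss.pts[j]
        d = q - p
        L = float(np.hypot(d[0], d[1]))
        if L < 1e-12:
            return []
        m = 0.5 * (p + q)
        e = np.array([-d[1], d[0]]) / L
        return [LineBis(m, e, 1.0, 0.0, (L / 2.0) ** 2, pair)]
    if ip or jp:
        pid, sid = (i, j) if ip else (j, i)
        k = sid - ss.npts
        p = ss.pts[pid]
        nrm, c = ss.seg_nrm[k], ss.seg_c[k]
        h0 = float(np.dot(nrm, p) - c)
        a0, u = ss.seg_a[k], ss.seg_dir[k]
        if abs(h0) <= ONLINE_TOL:
            # focus on the carrier line: bisector degenerates to the
            # perpendicular line through the focus
            return [LineBis(p.copy(), nrm.copy(), 1.0, 0.0, 0.0, pair)]
        n = nrm if h0 > 0 else -nrm
        h = abs(h0)
        sp = float(np.dot(p - a0, u))
        return [ParaBis(a0.copy(), u.copy(), n.copy(), sp, h, pair)]
    # segment / segment: one or two straight bisector lines
    k1, k2 = i - ss.npts, j - ss.npts
    n1, c1 = ss.seg_nrm[k1], ss.seg_c[k1]
    n2, c2 = ss.seg_nrm[k2], ss.seg_c[k2]
    out: list[LineBis | ParaBis] = []
    for sg in (1.0, -1.0):
        w = n1 - sg * n2
        wn = float(np.hypot(w[0], w[1]))
        if wn < 1e-9:
            continue  # (anti)parallel with this sign: no such bisector line
        cc = c1 - sg * c2
        o = w * (cc / (wn * wn))
        e = np.array([-w[1], w[0]]) / wn
        alpha = float(np.dot(n1, o) - c1)
        beta = float(np.dot(n1, e))
        out.append(LineBis(o, e, beta * beta, 2 * alpha * beta, alpha * alpha, pair))
    return out


# ---------------------------------------------------------------------------
# event solving: third-site tangencies along a bisector


def _solve_quad(A, B, C):
    """Vectorized real roots of A t^2 + B t + C = 0 (up to 2 per row)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    C = np.asarray(C, float)
    roots = np.full(A.shape + (2,), np.nan)
    lin = np.abs(A) < 1e-14
    nz = ~lin & True
    disc = B * B - 4 * A * C
    ok = nz & (disc >= 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        roots[..., 0] = np.where(ok, (-B - sq) / (2 * A), np.nan)
        roots[..., 1] = np.where(ok, (-B + sq) / (2 * A), np.nan)
        linroot = np.where(lin & (np.abs(B) > 1e-14), -C / np.where(B == 0, 1, B), np.nan)
    roots[..., 0] = np.where(lin, linroot, roots[..., 0])
    return roots


def _bis_params(bis: "LineBis | ParaBis"):
    """Flat parameter tuple shared by the jitted kernels."""
    if isinstance(bis, LineBis):
        return (
            0,
            float(bis.o[0]),
            float(bis.o[1]),
            float(bis.e[0]),
            float(bis.e[1]),
            0.0,
            0.0,
            float(bis.qa),
            float(bis.qb),
            float(bis.qc),
            0.0,
            1.0,
        )
    return (
        1,
        float(bis.o[0]),
        float(bis.o[1]),
        float(bis.u[0]),
        float(bis.u[1]),
        float(bis.n[0]),
        float(bis.n[1]),
        0.0,
        0.0,
        0.0,
        float(bis.sp),
        float(bis.h),
    )


def bisector_events(
    ss: SiteSet, bis: LineBis | ParaBis, cand: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tangency parameters of candidate third sites along a bisector.

    Generic events are quadratic roots; grazing contacts (a candidate
    point on a pair segment's carrier line, or a candidate segment whose
    carrier passes through a pair point site) are double roots that
    floating-point discriminants can lose, and are solved directly as
    linear perpendicular-crossing conditions.  Returns ``(params,
    site_ids)`` without validity filtering (callers validate feet,
    tangency and emptiness).
    """
    from ._kernels import events_kernel

    cand = np.ascontiguousarray(cand, np.int64)
    if cand.size == 0:
        return np.empty(0), np.empty(0, np.int64)
    i, j = bis.pair
    t, sid = events_kernel(
        *_bis_params(bis),
        int(i),
        int(j),
        cand,
        ss.npts,
        ss.pts,
        ss.seg_a,
        ss.seg_dir,
        ss.seg_nrm,
        ss.seg_c,
        10 * ONLINE_TOL,
    )
    good = np.isfinite(t)
    return t[good], sid[good]


def validate_events(
    ss: SiteSet,
    bis: LineBis | ParaBis,
    t: np.ndarray,
    third: np.ndarray,
    tol: float = TANGENT_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Keep events where i, j and the third site are all tangent (feet valid).

    Returns filtered ``(t, third, X, r)``.
    """
    if len(t) == 0:
        return t, third, np.empty((0, 2)), np.empty(0)

    from ._kernels import validate_kernel

    if isinstance(bis, LineBis):
        kind, ox, oy = 0, bis.o[0], bis.o[1]
        ex, ey, nx, ny = bis.e[0], bis.e[1], 0.0, 0.0
        qa, qb, qc, sp, h = bis.qa, bis.qb, bis.qc, 0.0, 1.0
    else:
        kind, ox, oy = 1, bis.o[0], bis.o[1]
        ex, ey, nx, ny = bis.u[0], bis.u[1], bis.n[0], bis.n[1]
        qa, qb, qc, sp, h = 0.0, 0.0, 0.0, bis.sp, bis.h
    i, j = bis.pair
    keep, tout, X, r = validate_kernel(
        kind,
        float(ox),
        float(oy),
        float(ex),
        float(ey),
        float(nx),
        float(ny),
        float(qa),
        float(qb),
        float(qc),
        float(sp),
        float(h),
        int(i),
        int(j),
        np.ascontiguousarray(t, float),
        np.ascontiguousarray(third, np.int64),
        ss.npts,
        ss.pts,
        ss.seg_a,
        ss.seg_dir,
        ss.seg_nrm,
        ss.seg_len,
        FEET_TOL,
        1e-4,
        tol,
    )
    return tout[keep], third[keep], X[keep], r[keep]
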