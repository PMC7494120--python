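"""Numba-compiled inner loops for diagram construction.

Pure-python/numpy formulations of these loops spend most of their time in
per-call overhead (the candidate sets are small); fusing them into jitted
scalar loops removes that. Semantics match :mod:`.geometry` exactly:
feet-clamped segment distances (infinite outside the segment, endpoints
handled by their point sites) and the line/parabola bisector
parameterizations.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["dists_to_sites", "validate_kernel", "events_kernel"]


@njit(cache=True)
def _push_quad(out_t, out_s, n, sid, A, B, C):
    """Append real roots of A t^2 + B t + C = 0."""
    if abs(A) < 1e-14:
        if abs(B) > 1e-14:
            out_t[n] = -C / B
            out_s[n] = sid
            n += 1
        return n
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return n
    sq = math.sqrt(disc)
    out_t[n] = (-B - sq) / (2.0 * A)
    out_s[n] = sid
    n += 1
    out_t[n] = (-B + sq) / (2.0 * A)
    out_s[n] = sid
    n += 1
    return n


@njit(cache=True)
def events_kernel(
    kind,
    ox,
    oy,
    ex,
    ey,
    nx,
    ny,
    qa,
    qb,
    qc,
    sp,
    h,
    iid,
    jid,
    cand,
    npts,
    pts,
    seg_a,
    seg_dir,
    seg_nrm,
    seg_c,
    online_tol,
):
    """Tangency-event parameters of candidate third sites along a bisector.

    Generic events are quadratic roots; grazing contacts (candidate point
    on a pair segment's carrier line, or candidate segment whose carrier
    passes through a pair point) are double roots solved directly as
    perpendicular-crossing conditions.
    """
    m = cand.size
    out_t = np.empty(6 * m + 8)
    out_s = np.empty(6 * m + 8, np.int64)
    n = 0
    for q in range(m):
        s = cand[q]
        if s < npts:
            px = pts[s, 0]
            py = pts[s, 1]
            rx = px - ox
            ry = py - oy
            if kind == 0:
                pe = rx * ex + ry * ey
                n = _push_quad(
                    out_t, out_s, n, s, 1.0 - qa, -2.0 * pe - qb, rx * rx + ry * ry - qc
                )
            else:
                sc = rx * ex + ry * ey
                hc = rx * nx + ry * ny
                A = 1.0 - hc / h
                B = -2.0 * sc + 2.0 * sp * hc / h
                C = sc * sc + hc * hc - (hc / h) * (sp * sp + h * h)
                n = _push_quad(out_t, out_s, n, s, A, B, C)
            # grazing: p on a pair segment's carrier line
            for pm in range(2):
                ps = iid if pm == 0 else jid
                if ps < npts:
                    continue
                k = ps - npts
                if abs(px * seg_nrm[k, 0] + py * seg_nrm[k, 1] - seg_c[k]) > online_tol:
                    continue
                ux = seg_dir[k, 0]
                uy = seg_dir[k, 1]
                if kind == 0:
                    den = ex * ux + ey * uy
                    if abs(den) > 1e-12:
                        out_t[n] = (rx * ux + ry * uy) / den
                        out_s[n] = s
                        n += 1
                else:
                    out_t[n] = rx * ex + ry * ey
                    out_s[n] = s
                    n += 1
        else:
            k = s - npts
            nkx = seg_nrm[k, 0]
            nky = seg_nrm[k, 1]
            ck = seg_c[k]
            if kind == 0:
                Av = nkx * ox + nky * oy - ck
                Bv = nkx * ex + nky * ey
                n = _push_quad(
                    out_t, out_s, n, s, Bv * Bv - qa, 2.0 * Av * Bv - qb, Av * Av - qc
                )
            else:
                g = nkx * nx + nky * ny
                nu = nkx * ex + nky * ey
                no = nkx * ox + nky * oy - ck
                for sg in range(2):
                    sgn = 1.0 if sg == 0 else -1.0
                    A2 = (g - sgn) / (2.0 * h)
                    A1 = nu - 2.0 * sp * A2
                    A0 = A2 * (sp * sp + h * h) + no
                    n = _push_quad(out_t, out_s, n, s, A2, A1, A0)
            # grazing: pair point on this candidate segment's carrier line
            for pm in range(2):
                pp = iid if pm == 0 else jid
                if pp >= npts:
                    continue
                ppx = pts[pp, 0]
                ppy = pts[pp, 1]
                if abs(ppx * nkx + ppy * nky - ck) > online_tol:
                    continue
                ux = seg_dir[k, 0]
                uy = seg_dir[k, 1]
                if kind == 0:
                    den = ex * ux + ey * uy
                    if abs(den) > 1e-12:
                        out_t[n] = ((ppx - ox) * ux + (ppy - oy) * uy) / den
                        out_s[n] = s
                        n += 1
                else:
                    A2 = (nx * ux + ny * uy) / (2.0 * h)
                    A1 = (ex * ux + ey * uy) - 2.0 * sp * A2
                    A0 = ((ox - ppx) * ux + (oy - ppy) * uy) + A2 * (sp * sp + h * h)
                    n = _push_quad(out_t, out_s, n, s, A2, A1, A0)
    return out_t[:n], out_s[:n]


@njit(cache=True)
def _site_dist(x0, y0, s, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol):
    if s < npts:
        return math.hypot(x0 - pts[s, 0], y0 - pts[s, 1])
    k = s - npts
    rx = x0 - seg_a[k, 0]
    ry = y0 - seg_a[k, 1]
    u = rx * seg_dir[k, 0] + ry * seg_dir[k, 1]
    if u < -feet_tol or u > seg_len[k] + feet_tol:
        return math.inf
    return abs(rx * seg_nrm[k, 0] + ry * seg_nrm[k, 1])


@njit(cache=True)
def dists_to_sites(x0, y0, sids, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol):
    out = np.empty(sids.size)
    for m in range(sids.size):
        out[m] = _site_dist(
            x0, y0, sids[m], npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol
        )
    return out


@njit(cache=True)
def _bis_point(kind, ox, oy, ex, ey, nx, ny, qa, qb, qc, sp, h, t):
    """(x, y, r) on the bisector at parameter t."""
    if kind == 0:  # line
        r2 = qa * t * t + qb * t + qc
        r = math.sqrt(r2) if r2 > 0.0 else 0.0
        return ox + t * ex, oy + t * ey, r
    y = ((t - sp) * (t - sp) + h * h) / (2.0 * h)
    return ox + t * ex + y * nx, oy + t * ey + y * ny, y


@njit(cache=True)
def validate_kernel(
    kind,
    ox,
    oy,
    ex,
    ey,
    nx,
    ny,
    qa,
    qb,
    qc,
    sp,
    h,
    iid,
    jid,
    t,
    third,
    npts,
    pts,
    seg_a,
    seg_dir,
    seg_nrm,
    seg_len,
    feet_tol,
    pre_tol,
    tol,
):
    """Filter + Newton-polish tangency events along one bisector.

    Returns (keep mask, polished t, X, r); keep requires the pair and the
    third site to all be tangent within ``tol`` with valid feet.
    """
    n = t.size
    keep = np.zeros(n, np.bool_)
    tout = np.empty(n)
    X = np.empty((n, 2))
    R = np.empty(n)
    hstep = 1e-6
    for m in range(n):
        tm = t[m]
        s3 = third[m]
        x0, y0, r0 = _bis_point(kind, ox, oy, ex, ey, nx, ny, qa, qb, qc, sp, h, tm)
        di = _site_dist(x0, y0, iid, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
        dj = _site_dist(x0, y0, jid, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
        d3 = _site_dist(x0, y0, s3, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
        if not (math.isfinite(di) and math.isfinite(dj) and math.isfinite(d3)):
            continue
        if abs(di - r0) > pre_tol or abs(dj - r0) > pre_tol or abs(d3 - r0) > pre_tol:
            continue
        # Newton polish on f(t) = d3(x(t)) - r(t)
        for _ in range(2):
            xa, ya, ra = _bis_point(kind, ox, oy, ex, ey, nx, ny, qa, qb, qc, sp, h, tm)
            f = (
                _site_dist(xa, ya, s3, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
                - ra
            )
            xb, yb, rb = _bis_point(
                kind, ox, oy, ex, ey, nx, ny, qa, qb, qc, sp, h, tm + hstep
            )
            f2 = (
                _site_dist(xb, yb, s3, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
                - rb
            )
            if not (math.isfinite(f) and math.isfinite(f2)):
                break
            fp = (f2 - f) / hstep
            if abs(fp) <= 1e-9:
                break
            step = f / fp
            if step > 10 * hstep:
                step = 10 * hstep
            elif step < -10 * hstep:
                step = -10 * hstep
            tm = tm - step
        x0, y0, r0 = _bis_point(kind, ox, oy, ex, ey, nx, ny, qa, qb, qc, sp, h, tm)
        di = _site_dist(x0, y0, iid, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
        dj = _site_dist(x0, y0, jid, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
        d3 = _site_dist(x0, y0, s3, npts, pts, seg_a, seg_dir, seg_nrm, seg_len, feet_tol)
        if (
            math.isfinite(di)
            and math.isfinite(dj)
            and math.isfinite(d3)
            and abs(di - r0) <= tol
            and abs(dj - r0) <= tol
            and abs(d3 - r0) <= tol
        ):
            keep[m] = True
            tout[m] = tm
            X[m, 0] = x0
            X[m, 1] = y0
            R[m] = r0
    return keep, tout, X, R
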