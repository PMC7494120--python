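"""Seeded synthetic rasters with known ground truth.

Every pipeline stage is testable without external data through four
generator families:

* geometric primitives (disk, annulus, bar, spiked disk) with analytically
  known area, inradius and protrusion length;
* a phenomenological *mesh* generator emulating multicellular network
  formation: seeded blob clusters joined by struts, where the probability
  of joining neighbouring clusters ("connectivity") and the strut
  half-width ("density") are the two ground-truth parameters.  The
  generator makes no attempt to model cell mechanics; it only guarantees
  the monotone structure-parameter relationships (more connectivity ->
  more holes / fewer components; more density -> thicker structures) that
  parameter-recovery experiments need;
* space-filling label mosaics (nearest-seed tessellation) for the
  label-image tracing convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .raster import RasterImage

__all__ = ["MeshParams", "make_primitive", "make_mesh", "make_label_mosaic"]


@dataclass
class MeshParams:
    connectivity: float = 0.5  # probability of joining adjacent seed blobs
    density: float = 2.0  # strut half-width, px
    n_seeds: int = 12
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.connectivity <= 1.0:
            raise ValueError("connectivity must be in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")


def _grid(shape: tuple[int, int]):
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    return xx.astype(float), yy.astype(float)


def make_primitive(
    kind: str,
    shape: tuple[int, int] = (128, 128),
    *,
    radius: float = 25.0,
    inner_radius: float = 15.0,
    width: float = 10.0,
    length: float = 40.0,
    spike_length: float = 10.0,
    spike_halfwidth: float = 1.0,
    center: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[RasterImage, dict]:
    """Rasterize a geometric primitive; returns (image, ground truth).

    kinds: ``disk`` (radius), ``annulus`` (radius, inner_radius), ``bar``
    (length x width, axis-aligned), ``spiked_disk`` (disk plus one
    horizontal spike of the given length beyond the disk edge).
    A pixel is foreground when its centre lies inside the ideal shape.
    """
    H, W = shape
    cx, cy = center if center is not None else ((W - 1) / 2.0, (H - 1) / 2.0)
    xx, yy = _grid(shape)
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    truth: dict = {"kind": kind, "center": (cx, cy)}
    if kind == "disk":
        if radius + 1 > min(cx, cy, W - 1 - cx, H - 1 - cy) + 0.5:
            raise ValueError("disk does not fit the frame")
        mask = r2 < radius**2
        truth.update(area=np.pi * radius**2, inradius=radius)
    elif kind == "annulus":
        if inner_radius >= radius:
            raise ValueError("inner_radius must be smaller than radius")
        if radius + 1 > min(cx, cy, W - 1 - cx, H - 1 - cy) + 0.5:
            raise ValueError("annulus does not fit the frame")
        mask = (r2 < radius**2) & (r2 >= inner_radius**2)
        truth.update(
            area=np.pi * (radius**2 - inner_radius**2),
            inradius=(radius - inner_radius) / 2.0,
            inner_radius=inner_radius,
        )
    elif kind == "bar":
        if length > W - 2 or width > H - 2:
            raise ValueError("bar does not fit the frame")
        mask = (np.abs(xx - cx) < length / 2.0) & (np.abs(yy - cy) < width / 2.0)
        truth.update(area=length * width, inradius=min(length, width) / 2.0)
    elif kind == "spiked_disk":
        if radius + spike_length + 1 > W - 1 - cx + 0.5:
            raise ValueError("spike does not fit the frame")
        mask = r2 < radius**2
        mask |= (
            (np.abs(yy - cy) <= spike_halfwidth)
            & (xx - cx >= 0)
            & (xx - cx < radius + spike_length)
        )
        truth.update(
            area=np.pi * radius**2,
            inradius=radius,
            spike_length=spike_length,
        )
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    return RasterImage(mask.astype(int)), truth


def make_mesh(
    params: MeshParams, shape: tuple[int, int] = (128, 128)
) -> tuple[RasterImage, dict]:
    """Random blob-and-strut network with known (connectivity, density).

    Seed points are scattered uniformly (margin kept from the frame); a
    seeded random subset of exactly ``round(connectivity * n_candidates)``
    Delaunay neighbour pairs is joined by struts of half-width
    ``density``, unioned with blobs of radius ``density + 1`` at the
    seeds.  Drawing an exact fraction (rather than i.i.d. coin flips per
    pair) makes the connectivity parameter the realized joined fraction;
    the stochasticity lies in the seed layout and in which pairs join.
    """
    H, W = shape
    rng = np.random.default_rng(params.seed)
    margin = params.density + 3.0
    pts = np.column_stack(
        [
            rng.uniform(margin, W - 1 - margin, params.n_seeds),
            rng.uniform(margin, H - 1 - margin, params.n_seeds),
        ]
    )
    xx, yy = _grid(shape)
    mask = np.zeros(shape, bool)
    blob_r = params.density + 1.0
    for p in pts:
        mask |= (xx - p[0]) ** 2 + (yy - p[1]) ** 2 < blob_r**2

    edges: set[tuple[int, int]] = set()
    if params.n_seeds >= 4:
        tri = Delaunay(pts)
        for s in tri.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                edges.add(tuple(sorted((int(s[a]), int(s[b])))))
    elif params.n_seeds >= 2:
        edges = {(i, i + 1) for i in range(params.n_seeds - 1)}
    cand = sorted(edges)
    n_draw = int(round(params.connectivity * len(cand)))
    chosen = rng.choice(len(cand), size=n_draw, replace=False) if n_draw else []
    drawn = []
    for idx in sorted(int(c) for c in chosen):
        a, b = cand[idx]
        pa, pb = pts[a], pts[b]
        d = pb - pa
        L = float(np.hypot(d[0], d[1]))
        u = d / L
        rel_x = xx - pa[0]
        rel_y = yy - pa[1]
        t = rel_x * u[0] + rel_y * u[1]
        perp = np.abs(rel_x * -u[1] + rel_y * u[0])
        mask |= (t >= 0) & (t <= L) & (perp < params.density)
        drawn.append((a, b))
    truth = {
        "connectivity": params.connectivity,
        "density": params.density,
        "n_seeds": params.n_seeds,
        "seed": params.seed,
        "points": pts,
        "candidate_edges": sorted(edges),
        "drawn_edges": drawn,
    }
    return RasterImage(mask.astype(int)), truth


def make_label_mosaic(
    n_cells: int, shape: tuple[int, int] = (64, 64), seed: int = 0, margin: int = 1
) -> tuple[RasterImage, dict]:
    """Nearest-seed label tessellation filling the frame interior.

    Labels 1..n_cells; a ``margin``-pixel background rim is kept so every
    cell boundary is traceable.  Ground truth includes the seed points and
    the 4-adjacency between labels.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    H, W = shape
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(margin, W - 1 - margin, n_cells), rng.uniform(margin, H - 1 - margin, n_cells)]
    )
    xx, yy = _grid(shape)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    _, owner = cKDTree(pts).query(flat)
    lab = (owner + 1).reshape(shape).astype(np.int32)
    lab[:margin, :] = 0
    lab[-margin:, :] = 0
    lab[:, :margin] = 0
    lab[:, -margin:] = 0
    adj = set()
    for sh in ((0, 1), (1, 0)):
        a = lab[: H - sh[0], : W - sh[1]]
        b = lab[sh[0]:, sh[1]:]
        m = (a != b) & (a > 0) & (b > 0)
        adj |= {tuple(sorted(p)) for p in np.column_stack([a[m], b[m]])}
    truth = {"points": pts, "adjacency": sorted((int(a), int(b)) for a, b in adj)}
    return RasterImage(lab, mode="label"), truth
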