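"""Shared fixtures: synthetic rasters, built graphs, and the seeded
mesh-parameter sweep (session-scoped; the expensive pieces are built once)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from voromorph.annotate import annotate
from voromorph.pipeline import extract_features
from voromorph.raster import RasterImage, trace_binary_boundaries
from voromorph.synth import MeshParams, make_mesh, make_primitive
from voromorph.voronoi import build_graph, default_frame

SWEEP_SEED = 1
SWEEP_SHAPE = (60, 60)
SWEEP_N_SEEDS = 12
SWEEP_CONNECTIVITIES = np.linspace(0.1, 1.0, 10)
SWEEP_DENSITIES = np.linspace(1.2, 2.0, 10)


def build_annotated(arr: np.ndarray):
    """Binary array -> (image, boundaries, graph, annotation)."""
    im = RasterImage(np.asarray(arr).astype(int))
    bs = trace_binary_boundaries(im)
    g = build_graph(bs, frame=default_frame(im.shape))
    return im, bs, g, annotate(g, bs)


@pytest.fixture(scope="session")
def disk_fixture():
    img, truth = make_primitive("disk", (60, 60), radius=25.0)
    return (*build_annotated(img.values), truth)


@pytest.fixture(scope="session")
def annulus_fixture():
    img, truth = make_primitive("annulus", (70, 70), radius=30.0, inner_radius=20.0)
    return (*build_annotated(img.values), truth)


@pytest.fixture(scope="session")
def bar_fixture():
    img, truth = make_primitive("bar", (20, 50), length=40.0, width=10.0)
    return (*build_annotated(img.values), truth)


@pytest.fixture(scope="session")
def spiked_fixtures():
    """Spiked disks for L in {5, 10, 20} plus the unspiked baseline."""
    out = {}
    img, _ = make_primitive("disk", (90, 90), radius=20.0)
    out["baseline"] = build_annotated(img.values)
    for L in (5, 10, 20):
        img, _ = make_primitive(
            "spiked_disk", (90, 90), radius=20.0, spike_length=float(L)
        )
        out[L] = build_annotated(img.values)
    return out


@pytest.fixture(scope="session")
def three_disks_fixture():
    arr = np.zeros((40, 40), bool)
    yy, xx = np.mgrid[0:40, 0:40]
    for cx, cy in ((10, 10), (30, 12), (16, 30)):
        arr |= (xx - cx) ** 2 + (yy - cy) ** 2 < 36
    return build_annotated(arr)


@pytest.fixture(scope="session")
def mesh_sweep():
    """The seeded 10x10 (connectivity, density) sweep: 100 images.

    Returns (per-boundary features, per-image targets).  This is the study
    condition for the parameter-recovery and ablation checks; built once
    per session.
    """
    rng = np.random.default_rng(SWEEP_SEED)
    feats, targets = [], []
    for i, c in enumerate(SWEEP_CONNECTIVITIES):
        for j, d in enumerate(SWEEP_DENSITIES):
            sd = int(rng.integers(0, 2**31 - 1))
            img, _ = make_mesh(
                MeshParams(
                    connectivity=float(c),
                    density=float(d),
                    n_seeds=SWEEP_N_SEEDS,
                    seed=sd,
                ),
                SWEEP_SHAPE,
            )
            iid = f"m{i}{j}"
            feats.append(extract_features(img, image_id=iid).features)
            targets.append(
                {"image_id": iid, "connectivity": float(c), "density": float(d)}
            )
    features = pd.concat(feats, ignore_index=True)
    targets = pd.DataFrame(targets).set_index("image_id")
    return features, targets


@pytest.fixture(scope="session")
def two_family_features():
    """Disks vs meshes: two structurally separable synthetic families."""
    rng = np.random.default_rng(3)
    feats = []
    labels = {}
    for k in range(8):
        r = float(rng.uniform(6, 11))
        img, _ = make_primitive("disk", (40, 40), radius=r)
        iid = f"disk{k}"
        feats.append(extract_features(img, image_id=iid).features)
        labels[iid] = "disk"
    for k in range(8):
        img, _ = make_mesh(
            MeshParams(
                connectivity=1.0,
                density=1.6,
                n_seeds=7,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
            (48, 48),
        )
        iid = f"mesh{k}"
        feats.append(extract_features(img, image_id=iid).features)
        labels[iid] = "mesh"
    features = pd.concat(feats, ignore_index=True)
    return features, pd.Series(labels)


@pytest.fixture(scope="session")
def separable_boundary_features():
    """Single-boundary shape families (disks vs bars) whose boundaries are
    linearly separable in the width/area metrics."""
    rng = np.random.default_rng(3)
    feats, fam = [], []
    for k in range(10):
        img, _ = make_primitive("disk", (40, 40), radius=float(rng.uniform(6, 9)))
        feats.append(extract_features(img, image_id=f"d{k}").features)
        fam.append("disk")
    for k in range(10):
        img, _ = make_primitive(
            "bar", (20, 44), length=float(rng.uniform(24, 34)), width=4.0
        )
        feats.append(extract_features(img, image_id=f"b{k}").features)
        fam.append("bar")
    return pd.concat(feats, ignore_index=True), np.array(fam)
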