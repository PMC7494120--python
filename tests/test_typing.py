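"""Boundary typing, histograms and image-level analyses."""

import numpy as np
import pandas as pd
import pytest

from voromorph.boundary_types import (
    BoundaryTyper,
    HistogramRegressor,
    fit_boundary_types,
    knn_classify,
    pca_embed,
    select_num_types,
)
from voromorph.profiles import FEATURE_NAMES, N_FEATURES


def _random_features(n, rng, image_ids=None):
    df = pd.DataFrame(rng.random((n, N_FEATURES)), columns=FEATURE_NAMES)
    df.insert(0, "image_id", image_ids if image_ids is not None else "img0")
    df.insert(1, "boundary_id", np.arange(n))
    return df


def test_single_type_assigns_everything_to_it():
    rng = np.random.default_rng(0)
    feats = _random_features(7, rng)
    model = fit_boundary_types(feats, n_types=1, seed=0)
    hist = model.transform(feats)
    assert hist.shape == (1, 1)
    assert int(hist.iloc[0, 0]) == 7


def test_duplicated_rows_get_identical_types_and_fit_is_deterministic():
    rng = np.random.default_rng(1)
    feats = _random_features(30, rng)
    dup = pd.concat([feats, feats], ignore_index=True)
    model = fit_boundary_types(dup, n_types=4, seed=7)
    t = model.predict(dup)
    assert np.array_equal(t[:30], t[30:])
    model2 = fit_boundary_types(dup, n_types=4, seed=7)
    assert np.array_equal(model.centroids_, model2.centroids_)
    assert np.array_equal(t, fit_boundary_types(dup, n_types=4, seed=7).predict(dup))


def test_too_few_boundaries_rejected():
    rng = np.random.default_rng(2)
    feats = _random_features(3, rng)
    with pytest.raises(ValueError, match="n_types"):
        fit_boundary_types(feats, n_types=5)


def test_histogram_conservation_and_reproducibility(two_family_features):
    feats, labels = two_family_features
    model = fit_boundary_types(feats, n_types=4, seed=0)
    hist = model.transform(feats)
    per_image = feats.groupby("image_id").size()
    assert (hist.sum(axis=1).loc[per_image.index] == per_image).all()
    hist2 = fit_boundary_types(feats, n_types=4, seed=0).transform(feats)
    pd.testing.assert_frame_equal(hist, hist2)
    norm = model.transform(feats, normalize=True)
    assert np.allclose(norm.sum(axis=1), 1.0)


def test_two_synthetic_families_cluster_purely(separable_boundary_features):
    feats, fam = separable_boundary_features
    model = fit_boundary_types(feats, n_types=2, seed=0)
    t = model.predict(feats)
    # purity 1.0: each cluster contains boundaries of a single family
    for k in (0, 1):
        kinds = set(fam[t == k])
        assert len(kinds) == 1


def test_ablation_flag_restricts_feature_columns(two_family_features):
    feats, _ = two_family_features
    m_full = fit_boundary_types(feats, n_types=2, seed=0)
    m_in = fit_boundary_types(feats, n_types=2, seed=0, use_out=False)
    assert len(m_full.center_) == 40
    assert len(m_in.center_) == 20
    hist = m_in.transform(feats)
    assert hist.sum().sum() == len(feats)


def test_model_roundtrip(tmp_path, two_family_features):
    feats, _ = two_family_features
    model = fit_boundary_types(feats, n_types=3, seed=1)
    model.save(tmp_path / "model.json")
    loaded = BoundaryTyper.load(tmp_path / "model.json")
    assert np.array_equal(model.predict(feats), loaded.predict(feats))


def test_knn_trivial_and_separable_cases(two_family_features):
    hist = pd.DataFrame(np.eye(4), columns=list("abcd"))
    preds, acc, conf = knn_classify(hist, ["x", "x", "x", "x"], k=3)
    assert acc == 1.0

    feats, labels = two_family_features
    model = fit_boundary_types(feats, n_types=4, seed=0)
    h = model.transform(feats)
    y = labels.loc[h.index].to_numpy()
    preds, acc, conf = knn_classify(h, y, k=3)
    assert acc == 1.0
    assert conf.loc["disk", "disk"] == 8 and conf.loc["mesh", "mesh"] == 8


def test_knn_rejects_too_large_k():
    hist = pd.DataFrame(np.eye(3))
    with pytest.raises(ValueError):
        knn_classify(hist, ["a", "b", "a"], k=3)


def test_pca_properties(two_family_features):
    feats, labels = two_family_features
    hist = fit_boundary_types(feats, n_types=4, seed=0).transform(feats)
    scores, ev, p = pca_embed(hist)
    assert np.all(np.diff(ev) <= 1e-12)
    X = np.asarray(hist, float)
    recon = scores.to_numpy() @ p.components_ + X.mean(axis=0)
    assert np.max(np.abs(recon - X)) < 1e-10
    # families separate along the leading components
    from sklearn.metrics import silhouette_score

    lab = labels.loc[hist.index].to_numpy()
    assert silhouette_score(scores.to_numpy()[:, :2], lab) > 0.5


def test_exact_linear_targets_interpolated():
    rng = np.random.default_rng(5)
    H = rng.integers(0, 20, size=(30, 6)).astype(float)
    coef = rng.normal(size=(6, 2))
    Y = np.exp(H @ coef * 0.05)  # log(Y) exactly linear in counts
    reg = HistogramRegressor().fit(H, Y)
    pred = reg.predict(H)
    assert np.max(np.abs(pred - np.log(Y))) < 1e-8


def test_regressor_rejects_nonpositive_targets_and_rank_deficiency():
    H = np.ones((4, 6))
    with pytest.raises(ValueError, match="positive"):
        HistogramRegressor().fit(H, np.array([-1.0, 1, 1, 1]))
    with pytest.raises(ValueError, match="rank"):
        HistogramRegressor().fit(H, np.ones(4))
    HistogramRegressor(ridge_alpha=1.0).fit(H, np.ones(4))  # ridge fallback works


def test_select_num_types(two_family_features):
    feats, labels = two_family_features
    assert select_num_types(feats, [12], criterion="knn_accuracy", labels=labels) == 12
    lab = labels
    n = select_num_types(
        feats, [2, 3, 6], criterion="knn_accuracy", labels=lab, seed=0
    )
    assert n in (2, 3, 6)
    # chosen N maximizes the LOO accuracy among the candidates
    accs = {}
    for cand in (2, 3, 6):
        h = fit_boundary_types(feats, n_types=cand, seed=0).transform(feats)
        _, acc, _ = knn_classify(h, lab.loc[h.index].to_numpy(), k=3)
        accs[cand] = acc
    best = max(accs.values())
    assert accs[n] == best
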