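"""Boundary typing and image-level analyses.

Boundaries from an image set are clustered in the 40-metric feature space
("boundary types", k-means on robustly standardized features); counting
the types per image gives a bag-of-boundary-types histogram that serves as
the per-image descriptor for classification (leave-one-out k-NN),
embedding (PCA) and regression of generative parameters (per-target least
squares on the histogram counts, log-transformed targets).

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``transform``, fitted attributes with trailing underscores) and compose
with sklearn model selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin, RegressorMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, Ridge

from .profiles import FEATURE_NAMES, N_FEATURES

__all__ = [
    "BoundaryTyper",
    "HistogramRegressor",
    "fit_boundary_types",
    "image_histograms",
    "select_num_types",
    "pca_embed",
    "knn_classify",
    "fit_param_regression",
    "feature_columns",
]


def feature_columns(use_in: bool = True, use_out: bool = True) -> list[str]:
    """Feature-name subset for the in-/out-graph ablation flags."""
    cols = []
    if use_in:
        cols += [n for n in FEATURE_NAMES if n.startswith("in_")]
    if use_out:
        cols += [n for n in FEATURE_NAMES if n.startswith("out_")]
    if not cols:
        raise ValueError("at least one of use_in/use_out must be set")
    return cols


class BoundaryTyper(ClusterMixin, BaseEstimator):
    """K-means boundary types over robustly standardized metrics.

    Features are centred by the median, scaled by the interquartile range
    (zero-IQR features dropped) and winsorized at ``clip`` scaled units
    before seeded k-means with multiple restarts.  The winsorization
    matters: higher-moment and area metrics have tails hundreds of IQRs
    long, and without it a handful of extreme boundaries capture whole
    clusters while structurally distinct small boundaries collapse into
    one.  ``predict`` assigns the nearest centroid in the standardized
    space, ties broken by the lowest type index (k-means' argmin over
    squared distances already picks the first minimum).

    Parameters
    ----------
    n_types : number of boundary types (clusters).
    n_restarts : k-means restarts (best inertia wins).
    random_state : seed for k-means++ initialisation.
    clip : winsorization bound in robust-scaled units.
    use_in, use_out : restrict to the in-/out-graph metric block
        (the out-graph ablation of the pipeline stability analysis).
    """

    def __init__(
        self,
        n_types: int = 12,
        n_restarts: int = 10,
        random_state: int = 0,
        clip: float = 3.0,
        use_in: bool = True,
        use_out: bool = True,
    ):
        self.n_types = n_types
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.clip = clip
        self.use_in = use_in
        self.use_out = use_out

    # -- helpers -----------------------------------------------------------

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[feature_columns(self.use_in, self.use_out)].to_numpy(float)
        else:
            X = np.asarray(X, float)
            full = len(feature_columns(self.use_in, self.use_out))
            if X.shape[1] == N_FEATURES and full != N_FEATURES:
                names = np.array(FEATURE_NAMES)
                keep = np.isin(names, feature_columns(self.use_in, self.use_out))
                X = X[:, keep]
            elif X.shape[1] != full:
                raise ValueError(
                    f"expected {full} (or {N_FEATURES}) features, got {X.shape[1]}"
                )
        return X

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.keep_] - self.center_[self.keep_]) / self.scale_[self.keep_]
        if self.clip:
            Z = np.clip(Z, -self.clip, self.clip)
        return Z

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None) -> "BoundaryTyper":
        X = self._matrix(X)
        if len(X) < self.n_types:
            raise ValueError(
                f"need at least n_types={self.n_types} boundaries, got {len(X)}"
            )
        self.center_ = np.median(X, axis=0)
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        self.scale_ = q75 - q25
        self.keep_ = self.scale_ > 0
        if not self.keep_.any():  # all-constant features: degenerate but legal
            self.keep_ = np.ones(X.shape[1], bool)
            self.scale_ = np.ones(X.shape[1])
        self.kmeans_ = KMeans(
            n_clusters=self.n_types,
            n_init=self.n_restarts,
            random_state=self.random_state,
        ).fit(self._standardize(X))
        self.centroids_ = self.kmeans_.cluster_centers_
        self.labels_ = self.kmeans_.labels_
        return self

    def predict(self, X) -> np.ndarray:
        return self.kmeans_.predict(self._standardize(self._matrix(X)))

    def transform(self, features: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
        """Per-image boundary-type histograms (rows: image_id)."""
        types = self.predict(features)
        ids = (
            features["image_id"].to_numpy()
            if isinstance(features, pd.DataFrame) and "image_id" in features
            else np.zeros(len(types), int)
        )
        out = {}
        for img in pd.unique(ids):
            m = ids == img
            out[img] = np.bincount(types[m], minlength=self.n_types)
        hist = pd.DataFrame.from_dict(
            out, orient="index", columns=[f"type_{k+1}" for k in range(self.n_types)]
        )
        hist.index.name = "image_id"
        if normalize:
            hist = hist.div(hist.sum(axis=1), axis=0)
        return hist

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        blob = {
            "format": "voromorph-boundary-typer/1",
            "params": self.get_params(),
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "keep": self.keep_.tolist(),
            "centroids": self.centroids_.tolist(),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "BoundaryTyper":
        blob = json.loads(Path(path).read_text())
        model = cls(**blob["params"])
        model.center_ = np.array(blob["center"])
        model.scale_ = np.array(blob["scale"])
        model.keep_ = np.array(blob["keep"], bool)
        model.centroids_ = np.array(blob["centroids"])
        km = KMeans(n_clusters=model.n_types, n_init=1)
        km.cluster_centers_ = model.centroids_
        km._n_threads = 1
        km.labels_ = np.zeros(len(model.centroids_), dtype=np.int32)
        model.kmeans_ = km
        return model


def fit_boundary_types(
    features, n_types: int = 12, seed: int = 0, **kw
) -> BoundaryTyper:
    return BoundaryTyper(n_types=n_types, random_state=seed, **kw).fit(features)


def image_histograms(
    model: BoundaryTyper, features: pd.DataFrame, normalize: bool = False
) -> pd.DataFrame:
    return model.transform(features, normalize=normalize)


def knn_classify(
    histograms: pd.DataFrame, labels, k: int = 3
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Leave-one-out k-NN on histogram rows (Euclidean).

    Majority vote; ties broken by the nearest single neighbour.  Returns
    (predictions, accuracy, confusion table).
    """
    X = np.asarray(histograms, float)
    y = np.asarray(labels)
    n = len(X)
    if k >= n:
        raise ValueError(f"k={k} needs at least {k + 1} images")
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    preds = []
    for i in range(n):
        nb = np.argsort(d[i], kind="stable")[:k]
        votes = pd.Series(y[nb]).value_counts()
        top = votes[votes == votes.iloc[0]].index
        if len(top) == 1:
            preds.append(top[0])
        else:  # tie: nearest neighbour among tied classes
            for j in nb:
                if y[j] in set(top):
                    preds.append(y[j])
                    break
    preds = np.array(preds)
    acc = float(np.mean(preds == y))
    classes = sorted(pd.unique(y))
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y, preds):
        conf.loc[t, p] += 1
    return preds, acc, conf


def pca_embed(histograms: pd.DataFrame, n_components: int | None = None):
    """Centred PCA of the per-image histograms.

    Returns (scores DataFrame, explained variance array, fitted PCA).
    """
    X = np.asarray(histograms, float)
    if len(X) < 2:
        raise ValueError("PCA needs at least two images")
    n_components = n_components or min(X.shape)
    p = PCA(n_components=n_components)
    scores = p.fit_transform(X)
    cols = [f"pc{i+1}" for i in range(scores.shape[1])]
    idx = histograms.index if isinstance(histograms, pd.DataFrame) else None
    return pd.DataFrame(scores, columns=cols, index=idx), p.explained_variance_, p


class HistogramRegressor(RegressorMixin, BaseEstimator):
    """Per-target linear regression of (log-transformed) generative
    parameters on boundary-type histogram counts.

    Ordinary least squares by default; ``ridge_alpha > 0`` switches to
    ridge regression for rank-deficient designs.  ``log_targets`` applies
    ``log`` to the targets before fitting (and keeps predictions on the
    log scale, matching how the recovery error is reported).
    """

    def __init__(self, log_targets: bool = True, ridge_alpha: float = 0.0):
        self.log_targets = log_targets
        self.ridge_alpha = ridge_alpha

    def _prep_y(self, y) -> np.ndarray:
        y = np.asarray(y, float)
        if y.ndim == 1:
            y = y[:, None]
        if self.log_targets:
            if np.any(y <= 0):
                raise ValueError("log-transformed targets must be positive")
            y = np.log(y)
        return y

    def fit(self, X, y) -> "HistogramRegressor":
        X = np.asarray(X, float)
        Y = self._prep_y(y)
        if self.ridge_alpha > 0:
            self.model_ = Ridge(alpha=self.ridge_alpha).fit(X, Y)
        else:
            if len(X) <= X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(
                    "rank-deficient design; use ridge_alpha > 0 or more images"
                )
            self.model_ = LinearRegression().fit(X, Y)
        self.n_targets_ = Y.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, float))

    def score_loo(self, X, y) -> pd.DataFrame:
        """Leave-one-out recovery: MAE and Pearson r per target (log scale)."""
        X = np.asarray(X, float)
        Y = self._prep_y(y)
        n = len(X)
        preds = np.empty_like(Y)
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            sub = HistogramRegressor(log_targets=False, ridge_alpha=self.ridge_alpha)
            sub.fit(X[m], Y[m])
            preds[i] = sub.predict(X[i : i + 1])[0]
        rows = []
        for t in range(Y.shape[1]):
            mae = float(np.mean(np.abs(preds[:, t] - Y[:, t])))
            r = float(pearsonr(preds[:, t], Y[:, t]).statistic)
            rows.append({"target": t, "mae": mae, "pearson_r": r})
        return pd.DataFrame(rows)


def fit_param_regression(histograms, targets, **kw) -> HistogramRegressor:
    return HistogramRegressor(**kw).fit(np.asarray(histograms, float), targets)


def select_num_types(
    features: pd.DataFrame,
    candidate_ns,
    criterion: str = "knn_accuracy",
    seed: int = 0,
    labels=None,
    targets=None,
    k: int = 3,
) -> int:
    """Pick the number of boundary types by downstream performance.

    ``knn_accuracy``: leave-one-out 3-NN accuracy on per-image labels;
    ``regression_cv``: mean leave-one-out MAE of the parameter regression.
    Ties go to the smallest candidate.
    """
    candidate_ns = sorted(set(int(n) for n in candidate_ns))
    if len(candidate_ns) == 1:
        return candidate_ns[0]
    if criterion == "knn_accuracy" and labels is None:
        raise ValueError("knn_accuracy criterion needs per-image labels")
    if criterion == "regression_cv" and targets is None:
        raise ValueError("regression_cv criterion needs per-image targets")
    best_n, best_score = None, None
    for n in candidate_ns:
        model = fit_boundary_types(features, n_types=n, seed=seed)
        hist = model.transform(features)
        if criterion == "knn_accuracy":
            lab = labels.loc[hist.index] if hasattr(labels, "loc") else labels
            _, acc, _ = knn_classify(hist, np.asarray(lab), k=k)
            score = acc
        elif criterion == "regression_cv":
            tg = targets.loc[hist.index] if hasattr(targets, "loc") else targets
            rep = HistogramRegressor().fit(hist, tg).score_loo(hist, tg)
            score = -float(rep["mae"].mean())
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best_score is None or score > best_score:
            best_n, best_score = n, score
    return best_n
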