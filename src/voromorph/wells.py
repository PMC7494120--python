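"""Per-well aggregation of per-cell graph metrics and held-out-plate
classification.

For screens where each cell is an individually segmented object (label
images), the per-cell 40-metric vectors are reduced per well: the
exterior/interior flag is dropped (19 metrics per side remain) and the
mean and standard deviation across the cells of the well are concatenated,
4 * 19 = 76 values per well.  Well vectors are normalized by subtracting
the per-plate median of the control wells, and treatment classes are
predicted with a decision tree trained with each plate held out in turn;
performance is reported as per-class precision/recall/F1
(F1 = 2 P R / (P + R)) and their unweighted mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier

from .profiles import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "WELL_FEATURE_NAMES",
    "aggregate_well",
    "aggregate_wells",
    "normalize_to_controls",
    "holdout_plate_classify",
    "PlateClassifier",
    "f1_report",
]

# Table-order per-cell metrics without the exterior/interior flag
CELL_METRIC_NAMES = [n for n in FEATURE_NAMES if not n.endswith("exterior_flag")]
WELL_FEATURE_NAMES = [f"mean_{n}" for n in CELL_METRIC_NAMES] + [
    f"std_{n}" for n in CELL_METRIC_NAMES
]  # 76


def aggregate_well(cell_features) -> np.ndarray:
    """Mean and standard deviation of the per-cell metrics of one well.

    ``cell_features``: DataFrame with the 40 metric columns (extra columns
    ignored) or an array of 40-vectors; returns the 76-vector
    (means then stds, in-graph block before out-graph, table row order).
    """
    if isinstance(cell_features, pd.DataFrame):
        X = cell_features[CELL_METRIC_NAMES].to_numpy(float)
    else:
        X = np.asarray(cell_features, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] == len(FEATURE_NAMES):
            keep = [i for i, n in enumerate(FEATURE_NAMES) if not n.endswith("exterior_flag")]
            X = X[:, keep]
        elif X.shape[1] != len(CELL_METRIC_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} or {len(CELL_METRIC_NAMES)} metrics"
            )
    if len(X) == 0:
        raise ValueError("empty well")
    return np.concatenate([X.mean(axis=0), X.std(axis=0)])


def aggregate_wells(cell_features: pd.DataFrame, well_col: str = "well_id") -> pd.DataFrame:
    """Aggregate a per-cell feature table into one row per well."""
    rows = {}
    for well, grp in cell_features.groupby(well_col, sort=True):
        rows[well] = aggregate_well(grp)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=WELL_FEATURE_NAMES)
    out.index.name = well_col
    return out


def normalize_to_controls(wells: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-plate control-well median feature vector.

    ``layout``: DataFrame indexed (or keyed) by well_id with columns
    plate_id, treatment_class (or class), is_control.
    """
    lay = layout.set_index("well_id") if "well_id" in layout.columns else layout
    cls_col = "treatment_class" if "treatment_class" in lay.columns else "class"
    feats = wells.select_dtypes(include=[np.number])
    out = feats.copy()
    for plate, grp in lay.groupby("plate_id"):
        plate_wells = [w for w in grp.index if w in feats.index]
        controls = [w for w in plate_wells if bool(grp.loc[w, "is_control"])]
        if not controls:
            raise ValueError(f"plate {plate!r} has no control wells")
        med = feats.loc[controls].median(axis=0)
        out.loc[plate_wells] = feats.loc[plate_wells] - med
    _ = cls_col
    return out


def f1_report(y_true, y_pred) -> pd.DataFrame:
    """Per-class precision, recall and F1 = 2PR/(P+R), plus the macro mean."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = sorted(set(y_true))
    rows = []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append({"class": c, "precision": prec, "recall": rec, "f1": f1})
    rep = pd.DataFrame(rows).set_index("class")
    rep.loc["macro_mean"] = rep.mean(axis=0)
    return rep


class PlateClassifier(BaseEstimator):
    """Leave-one-plate-out decision-tree classification of well vectors.

    A seeded CART tree (Gini impurity, depth-unlimited by default) is
    trained on all wells outside the held-out plate; pooled held-out
    predictions give the confusion table and F1 report.
    """

    def __init__(self, random_state: int = 0, max_depth: int | None = None):
        self.random_state = random_state
        self.max_depth = max_depth

    def evaluate(
        self, wells: pd.DataFrame, layout: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
        lay = layout.set_index("well_id") if "well_id" in layout.columns else layout
        cls_col = "treatment_class" if "treatment_class" in lay.columns else "class"
        common = [w for w in wells.index if w in lay.index]
        X = wells.loc[common].to_numpy(float)
        y = lay.loc[common, cls_col].to_numpy()
        plates = lay.loc[common, "plate_id"].to_numpy()
        uniq = sorted(set(plates))
        if len(uniq) < 2:
            raise ValueError("need at least two plates for held-out evaluation")
        if len(set(y)) < 2:
            raise ValueError("need at least two treatment classes")
        preds = np.empty(len(y), dtype=object)
        for plate in uniq:
            hold = plates == plate
            train_y = y[~hold]
            missing = set(y[hold]) - set(train_y)
            if missing:
                logger.warning(
                    "classes %s absent from training folds for plate %r",
                    sorted(missing),
                    plate,
                )
            tree = DecisionTreeClassifier(
                random_state=self.random_state, max_depth=self.max_depth
            )
            tree.fit(X[~hold], train_y)
            preds[hold] = tree.predict(X[hold])
        rep = f1_report(y, preds)
        classes = sorted(set(y) | set(preds))
        conf = pd.DataFrame(0, index=classes, columns=classes)
        for t, p in zip(y, preds):
            conf.loc[t, p] += 1
        self.report_ = rep
        self.confusion_ = conf
        return rep, conf, preds


def holdout_plate_classify(
    wells: pd.DataFrame,
    layout: pd.DataFrame,
    random_state: int = 0,
    max_depth: int | None = None,
):
    """Functional wrapper: returns (f1 report, confusion table, predictions)."""
    return PlateClassifier(random_state=random_state, max_depth=max_depth).evaluate(
        wells, layout
    )
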