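"""Well aggregation, plate normalization and held-out-plate F1."""

import numpy as np
import pandas as pd
import pytest

from voromorph.profiles import FEATURE_NAMES
from voromorph.wells import (
    WELL_FEATURE_NAMES,
    aggregate_well,
    aggregate_wells,
    f1_report,
    holdout_plate_classify,
    normalize_to_controls,
)


def _cells(n, rng):
    return pd.DataFrame(rng.normal(size=(n, 40)), columns=FEATURE_NAMES)


def test_vector_length_is_76():
    rng = np.random.default_rng(0)
    w = aggregate_well(_cells(5, rng))
    assert len(w) == len(WELL_FEATURE_NAMES) == 76


def test_identical_cells_have_zero_std():
    rng = np.random.default_rng(1)
    one = _cells(1, rng)
    well = pd.concat([one] * 4, ignore_index=True)
    w = aggregate_well(well)
    assert np.allclose(w[:38], one.drop(columns=[c for c in one if c.endswith("exterior_flag")]).to_numpy()[0])
    assert np.allclose(w[38:], 0.0)


def test_antisymmetric_cells_have_zero_mean_and_permutation_invariance():
    rng = np.random.default_rng(2)
    m = _cells(1, rng)
    well = pd.concat([m, -m], ignore_index=True)
    w = aggregate_well(well)
    assert np.allclose(w[:38], 0.0)
    perm = aggregate_well(well.iloc[::-1])
    assert np.allclose(w, perm)


def test_empty_well_rejected():
    with pytest.raises(ValueError, match="empty"):
        aggregate_well(np.empty((0, 40)))


def _toy_plate_data(rng, n_plates=4, wells_per_class=3, shift=0.0):
    rows, layout = [], []
    for p in range(n_plates):
        offset = rng.normal(scale=2.0, size=76)  # plate batch effect
        for cls, mu in (("ctrl", 0.0), ("A", 4.0), ("B", -4.0)):
            for k in range(wells_per_class):
                wid = f"p{p}_w{cls}{k}"
                vec = mu + offset + rng.normal(scale=0.3, size=76) + shift
                rows.append(pd.Series(vec, index=WELL_FEATURE_NAMES, name=wid))
                layout.append(
                    {
                        "well_id": wid,
                        "plate_id": f"p{p}",
                        "treatment_class": cls,
                        "is_control": cls == "ctrl",
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(layout)


def test_normalize_to_controls_properties():
    rng = np.random.default_rng(3)
    wells, layout = _toy_plate_data(rng)
    norm = normalize_to_controls(wells, layout)
    lay = layout.set_index("well_id")
    for p, grp in lay.groupby("plate_id"):
        ctrl = [w for w in grp.index if grp.loc[w, "is_control"]]
        assert np.allclose(norm.loc[ctrl].median(axis=0), 0.0)
    # translation invariance per plate, independence across plates
    shifted = wells.copy()
    p0 = [w for w in lay.index if lay.loc[w, "plate_id"] == "p0"]
    shifted.loc[p0] += 123.0
    norm2 = normalize_to_controls(shifted, layout)
    pd.testing.assert_frame_equal(norm, norm2)

    bad = layout.copy()
    bad.loc[bad.plate_id == "p0", "is_control"] = False
    with pytest.raises(ValueError, match="control"):
        normalize_to_controls(wells, bad)


def test_f1_matches_hand_computed_contingency():
    # 3-class toy confusion: a: tp=2 fp=1 fn=0; b: tp=1 fp=0 fn=1; c: tp=1 fp=1 fn=1
    y_true = ["a", "a", "b", "b", "c", "c"]
    y_pred = ["a", "a", "a", "b", "c", "b"]
    rep = f1_report(y_true, y_pred)
    assert rep.loc["a", "precision"] == pytest.approx(2 / 3)
    assert rep.loc["a", "recall"] == pytest.approx(1.0)
    assert rep.loc["a", "f1"] == pytest.approx(2 * (2 / 3) * 1 / (2 / 3 + 1))
    assert rep.loc["b", "f1"] == pytest.approx(2 * (1 / 2) * (1 / 2))
    # precision 0.5, recall 1 -> F1 = 2/3 (printed formula)
    rep2 = f1_report(["x", "y"], ["x", "x"])
    assert rep2.loc["x", "f1"] == pytest.approx(2 / 3)
    assert rep.loc["macro_mean", "f1"] == pytest.approx(
        np.mean([rep.loc[c, "f1"] for c in "abc"])
    )


def test_holdout_plate_classification_separates_toy_classes():
    rng = np.random.default_rng(4)
    wells, layout = _toy_plate_data(rng)
    norm = normalize_to_controls(wells, layout)
    rep, conf, preds = holdout_plate_classify(norm, layout, random_state=0)
    assert rep.loc["macro_mean", "f1"] == 1.0
    assert conf.to_numpy().sum() == len(wells)
    # deterministic under a fixed tree seed
    rep2, _, preds2 = holdout_plate_classify(norm, layout, random_state=0)
    assert np.array_equal(preds, preds2)
    pd.testing.assert_frame_equal(rep, rep2)


def test_aggregate_wells_from_cell_table():
    rng = np.random.default_rng(5)
    cells = _cells(12, rng)
    cells["well_id"] = ["w1"] * 5 + ["w2"] * 7
    wells = aggregate_wells(cells)
    assert wells.shape == (2, 76)
    assert np.allclose(
        wells.loc["w1"], aggregate_well(cells[cells.well_id == "w1"])
    )
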