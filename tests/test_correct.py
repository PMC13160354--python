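"""Tissue correction: z-scoring, residualization, separation diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmark import correct, simulate


def _frame(values, tissues):
    idx = pd.Index([f"c{i}" for i in range(len(values))], name="cell_line_id")
    x = pd.DataFrame({"g": values}, index=idx)
    t = pd.Series(tissues, index=idx)
    return x, t


def test_symmetric_triple_standardizes_to_unit_steps():
    x, t = _frame([1.0, 2.0, 3.0], ["A", "A", "A"])
    cm = correct.zscore_by_tissue(x, t)
    assert np.allclose(cm.values["g"], [-1.0, 0.0, 1.0])


def test_constant_stratum_zero_filled_and_recorded():
    x, t = _frame([5.0, 5.0, 5.0, 1.0, 2.0], ["A", "A", "A", "B", "B"])
    cm = correct.zscore_by_tissue(x, t)
    assert np.allclose(cm.values["g"].iloc[:3], 0.0)
    assert ("A", "g") in cm.degenerate_strata
    assert ("B", "g") not in cm.degenerate_strata


def test_zscore_strata_recomputed_independently():
    rng = np.random.default_rng(0)
    idx = pd.Index([f"c{i}" for i in range(12)])
    x = pd.DataFrame(rng.normal(size=(12, 5)), index=idx, columns=list("abcde"))
    t = pd.Series(["T1"] * 6 + ["T2"] * 6, index=idx)
    cm = correct.zscore_by_tissue(x, t)
    for tissue in ("T1", "T2"):
        sub = cm.values[t == tissue]
        assert np.abs(sub.mean(axis=0)).max() < 1e-10
        assert np.abs(sub.std(axis=0, ddof=1) - 1).max() < 1e-10


def test_zscore_idempotent():
    rng = np.random.default_rng(1)
    idx = pd.Index([f"c{i}" for i in range(20)])
    x = pd.DataFrame(rng.normal(size=(20, 4)), index=idx, columns=list("wxyz"))
    t = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
    once = correct.zscore_by_tissue(x, t).values
    twice = correct.zscore_by_tissue(once, t).values
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)


def test_unknown_sample_in_mapping_errors():
    x, t = _frame([1.0, 2.0], ["A", "A"])
    with pytest.raises(correct.TissueMappingError):
        correct.zscore_by_tissue(x, t.iloc[:1])


def test_residuals_equal_group_mean_subtraction_oracle():
    rng = np.random.default_rng(2)
    idx = pd.Index([f"c{i}" for i in range(15)])
    x = pd.DataFrame(rng.normal(size=(15, 3)), index=idx, columns=list("abc"))
    t = pd.Series(["A"] * 5 + ["B"] * 5 + ["C"] * 5, index=idx)
    cm = correct.residual_correct(x, t)
    # least-squares oracle on tissue indicator variables
    design = pd.get_dummies(t).to_numpy(float)
    for col in x.columns:
        beta, *_ = np.linalg.lstsq(design, x[col].to_numpy(), rcond=None)
        resid = x[col].to_numpy() - design @ beta
        assert np.allclose(cm.values[col].to_numpy(), resid, atol=1e-10)


def test_residuals_of_centered_data_are_identity():
    rng = np.random.default_rng(3)
    idx = pd.Index([f"c{i}" for i in range(8)])
    raw = rng.normal(size=(8, 2))
    t = pd.Series(["A"] * 4 + ["B"] * 4, index=idx)
    x = pd.DataFrame(raw, index=idx, columns=["g1", "g2"])
    x = x - x.groupby(t).transform("mean")  # zero tissue means by construction
    cm = correct.residual_correct(x, t)
    assert np.allclose(cm.values.to_numpy(), x.to_numpy(), atol=1e-12)


def test_residual_repeats_are_a_noop():
    x, t = _frame([1.0, 2.0, 3.0, 7.0, 9.0], ["A", "A", "A", "B", "B"])
    one = correct.residual_correct(x, t, repeats=1).values
    ten = correct.residual_correct(x, t, repeats=10).values
    pd.testing.assert_frame_equal(one, ten)


def test_residual_group_means_are_zero():
    rng = np.random.default_rng(4)
    idx = pd.Index([f"c{i}" for i in range(30)])
    x = pd.DataFrame(rng.normal(loc=5, size=(30, 6)), index=idx)
    t = pd.Series(np.repeat(["A", "B", "C"], 10), index=idx)
    cm = correct.residual_correct(x, t)
    gm = cm.values.groupby(t).mean()
    assert np.abs(gm.to_numpy()).max() < 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_zscore_property_all_strata_unit_scale(seed):
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(3, 8))
    n_b = int(rng.integers(3, 8))
    idx = pd.Index([f"c{i}" for i in range(n_a + n_b)])
    x = pd.DataFrame(rng.normal(size=(n_a + n_b, 3)), index=idx, columns=list("pqr"))
    t = pd.Series(["A"] * n_a + ["B"] * n_b, index=idx)
    cm = correct.zscore_by_tissue(x, t)
    for _, sub in cm.values.groupby(t):
        assert np.abs(sub.mean(axis=0)).max() < 1e-10
        assert np.abs(sub.std(axis=0, ddof=1) - 1).max() < 1e-10


def test_separation_score_on_separated_blobs_is_high():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 0.1, size=(15, 10))
    b = rng.normal(5, 0.1, size=(15, 10))
    idx = pd.Index([f"c{i}" for i in range(30)])
    x = pd.DataFrame(np.vstack([a, b]), index=idx)
    t = pd.Series(["A"] * 15 + ["B"] * 15, index=idx)
    assert correct.tissue_separation_score(x, t) > 0.9


def test_separation_score_near_zero_under_label_permutation():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 0.1, size=(15, 10))
    b = rng.normal(5, 0.1, size=(15, 10))
    idx = pd.Index([f"c{i}" for i in range(30)])
    x = pd.DataFrame(np.vstack([a, b]), index=idx)
    labels = np.array(["A"] * 15 + ["B"] * 15)
    scores = []
    for _ in range(100):
        t = pd.Series(rng.permutation(labels), index=idx)
        scores.append(correct.tissue_separation_score(x, t))
    assert abs(np.mean(scores)) < 0.1


def test_correction_reduces_separation_on_synthetic_screen():
    cfg = simulate.SimulationConfig(
        n_tissues=6, lines_per_tissue=12, n_genes=400, n_drugs=4, n_pathways=1, seed=8
    )
    ds, _ = simulate.simulate_screen(cfg)
    t = ds.tissue_map()
    raw = correct.tissue_separation_score(ds.expression, t)
    corrected = correct.tissue_separation_score(
        correct.zscore_by_tissue(ds.expression, t).values, t
    )
    assert raw > 0
    assert corrected < raw / 2


def test_separation_needs_two_tissues():
    x, t = _frame([1.0, 2.0, 3.0], ["A", "A", "A"])
    with pytest.raises(correct.TissueMappingError):
        correct.tissue_separation_score(x, t)
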