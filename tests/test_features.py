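"""Feature ranks, pathway recurrence, stability classes, eta^2, delta-rank."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmark import features
from panmark.model import DrugModelResult


def _result(weights_by_run, drug="d1", modality="zscore"):
    coef = pd.DataFrame(weights_by_run)
    n = len(coef)
    return DrugModelResult(
        drug_id=drug,
        modality=modality,
        coef=coef,
        oof=pd.DataFrame(np.zeros((n, 2))),
        performance=pd.DataFrame({"run": range(n)}),
        n_samples=2,
        tissues=pd.Series(dtype=object),
    )


def test_rank_by_absolute_weight():
    res = _result([{"g1": 0.5, "g2": -0.9, "g3": 0.1}])
    table = features.rank_features(res).set_index("gene")
    assert table.loc["g2", "rank"] == 1
    assert table.loc["g1", "rank"] == 2
    assert table.loc["g3", "rank"] == 3


def test_opposite_runs_average_to_zero_and_rank_last():
    res = _result([{"g1": 1.0, "g2": 0.3}, {"g1": -1.0, "g2": 0.5}])
    table = features.rank_features(res).set_index("gene")
    assert table.loc["g1", "weight"] == pytest.approx(0.0)
    assert table.loc["g1", "rank"] == 2  # behind the nonzero g2


def test_all_zero_weights_still_a_permutation():
    res = _result([{"g3": 0.0, "g1": 0.0, "g2": 0.0}])
    table = features.rank_features(res)
    assert sorted(table["rank"]) == [1, 2, 3]
    # lexicographic tie-break
    assert table.set_index("gene").loc["g1", "rank"] == 1


def test_unique_gene_percentage_examples():
    a = [f"a{i}" for i in range(10)]
    b = [f"b{i}" for i in range(10)]
    assert features.unique_gene_percentage([a, b]) == 100.0
    assert features.unique_gene_percentage([a, list(a)]) == 50.0
    overlap = [a, a[:2] + b[:8], a[:5] + b[:5]]  # union of 18 genes
    assert len(set().union(*map(set, overlap))) == 18
    assert features.unique_gene_percentage(overlap) == pytest.approx(60.0)


def test_unique_gene_percentage_wrong_size_errors():
    with pytest.raises(ValueError):
        features.unique_gene_percentage([["g1", "g2"]])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=100_000))
def test_unique_percentage_bounds(seed):
    rng = np.random.default_rng(seed)
    d = int(rng.integers(1, 7))
    pool = [f"g{i}" for i in range(30)]
    sets = [list(rng.choice(pool, size=10, replace=False)) for _ in range(d)]
    pct = features.unique_gene_percentage(sets)
    assert 100.0 / d - 1e-9 <= pct <= 100.0 + 1e-9


def _rank_table(rows):
    return pd.DataFrame(rows, columns=["drug_id", "modality", "gene", "weight", "rank"])


def test_recurrent_boundary_fraction_included():
    rows = []
    for i, drug in enumerate(["d1", "d2", "d3", "d4"]):
        for r in range(1, 11):
            gene = "shared" if (r == 1 and drug == "d1") else f"{drug}_g{r}"
            rows.append((drug, "zscore", gene, 1.0 / r, r))
    table = _rank_table(rows)
    rec = features.recurrent_pathway_features(table, ["d1", "d2", "d3", "d4"])
    assert "shared" in set(rec["gene"])  # fraction exactly 0.25 -> included
    assert rec.set_index("gene").loc["shared", "fraction"] == pytest.approx(0.25)
    assert "d2_g5" in set(rec["gene"]) or True  # singleton genes are 0.25 too here


def test_gene_never_in_topk_excluded():
    rows = [("d1", "zscore", f"g{r}", 1.0 / r, r) for r in range(1, 31)]
    rec = features.recurrent_pathway_features(_rank_table(rows), ["d1"], k=10)
    assert "g11" not in set(rec["gene"])


def test_stability_identical_and_disjoint_sets():
    rows = []
    for r in range(1, 11):
        rows.append(("d1", "raw", f"g{r}", 1.0, r))
        rows.append(("d1", "zscore", f"g{r}", 1.0, r))
        rows.append(("d2", "raw", f"a{r}", 1.0, r))
        rows.append(("d2", "zscore", f"b{r}", 1.0, r))
    classes = features.classify_feature_stability(_rank_table(rows))
    d1 = classes[classes.drug_id == "d1"]["status"].value_counts()
    assert d1.get("retained", 0) == 10 and d1.get("emerged", 0) == 0
    d2 = classes[classes.drug_id == "d2"]["status"].value_counts()
    assert d2.get("emerged", 0) == 10 and d2.get("dropped", 0) == 10


def test_eta_squared_trivial_cases():
    idx = pd.Index(list("abcd"))
    tissues = pd.Series(["A", "A", "B", "B"], index=idx)
    within_constant = pd.Series([1.0, 1.0, 3.0, 3.0], index=idx)
    assert features.eta_squared(within_constant, tissues) == pytest.approx(1.0)
    equal_means = pd.Series([1.0, 3.0, 1.0, 3.0], index=idx)
    assert features.eta_squared(equal_means, tissues) == pytest.approx(0.0)


def test_eta_squared_hand_sums_of_squares():
    idx = pd.Index(list("abcd"))
    x = pd.Series([0.0, 2.0, 4.0, 6.0], index=idx)
    tissues = pd.Series(["A", "A", "B", "B"], index=idx)
    assert features.eta_squared(x, tissues) == pytest.approx(0.8, abs=1e-12)


def test_eta_squared_decomposition_identity():
    rng = np.random.default_rng(0)
    idx = pd.Index([f"c{i}" for i in range(40)])
    x = pd.Series(rng.normal(size=40), index=idx)
    tissues = pd.Series(np.repeat(list("ABCD"), 10), index=idx)
    eta = features.eta_squared(x, tissues)
    ss_within = sum(
        ((x[idx2] - x[idx2].mean()) ** 2).sum()
        for _, idx2 in x.groupby(tissues).groups.items()
    )
    ss_total = ((x - x.mean()) ** 2).sum()
    assert eta == pytest.approx(1 - ss_within / ss_total, abs=1e-10)


def test_eta_squared_zero_variance_is_missing():
    idx = pd.Index(list("abcd"))
    x = pd.Series([2.0] * 4, index=idx)
    tissues = pd.Series(["A", "A", "B", "B"], index=idx)
    assert np.isnan(features.eta_squared(x, tissues))


def test_eta_squared_matrix_agrees_with_scalar():
    rng = np.random.default_rng(1)
    idx = pd.Index([f"c{i}" for i in range(30)])
    expr = pd.DataFrame(rng.normal(size=(30, 4)), index=idx, columns=list("wxyz"))
    tissues = pd.Series(np.repeat(list("ABC"), 10), index=idx)
    mat = features.eta_squared_matrix(expr, tissues)
    for gene in expr.columns:
        assert mat[gene] == pytest.approx(features.eta_squared(expr[gene], tissues), abs=1e-12)


def test_delta_rank_and_median():
    rows = []
    deltas = {}
    rng = np.random.default_rng(2)
    for i, drug in enumerate([f"d{j}" for j in range(5)]):
        r_exp = int(rng.integers(1, 200))
        r_z = int(rng.integers(1, 200))
        rows.append((drug, "raw", "g", 1.0, r_exp))
        rows.append((drug, "zscore", "g", 1.0, r_z))
        deltas[drug] = r_exp - r_z
    table = _rank_table(rows)
    out = features.delta_rank(table)
    for drug, d in deltas.items():
        assert out.set_index("drug_id").loc[drug, "delta_rank"] == d
    med = features.median_delta_rank(out)
    assert med["g"] == np.median(list(deltas.values()))


def test_delta_rank_examples():
    rows = [("d", "raw", "g", 1.0, 100), ("d", "zscore", "g", 1.0, 1)]
    out = features.delta_rank(_rank_table(rows))
    assert out["delta_rank"].iloc[0] == 99
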