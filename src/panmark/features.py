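"""Feature aggregation: gene ranks, pathway recurrence, stability, tissue attribution.

Per (drug, modality) the run-averaged weights ``w_bar_dg`` are ranked by
absolute value (rank 1 = largest). Pathway-level summaries use the top-10
genes of every informative drug model: the unique-gene percentage
``100 * n_unique / (10 * d_p)``, recurrent features (genes in the top 10 of at
least 25% of a pathway's drugs), retained/emerged classification across the
raw and corrected modalities, tissue attribution ``eta^2 = SS_between /
SS_total`` on uncorrected expression, and the rank shift
``delta_rank = rank_raw - rank_corrected`` (positive = improved after
correction).
"""

from __future__ import annotations

from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .correct import _tissue_series
from .model import DrugModelResult

STABILITY_CLASSES = ("retained", "emerged", "dropped")


def rank_features(result: DrugModelResult) -> pd.DataFrame:
    """Run-averaged weights and their absolute-value ranks for one drug model.

    Ties in |w_bar| are broken by gene identifier (lexicographic) so ranks are
    a deterministic permutation of 1..G.
    """
    w = result.mean_coef()
    order = sorted(w.index, key=lambda g: (-abs(w[g]), g))
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    return pd.DataFrame(
        {
            "drug_id": result.drug_id,
            "modality": result.modality,
            "gene": w.index,
            "weight": w.to_numpy(),
            "rank": rank.reindex(w.index).to_numpy(),
        }
    )


def build_rank_table(results: Iterable[DrugModelResult] | Mapping[str, DrugModelResult]) -> pd.DataFrame:
    """Concatenated rank table over many drug models."""
    if isinstance(results, Mapping):
        results = results.values()
    frames = [rank_features(r) for r in results]
    if not frames:
        return pd.DataFrame(columns=["drug_id", "modality", "gene", "weight", "rank"])
    return pd.concat(frames, ignore_index=True)


def top_k_genes(rank_table: pd.DataFrame, k: int = 10) -> dict[tuple[str, str], list[str]]:
    """(drug, modality) -> the k top-ranked genes, in rank order."""
    sub = rank_table[rank_table["rank"] <= k].sort_values("rank")
    return {
        key: list(group["gene"])
        for key, group in sub.groupby(["drug_id", "modality"], sort=True)
    }


def unique_gene_percentage(top_sets: Sequence[Collection[str]], k: int = 10) -> float:
    """100 * |union of top-k sets| / (k * number of drugs)."""
    if not top_sets:
        raise ValueError("need at least one top-k set")
    for s in top_sets:
        if len(s) != k:
            raise ValueError(f"every top set must have exactly {k} entries, got {len(s)}")
    union = set().union(*[set(s) for s in top_sets])
    return 100.0 * len(union) / (k * len(top_sets))


def pathway_unique_percentages(
    rank_table: pd.DataFrame,
    drugs: pd.DataFrame,
    modality: str,
    k: int = 10,
) -> pd.DataFrame:
    """Unique-gene percentage per pathway over the drugs present in the table."""
    pathway_of = drugs.set_index("drug_id")["pathway"]
    tops = top_k_genes(rank_table[rank_table["modality"] == modality], k)
    rows = []
    by_pathway: dict[str, list] = {}
    for (drug, _), genes in tops.items():
        pw = pathway_of.get(drug)
        if pw is not None:
            by_pathway.setdefault(pw, []).append(genes)
    for pw in sorted(by_pathway):
        sets = by_pathway[pw]
        rows.append(
            {"pathway": pw, "n_drugs": len(sets), "unique_pct": unique_gene_percentage(sets, k)}
        )
    return pd.DataFrame(rows, columns=["pathway", "n_drugs", "unique_pct"])


def recurrent_pathway_features(
    rank_table: pd.DataFrame,
    pathway_drugs: Sequence[str],
    min_fraction: float = 0.25,
    k: int = 10,
) -> pd.DataFrame:
    """Genes in the top-k of at least ``min_fraction`` of a pathway's drugs.

    ``rank_table`` must hold a single modality. Returns gene, appearance
    fraction (>= rule, so exactly min_fraction is included) and the mean rank
    among appearances.
    """
    drugs = [d for d in pathway_drugs if d in set(rank_table["drug_id"])]
    if not drugs:
        raise ValueError("pathway has no drug present in the rank table")
    sub = rank_table[rank_table["drug_id"].isin(drugs) & (rank_table["rank"] <= k)]
    rows = []
    for gene, group in sub.groupby("gene"):
        frac = group["drug_id"].nunique() / len(drugs)
        if frac >= min_fraction:
            rows.append({"gene": gene, "fraction": frac, "mean_rank": group["rank"].mean(),
                         "n_drugs": len(drugs)})
    out = pd.DataFrame(rows, columns=["gene", "fraction", "mean_rank", "n_drugs"])
    return out.sort_values(["fraction", "gene"], ascending=[False, True]).reset_index(drop=True)


def classify_feature_stability(
    rank_table: pd.DataFrame,
    raw_modality: str = "raw",
    corrected_modality: str = "zscore",
    k: int = 10,
) -> pd.DataFrame:
    """Per (drug, gene): retained / emerged / dropped across the two modalities.

    retained = in both top-k sets, emerged = corrected only, dropped = raw only
    (reported so proportions over the union are well defined). Drugs missing
    either modality are excluded.
    """
    tops = top_k_genes(rank_table, k)
    drugs = sorted(
        {d for d, m in tops if m == raw_modality} & {d for d, m in tops if m == corrected_modality}
    )
    rows = []
    for drug in drugs:
        raw = set(tops[(drug, raw_modality)])
        cor = set(tops[(drug, corrected_modality)])
        for gene in sorted(raw | cor):
            status = "retained" if gene in raw and gene in cor else ("emerged" if gene in cor else "dropped")
            rows.append({"drug_id": drug, "gene": gene, "status": status})
    return pd.DataFrame(rows, columns=["drug_id", "gene", "status"])


def stability_summary(classes: pd.DataFrame, drugs: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway mean retained/emerged/dropped proportions with model counts.

    Proportions are reported both over the union of the two top-k sets
    (columns ``*_pct_union``) and over the corrected top-k set alone
    (``*_pct_corrected``, where dropped genes do not enter).
    """
    pathway_of = drugs.set_index("drug_id")["pathway"]
    rows = []
    per_drug = []
    for drug, group in classes.groupby("drug_id"):
        counts = group["status"].value_counts()
        union = len(group)
        corrected = int(counts.get("retained", 0) + counts.get("emerged", 0))
        per_drug.append(
            {
                "drug_id": drug,
                "pathway": pathway_of.get(drug),
                "retained_pct_union": 100.0 * counts.get("retained", 0) / union,
                "emerged_pct_union": 100.0 * counts.get("emerged", 0) / union,
                "dropped_pct_union": 100.0 * counts.get("dropped", 0) / union,
                "retained_pct_corrected": 100.0 * counts.get("retained", 0) / corrected if corrected else np.nan,
                "emerged_pct_corrected": 100.0 * counts.get("emerged", 0) / corrected if corrected else np.nan,
            }
        )
    per_drug = pd.DataFrame(per_drug)
    for pw, group in per_drug.groupby("pathway"):
        row = {"pathway": pw, "n_models": len(group)}
        for col in group.columns:
            if col.endswith(("_union", "_corrected")):
                row[col] = group[col].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def eta_squared(x, tissues) -> float:
    """Tissue attribution of one gene: SS_between / SS_total.

    Computed on uncorrected expression; NaN when total variance is zero.
    """
    x = pd.Series(np.asarray(x, float)) if not isinstance(x, pd.Series) else x.astype(float)
    labels = _tissue_series(x.index, tissues) if isinstance(tissues, (pd.Series, Mapping)) else pd.Series(
        np.asarray(tissues), index=x.index
    )
    if labels.nunique() < 2:
        raise ValueError("eta squared needs at least 2 tissues")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0:
        return float("nan")
    means = x.groupby(labels).mean()
    sizes = x.groupby(labels).size()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    return ss_between / ss_total


def eta_squared_matrix(expression: pd.DataFrame, tissues) -> pd.Series:
    """Vectorized eta^2 per gene over an expression matrix."""
    labels = _tissue_series(expression.index, tissues)
    if labels.nunique() < 2:
        raise ValueError("eta squared needs at least 2 tissues")
    grand = expression.mean(axis=0)
    ss_total = ((expression - grand) ** 2).sum(axis=0)
    means = expression.groupby(labels).mean()
    sizes = expression.groupby(labels).size()
    ss_between = (means.sub(grand, axis=1) ** 2).mul(sizes, axis=0).sum(axis=0)
    out = ss_between / ss_total
    out[ss_total == 0] = np.nan
    return out


def delta_rank(
    rank_table: pd.DataFrame,
    raw_modality: str = "raw",
    corrected_modality: str = "zscore",
) -> pd.DataFrame:
    """delta_rank = rank_raw - rank_corrected per (drug, gene); positive = improved."""
    raw = rank_table[rank_table["modality"] == raw_modality].set_index(["drug_id", "gene"])["rank"]
    cor = rank_table[rank_table["modality"] == corrected_modality].set_index(["drug_id", "gene"])["rank"]
    joined = pd.DataFrame({"rank_raw": raw, "rank_corrected": cor}).dropna()
    joined["delta_rank"] = joined["rank_raw"] - joined["rank_corrected"]
    return joined.reset_index()


def median_delta_rank(deltas: pd.DataFrame) -> pd.Series:
    """Per-gene median of delta_rank over drugs."""
    return deltas.groupby("gene")["delta_rank"].median()
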