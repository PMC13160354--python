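"""Cancer-type context mapping of candidate biomarkers.

Candidate (gene, drug) pairs are correlated within each cancer type using
UNCORRECTED expression against AUC -- the corrected matrices serve discovery,
but context-of-use is judged on the measured expression scale. Pearson and
Spearman coefficients are reported for every (gene, drug, cancer type) stratum
with at least ``min_n`` lines holding both values; p-values are adjusted with
Benjamini-Hochberg (one global family by default), and a heatmap-ready subset
keeps strata with >= 10 lines.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ScreenDataset

log = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_type_drug_gene_correlations(
    ds: ScreenDataset,
    genes: Sequence[str],
    drugs: Sequence[str],
    min_n: int = 3,
    adjust_family: str = "global",
) -> pd.DataFrame:
    """Per-cancer-type expression/AUC correlations for candidate pairs.

    ``adjust_family`` chooses the BH family: "global" adjusts all rows of this
    invocation together (default), "per_gene" adjusts within each gene.
    Zero-variance strata are skipped with a logged reason.
    """
    if adjust_family not in ("global", "per_gene"):
        raise ValueError("adjust_family must be 'global' or 'per_gene'")
    tissue = ds.tissue_map()
    obs = ds.observed_response()
    rows = []
    for drug in drugs:
        resp = obs[obs["drug_id"] == drug].set_index("cell_line_id")["auc"]
        resp = resp[resp.index.isin(ds.expression.index)]
        groups = resp.groupby(tissue.reindex(resp.index))
        for gene in genes:
            expr = ds.expression[gene]
            for cancer_type, idx in groups.groups.items():
                if len(idx) < min_n:
                    continue
                x = expr.loc[idx].to_numpy(float)
                y = resp.loc[idx].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    log.info("skipping degenerate stratum (%s, %s, %s)", gene, drug, cancer_type)
                    continue
                pr = stats.pearsonr(x, y)
                sr = stats.spearmanr(x, y)
                rows.append(
                    {"gene": gene, "drug_id": drug, "cancer_type": cancer_type, "n": len(idx),
                     "pearson_r": pr.statistic, "pearson_p": pr.pvalue,
                     "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue)}
                )
    table = pd.DataFrame(
        rows,
        columns=["gene", "drug_id", "cancer_type", "n", "pearson_r", "pearson_p",
                 "spearman_rho", "spearman_p"],
    )
    if len(table):
        if adjust_family == "global":
            table["padj_bh"] = bh_adjust(table["pearson_p"])
        else:
            table["padj_bh"] = table.groupby("gene")["pearson_p"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        table["heatmap"] = table["n"] >= 10
    else:
        table["padj_bh"] = []
        table["heatmap"] = []
    return table


def heatmap_matrix(table: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Pearson r by (gene|drug pair x cancer type), strata with n >= min_n.

    Rows and columns are sorted, so repeated runs produce identical layouts;
    combinations without a qualifying stratum are left missing.
    """
    sub = table[table["n"] >= min_n].copy()
    if sub.empty:
        return pd.DataFrame()
    sub["pair"] = sub["gene"] + "|" + sub["drug_id"]
    wide = sub.pivot_table(index="pair", columns="cancer_type", values="pearson_r", aggfunc="first")
    return wide.sort_index(axis=0).sort_index(axis=1)
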