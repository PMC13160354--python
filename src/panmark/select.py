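"""Shuffled-response null models and informative-model selection.

For each drug, the response vector is permuted across its screened cell lines
and the full cross-validated pipeline is refitted on each shuffle, giving a set
of null tissue-weighted correlations per drug. The pooled distribution of
per-drug null means defines the informative threshold

    theta = m0 + 3 * s0,

where ``s0`` is the pooled sample standard deviation (default) or the standard
error (config). A drug is informative in a modality iff its mean weighted
Pearson strictly exceeds theta; the overall flag is the union over modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import ConfigError, ScreenDataset
from .model import (
    DrugModelResult,
    ModelSpec,
    derive_seed,
    fisher_z_mean,
    fit_drug_model_run,
    prepare_modality,
    run_performance,
)

log = logging.getLogger(__name__)

SPREAD_POLICIES = ("sd", "sem")


def shuffle_response(y: pd.Series, seed: int) -> pd.Series:
    """Uniform random permutation of the response values over the same lines."""
    if len(y) == 0:
        raise ValueError("cannot shuffle an empty response vector")
    rng = np.random.default_rng(int(seed))
    return pd.Series(rng.permutation(y.to_numpy()), index=y.index, name=y.name)


@dataclass
class NullDistribution:
    """Per-drug null weighted-Pearson values for one modality."""

    modality: str
    values: pd.DataFrame  # drug_id, null_run, weighted_pearson

    def per_drug_mean(self) -> pd.Series:
        """Fisher-z mean of the null values per drug."""
        return self.values.groupby("drug_id")["weighted_pearson"].agg(fisher_z_mean)

    def pooled(self) -> np.ndarray:
        """Distribution of per-drug null means (NaN-free)."""
        means = self.per_drug_mean().to_numpy(float)
        return means[np.isfinite(means)]


def build_null_distribution(
    ds: ScreenDataset,
    modality: str,
    spec: ModelSpec,
    n_nulls: int = 10,
    matrix: pd.DataFrame | None = None,
) -> NullDistribution:
    """Refit the CV pipeline on shuffled responses, ``n_nulls`` times per drug."""
    if matrix is None:
        matrix = prepare_modality(ds, modality)
    tissues = ds.tissue_map()
    rows = []
    for di, drug in enumerate(sorted(ds.response["drug_id"].unique())):
        y = ds.drug_response(drug)
        y = y[y.index.isin(matrix.index)]
        if len(y) < spec.folds or y.nunique() < 2:
            log.info("null models: skipping drug %s (%d usable lines)", drug, len(y))
            continue
        X = matrix.loc[y.index]
        for k in range(n_nulls):
            y_null = shuffle_response(y, derive_seed(spec.seed, 2, di, k))
            res = fit_drug_model_run(X, y_null, spec, derive_seed(spec.seed, 3, di, k))
            _, pw = run_performance(y_null, res.oof, tissues)
            rows.append({"drug_id": drug, "null_run": k, "weighted_pearson": pw})
    return NullDistribution(
        modality=modality,
        values=pd.DataFrame(rows, columns=["drug_id", "null_run", "weighted_pearson"]),
    )


def threshold_stats(nd: NullDistribution, spread: str = "sd") -> dict:
    """Pooled mean, spread and threshold of a null distribution."""
    if spread not in SPREAD_POLICIES:
        raise ConfigError(f"spread must be one of {SPREAD_POLICIES}")
    pooled = nd.pooled()
    if pooled.size < 2:
        raise ValueError("pooled null distribution needs at least 2 drugs")
    m0 = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    s0 = sd if spread == "sd" else sd / np.sqrt(pooled.size)
    return {"modality": nd.modality, "m0": m0, "s0": s0, "policy": spread,
            "theta": m0 + 3.0 * s0, "n_drugs": int(pooled.size)}


def informative_threshold(nd: NullDistribution, spread: str = "sd") -> float:
    """theta = m0 + 3 * s0 over the pooled per-drug null means."""
    return threshold_stats(nd, spread)["theta"]


def select_informative_models(
    perf: pd.DataFrame,
    thresholds: Mapping[str, float],
    drugs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag drugs whose mean weighted Pearson strictly exceeds the threshold.

    ``perf`` is the summary table from :func:`panmark.model.summarize_performance`;
    ``thresholds`` maps modality -> theta. Returns one row per drug with
    nullable per-modality flags, the union flag, and the pathway annotation
    when a drug table is given. A drug missing in one modality keeps a missing
    flag there and contributes to the union through the others.
    """
    wide = perf.pivot_table(index="drug_id", columns="modality", values="weighted_pearson", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    for modality, theta in thresholds.items():
        col = wide[modality] if modality in wide.columns else pd.Series(np.nan, index=wide.index)
        flag = pd.array(col > theta, dtype="boolean")  # strict: p_w == theta is not informative
        flag[col.isna().to_numpy()] = pd.NA
        out[f"informative_{modality}"] = flag
    flag_cols = [c for c in out.columns if c.startswith("informative_")]
    out["informative"] = out[flag_cols].fillna(False).any(axis=1)
    if drugs is not None:
        out = out.join(drugs.set_index("drug_id")["pathway"], how="left")
    return out.reset_index()
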