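"""Tissue-of-origin correction of expression matrices.

Two corrections are provided, matching common practice for removing lineage
structure before pan-cancer modelling:

* within-tissue z-scoring: ``Z = (x - mu_i) / sigma_i`` per (tissue i, gene)
  stratum, with the sample (n-1) standard deviation;
* residual correction: residuals of a per-gene least-squares fit of expression
  on tissue indicator variables, which equals subtraction of the tissue mean.

Degenerate strata (single-sample tissue or zero spread) are zero-filled rather
than dropped, keeping the matrix shape stable across modalities; they are
recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


class TissueMappingError(ValueError):
    """A sample is missing from the tissue mapping, or a tissue is empty."""


@dataclass
class CorrectedMatrix:
    """Tissue-corrected expression with the per-stratum statistics behind it."""

    values: pd.DataFrame
    stats: pd.DataFrame  # tissue, gene, mu, sigma, degenerate
    method: str  # "zscore" | "residual"

    @property
    def degenerate_strata(self) -> list[tuple[str, str]]:
        deg = self.stats[self.stats["degenerate"]]
        return list(zip(deg["tissue"], deg["gene"]))

    def write(self, values_path, stats_path=None) -> None:
        self.values.to_csv(values_path, sep="\t")
        if stats_path is not None:
            self.stats.to_csv(stats_path, sep="\t", index=False)


def _tissue_series(index: pd.Index, tissues) -> pd.Series:
    if isinstance(tissues, Mapping):
        tissues = pd.Series(tissues)
    tissues = tissues.reindex(index)
    if tissues.isna().any():
        missing = list(index[tissues.isna()])[:5]
        raise TissueMappingError(f"samples without a tissue label: {missing}")
    return tissues.astype(str)


def zscore_by_tissue(x: pd.DataFrame, tissues) -> CorrectedMatrix:
    """Standardize every (tissue, gene) stratum to mean 0, sample SD 1.

    Strata with a single sample or zero spread are set to 0 and recorded as
    degenerate.
    """
    labels = _tissue_series(x.index, tissues)
    z = pd.DataFrame(np.zeros(x.shape), index=x.index, columns=x.columns)
    stats_rows = []
    for tissue, idx in x.groupby(labels, sort=True).groups.items():
        sub = x.loc[idx]
        mu = sub.mean(axis=0)
        sigma = sub.std(axis=0, ddof=1) if len(idx) > 1 else pd.Series(np.nan, index=x.columns)
        degenerate = sigma.isna() | (sigma == 0)
        scaled = (sub - mu).div(sigma.where(~degenerate, 1.0), axis=1)
        scaled.loc[:, degenerate] = 0.0
        z.loc[idx] = scaled
        stats_rows.append(
            pd.DataFrame(
                {"tissue": tissue, "gene": x.columns, "mu": mu.to_numpy(),
                 "sigma": sigma.to_numpy(), "degenerate": degenerate.to_numpy()}
            )
        )
    stats = pd.concat(stats_rows, ignore_index=True)
    return CorrectedMatrix(values=z, stats=stats, method="zscore")


def residual_correct(x: pd.DataFrame, tissues, repeats: int = 10) -> CorrectedMatrix:
    """Residuals of per-gene least squares of expression on tissue indicators.

    The projection equals per-tissue mean subtraction. The fit is deterministic,
    so the ``repeats`` averaging (kept for interface compatibility) returns the
    identical matrix for any ``repeats >= 1``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    labels = _tissue_series(x.index, tissues)
    mu = x.groupby(labels).transform("mean")
    residuals = x - mu
    stats_rows = []
    for tissue, idx in x.groupby(labels, sort=True).groups.items():
        sub = x.loc[idx]
        m = sub.mean(axis=0)
        sigma = sub.std(axis=0, ddof=1) if len(idx) > 1 else pd.Series(np.nan, index=x.columns)
        degenerate = (len(idx) == 1) | sigma.isna() | (sigma == 0)
        stats_rows.append(
            pd.DataFrame(
                {"tissue": tissue, "gene": x.columns, "mu": m.to_numpy(),
                 "sigma": sigma.to_numpy(), "degenerate": np.asarray(degenerate)}
            )
        )
    stats = pd.concat(stats_rows, ignore_index=True)
    return CorrectedMatrix(values=residuals, stats=stats, method="residual")


def tissue_separation_score(m: pd.DataFrame, tissues, n_components: int = 2) -> float:
    """Silhouette of the tissue labels in the top principal-component projection.

    Returns a value in [-1, 1]; higher means stronger tissue clustering. Used as
    the diagnostic that corrections are expected to reduce.
    """
    labels = _tissue_series(m.index, tissues)
    if labels.nunique() < 2:
        raise TissueMappingError("tissue separation needs at least 2 tissues")
    n_comp = min(n_components, m.shape[0] - 1, m.shape[1])
    proj = PCA(n_components=n_comp, random_state=0).fit_transform(m.to_numpy(float))
    return float(silhouette_score(proj, labels.to_numpy()))
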