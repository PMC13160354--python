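"""Per-drug penalized linear drug-response models with repeated cross-validation.

For each drug and input modality a linear model of AUC on gene expression is
fitted under k-fold cross-validation, repeated with distinct fold seeds. The
penalty strength is chosen at the minimum of the cross-validated squared error
over a log-spaced grid (the fold split itself provides the validation error,
as in standard cv-regularization practice), out-of-fold predictions are kept
for evaluation, and the reported coefficients come from a refit on all samples
at the chosen penalty, on standardized predictors so absolute-weight ranks are
comparable across genes.

Evaluation uses the plain Pearson correlation of out-of-fold predictions with
observations, and the tissue-weighted Pearson correlation

    p_w = tanh( sum_i (n_i - 1) * arctanh(p_i) / sum_i (n_i - 1) )

over per-tissue correlations ``p_i`` restricted to tissues with ``n_i >= 3``
treated lines. Weighting by tissue counteracts Simpson's-paradox inflation:
between-tissue response offsets can make a pooled correlation large even when
no within-tissue signal exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .dataio import ConfigError, ScreenDataset
from . import correct

log = logging.getLogger(__name__)

MODALITIES = ("raw", "zscore", "residual", "tissue_labels")

#: clamp for correlations before the Fisher z-transform
_CLAMP = 1.0 - 1e-12


class ModelError(ValueError):
    """Invalid modelling input (too few samples, misaligned design matrix...)."""


def _default_grid() -> tuple[float, ...]:
    return tuple(np.logspace(-2, 4, 13))


@dataclass
class ModelSpec:
    """Settings of the per-drug penalized regression.

    ``alpha`` is the elastic-net mixing parameter: 0 = ridge (the default model
    for all downstream analyses), 1 = lasso, intermediate values elastic net.
    ``penalty_grid`` is the grid of penalty strengths searched by cross-validated
    squared error.
    """

    alpha: float = 0.0
    folds: int = 10
    repeats: int = 10
    penalty_grid: Sequence[float] = field(default_factory=_default_grid)
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must be in [0, 1]")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        grid = np.asarray(list(self.penalty_grid), float)
        if grid.size == 0 or (grid < 0).any():
            raise ConfigError("penalty_grid must be non-empty and non-negative")


@dataclass
class RunResult:
    """Outcome of one cross-validated fit: final coefficients (standardized
    predictor scale), out-of-fold predictions, chosen penalty."""

    coef: pd.Series
    oof: pd.Series
    penalty: float
    degenerate: bool = False


@dataclass
class DrugModelResult:
    """All repeated runs of one (drug, modality) model."""

    drug_id: str
    modality: str
    coef: pd.DataFrame  # runs x genes
    oof: pd.DataFrame  # runs x cell lines
    performance: pd.DataFrame  # run, pearson, weighted_pearson
    n_samples: int
    tissues: pd.Series  # cell_line -> tissue for the modelled lines

    def mean_coef(self) -> pd.Series:
        """Run-averaged weights w_bar per gene."""
        return self.coef.mean(axis=0)


def derive_seed(base: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and an index key."""
    return int(np.random.SeedSequence([int(base) & 0x7FFFFFFF, *key]).generate_state(1)[0] % (2**31))


def _standardize(m: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = m.mean(axis=0)
    if scale:
        sd = m.std(axis=0)
        safe = np.where(sd > 0, sd, 1.0)
    else:
        sd = safe = np.ones(m.shape[1])
    xs = (m - mu) / safe
    xs[:, sd == 0] = 0.0
    return xs, mu, safe


def ridge_path(xs: np.ndarray, yc: np.ndarray, penalties: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every penalty at once via one SVD.

    ``xs`` must be column-centered (standardized) and ``yc`` centered; returns a
    (p, L) matrix. One decomposition serves the whole grid, which keeps the
    repeated-CV pipeline tractable; agreement with sklearn's Ridge is asserted
    in the test-suite.
    """
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uty = u.T @ yc
    lam = np.asarray(penalties, float)
    smax = s.max() if s.size else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = s[:, None] / (s[:, None] ** 2 + lam[None, :])
    if smax > 0:
        d[s < smax * 1e-12, :] = 0.0
    else:
        d[:] = 0.0
    d = np.nan_to_num(d, nan=0.0, posinf=0.0, neginf=0.0)
    return vt.T @ (d * uty[:, None])


def _enet_path(xs: np.ndarray, yc: np.ndarray, penalties: np.ndarray, l1_ratio: float) -> np.ndarray:
    from sklearn.linear_model import enet_path

    order = np.argsort(penalties)[::-1]  # sklearn wants decreasing alphas
    _, coefs, _ = enet_path(xs, yc, l1_ratio=l1_ratio, alphas=penalties[order], max_iter=5000)
    out = np.empty_like(coefs)
    out[:, order] = coefs
    return out


def _coef_path(xs, yc, penalties, alpha):
    if alpha == 0:
        return ridge_path(xs, yc, penalties)
    return _enet_path(xs, yc, penalties, alpha)


def fit_drug_model_run(
    X: pd.DataFrame, y: pd.Series, spec: ModelSpec, run_seed: int
) -> RunResult:
    """One cross-validated fit of AUC on the design matrix.

    Fold assignment is drawn from ``run_seed``; the penalty minimizing the
    cross-validated squared error over ``spec.penalty_grid`` is selected, its
    out-of-fold predictions are returned, and the coefficients come from a
    final fit on all samples at that penalty. A constant response yields the
    degenerate result (zero coefficients, mean predictions).
    """
    if not X.index.equals(y.index):
        X = X.reindex(y.index)
        if X.isna().any().any():
            raise ModelError("design matrix does not cover all response samples")
    n = len(y)
    if n < spec.folds:
        raise ModelError(f"need at least {spec.folds} samples, got {n}")
    yv = y.to_numpy(float)
    xm = X.to_numpy(float)
    if np.ptp(yv) == 0:
        return RunResult(
            coef=pd.Series(0.0, index=X.columns),
            oof=pd.Series(np.full(n, yv.mean()), index=y.index),
            penalty=float("nan"),
            degenerate=True,
        )

    grid = np.sort(np.asarray(list(spec.penalty_grid), float))
    kf = KFold(n_splits=spec.folds, shuffle=True, random_state=int(run_seed) % (2**32))
    oof = np.empty((n, grid.size))
    for tr, te in kf.split(xm):
        xs, mu, sd = _standardize(xm[tr], spec.standardize_features)
        ybar = yv[tr].mean()
        coefs = _coef_path(xs, yv[tr] - ybar, grid, spec.alpha)
        xte = (xm[te] - mu) / sd
        oof[te, :] = xte @ coefs + ybar
    sse = ((oof - yv[:, None]) ** 2).sum(axis=0)
    best = int(np.argmin(sse))

    xs, _, _ = _standardize(xm, spec.standardize_features)
    ybar = yv.mean()
    coef = _coef_path(xs, yv - ybar, grid[best : best + 1], spec.alpha)[:, 0]
    return RunResult(
        coef=pd.Series(coef, index=X.columns),
        oof=pd.Series(oof[:, best], index=y.index),
        penalty=float(grid[best]),
    )


def pearson(a, b) -> float:
    """Pearson correlation; NaN for degenerate inputs (length < 2, zero spread)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def per_tissue_correlations(
    y: pd.Series, y_hat: pd.Series, tissues: pd.Series, min_n: int = 3
) -> pd.DataFrame:
    """Per-tissue Pearson correlations of predictions with observations.

    Tissues with fewer than ``min_n`` treated lines, or a constant prediction or
    observation, are excluded (p_i undefined).
    """
    labels = tissues.reindex(y.index)
    rows = []
    for tissue, idx in y.groupby(labels).groups.items():
        if len(idx) < min_n:
            continue
        r = pearson(y.loc[idx], y_hat.loc[idx])
        if np.isfinite(r):
            rows.append({"tissue": tissue, "n": len(idx), "r": r})
    return pd.DataFrame(rows, columns=["tissue", "n", "r"])


def weighted_pearson(pairs) -> float:
    """Fisher-z tissue-weighted correlation.

    ``pairs`` is an iterable of ``(tissue, n_i, p_i)`` or a DataFrame with
    columns ``tissue``, ``n``, ``r``. Pairs with ``n_i < 3`` or undefined
    ``p_i`` are excluded; ``p_i = +/-1`` is clamped to keep arctanh finite.
    Returns NaN when no pair survives.
    """
    if isinstance(pairs, pd.DataFrame):
        it = [(row["tissue"], row["n"], row["r"]) for _, row in pairs.iterrows()]
    else:
        it = list(pairs)
    ws, zs = [], []
    for _, n_i, p_i in it:
        if n_i < 3 or not np.isfinite(p_i):
            continue
        p_i = min(max(float(p_i), -_CLAMP), _CLAMP)
        ws.append(n_i - 1)
        zs.append(np.arctanh(p_i))
    if not ws:
        return float("nan")
    ws = np.asarray(ws, float)
    zs = np.asarray(zs, float)
    return float(np.tanh((ws * zs).sum() / ws.sum()))


def fisher_z_mean(values: Iterable[float]) -> float:
    """Mean of correlations on the Fisher z-scale; NaNs ignored, all-NaN -> NaN."""
    vals = np.asarray([v for v in values if np.isfinite(v)], float)
    if vals.size == 0:
        return float("nan")
    vals = np.clip(vals, -_CLAMP, _CLAMP)
    return float(np.tanh(np.arctanh(vals).mean()))


def run_performance(y: pd.Series, oof: pd.Series, tissues: pd.Series) -> tuple[float, float]:
    """(unweighted, tissue-weighted) Pearson of one run's out-of-fold predictions."""
    p = pearson(y, oof.reindex(y.index))
    pw = weighted_pearson(per_tissue_correlations(y, oof, tissues))
    return p, pw


def prepare_modality(ds: ScreenDataset, modality: str) -> pd.DataFrame:
    """Design matrix for one input modality, indexed by cell line."""
    if modality == "raw":
        return ds.expression
    if modality == "zscore":
        return correct.zscore_by_tissue(ds.expression, ds.tissue_map()).values
    if modality == "residual":
        return correct.residual_correct(ds.expression, ds.tissue_map()).values
    if modality == "tissue_labels":
        labels = ds.tissue_map().reindex(ds.expression.index)
        return pd.get_dummies(labels).astype(float)
    raise ConfigError(f"unknown modality '{modality}'; expected one of {MODALITIES}")


def run_drug_model(
    X: pd.DataFrame,
    y: pd.Series,
    tissues: pd.Series,
    spec: ModelSpec,
    run_seeds: Sequence[int],
    drug_id: str = "",
    modality: str = "",
) -> DrugModelResult:
    """Execute the repeated runs for one drug on a prepared design matrix."""
    coefs, oofs, perf = [], [], []
    for run, seed in enumerate(run_seeds):
        res = fit_drug_model_run(X, y, spec, seed)
        p, pw = (float("nan"), float("nan")) if res.degenerate else run_performance(y, res.oof, tissues)
        coefs.append(res.coef)
        oofs.append(res.oof)
        perf.append({"run": run, "pearson": p, "weighted_pearson": pw, "penalty": res.penalty})
    return DrugModelResult(
        drug_id=drug_id,
        modality=modality,
        coef=pd.DataFrame(coefs).reset_index(drop=True),
        oof=pd.DataFrame(oofs).reset_index(drop=True),
        performance=pd.DataFrame(perf),
        n_samples=len(y),
        tissues=tissues.reindex(y.index),
    )


def run_repeated_models(
    ds: ScreenDataset,
    modality: str,
    spec: ModelSpec,
    matrix: pd.DataFrame | None = None,
) -> dict[str, DrugModelResult]:
    """Fit the repeated-CV model for every drug of the screen in one modality.

    Drugs with fewer usable lines than folds (or a constant response) are
    skipped with a logged reason. ``matrix`` short-circuits modality
    preparation when the caller already holds the design matrix.
    """
    if matrix is None:
        matrix = prepare_modality(ds, modality)
    tissues = ds.tissue_map()
    results: dict[str, DrugModelResult] = {}
    for di, drug in enumerate(sorted(ds.response["drug_id"].unique())):
        y = ds.drug_response(drug)
        y = y[y.index.isin(matrix.index)]
        if len(y) < spec.folds:
            log.info("skipping drug %s in %s: %d lines < %d folds", drug, modality, len(y), spec.folds)
            continue
        if y.nunique() < 2:
            log.info("skipping drug %s in %s: constant response", drug, modality)
            continue
        seeds = [derive_seed(spec.seed, 1, di, r) for r in range(spec.repeats)]
        results[drug] = run_drug_model(
            matrix.loc[y.index], y, tissues, spec, seeds, drug_id=drug, modality=modality
        )
    return results


def summarize_performance(results: Mapping[str, DrugModelResult] | Iterable[DrugModelResult]) -> pd.DataFrame:
    """Per-drug, per-modality performance: Fisher-z mean over the repeats."""
    if isinstance(results, Mapping):
        results = results.values()
    rows = []
    for res in results:
        labels = res.tissues
        n_tissues = int((labels.groupby(labels).size() >= 3).sum())
        rows.append(
            {
                "drug_id": res.drug_id,
                "modality": res.modality,
                "pearson": fisher_z_mean(res.performance["pearson"]),
                "weighted_pearson": fisher_z_mean(res.performance["weighted_pearson"]),
                "n": res.n_samples,
                "n_tissues": n_tissues,
            }
        )
    return pd.DataFrame(rows, columns=["drug_id", "modality", "pearson", "weighted_pearson", "n", "n_tissues"])
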