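"""Preranked drug-set enrichment of candidate biomarker features.

For a candidate gene, drugs are ranked by the gene's run-averaged model weight
and a classic weighted running-sum statistic tests whether the drugs of a
target pathway concentrate at one end of the ranking. A negative enrichment
score means the pathway's drugs sit at the most-negative-weight (sensitivity)
end. Significance comes from Monte-Carlo permutations of same-size drug sets,
``p = (b + 1) / (n_perm + 1)`` with b counting permutations at least as
extreme as the observed score in its own direction (the signed-tail
convention of preranked enrichment tools; a positive and a negative score are
each tested toward their own end), with Bonferroni adjustment over the tested
feature x pathway grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


class EnrichmentError(ValueError):
    """Invalid ranked list or drug set (empty set, set = universe, ...)."""


@dataclass
class RankedDrugList:
    """Drugs ordered ascending by a feature's model weight ("lowest to highest")."""

    gene: str
    drugs: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.drugs) != self.weights.size:
            raise EnrichmentError("drugs and weights must have equal length")
        if len(self.drugs) < 2:
            raise EnrichmentError("ranked drug list needs at least 2 drugs")
        if len(set(self.drugs)) != len(self.drugs):
            raise EnrichmentError("duplicated drugs in ranked list")

    @property
    def universe_size(self) -> int:
        return len(self.drugs)


def rank_drugs_for_feature(
    rank_table: pd.DataFrame,
    gene: str,
    modality: str,
    universe: Sequence[str] | None = None,
) -> RankedDrugList:
    """Ranked drug list for one gene from the feature rank table.

    ``universe`` restricts (and must be covered by) the drugs of the table,
    typically the informative models of the modality; ties in weight are broken
    by drug id. Row order of the input table does not matter.
    """
    sub = rank_table[(rank_table["modality"] == modality) & (rank_table["gene"] == gene)]
    weights = sub.set_index("drug_id")["weight"]
    drugs = sorted(weights.index) if universe is None else list(universe)
    missing = [d for d in drugs if d not in weights.index]
    if missing:
        raise EnrichmentError(f"gene {gene} absent from models of drugs: {missing}")
    order = sorted(drugs, key=lambda d: (weights[d], d))
    return RankedDrugList(gene=gene, drugs=order, weights=weights[order].to_numpy())


def _running_sum_es(absw: np.ndarray, hits: np.ndarray) -> float:
    """Signed maximum deviation of the running sum; |w|^exponent already applied.

    ``absw`` and ``hits`` follow the descending-weight order. When the hit
    weights sum to zero (all-zero weights) hits fall back to equal increments.
    """
    m = int(hits.sum())
    n = hits.size
    denom = absw[hits].sum()
    steps = np.where(hits, absw / denom if denom > 0 else 1.0 / m, -1.0 / (n - m))
    run = np.cumsum(steps)
    pos = run.max()
    neg = run.min()
    return float(pos if pos >= -neg else neg)


def enrichment_score(
    rl: RankedDrugList, drug_set: Collection[str], weight_exponent: float = 1.0
) -> float:
    """Weighted running-sum enrichment score of a drug set, in [-1, 1].

    The list is walked in descending weight order; set members step the sum up
    by |w|^exponent (normalized by the set total), non-members step it down by
    1/(M - m). The score is the extreme of the running sum; negative scores
    mean concentration at the negative-weight (sensitivity) end. On a tie
    between the positive and negative extremes the positive one is returned.
    """
    members = set(drug_set)
    if not members:
        raise EnrichmentError("drug set is empty")
    if not members <= set(rl.drugs):
        raise EnrichmentError("drug set is not a subset of the ranked universe")
    if len(members) >= rl.universe_size:
        raise EnrichmentError("drug set equals the universe; complement undefined")
    # descending by weight = reverse of the ascending ranked list
    desc = rl.drugs[::-1]
    absw = np.abs(rl.weights[::-1]) ** weight_exponent
    hits = np.array([d in members for d in desc])
    return _running_sum_es(absw, hits)


def _as_extreme(es_perm: float, es_obs: float) -> bool:
    """Is a permutation score at least as extreme as the observed one, in the
    observed score's own direction?"""
    if es_obs >= 0:
        return es_perm >= es_obs - 1e-12
    return es_perm <= es_obs + 1e-12


def permutation_pvalue(
    rl: RankedDrugList,
    drug_set: Collection[str],
    n_perm: int = 10000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, float]:
    """Monte-Carlo permutation p-value, signed toward the observed direction.

    Random same-size drug sets are drawn from the universe; ``p = (b + 1) /
    (n_perm + 1)`` where b counts permutations whose score is at least as
    extreme as ES_obs in its own tail (ES_perm <= ES_obs for a negative
    observation, >= for a non-negative one). Returns (ES_obs, p).
    """
    es_obs = enrichment_score(rl, drug_set, weight_exponent)
    m = len(set(drug_set))
    absw = np.abs(rl.weights[::-1]) ** weight_exponent
    n = rl.universe_size
    rng = np.random.default_rng(int(seed))
    b = 0
    hits = np.zeros(n, dtype=bool)
    for _ in range(n_perm):
        hits[:] = False
        hits[rng.choice(n, size=m, replace=False)] = True
        if _as_extreme(_running_sum_es(absw, hits), es_obs):
            b += 1
    return es_obs, (b + 1) / (n_perm + 1)


def exhaustive_pvalue(
    rl: RankedDrugList, drug_set: Collection[str], weight_exponent: float = 1.0
) -> tuple[float, float]:
    """Exact permutation p-value by enumerating all same-size drug sets."""
    es_obs = enrichment_score(rl, drug_set, weight_exponent)
    m = len(set(drug_set))
    total = b = 0
    for combo in itertools.combinations(rl.drugs, m):
        total += 1
        if _as_extreme(enrichment_score(rl, combo, weight_exponent), es_obs):
            b += 1
    return es_obs, b / total


def hypergeom_topk_test(
    rl: RankedDrugList, drug_set: Collection[str], k: int
) -> float:
    """Simple top-k overlap test (hypergeometric upper tail), for comparison.

    Tests over-representation of the set among the k most-negative-weight
    drugs of the ranking.
    """
    members = set(drug_set)
    if not 0 < k < rl.universe_size:
        raise EnrichmentError("k must be in (0, universe size)")
    top = set(rl.drugs[:k])  # ascending list: most negative weights first
    overlap = len(top & members)
    return float(hypergeom.sf(overlap - 1, rl.universe_size, len(members), k))


def run_feature_pathway_enrichment(
    features: Sequence[str],
    rank_table: pd.DataFrame,
    drugs: pd.DataFrame,
    modality: str = "zscore",
    universe: Sequence[str] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_pathway_drugs: int = 2,
) -> pd.DataFrame:
    """ES, permutation p and Bonferroni-adjusted p for each feature x pathway.

    Only pathways with at least ``min_pathway_drugs`` drugs inside the universe
    (and strictly fewer than the whole universe) are tested; the Bonferroni
    factor is the number of combinations actually tested.
    """
    if not features:
        raise EnrichmentError("no candidate features given")
    if universe is None:
        universe = sorted(rank_table.loc[rank_table["modality"] == modality, "drug_id"].unique())
    universe = list(universe)
    pathway_of = drugs.set_index("drug_id")["pathway"]
    sets: dict[str, list[str]] = {}
    for d in universe:
        pw = pathway_of.get(d)
        if pw is not None:
            sets.setdefault(pw, []).append(d)
    sets = {
        pw: ds
        for pw, ds in sets.items()
        if min_pathway_drugs <= len(ds) < len(universe)
    }
    rows = []
    for fi, gene in enumerate(features):
        rl = rank_drugs_for_feature(rank_table, gene, modality, universe)
        for pi, pw in enumerate(sorted(sets)):
            es, p = permutation_pvalue(
                rl, sets[pw], n_perm=n_perm,
                seed=int(np.random.SeedSequence([int(seed), fi, pi]).generate_state(1)[0] % 2**31),
                weight_exponent=weight_exponent,
            )
            rows.append(
                {"feature": gene, "pathway": pw, "set_size": len(sets[pw]), "es": es,
                 "pval": p, "n_perm": n_perm}
            )
    out = pd.DataFrame(rows, columns=["feature", "pathway", "set_size", "es", "pval", "n_perm"])
    n_tests = len(out)
    out["padj_bonferroni"] = (out["pval"] * n_tests).clip(upper=1.0)
    return out.sort_values(["padj_bonferroni", "feature", "pathway"]).reset_index(drop=True)
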