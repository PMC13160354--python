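"""Synthetic drug-screen generator with planted pan-cancer biomarkers.

The generator emulates the statistical structure that the analysis pipeline
assumes in real cell-line screens:

* tissue-structured expression ``x_cg = b_g + t_{tau(c),g} +
  c_g * [tau(c) non-solid] + L_g . f_c + e_cg`` with gene baselines
  ``b_g ~ N(mu_b, sigma_b^2)``, per-tissue effects ``t ~ N(0, sigma_t^2)``, a
  shared solid/non-solid expression axis ``c_g`` (the dominant lineage
  separation real panels show in their top principal components), a small
  number of latent co-expression factors ``f_c`` with dense loadings ``L``
  (transcriptional programs -- proliferation, stress response -- spanning the
  panel), and residual noise; factors and noise together carry ``sigma_e^2``
  of within-tissue variance;
* AUC responses ``auc_cd = alpha_d + delta * [tau(c) non-solid] + u_{tau(c)}
  - beta_d * z*_{c,g*} + w_d . f_c + eps`` where ``u_tau`` is a per-tissue
  sensitivity offset shared across drugs, ``z*`` is the within-tissue
  standardized expression of the pathway's planted biomarker gene (higher
  expression => lower AUC => more sensitive) and ``w_d . f_c`` is a dense
  program-level response component shared with expression (what makes drug
  response partly predictable for every drug, as in real screens), clipped to
  [0, 1];
* tissue-proxy decoy genes that are affine functions of the tissue-level mean
  sensitivity plus small noise (pure lineage surrogates with very high tissue
  attribution but no within-tissue information);
* per-drug incomplete screening coverage.

Ground truth (planted effects, carrier drugs, decoys) is returned alongside the
dataset so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import ConfigError, ScreenDataset


@dataclass(frozen=True)
class PlantedBiomarker:
    """A single-gene effect shared by the drugs of one pathway.

    ``effect`` is the AUC decrease per within-tissue standard deviation of the
    gene's expression; ``carrier_fraction`` is the fraction of the pathway's
    drugs that carry the effect.
    """

    gene_index: int
    effect: float
    carrier_fraction: float = 1.0


def _default_effect(noise_sd: float, background_sd: float) -> float:
    # effect size such that beta^2 = (background^2 + noise^2) / 3, i.e. the
    # planted gene explains 25% of the within-tissue response variance
    return np.sqrt((background_sd**2 + noise_sd**2) / 3.0)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic screen.

    Defaults describe a small pan-cancer panel: 10 cancer types of 20 lines,
    2000 genes plus one tissue-proxy decoy, 30 drugs split over 3 target
    pathways, each pathway sharing one planted biomarker whose effect explains
    25% of the within-tissue response variance. Tissue centroids live on a
    3-dimensional lineage manifold (sigma_t^2 = 0.5 against within-tissue
    variance 1.0, log2 scale around a baseline of 7) plus a solid/non-solid
    expression axis, so tissue structure dominates the top principal
    components as in real panels; 30% of the within-tissue variance sits in 5
    latent co-expression factors that also drive a shared response component,
    making every drug partly predictable from expression. Responses carry a
    per-tissue sensitivity offset (sd 0.1) and a non-solid shift of -0.15, and
    each drug is screened in 90% of lines.
    """

    n_tissues: int = 10
    lines_per_tissue: int | Sequence[int] = 20
    n_genes: int = 2000
    n_drugs: int = 30
    n_pathways: int = 3
    pathways: Mapping[str, str] | None = None  # drug_id -> pathway; default: contiguous blocks
    tissue_effect_var: float = 0.5
    residual_var: float = 1.0
    baseline_mean: float = 7.0
    baseline_var: float = 1.0
    class_effect_var: float = 0.3  # solid/non-solid expression axis variance
    n_tissue_dims: int = 3  # rank of the tissue-centroid structure; 0 = full rank
    n_factors: int = 5
    factor_share: float = 0.3  # share of residual_var carried by latent factors
    biomarker_map: Mapping[str, PlantedBiomarker] | None = None  # pathway -> planted effect
    solid_shift: float = -0.15  # AUC offset added to non-solid lines
    tissue_response_sd: float = 0.1  # per-tissue AUC offset shared across drugs
    nonsolid_fraction: float = 0.3
    auc_baseline_range: tuple[float, float] = (0.5, 0.7)
    response_background_sd: float = 0.1  # within-tissue response sd from expression programs
    response_noise_sd: float = 0.1
    decoy_genes: int = 1
    decoy_noise_sd: float = 0.1
    drug_coverage: float = 0.9
    seed: int = 0

    def line_counts(self) -> list[int]:
        if isinstance(self.lines_per_tissue, int):
            return [self.lines_per_tissue] * self.n_tissues
        counts = list(self.lines_per_tissue)
        if len(counts) != self.n_tissues:
            raise ConfigError("lines_per_tissue list length must equal n_tissues")
        return counts

    def tissue_names(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]

    def gene_names(self) -> list[str]:
        genes = [f"G{i + 1:04d}" for i in range(self.n_genes)]
        genes += [f"DECOY{i + 1}" for i in range(self.decoy_genes)]
        return genes

    def drug_names(self) -> list[str]:
        return [f"D{i + 1:03d}" for i in range(self.n_drugs)]

    def pathway_of(self) -> dict[str, str]:
        if self.pathways is not None:
            return dict(self.pathways)
        drugs = self.drug_names()
        per = int(np.ceil(self.n_drugs / self.n_pathways))
        return {d: f"PW{i // per + 1}" for i, d in enumerate(drugs)}

    def planted(self) -> dict[str, PlantedBiomarker]:
        if self.biomarker_map is not None:
            return dict(self.biomarker_map)
        pathways = sorted(set(self.pathway_of().values()))
        beta = _default_effect(self.response_noise_sd, self.response_background_sd)
        return {p: PlantedBiomarker(gene_index=i, effect=beta) for i, p in enumerate(pathways)}

    def validate(self) -> None:
        if self.n_tissues < 2:
            raise ConfigError("need at least 2 tissues")
        if min(self.line_counts()) < 2:
            raise ConfigError("each tissue needs at least 2 lines")
        if self.tissue_effect_var < 0 or self.baseline_var < 0 or self.class_effect_var < 0:
            raise ConfigError("variances must be non-negative")
        if self.tissue_response_sd < 0:
            raise ConfigError("tissue_response_sd must be non-negative")
        if self.residual_var <= 0 or self.response_noise_sd <= 0:
            raise ConfigError("residual_var and response_noise_sd must be positive")
        if not 0 <= self.factor_share < 1 or self.n_factors < 0 or self.response_background_sd < 0:
            raise ConfigError("invalid latent-factor settings")
        if not 0 < self.drug_coverage <= 1:
            raise ConfigError("drug_coverage must be in (0, 1]")
        for pathway, planted in self.planted().items():
            if not 0 <= planted.gene_index < self.n_genes:
                raise ConfigError(
                    f"biomarker gene index {planted.gene_index} for pathway {pathway} "
                    f"outside [0, {self.n_genes})"
                )
            if not 0 < planted.carrier_fraction <= 1:
                raise ConfigError("carrier_fraction must be in (0, 1]")

    def tissue_variance_fraction(self) -> float:
        """Expected per-gene fraction of expression variance between tissues.

        The solid/non-solid axis contributes p(1-p) of its variance to the
        between-tissue component, where p is the non-solid line fraction.
        """
        counts = np.asarray(self.line_counts(), float)
        n_nonsolid = int(round(self.nonsolid_fraction * self.n_tissues))
        p = counts[self.n_tissues - n_nonsolid:].sum() / counts.sum() if n_nonsolid else 0.0
        between = self.tissue_effect_var + p * (1 - p) * self.class_effect_var
        return between / (between + self.residual_var)


@dataclass
class GroundTruth:
    """Planted structure of a simulated screen."""

    planted: pd.DataFrame  # pathway, gene, effect, carrier_fraction
    carriers: pd.DataFrame  # drug_id, pathway, gene, effect
    decoy_genes: list[str]
    drug_has_signal: pd.Series  # drug_id -> bool
    tissue_variance_fraction: float

    def write(self, path) -> None:
        rows = self.carriers.copy()
        rows["record"] = "planted"
        for decoy in self.decoy_genes:
            rows = pd.concat(
                [rows, pd.DataFrame([{"drug_id": "", "pathway": "", "gene": decoy,
                                      "effect": np.nan, "record": "decoy"}])],
                ignore_index=True,
            )
        rows["tissue_variance_fraction"] = self.tissue_variance_fraction
        rows.to_csv(path, sep="\t", index=False)


def _within_tissue_standardize(values: np.ndarray, tissue_idx: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    for t in np.unique(tissue_idx):
        mask = tissue_idx == t
        sub = values[mask]
        sd = sub.std(ddof=1)
        out[mask] = (sub - sub.mean()) / sd if sd > 0 else 0.0
    return out


def simulate_screen(cfg: SimulationConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a synthetic screen plus its ground truth.

    All draws come from one seeded generator, so identical configs produce
    byte-identical datasets.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    tissues = cfg.tissue_names()
    counts = cfg.line_counts()
    n_nonsolid = int(round(cfg.nonsolid_fraction * cfg.n_tissues))
    tumor_class = {
        t: ("non_solid" if i >= cfg.n_tissues - n_nonsolid else "solid")
        for i, t in enumerate(tissues)
    }
    n_lines = sum(counts)
    line_ids = [f"CL{i + 1:04d}" for i in range(n_lines)]
    tissue_idx = np.repeat(np.arange(cfg.n_tissues), counts)
    line_tissue = np.array(tissues)[tissue_idx]
    nonsolid = np.array([tumor_class[t] == "non_solid" for t in line_tissue], dtype=float)

    # expression: baseline + tissue effect + class axis + latent factors + noise
    baseline = rng.normal(cfg.baseline_mean, np.sqrt(cfg.baseline_var), size=cfg.n_genes)
    if cfg.n_tissue_dims:
        # low-rank tissue centroids: lineages share a few expression programs,
        # which concentrates tissue separation in the top principal components
        d = cfg.n_tissue_dims
        scores = rng.normal(0.0, 1.0, size=(cfg.n_tissues, d))
        axes = rng.normal(0.0, np.sqrt(cfg.tissue_effect_var / d), size=(d, cfg.n_genes))
        tissue_fx = scores @ axes
    else:
        tissue_fx = rng.normal(
            0.0, np.sqrt(cfg.tissue_effect_var), size=(cfg.n_tissues, cfg.n_genes)
        )
    class_fx = rng.normal(0.0, np.sqrt(cfg.class_effect_var), size=cfg.n_genes)
    k = cfg.n_factors
    iid_var = cfg.residual_var * (1.0 - (cfg.factor_share if k else 0.0))
    noise = rng.normal(0.0, np.sqrt(iid_var), size=(n_lines, cfg.n_genes))
    expr = (
        baseline[None, :]
        + tissue_fx[tissue_idx, :]
        + nonsolid[:, None] * class_fx[None, :]
        + noise
    )
    if k:
        factors = rng.normal(0.0, 1.0, size=(n_lines, k))
        loadings = rng.normal(
            0.0, np.sqrt(cfg.residual_var * cfg.factor_share / k), size=(cfg.n_genes, k)
        )
        expr += factors @ loadings.T
    else:
        factors = np.zeros((n_lines, 0))

    genes = cfg.gene_names()
    pathway_of = cfg.pathway_of()
    planted = cfg.planted()
    drug_ids = cfg.drug_names()

    alpha = rng.uniform(*cfg.auc_baseline_range, size=cfg.n_drugs)
    eps = rng.normal(0.0, cfg.response_noise_sd, size=(n_lines, cfg.n_drugs))
    if k and cfg.response_background_sd > 0:
        program_weights = rng.normal(
            0.0, cfg.response_background_sd / np.sqrt(k), size=(k, cfg.n_drugs)
        )
        eps = eps + factors @ program_weights

    # carrier assignment per pathway
    carrier_rows = []
    carrier_of_drug: dict[str, PlantedBiomarker | None] = {d: None for d in drug_ids}
    for pathway in sorted(set(pathway_of.values())):
        if pathway not in planted:
            continue
        effect = planted[pathway]
        members = [d for d in drug_ids if pathway_of[d] == pathway]
        n_carry = max(1, int(round(effect.carrier_fraction * len(members))))
        chosen = sorted(rng.choice(members, size=n_carry, replace=False))
        for d in chosen:
            carrier_of_drug[d] = effect
            carrier_rows.append(
                {"drug_id": d, "pathway": pathway,
                 "gene": genes[effect.gene_index], "effect": effect.effect}
            )

    zstar = {
        p: _within_tissue_standardize(expr[:, planted[p].gene_index], tissue_idx)
        for p in planted
    }
    tissue_offsets = rng.normal(0.0, cfg.tissue_response_sd, size=cfg.n_tissues)
    auc = (
        alpha[None, :]
        + cfg.solid_shift * nonsolid[:, None]
        + tissue_offsets[tissue_idx, None]
        + eps
    )
    for j, d in enumerate(drug_ids):
        effect = carrier_of_drug[d]
        if effect is not None:
            auc[:, j] -= effect.effect * zstar[pathway_of[d]]
    auc = np.clip(auc, 0.0, 1.0)

    # screening coverage: each drug observed in a random subset of lines
    n_obs = max(2, int(round(cfg.drug_coverage * n_lines)))
    rows = []
    for j, d in enumerate(drug_ids):
        chosen = np.sort(rng.choice(n_lines, size=n_obs, replace=False))
        for c in chosen:
            rows.append((line_ids[c], d, auc[c, j]))
    response = pd.DataFrame(rows, columns=["cell_line_id", "drug_id", "auc"])

    # decoy genes: affine in the tissue-level mean sensitivity, plus small noise
    decoy_cols = np.empty((n_lines, cfg.decoy_genes))
    if cfg.decoy_genes:
        tissue_mean_auc = np.array(
            [auc[tissue_idx == t, :].mean() for t in range(cfg.n_tissues)]
        )
        sd = tissue_mean_auc.std(ddof=1)
        profile = (tissue_mean_auc - tissue_mean_auc.mean()) / sd if sd > 0 else np.zeros(cfg.n_tissues)
        scale = np.sqrt(cfg.tissue_effect_var + cfg.residual_var)
        for k in range(cfg.decoy_genes):
            decoy_cols[:, k] = (
                cfg.baseline_mean
                + scale * profile[tissue_idx]
                + rng.normal(0.0, cfg.decoy_noise_sd, size=n_lines)
            )
        expr = np.hstack([expr, decoy_cols])

    expression = pd.DataFrame(expr, index=pd.Index(line_ids, name="cell_line_id"), columns=genes)
    samples = pd.DataFrame(
        {"cell_line_id": line_ids, "cancer_type": line_tissue,
         "tumor_class": [tumor_class[t] for t in line_tissue]}
    )
    drugs = pd.DataFrame({"drug_id": drug_ids, "pathway": [pathway_of[d] for d in drug_ids]})
    ds = ScreenDataset(expression=expression, samples=samples, response=response, drugs=drugs)

    carriers = pd.DataFrame(carrier_rows, columns=["drug_id", "pathway", "gene", "effect"])
    planted_df = pd.DataFrame(
        [
            {"pathway": p, "gene": genes[b.gene_index], "effect": b.effect,
             "carrier_fraction": b.carrier_fraction}
            for p, b in sorted(planted.items())
        ],
        columns=["pathway", "gene", "effect", "carrier_fraction"],
    )
    truth = GroundTruth(
        planted=planted_df,
        carriers=carriers,
        decoy_genes=[g for g in genes if g.startswith("DECOY")][: cfg.decoy_genes],
        drug_has_signal=pd.Series(
            {d: carrier_of_drug[d] is not None for d in drug_ids}, name="has_signal"
        ),
        tissue_variance_fraction=cfg.tissue_variance_fraction(),
    )
    return ds, truth


def simulate_null_screen(cfg: SimulationConfig) -> tuple[ScreenDataset, GroundTruth]:
    """As :func:`simulate_screen` with every response signal removed.

    Planted effects and the shared expression-program response component are
    both zeroed (responses carry no expression signal at all); tissue structure
    in expression and the solid/non-solid response shift are retained. Used for
    calibration of the informative-model threshold.
    """
    null_cfg = dataclasses.replace(cfg, biomarker_map={}, response_background_sd=0.0)
    return simulate_screen(null_cfg)


def simulate_tissue_shift_fixture(
    n_tissues: int = 6,
    lines_per_tissue: int = 1200,
    shift_sd: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Between-tissue-shift-only response fixture for the Simpson's-paradox demo.

    Returns ``(tissue_onehot, auc, tissues)``: the response is a per-tissue
    offset plus noise with no within-tissue signal, so a tissue-label model
    attains a high pooled prediction-observation correlation while its
    tissue-weighted correlation sits near zero.

    Out-of-fold predictions of a groupwise-mean model carry a negative
    within-group bias of about -1/sqrt(fold size per tissue) (the held-out
    fold's mean is missing from the estimate), so the default fixture uses
    many lines per tissue to keep that bias small against the demonstrated
    effect; use few folds (e.g. 3) when fitting it.
    """
    rng = np.random.default_rng(seed)
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]
    line_ids = [f"CL{i + 1:04d}" for i in range(n_tissues * lines_per_tissue)]
    labels = pd.Series(np.repeat(tissues, lines_per_tissue), index=line_ids, name="cancer_type")
    shifts = rng.normal(0.0, shift_sd, size=n_tissues)
    y = 0.5 + np.repeat(shifts, lines_per_tissue) + rng.normal(0.0, noise_sd, size=len(line_ids))
    onehot = pd.get_dummies(labels).astype(float)
    return onehot, pd.Series(y, index=line_ids, name="auc"), labels


def write_simulation(ds: ScreenDataset, truth: GroundTruth, cfg: SimulationConfig, out_dir) -> dict:
    """Write dataset TSVs, ground truth and the resolved config snapshot."""
    from . import dataio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = dataio.write_dataset(ds, out)
    truth_path = out / "ground_truth.tsv"
    truth.write(truth_path)
    snapshot = dataclasses.asdict(cfg)
    snapshot["pathways"] = cfg.pathway_of()
    snapshot["biomarker_map"] = {
        p: {"gene_index": int(b.gene_index), "effect": float(b.effect),
            "carrier_fraction": float(b.carrier_fraction)}
        for p, b in cfg.planted().items()
    }
    snapshot = {k: (v.tolist() if hasattr(v, "tolist") else v) for k, v in snapshot.items()}
    import yaml

    cfg_path = out / "simulation_config.yaml"
    cfg_path.write_text(yaml.safe_dump(snapshot, sort_keys=True))
    paths.update({"ground_truth": str(truth_path), "config_snapshot": str(cfg_path)})
    return paths
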