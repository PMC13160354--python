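"""Config-driven end-to-end pipeline and its manifest.

Stage order: simulate (or load) -> qc -> correct -> fit -> select -> features
-> enrich -> context. Every stage writes plain TSV tables into the output
directory and appends its row counts to a JSON manifest; with a fixed seed a
rerun reproduces all outputs bit-identically. Timing is logged to stderr only,
so manifests stay comparable across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import context as context_mod
from . import correct as correct_mod
from . import dataio, enrich, features, model, select, simulate

log = logging.getLogger("panmark.pipeline")

STAGES = ("simulate", "qc", "correct", "fit", "select", "features", "enrich", "context")

CORRECTED_MODALITIES = ("zscore", "residual")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        cfg = dict(config)
    else:
        cfg = yaml.safe_load(Path(config).read_text())
    if not isinstance(cfg, dict):
        raise dataio.ConfigError("config must be a mapping")
    if "output_dir" not in cfg:
        raise dataio.ConfigError("config must declare output_dir")
    if ("inputs" in cfg) == ("simulate" in cfg):
        raise dataio.ConfigError("config must declare exactly one of 'inputs' or 'simulate'")
    cfg.setdefault("seed", 0)
    cfg.setdefault("modalities", ["raw", "zscore"])
    for m in cfg["modalities"]:
        if m not in model.MODALITIES:
            raise dataio.ConfigError(f"unknown modality '{m}'")
    cfg.setdefault("qc", {})
    cfg.setdefault("model", {})
    cfg.setdefault("select", {})
    cfg.setdefault("features", {})
    cfg.setdefault("enrich", {})
    cfg.setdefault("context", {})
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Hash of the analysis settings; the output location does not contribute."""
    canon = json.dumps(
        {k: v for k, v in cfg.items() if k != "output_dir"}, sort_keys=True, default=str
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _model_spec(cfg: dict) -> model.ModelSpec:
    mc = dict(cfg.get("model", {}))
    kwargs = {}
    for key in ("alpha", "folds", "repeats", "penalty_grid", "standardize_features"):
        if key in mc:
            kwargs[key] = mc[key]
    kwargs["seed"] = mc.get("seed", model.derive_seed(cfg["seed"], 11))
    return model.ModelSpec(**kwargs)


class _Runner:
    """Holds pipeline state between stages and records the manifest."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.out = Path(cfg["output_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "stages": [],
            "outputs": [],
        }
        self.ds: dataio.ScreenDataset | None = None
        self.truth: simulate.GroundTruth | None = None
        self.matrices: dict[str, pd.DataFrame] = {}
        self.results: dict[str, dict[str, model.DrugModelResult]] = {}
        self.perf: pd.DataFrame | None = None
        self.informative: pd.DataFrame | None = None
        self.rank_table: pd.DataFrame | None = None
        self.recurrent: pd.DataFrame | None = None
        self.candidates: list[str] = []

    def record(self, stage: str, rows_in: int, rows_out: int, elapsed: float) -> None:
        log.info("stage=%s rows_in=%d rows_out=%d elapsed=%.2fs", stage, rows_in, rows_out, elapsed)
        self.manifest["stages"].append({"name": stage, "rows_in": rows_in, "rows_out": rows_out})

    def write(self, name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = self.out / name
        df.to_csv(path, sep="\t", index=index)
        self.manifest["outputs"].append(name)

    # ---- stages -------------------------------------------------------
    def stage_simulate(self) -> None:
        t0 = time.perf_counter()
        if "simulate" in self.cfg:
            sim_cfg = dict(self.cfg["simulate"])
            if "biomarker_map" in sim_cfg and sim_cfg["biomarker_map"] is not None:
                sim_cfg["biomarker_map"] = {
                    p: simulate.PlantedBiomarker(**b) if isinstance(b, Mapping) else b
                    for p, b in sim_cfg["biomarker_map"].items()
                }
            sim_cfg.setdefault("seed", model.derive_seed(self.cfg["seed"], 10))
            scfg = simulate.SimulationConfig(**sim_cfg)
            self.ds, self.truth = simulate.simulate_screen(scfg)
            simulate.write_simulation(self.ds, self.truth, scfg, self.out / "dataset")
            for name in ("expression.tsv", "samples.tsv", "response.tsv", "drugs.tsv",
                         "ground_truth.tsv", "simulation_config.yaml"):
                self.manifest["outputs"].append(f"dataset/{name}")
        else:
            paths = self.cfg["inputs"]
            self.ds = dataio.load_dataset(
                paths["expression"], paths["samples"], paths["response"], paths["drugs"]
            )
        self.record("simulate", 0, len(self.ds.expression), time.perf_counter() - t0)

    def stage_qc(self) -> None:
        t0 = time.perf_counter()
        n_in = len(self.ds.expression)
        coverage = self.cfg["qc"].get("min_drug_coverage", 0.10)
        self.ds, report = dataio.apply_qc_filters(self.ds, coverage)
        dataio.write_qc_report(report, self.out / "qc_report.json")
        self.manifest["outputs"].append("qc_report.json")
        dataio.write_dataset(self.ds, self.out / "dataset_qc")
        for name in ("expression.tsv", "samples.tsv", "response.tsv", "drugs.tsv"):
            self.manifest["outputs"].append(f"dataset_qc/{name}")
        self.record("qc", n_in, len(self.ds.expression), time.perf_counter() - t0)

    def stage_correct(self) -> None:
        t0 = time.perf_counter()
        tissues = self.ds.tissue_map()
        diag_rows = [{"modality": "raw",
                      "tissue_separation": correct_mod.tissue_separation_score(self.ds.expression, tissues)}]
        self.matrices["raw"] = self.ds.expression
        for modality in self.cfg["modalities"]:
            if modality not in CORRECTED_MODALITIES:
                continue
            cm = (
                correct_mod.zscore_by_tissue(self.ds.expression, tissues)
                if modality == "zscore"
                else correct_mod.residual_correct(self.ds.expression, tissues)
            )
            self.matrices[modality] = cm.values
            cm.write(self.out / f"corrected_{modality}.tsv", self.out / f"strata_{modality}.tsv")
            self.manifest["outputs"] += [f"corrected_{modality}.tsv", f"strata_{modality}.tsv"]
            diag_rows.append(
                {"modality": modality,
                 "tissue_separation": correct_mod.tissue_separation_score(cm.values, tissues)}
            )
        diagnostics = pd.DataFrame(diag_rows)
        self.write("diagnostics.tsv", diagnostics)
        self.record("correct", len(self.ds.expression), len(diagnostics), time.perf_counter() - t0)

    def stage_fit(self) -> None:
        t0 = time.perf_counter()
        spec = _model_spec(self.cfg)
        summaries = []
        pred_rows = []
        coef_rows = []
        for modality in self.cfg["modalities"]:
            matrix = self.matrices.get(modality)
            if matrix is None:
                matrix = model.prepare_modality(self.ds, modality)
                self.matrices[modality] = matrix
            res = model.run_repeated_models(self.ds, modality, spec, matrix=matrix)
            self.results[modality] = res
            summaries.append(model.summarize_performance(res))
            if self.cfg["model"].get("write_predictions", True):
                for drug, r in res.items():
                    for run in range(len(r.oof)):
                        oof = r.oof.iloc[run]
                        y = self.ds.drug_response(drug).reindex(oof.index)
                        pred_rows.append(
                            pd.DataFrame({"drug_id": drug, "modality": modality, "run": run,
                                          "cell_line_id": oof.index, "auc": y.to_numpy(),
                                          "predicted": oof.to_numpy()})
                        )
            if self.cfg["model"].get("write_coefficients", False):
                for drug, r in res.items():
                    w = r.mean_coef()
                    coef_rows.append(
                        pd.DataFrame({"drug_id": drug, "modality": modality,
                                      "gene": w.index, "weight": w.to_numpy()})
                    )
        self.perf = pd.concat(summaries, ignore_index=True)
        self.write("performance.tsv", self.perf)
        if pred_rows:
            self.write("predictions.tsv", pd.concat(pred_rows, ignore_index=True))
        if coef_rows:
            self.write("coefficients.tsv", pd.concat(coef_rows, ignore_index=True))
        self.record("fit", len(self.ds.response), len(self.perf), time.perf_counter() - t0)

    def stage_select(self) -> None:
        t0 = time.perf_counter()
        spec = _model_spec(self.cfg)
        sc = self.cfg["select"]
        n_nulls = sc.get("n_nulls", 10)
        spread = sc.get("spread", "sd")
        modalities = sc.get("modalities", self.cfg["modalities"])
        null_rows = []
        thr_rows = []
        thresholds = {}
        for modality in modalities:
            nd = select.build_null_distribution(
                self.ds, modality, spec, n_nulls=n_nulls, matrix=self.matrices.get(modality)
            )
            stats = select.threshold_stats(nd, spread)
            thresholds[modality] = stats["theta"]
            thr_rows.append(stats)
            nv = nd.values.copy()
            nv.insert(0, "modality", modality)
            null_rows.append(nv)
        self.informative = select.select_informative_models(self.perf, thresholds, self.ds.drugs)
        self.write("null_performance.tsv", pd.concat(null_rows, ignore_index=True))
        self.write("thresholds.tsv", pd.DataFrame(thr_rows))
        self.write("informative.tsv", self.informative)
        self.record("select", len(self.perf), len(self.informative), time.perf_counter() - t0)

    def stage_features(self) -> None:
        t0 = time.perf_counter()
        fc = self.cfg["features"]
        k = fc.get("top_k", 10)
        min_fraction = fc.get("min_recurrent_fraction", 0.25)
        corrected = fc.get("corrected_modality", "zscore" if "zscore" in self.cfg["modalities"]
                           else self.cfg["modalities"][-1])
        informative_drugs = set(self.informative.loc[self.informative["informative"], "drug_id"])
        tables = []
        for modality, res in self.results.items():
            tables.append(features.build_rank_table(
                [r for d, r in res.items() if d in informative_drugs]
            ))
        self.rank_table = pd.concat(tables, ignore_index=True)
        self.write("ranks.tsv", self.rank_table)

        corr_table = self.rank_table[self.rank_table["modality"] == corrected]
        self.write("pathway_summary.tsv",
                   features.pathway_unique_percentages(self.rank_table, self.ds.drugs, corrected, k))
        rec_rows = []
        pathway_of = self.ds.pathway_map()
        for pw in sorted(pathway_of.unique()):
            members = [d for d in pathway_of.index[pathway_of == pw] if d in informative_drugs]
            if not members:
                continue
            rec = features.recurrent_pathway_features(corr_table, members, min_fraction, k)
            rec.insert(0, "pathway", pw)
            rec_rows.append(rec)
        self.recurrent = (pd.concat(rec_rows, ignore_index=True) if rec_rows
                          else pd.DataFrame(columns=["pathway", "gene", "fraction", "mean_rank", "n_drugs"]))
        self.write("recurrent.tsv", self.recurrent)

        raw_mod = fc.get("raw_modality", "raw")
        if raw_mod in self.results and corrected in self.results:
            classes = features.classify_feature_stability(self.rank_table, raw_mod, corrected, k)
            eta = features.eta_squared_matrix(self.ds.expression, self.ds.tissue_map())
            deltas = features.delta_rank(self.rank_table, raw_mod, corrected)
            med = features.median_delta_rank(deltas)
            gene_summary = (
                classes.groupby("gene")["status"]
                .value_counts()
                .unstack(fill_value=0)
                .reindex(columns=list(features.STABILITY_CLASSES), fill_value=0)
            )
            gene_summary["modal_class"] = gene_summary.idxmax(axis=1)
            gene_summary["eta2"] = eta.reindex(gene_summary.index)
            gene_summary["median_delta_rank"] = med.reindex(gene_summary.index)
            self.write("stability.tsv", gene_summary.reset_index())
            self.write("stability_classes.tsv", classes)
            self.write("stability_pathways.tsv", features.stability_summary(classes, self.ds.drugs))
        self.record("features", len(self.rank_table), len(self.recurrent), time.perf_counter() - t0)

    def stage_enrich(self) -> None:
        t0 = time.perf_counter()
        ec = self.cfg["enrich"]
        corrected = self.cfg["features"].get(
            "corrected_modality", "zscore" if "zscore" in self.cfg["modalities"] else self.cfg["modalities"][-1]
        )
        cand = ec.get("features")
        if cand is None:
            cand = list(dict.fromkeys(self.recurrent["gene"]))[: ec.get("max_features", 10)]
        self.candidates = list(cand)
        informative_drugs = sorted(self.informative.loc[self.informative["informative"], "drug_id"])
        if not self.candidates or len(informative_drugs) < 3:
            result = pd.DataFrame(
                columns=["feature", "pathway", "set_size", "es", "pval", "n_perm", "padj_bonferroni"]
            )
        else:
            result = enrich.run_feature_pathway_enrichment(
                self.candidates,
                self.rank_table,
                self.ds.drugs,
                modality=corrected,
                universe=informative_drugs,
                n_perm=ec.get("n_perm", 10000),
                seed=model.derive_seed(self.cfg["seed"], 12),
                weight_exponent=ec.get("weight_exponent", 1.0),
            )
        self.write("enrichment.tsv", result)
        self.record("enrich", len(self.candidates), len(result), time.perf_counter() - t0)

    def stage_context(self) -> None:
        t0 = time.perf_counter()
        cc = self.cfg["context"]
        genes = cc.get("genes") or self.candidates
        drug_ids = cc.get("drugs") or sorted(
            self.informative.loc[self.informative["informative"], "drug_id"]
        )
        genes = [g for g in genes if g in self.ds.expression.columns]
        table = context_mod.per_type_drug_gene_correlations(
            self.ds, genes, drug_ids,
            min_n=cc.get("min_n", 3),
            adjust_family=cc.get("family", "global"),
        )
        self.write("context_correlations.tsv", table)
        heat = context_mod.heatmap_matrix(table, cc.get("heatmap_min_n", 10))
        self.write("context_heatmap.tsv", heat, index=True)
        self.record("context", len(genes) * len(drug_ids), len(table), time.perf_counter() - t0)


def run_pipeline(
    config: str | Path | Mapping,
    until: str | None = None,
    seed_override: int | None = None,
    out_override: str | None = None,
) -> dict:
    """Execute the pipeline, optionally stopping after stage ``until``.

    Returns the manifest (also written to ``manifest.json``); any stage
    failure is re-raised as :class:`StageError` naming the stage.
    """
    cfg = load_config(config)
    if seed_override is not None:
        cfg["seed"] = int(seed_override)
    if out_override is not None:
        cfg["output_dir"] = str(out_override)
    if until is not None and until not in STAGES:
        raise dataio.ConfigError(f"unknown stage '{until}'")
    runner = _Runner(cfg)
    stage_fns = {
        "simulate": runner.stage_simulate,
        "qc": runner.stage_qc,
        "correct": runner.stage_correct,
        "fit": runner.stage_fit,
        "select": runner.stage_select,
        "features": runner.stage_features,
        "enrich": runner.stage_enrich,
        "context": runner.stage_context,
    }
    for stage in STAGES:
        try:
            stage_fns[stage]()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        if stage == until:
            break
    manifest_path = runner.out / "manifest.json"
    manifest_path.write_text(json.dumps(runner.manifest, indent=2, sort_keys=True) + "\n")
    return runner.manifest
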