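"""Tabular I/O, schema validation and QC filtering for pharmacogenomic screens.

All inputs are tab-delimited UTF-8 text with a header row:

* expression: ``cell_line_id`` plus one numeric column per gene (log2-scale,
  complete -- missing expression values are an error),
* samples: ``cell_line_id``, ``cancer_type``, ``tumor_class`` (solid / non_solid),
* response: ``cell_line_id``, ``drug_id``, ``auc`` (in [0, 1] by convention,
  lower = more sensitive; empty or "NA" marks a screened-but-missing record),
* drugs: ``drug_id``, ``pathway``.

Identifiers are opaque, case-sensitive strings and are never normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is absent or a categorical field holds an unknown value."""


class ParseError(ValueError):
    """A numeric field failed to parse; the message names the 1-based data row."""


class IntegrityError(ValueError):
    """Duplicated identifiers or inconsistent cross-references between tables."""


class QCError(RuntimeError):
    """Raised when no data survives quality control."""


class ConfigError(ValueError):
    """Invalid pipeline or simulation configuration."""


SAMPLE_COLUMNS = ("cell_line_id", "cancer_type", "tumor_class")
RESPONSE_COLUMNS = ("cell_line_id", "drug_id", "auc")
DRUG_COLUMNS = ("drug_id", "pathway")
TUMOR_CLASSES = ("solid", "non_solid")
#: tokens accepted as a missing AUC value
NA_TOKENS = frozenset({"", "NA", "NaN", "nan", "na"})


@dataclass
class ScreenDataset:
    """A joined drug screen: expression, sample annotation, response, drug annotation.

    ``expression`` is cell-lines-as-rows (samples x genes); ``response`` is long
    format with one row per screened (cell line, drug) pair, ``auc`` NaN when the
    measurement is missing.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    response: pd.DataFrame
    drugs: pd.DataFrame

    def tissue_map(self) -> pd.Series:
        """cell_line_id -> cancer_type."""
        return self.samples.set_index("cell_line_id")["cancer_type"]

    def tumor_class_map(self) -> pd.Series:
        """cell_line_id -> solid / non_solid."""
        return self.samples.set_index("cell_line_id")["tumor_class"]

    def pathway_map(self) -> pd.Series:
        """drug_id -> target pathway."""
        return self.drugs.set_index("drug_id")["pathway"]

    def observed_response(self) -> pd.DataFrame:
        """Response rows with a finite AUC (the usable training records)."""
        return self.response[np.isfinite(self.response["auc"].to_numpy(float))]

    def drug_response(self, drug_id: str) -> pd.Series:
        """Observed AUC for one drug, indexed by cell line."""
        obs = self.observed_response()
        sub = obs[obs["drug_id"] == drug_id]
        return sub.set_index("cell_line_id")["auc"].astype(float)

    def check_invariants(self) -> None:
        """Validate the post-QC contract; raises IntegrityError on violation."""
        lines = set(self.expression.index)
        annotated = set(self.samples["cell_line_id"])
        if lines != annotated:
            raise IntegrityError("expression and sample annotation cover different cell lines")
        responded = set(self.observed_response()["cell_line_id"])
        missing = lines - responded
        if missing:
            raise IntegrityError(f"cell lines without any response record: {sorted(missing)[:5]}")
        dup = self.response.duplicated(subset=["cell_line_id", "drug_id"])
        if dup.any():
            raise IntegrityError("duplicated (cell_line_id, drug_id) response rows")
        unknown = set(self.response["drug_id"]) - set(self.drugs["drug_id"])
        if unknown:
            raise IntegrityError(f"response drugs missing from drug annotation: {sorted(unknown)[:5]}")


@dataclass
class QCReport:
    n_lines_in: int
    n_lines_out: int
    n_drugs_in: int
    n_drugs_out: int
    dropped_lines: list = field(default_factory=list)  # (cell_line_id, reason)
    dropped_drugs: list = field(default_factory=list)  # (drug_id, reason)

    def to_dict(self) -> dict:
        return {
            "n_lines_in": self.n_lines_in,
            "n_lines_out": self.n_lines_out,
            "n_drugs_in": self.n_drugs_in,
            "n_drugs_out": self.n_drugs_out,
            "dropped_lines": [list(t) for t in self.dropped_lines],
            "dropped_drugs": [list(t) for t in self.dropped_drugs],
        }


def _read_tsv(path, required: Iterable[str], table: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table {path}: missing required column '{col}'")
    return df


def _parse_numeric(raw: pd.Series, table: str, allow_missing: bool = False) -> pd.Series:
    values = pd.to_numeric(raw.str.strip(), errors="coerce")
    missing_token = raw.str.strip().isin(NA_TOKENS)
    bad = values.isna() & ~missing_token
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{table}: non-numeric value '{raw.iloc[row]}' in column '{raw.name}' at data row {row + 1}"
        )
    if not allow_missing and missing_token.any():
        row = int(np.flatnonzero(missing_token.to_numpy())[0])
        raise ParseError(f"{table}: missing value in column '{raw.name}' at data row {row + 1}")
    inf = np.isinf(values.to_numpy(float))
    if inf.any():
        row = int(np.flatnonzero(inf)[0])
        raise ParseError(f"{table}: non-finite value in column '{raw.name}' at data row {row + 1}")
    return values.astype(float)


def load_expression(path) -> pd.DataFrame:
    df = _read_tsv(path, ["cell_line_id"], "expression")
    if df["cell_line_id"].duplicated().any():
        dup = df.loc[df["cell_line_id"].duplicated(), "cell_line_id"].iloc[0]
        raise IntegrityError(f"expression: duplicated cell_line_id '{dup}'")
    out = pd.DataFrame(index=pd.Index(df["cell_line_id"], name="cell_line_id"))
    for col in df.columns[1:]:
        out[col] = _parse_numeric(df[col], "expression").to_numpy()
    return out


def load_samples(path) -> pd.DataFrame:
    df = _read_tsv(path, SAMPLE_COLUMNS, "samples")[list(SAMPLE_COLUMNS)]
    if df["cell_line_id"].duplicated().any():
        dup = df.loc[df["cell_line_id"].duplicated(), "cell_line_id"].iloc[0]
        raise IntegrityError(f"samples: duplicated cell_line_id '{dup}'")
    bad = ~df["tumor_class"].isin(TUMOR_CLASSES)
    if bad.any():
        raise SchemaError(
            f"samples: tumor_class must be one of {TUMOR_CLASSES}, got '{df.loc[bad, 'tumor_class'].iloc[0]}'"
        )
    return df.reset_index(drop=True)


def load_response(path) -> pd.DataFrame:
    df = _read_tsv(path, RESPONSE_COLUMNS, "response")[list(RESPONSE_COLUMNS)]
    dup = df.duplicated(subset=["cell_line_id", "drug_id"])
    if dup.any():
        pair = df.loc[dup, ["cell_line_id", "drug_id"]].iloc[0]
        raise IntegrityError(
            f"response: duplicated record for ({pair['cell_line_id']}, {pair['drug_id']})"
        )
    df["auc"] = _parse_numeric(df["auc"], "response", allow_missing=True)
    return df.reset_index(drop=True)


def load_drugs(path) -> pd.DataFrame:
    df = _read_tsv(path, DRUG_COLUMNS, "drugs")[list(DRUG_COLUMNS)]
    if df["drug_id"].duplicated().any():
        dup = df.loc[df["drug_id"].duplicated(), "drug_id"].iloc[0]
        raise IntegrityError(f"drugs: duplicated drug_id '{dup}'")
    return df.reset_index(drop=True)


def load_dataset(expression_path, samples_path, response_path, drugs_path) -> ScreenDataset:
    """Load the four screen tables; no QC is applied, file order is preserved."""
    return ScreenDataset(
        expression=load_expression(expression_path),
        samples=load_samples(samples_path),
        response=load_response(response_path),
        drugs=load_drugs(drugs_path),
    )


def write_dataset(ds: ScreenDataset, out_dir) -> dict:
    """Write the four tables as TSV into ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "response": out / "response.tsv",
        "drugs": out / "drugs.tsv",
    }
    ds.expression.to_csv(paths["expression"], sep="\t")
    ds.samples.to_csv(paths["samples"], sep="\t", index=False)
    ds.response.to_csv(paths["response"], sep="\t", index=False)
    ds.drugs.to_csv(paths["drugs"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def _line_filter(ds: ScreenDataset, lines: list, drugs: set) -> tuple[list, list]:
    """Keep lines with expression, annotation and >=1 observed AUC among ``drugs``."""
    expr = set(ds.expression.index)
    annotated = set(ds.samples["cell_line_id"])
    obs = ds.observed_response()
    responded = set(obs.loc[obs["drug_id"].isin(drugs), "cell_line_id"])
    kept, dropped = [], []
    for cl in lines:
        if cl not in expr:
            dropped.append((cl, "missing expression"))
        elif cl not in annotated:
            dropped.append((cl, "missing annotation"))
        elif cl not in responded:
            dropped.append((cl, "missing response"))
        else:
            kept.append(cl)
    return kept, dropped


def _drug_filter(
    ds: ScreenDataset, drugs: list, kept_lines: list, min_coverage: float
) -> tuple[list, list]:
    """Keep drugs observed in >= min_coverage of ``kept_lines`` and >1 cancer type."""
    obs = ds.observed_response()
    obs = obs[obs["cell_line_id"].isin(set(kept_lines))]
    tissue = ds.tissue_map()
    n_lines = len(kept_lines)
    counts = obs.groupby("drug_id")["cell_line_id"].agg(list)
    kept, dropped = [], []
    for drug in drugs:
        lines = counts.get(drug, [])
        if len(lines) < min_coverage * n_lines:
            dropped.append((drug, f"screened in {len(lines)}/{n_lines} lines (<{min_coverage:.0%})"))
            continue
        n_types = tissue.reindex(lines).nunique()
        if n_types <= 1:
            dropped.append((drug, "screened in a single cancer type"))
            continue
        kept.append(drug)
    return kept, dropped


def apply_qc_filters(
    ds: ScreenDataset, min_drug_coverage: float = 0.10
) -> tuple[ScreenDataset, QCReport]:
    """Apply the full-information line filter, then the drug coverage filters.

    Cell lines must have expression, a tissue annotation and at least one observed
    AUC; drugs must then be observed in at least ``min_drug_coverage`` of the
    retained lines (strictly fewer is dropped) and in more than one cancer type.
    The lines-then-drugs pass repeats until stable so that the operation is
    idempotent; the coverage denominator is always the current post-line-filter
    line count.
    """
    if not 0 < min_drug_coverage < 1:
        raise ConfigError(f"min_drug_coverage must be in (0, 1), got {min_drug_coverage}")

    all_lines = list(
        dict.fromkeys(
            list(ds.expression.index)
            + list(ds.samples["cell_line_id"])
            + list(ds.response["cell_line_id"])
        )
    )
    all_drugs = list(dict.fromkeys(list(ds.response["drug_id"]) + list(ds.drugs["drug_id"])))

    lines, drugs = list(all_lines), list(all_drugs)
    dropped_lines: list = []
    dropped_drugs: list = []
    while True:
        kept_lines, dl = _line_filter(ds, lines, set(drugs))
        kept_drugs, dd = _drug_filter(ds, drugs, kept_lines, min_drug_coverage)
        dropped_lines.extend(dl)
        dropped_drugs.extend(dd)
        stable = (kept_lines == lines) and (kept_drugs == drugs)
        lines, drugs = kept_lines, kept_drugs
        if stable:
            break
        if not lines or not drugs:
            raise QCError("no data survives QC")
    if not lines or not drugs:
        raise QCError("no data survives QC")

    line_set, drug_set = set(lines), set(drugs)
    response = ds.response[
        ds.response["cell_line_id"].isin(line_set) & ds.response["drug_id"].isin(drug_set)
    ].reset_index(drop=True)
    filtered = ScreenDataset(
        expression=ds.expression.loc[[cl for cl in ds.expression.index if cl in line_set]],
        samples=ds.samples[ds.samples["cell_line_id"].isin(line_set)].reset_index(drop=True),
        response=response,
        drugs=ds.drugs[ds.drugs["drug_id"].isin(set(response["drug_id"]))].reset_index(drop=True),
    )
    report = QCReport(
        n_lines_in=len(all_lines),
        n_lines_out=len(lines),
        n_drugs_in=len(all_drugs),
        n_drugs_out=len(filtered.drugs),
        dropped_lines=dropped_lines,
        dropped_drugs=dropped_drugs + [
            (d, "no response records after line filtering")
            for d in all_drugs
            if d not in drug_set and d not in {x for x, _ in dropped_drugs}
        ],
    )
    # recount drug drops so that n_out = n_in - |dropped|
    report.n_drugs_out = report.n_drugs_in - len(report.dropped_drugs)
    filtered.check_invariants()
    return filtered, report


def write_qc_report(report: QCReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
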