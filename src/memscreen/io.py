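"""Readers and writers for the pipeline's table dialects, plus run logging.

Proteomic tables are tab-separated (matching search-engine export
convention); clinical and plate tables are comma-separated.  All files
are UTF-8 with a required header row.  On ingest, empty cells, ``NA`` and
literal zeros in area columns parse as MISSING (a peak area of an
unidentified protein is absent, not zero, in engine exports).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .pharm import DoseResponseDataset, FourPLFit, GrowthCurve, viability_from_od
from .quantnorm import QuantTable, QuantTableError
from .screen import AnnotationTable, CandidateTable, VennPartition
from .tma import COVARIATE_LEVELS, TMACase, AssociationReport

RAW_AREA_PREFIX = "Area_"
NORM_AREA_PREFIX = "NormArea_"
QUANT_META_COLUMNS = ("Accession", "Gene", "Description")

TMA_COLUMNS = (
    "case_id", "tissue_class", "ihc_score", "age_group", "pt_status",
    "grade", "ln_metastasis", "stage", "her2_status",
)

PLATE_COLUMNS = (
    "drug", "cotreatment_drug", "cotreatment_dose_uM", "concentration_uM",
    "experiment", "replicate", "od570", "od650",
)


class TableFormatError(ValueError):
    """Raised when an on-disk table does not match its dialect."""


# ----------------------------------------------------------------------
# quant tables
# ----------------------------------------------------------------------

def read_quant_table(path, cell_line: Optional[str] = None) -> QuantTable:
    """Read a tab-separated protein quant export.

    Expected header: ``Accession  Gene  Description  Area_<rep>...`` (or
    ``NormArea_`` columns for normalized tables).  Empty cells, ``NA``
    and 0 parse as MISSING.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in QUANT_META_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    norm_cols = [c for c in df.columns if c.startswith(NORM_AREA_PREFIX)]
    raw_cols = [c for c in df.columns if c.startswith(RAW_AREA_PREFIX)]
    area_cols, prefix, normalized = (
        (norm_cols, NORM_AREA_PREFIX, True) if norm_cols else (raw_cols, RAW_AREA_PREFIX, False)
    )
    if not area_cols:
        raise TableFormatError(
            f"{path.name}: no {RAW_AREA_PREFIX}* or {NORM_AREA_PREFIX}* columns"
        )
    dup = df["Accession"][df["Accession"].duplicated()].unique().tolist()
    if dup:
        raise TableFormatError(f"{path.name}: duplicate accessions {dup}")

    areas = {}
    for col in area_cols:
        raw = df[col].str.strip()
        missing = raw.isin(["", "NA", "na", "NaN", "nan"])
        parsed = pd.to_numeric(raw.mask(missing), errors="coerce")
        bad = ~missing & parsed.isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise TableFormatError(
                f"{path.name}: non-numeric area {raw.iloc[row]!r} "
                f"(row {row + 2}, column {col})"
            )
        areas[col.removeprefix(prefix)] = parsed.mask(parsed == 0)
    area_frame = pd.DataFrame(areas)
    area_frame.index = pd.Index(df["Accession"], name="accession")
    proteins = pd.DataFrame(
        {"gene": df["Gene"].to_numpy(), "description": df["Description"].to_numpy()},
        index=area_frame.index,
    )
    try:
        return QuantTable(
            cell_line=cell_line or path.stem,
            proteins=proteins,
            areas=area_frame,
            normalized=normalized,
        )
    except QuantTableError as exc:
        raise TableFormatError(f"{path.name}: {exc}") from exc


def write_quant_table(table: QuantTable, path) -> None:
    prefix = NORM_AREA_PREFIX if table.normalized else RAW_AREA_PREFIX
    out = pd.DataFrame(
        {
            "Accession": table.areas.index,
            "Gene": table.proteins["gene"].to_numpy(),
            "Description": table.proteins["description"].to_numpy(),
        }
    )
    for rep in table.areas.columns:
        out[f"{prefix}{rep}"] = table.areas[rep].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_summary_table(summaries: pd.DataFrame, path) -> None:
    """Write a per-protein summary frame as the summary TSV dialect."""
    out = pd.DataFrame(
        {
            "Accession": summaries.index,
            "Gene": summaries["gene"].to_numpy(),
            "Description": summaries["description"].to_numpy(),
            "N_Detected": summaries["n_detected"].to_numpy(),
            "Mean_NormArea": summaries["mean_norm_area"].to_numpy(),
            "SD": summaries["sd_norm_area"].to_numpy(),
            "CV_Percent": summaries["cv_percent"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_candidate_table(candidates: CandidateTable, path) -> None:
    out = candidates.frame.rename(
        columns={
            "accession": "Accession",
            "gene": "Gene",
            "protein": "Protein",
            "mean_norm_area": "Mean_NormArea",
            "sd_norm_area": "SD",
            "cv_percent": "CV_Percent",
        }
    )
    out.to_csv(path, sep="\t", index=True, index_label="Rank",
               na_rep="NA", float_format="%.6g")


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------

def read_annotation(path) -> AnnotationTable:
    """Read an ``Accession<TAB>Localization`` table (semicolon-separated terms)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Accession", "Localization"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    dup = df["Accession"][df["Accession"].duplicated()].unique().tolist()
    if dup:
        raise TableFormatError(f"{path.name}: duplicate accessions {dup}")
    mapping = {
        row.Accession: [t for t in row.Localization.split(";")]
        for row in df.itertuples()
    }
    return AnnotationTable.from_mapping(mapping)


def write_annotation(annotation: AnnotationTable, path) -> None:
    out = pd.DataFrame(
        {
            "Accession": list(annotation.terms),
            "Localization": [
                "; ".join(sorted(terms)) for terms in annotation.terms.values()
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# TMA cohort
# ----------------------------------------------------------------------

def read_tma_cases(path) -> List[TMACase]:
    """Read the TMA cohort CSV; empty cells are missing values."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("case_id", "tissue_class", "ihc_score"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    cases = []
    for row in df.to_dict(orient="records"):
        score = row["ihc_score"].strip()
        covariates = {
            cov: (row[cov].strip() or None)
            for cov in COVARIATE_LEVELS
            if cov in df.columns
        }
        cases.append(
            TMACase(
                case_id=row["case_id"],
                tissue_class=row["tissue_class"],
                ihc_score=int(score) if score else None,
                covariates=covariates,
            )
        )
    return cases


def write_tma_cases(cases: Sequence[TMACase], path) -> None:
    rows = []
    for case in cases:
        row = {
            "case_id": case.case_id,
            "tissue_class": case.tissue_class,
            "ihc_score": "" if case.ihc_score is None else case.ihc_score,
        }
        for cov in COVARIATE_LEVELS:
            row[cov] = case.covariates.get(cov) or ""
        rows.append(row)
    pd.DataFrame(rows, columns=list(TMA_COLUMNS)).to_csv(path, index=False)


def write_association_report(report: AssociationReport, tsv_path, json_path=None) -> None:
    report.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {"rule": report.rule, "alpha": report.alpha, "comparisons": {}}
        for name, row in report.rows.items():
            if row.result is None:
                payload["comparisons"][name] = {"error": row.error}
            else:
                payload["comparisons"][name] = {
                    "statistic": row.result.statistic,
                    "df": row.result.df,
                    "p_value": row.result.p_value,
                    "expected_counts": row.result.expected_counts.tolist(),
                    "low_expected_warning": row.result.low_expected_warning,
                    "n_dropped": row.table.n_dropped if row.table else None,
                    "counts": row.table.counts.to_dict() if row.table else None,
                }
        Path(json_path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


# ----------------------------------------------------------------------
# dose-response plates
# ----------------------------------------------------------------------

def read_plate_csv(path) -> List[DoseResponseDataset]:
    """Read a plate-style dose-response CSV into per-condition datasets.

    Rows with ``concentration_uM == 0`` are vehicle controls; treated
    wells are converted to viability fractions against the mean
    background-corrected vehicle signal of the same condition and
    experiment.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in PLATE_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    df["cotreatment_drug"] = df["cotreatment_drug"].fillna("")
    datasets = []
    for (drug, co_drug, co_dose), grp in df.groupby(
        ["drug", "cotreatment_drug", "cotreatment_dose_uM"], dropna=False
    ):
        vehicle = grp[grp["concentration_uM"] == 0]
        treated = grp[grp["concentration_uM"] > 0]
        if vehicle.empty:
            raise TableFormatError(f"{path.name}: no vehicle rows for {drug!r}")
        doses = np.sort(treated["concentration_uM"].unique())
        experiments = np.sort(treated["experiment"].unique())
        replicates = np.sort(treated["replicate"].unique())
        viability = np.full((len(doses), len(experiments), len(replicates)), np.nan)
        vehicle_means = {
            exp: (sub["od570"] - sub["od650"]).mean()
            for exp, sub in vehicle.groupby("experiment")
        }
        for row in treated.itertuples():
            d = int(np.searchsorted(doses, row.concentration_uM))
            e = int(np.searchsorted(experiments, row.experiment))
            r = int(np.searchsorted(replicates, row.replicate))
            viability[d, e, r] = viability_from_od(
                row.od570, row.od650, vehicle_means[row.experiment]
            )
        cotreatment = (str(co_drug), float(co_dose)) if co_drug else None
        datasets.append(
            DoseResponseDataset(
                drug=str(drug),
                concentrations=doses,
                viability=viability,
                cotreatment=cotreatment,
            )
        )
    return datasets


def write_plate_csv(datasets: Sequence[DoseResponseDataset], path) -> None:
    """Write datasets in plate dialect (simulation convention: OD = viability).

    Vehicle rows carry od570 = 1 and od650 = 0 so that reading the file
    back reconstructs the viability fractions exactly.
    """
    rows = []
    for ds in datasets:
        co_drug, co_dose = ds.cotreatment if ds.cotreatment else ("", "")
        for e in range(ds.viability.shape[1]):
            for r in range(ds.viability.shape[2]):
                rows.append((ds.drug, co_drug, co_dose, 0.0, e + 1, r + 1, 1.0, 0.0))
                for d, conc in enumerate(ds.concentrations):
                    rows.append(
                        (ds.drug, co_drug, co_dose, conc, e + 1, r + 1,
                         float(ds.viability[d, e, r]), 0.0)
                    )
    pd.DataFrame(rows, columns=list(PLATE_COLUMNS)).to_csv(path, index=False)


def write_fit_report(fits: Dict[str, FourPLFit], path) -> None:
    payload = {}
    for name, fit in fits.items():
        payload[name] = {
            "bottom": fit.bottom,
            "top": fit.top,
            "hill_slope": fit.hill_slope,
            "ic50": fit.ic50,
            "ic50_mean": fit.ic50_mean,
            "ic50_sd": fit.ic50_sd,
            "per_experiment_ic50s": fit.per_experiment_ic50s.tolist(),
            "converged": fit.converged,
            "rss": fit.rss,
            "ic50_unidentifiable": fit.ic50_unidentifiable,
            "ic50_extrapolated": fit.ic50_extrapolated,
        }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def write_venn_json(venn: VennPartition, path) -> None:
    Path(path).write_text(json.dumps(venn.to_dict(), indent=2), encoding="utf-8")


# ----------------------------------------------------------------------
# growth curves
# ----------------------------------------------------------------------

def read_growth_curves(path) -> List[GrowthCurve]:
    """Read a ``treatment,timepoint_h,replicate,od`` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("treatment", "timepoint_h", "replicate", "od"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    curves = []
    for treatment, grp in df.groupby("treatment"):
        times = np.sort(grp["timepoint_h"].unique())
        reps = np.sort(grp["replicate"].unique())
        od = np.full((len(times), len(reps)), np.nan)
        for row in grp.itertuples():
            t = int(np.searchsorted(times, row.timepoint_h))
            r = int(np.searchsorted(reps, row.replicate))
            od[t, r] = row.od
        curves.append(GrowthCurve(str(treatment), times, od))
    return curves


def write_growth_curves(curves: Sequence[GrowthCurve], path) -> None:
    rows = []
    for curve in curves:
        for t, time_h in enumerate(curve.timepoints):
            for r in range(curve.od_values.shape[1]):
                rows.append((curve.treatment, time_h, r + 1, curve.od_values[t, r]))
    pd.DataFrame(
        rows, columns=["treatment", "timepoint_h", "replicate", "od"]
    ).to_csv(path, index=False)


# ----------------------------------------------------------------------
# run log
# ----------------------------------------------------------------------

@dataclass
class RunLog:
    """Structured record of one pipeline invocation."""

    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    events: List[dict] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    input_checksums: Dict[str, str] = field(default_factory=dict)

    def event(self, message: str, **details) -> None:
        self.events.append(
            {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "message": message, **details}
        )

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        self.event("warning", detail=message)

    def checksum(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[str(path)] = digest

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
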