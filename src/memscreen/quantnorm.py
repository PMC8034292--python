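"""Label-free, peak-area-based normalization of protein quantification tables.

Protein-level peak areas exported from an identification/quantification
engine are placed on a common scale by total-ion normalization: each
replicate (one LC-MS/MS run) is divided by its total peak area and scaled
to parts-per-10^6, so a value of 70 means the protein carried 70 ppm of the
run's summed precursor signal.  A cell that is missing means the protein
was not identified in that run; missing cells are excluded from the total,
from means and from standard deviations (they are absent observations, not
zeros).  Per-protein replicate summaries (detection count at a normalized-
area floor, mean, sample SD, %CV) are the row model consumed by the
candidate screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Scale of the normalized unit: parts per 10^6 of a run's total peak area.
PPM_SCALE = 1_000_000.0

#: Default limit of detection on the normalized-area scale.
DEFAULT_DETECTION_THRESHOLD = 70.0

PROTEIN_COLUMNS = ("gene", "description")


class QuantTableError(ValueError):
    """Raised when a quantification table violates its invariants."""


@dataclass
class QuantTable:
    """A protein x replicate peak-area matrix for one cell line.

    Parameters
    ----------
    cell_line:
        Label of the biological sample (e.g. a cell-line name).
    proteins:
        DataFrame indexed by accession with columns ``gene`` and
        ``description``.
    areas:
        DataFrame indexed by accession (same index as ``proteins``), one
        column per biological replicate.  ``NaN`` encodes MISSING: the
        protein was not identified in that replicate's run.
    normalized:
        False for raw engine exports (arbitrary intensity units), True
        once values are normalized areas in parts-per-10^6.
    """

    cell_line: str
    proteins: pd.DataFrame
    areas: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def accessions(self) -> pd.Index:
        return self.areas.index

    @property
    def replicates(self) -> pd.Index:
        return self.areas.columns

    @property
    def n_replicates(self) -> int:
        return self.areas.shape[1]

    def validate(self) -> None:
        if self.areas.shape[1] < 1:
            raise QuantTableError("table needs at least one replicate column")
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].unique().tolist()
            raise QuantTableError(f"duplicate accessions: {dups}")
        if not self.areas.index.equals(self.proteins.index):
            raise QuantTableError("proteins and areas must share the same accession index")
        values = self.areas.to_numpy(dtype=float)
        if np.any(values[~np.isnan(values)] < 0):
            bad = self.areas[(self.areas < 0).any(axis=1)].index.tolist()
            raise QuantTableError(f"negative peak areas for accessions: {bad}")
        if np.isnan(values).all(axis=1).any():
            bad = self.areas.index[np.isnan(values).all(axis=1)].tolist()
            raise QuantTableError(f"proteins with no identified replicate: {bad}")

    def copy(self) -> "QuantTable":
        return replace(self, proteins=self.proteins.copy(), areas=self.areas.copy())


@dataclass(frozen=True)
class ProteinSummary:
    """Per-protein replicate summary (one row of a candidate table).

    ``cv_percent`` is ``nan`` when undefined, i.e. fewer than two
    identified replicates or a zero mean.
    """

    accession: str
    n_replicates_total: int
    n_detected: int
    mean_norm_area: float
    sd_norm_area: float
    cv_percent: float

    @property
    def cv_defined(self) -> bool:
        return not np.isnan(self.cv_percent)


def normalize_replicate(raw_areas) -> np.ndarray:
    """Normalize one replicate column to parts-per-10^6 of its total.

    Missing entries (NaN) are excluded from the total and stay missing.

    Raises
    ------
    QuantTableError
        If every entry is missing, the present total is zero, or any
        present value is negative.
    """
    values = np.asarray(raw_areas, dtype=float)
    present = ~np.isnan(values)
    if not present.any():
        raise QuantTableError("empty replicate: all values missing")
    if np.any(values[present] < 0):
        rows = np.nonzero(present & (values < 0))[0].tolist()
        raise QuantTableError(f"negative peak area at rows {rows}")
    total = values[present].sum()
    if total <= 0:
        raise QuantTableError("empty replicate: total present area is zero")
    out = np.full_like(values, np.nan)
    out[present] = values[present] / total * PPM_SCALE
    return out


def normalize_table(table: QuantTable) -> QuantTable:
    """Normalize every replicate column of a table independently.

    Protein order and the missingness pattern are preserved; each output
    column sums to 10^6 over its present entries.
    """
    columns = {}
    for rep in table.areas.columns:
        try:
            columns[rep] = normalize_replicate(table.areas[rep].to_numpy())
        except QuantTableError as exc:
            raise QuantTableError(f"replicate {rep!r}: {exc}") from exc
    areas = pd.DataFrame(columns, index=table.areas.index)
    return QuantTable(
        cell_line=table.cell_line,
        proteins=table.proteins.copy(),
        areas=areas,
        normalized=True,
    )


def summarize_protein(
    norm_values,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    accession: str = "",
) -> ProteinSummary:
    """Summarize one protein's normalized areas across replicates.

    Mean and SD are over identified (non-missing) replicates only; the SD
    uses the sample (n-1) denominator.  ``n_detected`` counts replicates
    whose value is at or above the detection threshold (inclusive, so a
    value exactly at the floor is detected); missing counts as not
    detected.
    """
    values = np.asarray(norm_values, dtype=float)
    if values.size < 1:
        raise QuantTableError("at least one replicate required")
    present = values[~np.isnan(values)]
    n_detected = int((present >= detection_threshold).sum())
    mean = float(present.mean()) if present.size else float("nan")
    sd = float(present.std(ddof=1)) if present.size >= 2 else float("nan")
    if present.size >= 2 and mean != 0:
        cv = 100.0 * sd / mean
    else:
        cv = float("nan")
    return ProteinSummary(
        accession=accession,
        n_replicates_total=int(values.size),
        n_detected=n_detected,
        mean_norm_area=mean,
        sd_norm_area=sd,
        cv_percent=cv,
    )


def summarize_table(
    table: QuantTable,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Per-protein summaries for a normalized table, as a DataFrame.

    Returns a frame indexed by accession with columns ``gene``,
    ``description``, ``n_replicates_total``, ``n_detected``,
    ``mean_norm_area``, ``sd_norm_area``, ``cv_percent``.
    """
    values = table.areas.to_numpy(dtype=float)
    present = ~np.isnan(values)
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=1)
        sd = np.full(values.shape[0], np.nan)
        multi = n_present >= 2
        if multi.any():
            sd[multi] = np.nanstd(values[multi], axis=1, ddof=1)
        cv = np.where((n_present >= 2) & (mean != 0), 100.0 * sd / mean, np.nan)
    n_detected = np.nansum(values >= detection_threshold, axis=1).astype(int)
    out = pd.DataFrame(
        {
            "gene": table.proteins["gene"],
            "description": table.proteins["description"],
            "n_replicates_total": table.n_replicates,
            "n_detected": n_detected,
            "mean_norm_area": mean,
            "sd_norm_area": sd,
            "cv_percent": cv,
        },
        index=table.areas.index,
    )
    out.index.name = "accession"
    return out
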