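"""Cancer-exclusive membrane-protein candidate screen.

The screen turns per-protein replicate summaries of a cancer cell line and
a benign control line into a ranked candidate table through a cascade of
filters:

1. membrane refinement — keep proteins whose subcellular-localization
   annotation contains a membrane term;
2. detection in the cancer line — present at or above the normalized-area
   floor in at least a fraction (default 75%) of biological replicates;
3. exclusivity — *not* expressed in the control line, where control
   expression is defined as detection in at least three control
   replicates at the same floor;
4. replicate consistency — %CV across identified replicates at or below a
   ceiling (default 40%).

Survivors are ranked by mean normalized area (descending, accession as a
deterministic tie-break) and truncated to the top N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Literal, Mapping, Set

import numpy as np
import pandas as pd

from .quantnorm import DEFAULT_DETECTION_THRESHOLD, ProteinSummary

Role = Literal["cancer", "control"]

#: Subcellular-localization terms counted as membrane-associated.
DEFAULT_MEMBRANE_TERMS: FrozenSet[str] = frozenset(
    {
        "membrane",
        "cell membrane",
        "plasma membrane",
        "mitochondrion membrane",
        "endoplasmic reticulum membrane",
        "golgi membrane",
    }
)


class ScreenConfigError(ValueError):
    """Raised for invalid screening thresholds."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the candidate-selection cascade.

    detection_threshold:
        Normalized-area floor below which a replicate measurement does not
        count as a detection (inclusive comparison).
    presence_fraction:
        Fraction of cancer replicates that must be detections (>=).
    control_min_detected_reps:
        Number of detected control replicates that defines expression in
        the control line; candidates must fall below it.
    cv_max_percent:
        Ceiling on the %CV across identified replicates (inclusive).
    top_n:
        Number of rows kept in the ranked candidate table.
    """

    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD
    presence_fraction: float = 0.75
    control_min_detected_reps: int = 3
    cv_max_percent: float = 40.0
    top_n: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.presence_fraction <= 1:
            raise ScreenConfigError("presence_fraction must be in (0, 1]")
        if self.detection_threshold <= 0 or self.cv_max_percent <= 0:
            raise ScreenConfigError("thresholds must be positive")
        if self.control_min_detected_reps < 1:
            raise ScreenConfigError("control_min_detected_reps must be >= 1")
        if self.top_n < 1:
            raise ScreenConfigError("top_n must be >= 1")

    def to_dict(self) -> Dict[str, float]:
        return {
            "detection_threshold": self.detection_threshold,
            "presence_fraction": self.presence_fraction,
            "control_min_detected_reps": self.control_min_detected_reps,
            "cv_max_percent": self.cv_max_percent,
            "top_n": self.top_n,
        }


@dataclass
class AnnotationTable:
    """Accession -> subcellular-localization terms, with a membrane flag.

    Terms are lowercase-normalized on construction.  An accession is
    membrane-associated iff any of its terms is in ``membrane_terms``.
    """

    terms: Dict[str, FrozenSet[str]]
    membrane_terms: FrozenSet[str] = DEFAULT_MEMBRANE_TERMS

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Iterable[str]],
        membrane_terms: FrozenSet[str] = DEFAULT_MEMBRANE_TERMS,
    ) -> "AnnotationTable":
        terms = {
            str(acc): frozenset(t.strip().lower() for t in items if t.strip())
            for acc, items in mapping.items()
        }
        return cls(terms=terms, membrane_terms=membrane_terms)

    def is_membrane(self, accession: str) -> bool:
        return bool(self.terms.get(accession, frozenset()) & self.membrane_terms)

    @property
    def membrane_accessions(self) -> Set[str]:
        return {acc for acc in self.terms if self.is_membrane(acc)}

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class DetectionCall:
    accession: str
    cell_line: str
    detected: bool
    n_detected: int
    rule_applied: str


@dataclass(frozen=True)
class MembraneFilterReport:
    n_input: int
    n_retained: int
    n_unannotated: int
    n_non_membrane: int


@dataclass(frozen=True)
class VennPartition:
    """Two-set comparison of detected accessions (A vs B)."""

    common: FrozenSet[str]
    unique_a: FrozenSet[str]
    unique_b: FrozenSet[str]

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)

    def to_dict(self) -> dict:
        return {
            "common": self.n_common,
            "unique_a": self.n_unique_a,
            "unique_b": self.n_unique_b,
            "common_members": sorted(self.common),
            "unique_a_members": sorted(self.unique_a),
            "unique_b_members": sorted(self.unique_b),
        }


@dataclass
class CandidateTable:
    """Ranked Top-N output of the screen, plus provenance."""

    frame: pd.DataFrame  # rank-indexed: accession, gene, protein, mean, sd, cv
    config: ScreenConfig
    cancer_line: str = ""
    control_line: str = ""
    membrane_report: MembraneFilterReport | None = None

    @property
    def accessions(self) -> Set[str]:
        return set(self.frame["accession"])

    def __len__(self) -> int:
        return len(self.frame)


def call_detection(summary: ProteinSummary, role: Role, config: ScreenConfig,
                   cell_line: str = "") -> DetectionCall:
    """Apply the cancer- or control-line detection rule to one summary.

    Cancer rule: detected iff the detected fraction of replicates is at
    least ``presence_fraction``.  Control rule: detected (i.e. expressed
    in the control line) iff at least ``control_min_detected_reps``
    replicates are detections.
    """
    if role == "cancer":
        detected = (
            summary.n_detected / summary.n_replicates_total
            >= config.presence_fraction
        )
        rule = "cancer-rule"
    elif role == "control":
        detected = summary.n_detected >= config.control_min_detected_reps
        rule = "control-rule"
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown role {role!r}")
    return DetectionCall(
        accession=summary.accession,
        cell_line=cell_line,
        detected=bool(detected),
        n_detected=summary.n_detected,
        rule_applied=rule,
    )


def detected_accessions(summaries: pd.DataFrame, role: Role,
                        config: ScreenConfig) -> Set[str]:
    """Accessions of a summary frame passing the role's detection rule."""
    if role == "cancer":
        mask = (
            summaries["n_detected"] / summaries["n_replicates_total"]
            >= config.presence_fraction
        )
    else:
        mask = summaries["n_detected"] >= config.control_min_detected_reps
    return set(summaries.index[mask])


def filter_membrane(
    summaries: pd.DataFrame, annotation: AnnotationTable
) -> tuple[pd.DataFrame, MembraneFilterReport]:
    """Retain membrane-associated proteins; report what was dropped.

    Accessions missing from the annotation are dropped (and counted
    separately from annotated-but-non-membrane ones).
    """
    annotated = summaries.index.map(lambda a: a in annotation)
    membrane = summaries.index.map(annotation.is_membrane)
    report = MembraneFilterReport(
        n_input=len(summaries),
        n_retained=int(membrane.to_numpy().sum()),
        n_unannotated=int((~annotated.to_numpy()).sum()),
        n_non_membrane=int((annotated.to_numpy() & ~membrane.to_numpy()).sum()),
    )
    return summaries[membrane.to_numpy()], report


def compute_venn(detected_a: Iterable[str], detected_b: Iterable[str]) -> VennPartition:
    """Partition two detected-accession sets into common/unique-A/unique-B."""
    a, b = set(detected_a), set(detected_b)
    return VennPartition(
        common=frozenset(a & b),
        unique_a=frozenset(a - b),
        unique_b=frozenset(b - a),
    )


def select_candidates(
    cancer_summaries: pd.DataFrame,
    control_summaries: pd.DataFrame,
    annotation: AnnotationTable,
    config: ScreenConfig = ScreenConfig(),
    cancer_line: str = "",
    control_line: str = "",
) -> CandidateTable:
    """Run the full cascade and return the ranked Top-N candidate table.

    Both summary frames must have been computed with the same detection
    threshold as ``config.detection_threshold``.  A protein absent from
    the control summary frame was never identified in the control line
    and trivially fails the control expression rule.
    """
    membrane, report = filter_membrane(cancer_summaries, annotation)
    cancer_detected = detected_accessions(membrane, "cancer", config)
    control_expressed = detected_accessions(control_summaries, "control", config)
    keep = membrane.loc[sorted(cancer_detected - control_expressed)]
    keep = keep[keep["cv_percent"] <= config.cv_max_percent]
    # rows are already in accession order; a stable sort on mean therefore
    # breaks ties lexicographically by accession
    keep = keep.sort_values("mean_norm_area", ascending=False, kind="mergesort")
    keep = keep.head(config.top_n)
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(keep) + 1),
            "accession": keep.index,
            "gene": keep["gene"].to_numpy(),
            "protein": keep["description"].to_numpy(),
            "mean_norm_area": keep["mean_norm_area"].to_numpy(),
            "sd_norm_area": keep["sd_norm_area"].to_numpy(),
            "cv_percent": keep["cv_percent"].to_numpy(),
        }
    ).set_index("rank")
    return CandidateTable(
        frame=frame,
        config=config,
        cancer_line=cancer_line,
        control_line=control_line,
        membrane_report=report,
    )
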