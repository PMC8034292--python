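"""Seeded generators for every pipeline stage, with recoverable ground truth.

Three independent generator namespaces emulate the statistical structure
of the study's three data layers:

* a label-free proteomics experiment — log-normal protein abundances over
  a shared universe, four biological replicates per cell line with
  multiplicative replicate noise, abundance-dependent dropout, and a
  planted set of cancer-exclusive membrane proteins per cancer line;
* a tissue-microarray cohort — benign and carcinoma cases with a
  group-dependent positivity probability, ordinal 1-4 scores, and
  clinicopathological covariates tied to positivity through a logistic
  model;
* MTT dose-response plates — 4PL viability curves with additive Gaussian
  noise, truncated at zero, in an experiments x replicates layout.

All randomness flows from a single integer seed through named substreams,
so each stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pharm import DoseResponseDataset, GrowthCurve, four_pl
from .quantnorm import QuantTable
from .screen import AnnotationTable
from .tma import COVARIATE_LEVELS, TMACase


class SynthConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a top-level seed (stable across platforms)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ----------------------------------------------------------------------
# quantitative proteomics experiment
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SynthQuantConfig:
    """World model for the synthetic label-free quant experiment.

    Defaults emulate the study scale: ~2300 identified proteins per cell
    line of which roughly a quarter are membrane-associated, 4 biological
    replicates, replicate CV around 20% (the printed candidate-table CVs
    span roughly 10-40%), and 30 planted cancer-exclusive membrane
    proteins per cancer line whose abundance is boosted so they populate
    the top of the ranking.

    ``dropout`` is the maximum missingness probability, approached by the
    lowest-abundance proteins; the probability decays logistically with
    log-abundance and is ``dropout/2`` at the median abundance.
    ``control_exclusive_mode`` is "absent" (planted exclusives carry no
    control signal at all) or "trace" (present in control at a low
    abundance that normalizes below the detection floor).
    """

    n_proteins: int = 2300
    membrane_fraction: float = 0.26
    n_replicates: int = 4
    mu_log: float = 11.0  # natural-log mean of raw peak areas (arbitrary units)
    sigma_log: float = 1.0
    replicate_cv: float = 0.20
    dropout: float = 0.0
    dropout_slope: float = 1.0
    n_exclusive_cancer: int = 30
    exclusive_abundance_boost: float = 5.0
    control_exclusive_mode: str = "absent"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.membrane_fraction <= 1 or not 0 <= self.dropout <= 1:
            raise SynthConfigError("fractions must be in [0, 1]")
        if min(self.n_proteins, self.n_replicates, self.n_exclusive_cancer) < 1:
            raise SynthConfigError("counts must be positive")
        n_membrane = int(round(self.n_proteins * self.membrane_fraction))
        if 2 * self.n_exclusive_cancer > n_membrane:
            raise SynthConfigError(
                "not enough membrane proteins to plant exclusives for both cancer lines"
            )
        if self.control_exclusive_mode not in ("absent", "trace"):
            raise SynthConfigError("control_exclusive_mode must be 'absent' or 'trace'")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    seed: int
    exclusive_accessions: Optional[Dict[str, List[str]]] = None
    membrane_accessions: Optional[List[str]] = None
    true_abundance: Optional[Dict[str, float]] = None
    tma_params: Optional[dict] = None
    dose_params: Optional[dict] = None

    def to_json(self, path) -> None:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


CELL_LINES = ("cancer_a", "cancer_b", "control")


def gen_quant_experiment(
    config: SynthQuantConfig,
) -> Tuple[Dict[str, QuantTable], AnnotationTable, GroundTruth]:
    """Generate raw quant tables for two cancer lines and one control.

    The three tables share a protein universe.  Each cancer line has its
    own disjoint planted exclusive set: abundance-boosted membrane
    proteins with consistent signal in that line and no (or sub-floor
    "trace") signal in the control line and in the other cancer line.
    Deterministic for a fixed config.
    """
    rng = substream(config.seed, "quant")
    n = config.n_proteins
    accessions = np.array([f"SYN{i:05d}" for i in range(1, n + 1)])
    genes = np.array([f"G{i:05d}" for i in range(1, n + 1)])
    descriptions = np.array([f"synthetic protein {i}" for i in range(1, n + 1)])

    n_membrane = int(round(n * config.membrane_fraction))
    membrane_idx = rng.choice(n, size=n_membrane, replace=False)
    membrane_mask = np.zeros(n, dtype=bool)
    membrane_mask[membrane_idx] = True

    planted = rng.choice(membrane_idx, size=2 * config.n_exclusive_cancer, replace=False)
    exclusive_idx = {
        "cancer_a": planted[: config.n_exclusive_cancer],
        "cancer_b": planted[config.n_exclusive_cancer:],
    }

    base = rng.lognormal(config.mu_log, config.sigma_log, size=n)
    for idx in exclusive_idx.values():
        base[idx] = (
            np.exp(config.mu_log) * config.exclusive_abundance_boost
            * rng.lognormal(0.0, 0.25, size=len(idx))
        )
    sigma_rep = np.sqrt(np.log1p(config.replicate_cv ** 2))

    proteins = pd.DataFrame(
        {"gene": genes, "description": descriptions},
        index=pd.Index(accessions, name="accession"),
    )

    tables: Dict[str, QuantTable] = {}
    for line in CELL_LINES:
        abundance = base.copy()
        absent = np.zeros(n, dtype=bool)
        for owner, idx in exclusive_idx.items():
            if line == owner:
                continue
            if line == "control" and config.control_exclusive_mode == "trace":
                # low abundance that normalizes well below the detection floor
                abundance[idx] = np.exp(config.mu_log) * 1e-4
            else:
                absent[idx] = True
        values = abundance[:, None] * rng.lognormal(
            0.0, sigma_rep, size=(n, config.n_replicates)
        )
        if config.dropout > 0:
            rel = abundance / np.exp(config.mu_log)
            p_miss = config.dropout / (1.0 + rel ** config.dropout_slope)
            miss = rng.random((n, config.n_replicates)) < p_miss[:, None]
            values[miss] = np.nan
        values[absent] = np.nan
        keep_rows = ~np.isnan(values).all(axis=1)
        areas = pd.DataFrame(
            values[keep_rows],
            index=pd.Index(accessions[keep_rows], name="accession"),
            columns=[f"rep{r + 1}" for r in range(config.n_replicates)],
        )
        tables[line] = QuantTable(
            cell_line=line,
            proteins=proteins.loc[areas.index].copy(),
            areas=areas,
            normalized=False,
        )

    terms = {
        acc: ["cell membrane"] if membrane_mask[i] else ["cytoplasm"]
        for i, acc in enumerate(accessions)
    }
    annotation = AnnotationTable.from_mapping(terms)
    truth = GroundTruth(
        seed=config.seed,
        exclusive_accessions={
            line: sorted(accessions[idx]) for line, idx in exclusive_idx.items()
        },
        membrane_accessions=sorted(accessions[membrane_mask]),
        true_abundance={acc: float(a) for acc, a in zip(accessions, base)},
    )
    return tables, annotation, truth


# ----------------------------------------------------------------------
# tissue-microarray cohort
# ----------------------------------------------------------------------

def _default_covariate_freqs() -> Dict[str, Dict[str, float]]:
    # Level frequencies among evaluable carcinoma cases, matching the
    # cohort margins the generator emulates.
    return {
        "age_group": {">40": 0.59, "<=40": 0.41},
        "pt_status": {"T2": 0.71, "T3": 0.29},
        "grade": {"II": 0.33, "II~III": 0.27, "III": 0.40},
        "ln_metastasis": {"negative": 0.50, "positive": 0.50},
        "stage": {"IIA": 0.29, "IIB": 0.57, "IIIA": 0.14},
        "her2_status": {"negative": 0.51, "positive": 0.49},
    }


def _default_missing_rates() -> Dict[str, float]:
    return {
        "age_group": 0.0,
        "pt_status": 0.17,
        "grade": 0.27,
        "ln_metastasis": 0.02,
        "stage": 0.15,
        "her2_status": 0.15,
    }


@dataclass(frozen=True)
class SynthTMAConfig:
    """Cohort generator: group sizes and positivity model.

    Cancer positivity follows a per-case logistic model whose intercept
    is logit(``positivity_prob_cancer``) and whose covariate effects are
    log odds ratios (default 0, i.e. no association).  Positive cases
    draw a score from {2, 3, 4} with ``positive_score_weights``; negative
    cases score 1.  ``n_unevaluable`` cores per group get no score.
    """

    n_benign: int = 18
    n_cancer: int = 42
    positivity_prob_benign: float = 0.0
    positivity_prob_cancer: float = 0.49
    positive_score_weights: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    covariate_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_covariate_freqs
    )
    covariate_missing_rates: Mapping[str, float] = field(
        default_factory=_default_missing_rates
    )
    covariate_log_odds: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_unevaluable: Tuple[int, int] = (1, 1)  # (benign, cancer)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.positivity_prob_benign, self.positivity_prob_cancer):
            if not 0 <= p <= 1:
                raise SynthConfigError("probabilities must be in [0, 1]")


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def gen_tma_cohort(config: SynthTMAConfig) -> Tuple[List[TMACase], GroundTruth]:
    """Sample a benign + carcinoma cohort with planted association structure."""
    rng = substream(config.seed, "tma")
    cases: List[TMACase] = []

    def sample_covariates() -> Dict[str, Optional[str]]:
        covs: Dict[str, Optional[str]] = {}
        for cov, freqs in config.covariate_freqs.items():
            if rng.random() < config.covariate_missing_rates.get(cov, 0.0):
                covs[cov] = None
            else:
                levels = list(freqs)
                probs = np.array([freqs[lv] for lv in levels], dtype=float)
                covs[cov] = str(rng.choice(levels, p=probs / probs.sum()))
        return covs

    score_choices = np.array([2, 3, 4])
    weights = np.asarray(config.positive_score_weights, dtype=float)
    weights = weights / weights.sum()

    for klass, n_total, base_p, n_miss in (
        ("normal_benign", config.n_benign, config.positivity_prob_benign,
         config.n_unevaluable[0]),
        ("carcinoma", config.n_cancer, config.positivity_prob_cancer,
         config.n_unevaluable[1]),
    ):
        for i in range(n_total):
            unevaluable = i < n_miss
            covs = sample_covariates() if klass == "carcinoma" else {}
            logit_p = _logit(base_p)
            for cov, value in covs.items():
                if value is not None:
                    logit_p += config.covariate_log_odds.get(cov, {}).get(value, 0.0)
            p = 1.0 / (1.0 + np.exp(-logit_p))
            if unevaluable:
                score = None
            elif rng.random() < p:
                score = int(rng.choice(score_choices, p=weights))
            else:
                score = 1
            cases.append(TMACase(f"{klass}-{i + 1:03d}", klass, score, covs))

    truth = GroundTruth(
        seed=config.seed,
        tma_params={
            "positivity_prob_benign": config.positivity_prob_benign,
            "positivity_prob_cancer": config.positivity_prob_cancer,
            "covariate_log_odds": {
                k: dict(v) for k, v in config.covariate_log_odds.items()
            },
        },
    )
    return cases, truth


# ----------------------------------------------------------------------
# dose-response plates and growth curves
# ----------------------------------------------------------------------

def study_dose_grid(n_points: int = 8, low: float = 0.01, high: float = 30.0) -> np.ndarray:
    """Log-spaced dose grid in uM (default 8 points, 0.01-30 uM)."""
    return np.geomspace(low, high, n_points)


def _default_conditions() -> Dict[str, dict]:
    # Monotherapy vs fixed-dose combination: the combination shifts the
    # IC50 from 2.3 to 1.0 uM and plateaus near 60% growth inhibition.
    # The hill slope of 1.5 is calibrated so that per-experiment fitted
    # IC50s reproduce with a between-experiment SD of ~0.2 uM at this
    # design (8 doses, triplicate, viability noise SD 0.05).
    return {
        "lapatinib": dict(bottom=0.20, top=1.0, ic50=2.3, hill=1.5),
        "lapatinib+dfp50": dict(bottom=0.40, top=1.0, ic50=1.0, hill=1.5,
                                drug="lapatinib",
                                cotreatment=("deferiprone", 50.0)),
    }


@dataclass(frozen=True)
class SynthDoseConfig:
    """True 4PL parameters per condition plus plate design and noise."""

    conditions: Mapping[str, dict] = field(default_factory=_default_conditions)
    dose_grid: Tuple[float, ...] = tuple(study_dose_grid())
    n_experiments: int = 3
    n_replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dose_grid) <= 0:
            raise SynthConfigError("doses must be positive")
        if self.noise_sd < 0:
            raise SynthConfigError("noise SD must be >= 0")


def gen_dose_response(
    config: SynthDoseConfig,
) -> Tuple[List[DoseResponseDataset], GroundTruth]:
    """Simulate viability plates: 4PL mean + Gaussian noise, floored at 0."""
    rng = substream(config.seed, "dose")
    doses = np.asarray(config.dose_grid, dtype=float)
    datasets: List[DoseResponseDataset] = []
    for name, params in config.conditions.items():
        mean = four_pl(doses, params["bottom"], params["top"],
                       params["ic50"], params["hill"])
        noise = rng.normal(
            0.0, config.noise_sd,
            size=(len(doses), config.n_experiments, config.n_replicates),
        )
        viability = np.clip(mean[:, None, None] + noise, 0.0, None)
        datasets.append(
            DoseResponseDataset(
                drug=params.get("drug", name),
                concentrations=doses,
                viability=viability,
                cotreatment=params.get("cotreatment"),
            )
        )
    truth = GroundTruth(
        seed=config.seed,
        dose_params={
            name: {k: v for k, v in params.items()
                   if k not in ("cotreatment", "drug")}
            for name, params in config.conditions.items()
        },
    )
    return datasets, truth


def gen_growth_curves(
    effects: Mapping[str, float],
    reference: str = "NC-siRNA",
    timepoints: Sequence[float] = (24.0, 48.0, 72.0),
    base_od: float = 0.3,
    growth_rate: float = 0.02,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> List[GrowthCurve]:
    """Simulate MTT growth curves for knockdown comparisons.

    ``effects`` maps treatment label to the fractional OD reduction at
    the final timepoint relative to the reference (e.g. 0.3 for a 30%
    reduction); the reduction ramps in linearly over time.  Noise is
    multiplicative Gaussian with coefficient ``noise_cv``.
    """
    rng = substream(seed, "growth")
    t = np.asarray(timepoints, dtype=float)
    ref_mean = base_od * np.exp(growth_rate * t)
    curves = [
        GrowthCurve(
            reference, t,
            ref_mean[:, None]
            * (1 + noise_cv * rng.standard_normal((len(t), n_replicates))),
        )
    ]
    ramp = (t - t[0]) / (t[-1] - t[0])
    for name, effect in effects.items():
        mean = ref_mean * (1 - effect * ramp)
        curves.append(
            GrowthCurve(
                name, t,
                mean[:, None]
                * (1 + noise_cv * rng.standard_normal((len(t), n_replicates))),
            )
        )
    return curves
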