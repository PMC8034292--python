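"""IHC tissue-microarray scoring and chi-square association analysis.

Cores are scored on an ordinal 1-4 intensity scale (negative, weak,
moderate, strong).  Two binarizations are supported: the *intensity* rule
(low = 1-2, high = 3-4) and the *positivity* rule (negative = 1, positive
= 2-4), the latter being the default for positive-vs-negative association
tables.  Associations between marker positivity and clinicopathological
covariates are tested with Pearson's chi-square on r x 2 contingency
tables, without continuity correction; cases missing a covariate (or with
an unevaluable core) are dropped per comparison and counted.

A margin-fixed Monte-Carlo permutation null for the chi-square statistic
is provided as an independent check of the asymptotic p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

SCORE_SCALE = (1, 2, 3, 4)

TISSUE_CLASSES = ("normal_benign", "carcinoma")

#: Clinicopathological covariates and their level vocabularies.
COVARIATE_LEVELS: Dict[str, Tuple[str, ...]] = {
    "age_group": (">40", "<=40"),
    "pt_status": ("T2", "T3"),
    "grade": ("II", "II~III", "III"),
    "ln_metastasis": ("negative", "positive"),
    "stage": ("IIA", "IIB", "IIIA"),
    "her2_status": ("negative", "positive"),
}

BinarizationRule = Literal["positivity", "intensity"]


class TMAError(ValueError):
    """Raised for invalid scores, covariates or degenerate tables."""


class DegenerateTableError(TMAError):
    """Raised when a contingency table cannot be formed or tested."""


@dataclass(frozen=True)
class TMACase:
    """One tissue-microarray case.

    ``ihc_score`` is None for unevaluable cores; covariate values are
    None when not reported for the case.
    """

    case_id: str
    tissue_class: str
    ihc_score: Optional[int] = None
    covariates: Mapping[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise TMAError(f"unknown tissue class {self.tissue_class!r}")
        if self.ihc_score is not None and self.ihc_score not in SCORE_SCALE:
            raise TMAError(f"IHC score {self.ihc_score!r} outside scale 1-4")
        for name, value in self.covariates.items():
            levels = COVARIATE_LEVELS.get(name)
            if levels is None:
                raise TMAError(f"unknown covariate {name!r}")
            if value is not None and value not in levels:
                raise TMAError(f"covariate {name}: unknown level {value!r}")


@dataclass
class ContingencyTable:
    """r x c counts with labelled margins and a dropped-case count."""

    counts: pd.DataFrame  # rows: covariate levels; columns: outcome labels
    n_dropped: int = 0

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise DegenerateTableError(
                f"need at least 2x2 counts, got {arr.shape[0]}x{arr.shape[1]}"
            )
        if (arr < 0).any():
            raise TMAError("negative counts")
        if arr.sum() <= 0:
            raise DegenerateTableError("empty contingency table")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: np.ndarray
    low_expected_warning: bool

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def binarize_score(score: int, rule: BinarizationRule = "positivity") -> str:
    """Map an ordinal 1-4 score to a binary label.

    ``positivity`` (default): 1 -> "negative", 2-4 -> "positive".
    ``intensity``: 1-2 -> "low", 3-4 -> "high".
    """
    if score not in SCORE_SCALE:
        raise TMAError(f"IHC score {score!r} outside scale 1-4")
    if rule == "positivity":
        return "negative" if score == 1 else "positive"
    if rule == "intensity":
        return "low" if score <= 2 else "high"
    raise TMAError(f"unknown binarization rule {rule!r}")


def _outcome_labels(rule: BinarizationRule) -> Tuple[str, str]:
    return ("positive", "negative") if rule == "positivity" else ("high", "low")


def build_contingency(
    cases: Sequence[TMACase],
    covariate: str,
    rule: BinarizationRule = "positivity",
) -> ContingencyTable:
    """Cross-tabulate a covariate (or tissue class) against the binarized score.

    ``covariate`` may be ``"tissue_class"`` or any clinicopathological
    covariate name.  Cases with an unevaluable core or a missing covariate
    value are dropped and counted in ``n_dropped``.
    """
    if covariate == "tissue_class":
        levels: Tuple[str, ...] = TISSUE_CLASSES
        getter = lambda c: c.tissue_class
    elif covariate in COVARIATE_LEVELS:
        levels = COVARIATE_LEVELS[covariate]
        getter = lambda c: c.covariates.get(covariate)
    else:
        raise TMAError(f"unknown covariate {covariate!r}")

    pos_label, neg_label = _outcome_labels(rule)
    counts = {level: {pos_label: 0, neg_label: 0} for level in levels}
    n_dropped = 0
    for case in cases:
        level = getter(case)
        if case.ihc_score is None or level is None:
            n_dropped += 1
            continue
        counts[level][binarize_score(case.ihc_score, rule)] += 1
    frame = pd.DataFrame(counts).T[[pos_label, neg_label]]
    frame = frame[frame.sum(axis=1) > 0]  # drop unobserved levels
    if frame.shape[0] < 2:
        raise DegenerateTableError(
            f"covariate {covariate!r}: fewer than 2 observed levels"
        )
    return ContingencyTable(counts=frame, n_dropped=n_dropped)


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    statistic = sum (O-E)^2 / E with E = row_total x col_total / N; the
    p-value is the chi-square upper tail at df = (r-1)(c-1).  Any expected
    count below 5 raises ``low_expected_warning`` but does not change the
    test.
    """
    counts = table.counts.to_numpy(dtype=float)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        empty_rows = table.counts.index[row_tot == 0].tolist()
        empty_cols = table.counts.columns[col_tot == 0].tolist()
        raise DegenerateTableError(
            f"zero marginal totals (rows {empty_rows}, columns {empty_cols})"
        )
    statistic, p_value, df, expected = stats.chi2_contingency(
        counts, correction=False
    )
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        expected_counts=np.asarray(expected),
        low_expected_warning=bool((np.asarray(expected) < 5).any()),
    )


def permutation_chi_square_p(
    table: ContingencyTable,
    n_draws: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo permutation p-value for the chi-square statistic.

    Tables are drawn from the null of independence conditional on both
    margins (for 2 x 2 tables, a hypergeometric draw of the top-left
    cell); the p-value is the fraction of draws whose statistic is at
    least the observed one.
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = table.counts.to_numpy(dtype=float)
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = counts.sum()
    expected = np.outer(r, c) / n
    observed_stat = ((counts - expected) ** 2 / expected).sum()
    if counts.shape == (2, 2):
        a = rng.hypergeometric(int(c[0]), int(c[1]), int(r[0]), size=n_draws)
        cells = np.stack(
            [a, r[0] - a, c[0] - a, r[1] - (c[0] - a)], axis=1
        ).reshape(-1, 2, 2)
    else:
        sampler = stats.random_table(r.astype(int), c.astype(int))
        cells = sampler.rvs(n_draws, random_state=rng)
    stats_draws = ((cells - expected) ** 2 / expected).sum(axis=(1, 2))
    return float(np.mean(stats_draws >= observed_stat - 1e-9))


@dataclass
class AssociationRow:
    comparison: str
    table: Optional[ContingencyTable]
    result: Optional[ChiSquareResult]
    error: Optional[str] = None

    @property
    def p_value(self) -> float:
        return self.result.p_value if self.result is not None else float("nan")


@dataclass
class AssociationReport:
    """Per-covariate chi-square results plus the benign-vs-cancer row."""

    rows: Dict[str, AssociationRow]
    rule: BinarizationRule
    alpha: float = 0.05

    def p_values(self) -> Dict[str, float]:
        return {name: row.p_value for name, row in self.rows.items()}

    def to_frame(self) -> pd.DataFrame:
        records = []
        for name, row in self.rows.items():
            if row.result is None:
                records.append((name, np.nan, np.nan, "", row.error or "NA"))
            else:
                records.append(
                    (
                        name,
                        round(row.result.statistic, 4),
                        round(row.result.p_value, 4),
                        "*" if row.result.significant(self.alpha) else "",
                        f"dropped={row.table.n_dropped}" if row.table else "",
                    )
                )
        return pd.DataFrame(
            records,
            columns=["comparison", "chi_square", "p_value", "significant", "notes"],
        )


def association_report(
    cases: Sequence[TMACase],
    rule: BinarizationRule = "positivity",
    covariates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> AssociationReport:
    """Run the benign-vs-cancer comparison and all per-covariate tests.

    Covariate associations are evaluated among carcinoma cases only;
    degenerate tables (a covariate missing for nearly all cases, or a
    single observed level) yield NA rows rather than aborting the report.
    """
    covariates = list(COVARIATE_LEVELS) if covariates is None else list(covariates)
    rows: Dict[str, AssociationRow] = {}

    def run(name: str, subset: Sequence[TMACase], key: str) -> None:
        try:
            table = build_contingency(subset, key, rule)
            rows[name] = AssociationRow(name, table, pearson_chi_square(table))
        except DegenerateTableError as exc:
            rows[name] = AssociationRow(name, None, None, error=str(exc))

    run("tissue_class", cases, "tissue_class")
    cancers = [c for c in cases if c.tissue_class == "carcinoma"]
    for cov in covariates:
        run(cov, cancers, cov)
    return AssociationReport(rows=rows, rule=rule, alpha=alpha)


def positivity_fraction(cases: Sequence[TMACase],
                        tissue_class: str = "carcinoma",
                        rule: BinarizationRule = "positivity") -> Tuple[int, int]:
    """(n_positive, n_evaluable) among cases of a tissue class."""
    pos_label, _ = _outcome_labels(rule)
    scored = [
        c for c in cases if c.tissue_class == tissue_class and c.ihc_score is not None
    ]
    n_pos = sum(binarize_score(c.ihc_score, rule) == pos_label for c in scored)
    return n_pos, len(scored)


def reconstruct_cohort(
    benign: Tuple[int, int],
    cancer: Tuple[int, int],
    covariate_counts: Optional[Mapping[str, Mapping[str, Tuple[int, int]]]] = None,
    n_unevaluable: Tuple[int, int] = (0, 0),
) -> List[TMACase]:
    """Build a case list whose marginal tables match published counts.

    ``benign`` and ``cancer`` give (n_positive, n_negative) evaluable
    cases per tissue class; ``covariate_counts`` maps covariate ->
    level -> (n_positive, n_negative) among cancer cases.  Each covariate
    is assigned independently within the positive and negative groups (so
    every single-covariate cross-tabulation is reproduced; the joint
    distribution across covariates is not modelled).  Positive cases get
    score 2 and negative cases score 1; unevaluable cases get no score.
    """
    covariate_counts = covariate_counts or {}
    cases: List[TMACase] = []

    def assignments(group_size: int, per_level: Mapping[str, int]) -> List[Optional[str]]:
        values: List[Optional[str]] = []
        for level, count in per_level.items():
            values.extend([level] * count)
        if len(values) > group_size:
            raise TMAError("covariate counts exceed group size")
        values.extend([None] * (group_size - len(values)))
        return values

    for klass, (n_pos, n_neg), n_miss in zip(
        TISSUE_CLASSES, (benign, cancer), n_unevaluable
    ):
        group_scores = [2] * n_pos + [1] * n_neg
        cov_values: Dict[str, List[Optional[str]]] = {}
        if klass == "carcinoma":
            for cov, per_level in covariate_counts.items():
                pos_part = assignments(n_pos, {lv: pn for lv, (pn, _) in per_level.items()})
                neg_part = assignments(n_neg, {lv: nn for lv, (_, nn) in per_level.items()})
                cov_values[cov] = pos_part + neg_part
        for i, score in enumerate(group_scores):
            covs = {cov: vals[i] for cov, vals in cov_values.items()}
            cases.append(
                TMACase(f"{klass}-{i + 1:03d}", klass, score, covs)
            )
        for j in range(n_miss):
            cases.append(TMACase(f"{klass}-x{j + 1}", klass, None, {}))
    return cases
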