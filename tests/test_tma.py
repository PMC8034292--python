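"""IHC binarization, contingency construction and chi-square association."""

import numpy as np
import pandas as pd
import pytest

from memscreen import (
    ContingencyTable,
    DegenerateTableError,
    TMACase,
    association_report,
    binarize_score,
    build_contingency,
    pearson_chi_square,
    permutation_chi_square_p,
    positivity_fraction,
)
from memscreen.synthdata import SynthTMAConfig, gen_tma_cohort
from memscreen.tma import TMAError
from conftest import TABLE3_PVALUES


def table_of(counts, rows=None, cols=("positive", "negative")):
    counts = np.asarray(counts)
    rows = rows or [f"r{i}" for i in range(counts.shape[0])]
    return ContingencyTable(pd.DataFrame(counts, index=rows, columns=list(cols)))


@pytest.mark.parametrize(
    "score, rule, label",
    [
        (1, "positivity", "negative"),
        (2, "positivity", "positive"),
        (4, "positivity", "positive"),
        (1, "intensity", "low"),
        (2, "intensity", "low"),
        (3, "intensity", "high"),
    ],
)
def test_binarize_score(score, rule, label):
    assert binarize_score(score, rule) == label


def test_binarize_score_rejects_out_of_scale():
    with pytest.raises(TMAError):
        binarize_score(5)
    with pytest.raises(TMAError):
        binarize_score(0, "intensity")


def test_build_contingency_counts_and_drops():
    cases = [
        TMACase("c1", "carcinoma", 3),
        TMACase("c2", "carcinoma", 1),
        TMACase("b1", "normal_benign", 1),
        TMACase("b2", "normal_benign", None),  # unevaluable core
    ]
    table = build_contingency(cases, "tissue_class")
    assert table.counts.loc["carcinoma"].tolist() == [1, 1]
    assert table.counts.loc["normal_benign"].tolist() == [0, 1]
    assert table.n_dropped == 1


def test_build_contingency_degenerate_when_covariate_absent():
    cases = [TMACase("c1", "carcinoma", 2), TMACase("c2", "carcinoma", 1)]
    with pytest.raises(DegenerateTableError):
        build_contingency(cases, "her2_status")


def test_chi_square_proportional_rows_give_zero_statistic():
    res = pearson_chi_square(table_of([[10, 10], [5, 5]]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_known_two_by_two():
    res = pearson_chi_square(table_of([[7, 13], [13, 7]]))
    assert res.statistic == pytest.approx(3.6, abs=1e-9)
    assert res.df == 1
    assert res.p_value == pytest.approx(0.0578, abs=5e-5)


def test_chi_square_three_by_two():
    res = pearson_chi_square(table_of([[10, 0], [4, 4], [4, 8]]))
    assert res.df == 2
    assert res.p_value == pytest.approx(0.0051, abs=5e-5)


def test_chi_square_invariances():
    """Permutation of rows/columns and transposition leave the test unchanged."""
    base = pearson_chi_square(table_of([[3, 9], [11, 5]]))
    perm = pearson_chi_square(table_of([[11, 5], [3, 9]]))
    transposed = pearson_chi_square(table_of([[3, 11], [9, 5]]))
    for other in (perm, transposed):
        assert other.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert other.p_value == pytest.approx(base.p_value, rel=1e-12)


def test_low_expected_warning_flag():
    # benign-vs-cancer style table: all expected counts >= 5, no warning
    res = pearson_chi_square(table_of([[0, 17], [20, 21]]))
    assert not res.low_expected_warning
    assert res.p_value == pytest.approx(0.0004, abs=5e-5)
    # grade-style 3x2 table has an expected count of 4 -> warning, test unchanged
    low = pearson_chi_square(table_of([[10, 0], [4, 4], [4, 8]]))
    assert low.low_expected_warning


def test_permutation_null_tracks_analytic_p_at_moderate_counts():
    """The asymptotic tail approximates the margin-fixed exact null to a few
    hundredths when all expected counts are >= 5 (the residual gap is the
    chi-square approximation error at small N, not Monte-Carlo noise)."""
    rng = np.random.default_rng(5)
    for counts in ([[7, 13], [13, 7]], [[15, 9], [3, 7]], [[14, 10], [6, 11]]):
        table = table_of(counts)
        p_mc = permutation_chi_square_p(table, n_draws=50_000, rng=rng)
        p_asym = pearson_chi_square(table).p_value
        assert abs(p_mc - p_asym) < 0.08


def test_permutation_null_r_by_c():
    rng = np.random.default_rng(6)
    table = table_of([[10, 0], [4, 4], [4, 8]])
    p_mc = permutation_chi_square_p(table, n_draws=20_000, rng=rng)
    assert 0.0 < p_mc < 0.05


def test_association_report_reproduces_published_pvalues(table3_cohort):
    report = association_report(table3_cohort)
    for name, printed in TABLE3_PVALUES.items():
        assert round(report.rows[name].p_value, 4) == printed


def test_association_report_handles_degenerate_covariates():
    cases = [TMACase(f"b{i}", "normal_benign", 1) for i in range(5)] + [
        TMACase(f"c{i}", "carcinoma", 2) for i in range(5)
    ]
    report = association_report(cases)
    assert report.rows["tissue_class"].result is not None
    assert report.rows["her2_status"].result is None
    assert "levels" in report.rows["her2_status"].error


def test_positivity_fraction(table3_cohort):
    n_pos, n_eval = positivity_fraction(table3_cohort)
    assert (n_pos, n_eval) == (20, 41)


def test_null_cohort_type_one_error_rate():
    """With equal positivity in both groups the benign-vs-cancer test should
    reject at roughly the nominal 5% rate."""
    rejections = 0
    n_runs = 400
    for seed in range(n_runs):
        cases, _ = gen_tma_cohort(
            SynthTMAConfig(
                positivity_prob_benign=0.5, positivity_prob_cancer=0.5, seed=seed
            )
        )
        report = association_report(cases, covariates=[])
        rejections += report.rows["tissue_class"].p_value < 0.05
    rate = rejections / n_runs
    assert 0.02 <= rate <= 0.09
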