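"""Candidate screen: detection rules, membrane filter, Venn, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memscreen import (
    AnnotationTable,
    ScreenConfig,
    call_detection,
    compute_venn,
    filter_membrane,
    normalize_table,
    select_candidates,
    summarize_protein,
    summarize_table,
)
from memscreen.screen import ScreenConfigError
from memscreen.synthdata import SynthQuantConfig, gen_quant_experiment
from conftest import NAN, make_quant_table


def summary_of(values, threshold=70, accession="P1"):
    return summarize_protein(values, threshold, accession=accession)


@pytest.mark.parametrize(
    "values, role, detected",
    [
        ([80, 75, 90, NAN], "cancer", True),   # 3/4 = 0.75, boundary passes
        ([80, 60, 90, NAN], "cancer", False),  # 2/4 below presence fraction
        ([71, 71, NAN, NAN], "control", False),  # control rule needs >= 3
        ([71, 71, 70, NAN], "control", True),
    ],
)
def test_detection_rules(values, role, detected):
    call = call_detection(summary_of(values), role, ScreenConfig())
    assert call.detected is detected
    assert call.rule_applied == f"{role}-rule"


def test_screen_config_validation():
    with pytest.raises(ScreenConfigError):
        ScreenConfig(presence_fraction=0.0)
    with pytest.raises(ScreenConfigError):
        ScreenConfig(top_n=0)


def test_membrane_filter_drops_and_reports():
    annotation = AnnotationTable.from_mapping(
        {"P001": ["Cell Membrane"], "P002": ["cytoplasm"]}
    )
    table = make_quant_table([[100, 100]] * 3, normalized=True)
    summaries = summarize_table(table, 70)
    kept, report = filter_membrane(summaries, annotation)
    assert list(kept.index) == ["P001"]
    assert report.n_unannotated == 1  # P003 absent from the annotation
    assert report.n_non_membrane == 1
    assert report.n_retained == 1


@given(
    a=st.sets(st.integers(0, 40)),
    b=st.sets(st.integers(0, 40)),
)
@settings(max_examples=200, deadline=None)
def test_venn_partition_laws(a, b):
    """Disjointness and union reconstruction hold for any two sets."""
    a = {f"p{i}" for i in a}
    b = {f"p{i}" for i in b}
    v = compute_venn(a, b)
    assert not v.common & v.unique_a and not v.common & v.unique_b
    assert not v.unique_a & v.unique_b
    assert v.common | v.unique_a == a
    assert v.common | v.unique_b == b
    assert v.n_common + v.n_unique_a + v.n_unique_b == len(a | b)


def test_select_candidates_toy_cascade():
    """Exclusivity, control expression and CV ceiling each knock a protein out."""
    # P1 clean candidate; P2 expressed in control; P3 too variable in cancer
    cancer = make_quant_table(
        [[100, 100, 100, 100], [500, 480, 520, 510], [900, 200, 100, 80]],
        accessions=["P1", "P2", "P3"],
        normalized=True,
    )
    control = make_quant_table(
        [[80, 80, 80, NAN]], accessions=["P2"], normalized=True
    )
    annotation = AnnotationTable.from_mapping(
        {p: ["plasma membrane"] for p in ("P1", "P2", "P3")}
    )
    result = select_candidates(
        summarize_table(cancer, 70), summarize_table(control, 70),
        annotation, ScreenConfig(),
    )
    assert list(result.frame["accession"]) == ["P1"]
    assert result.frame.index.tolist() == [1]


def test_select_candidates_ranking_and_truncation():
    values = [[m] * 4 for m in (300.0, 500.0, 500.0, 100.0, 250.0)]
    acc = ["P5", "P2", "P1", "P4", "P3"]
    cancer = make_quant_table(values, accessions=acc, normalized=True)
    control = make_quant_table([[75.0] * 4], accessions=["PX"], normalized=True)
    annotation = AnnotationTable.from_mapping({p: ["membrane"] for p in acc})
    full = select_candidates(
        summarize_table(cancer, 70), summarize_table(control, 70),
        annotation, ScreenConfig(top_n=30),
    )
    # mean descending, accession ascending on ties
    assert list(full.frame["accession"]) == ["P1", "P2", "P5", "P3", "P4"]
    top1 = select_candidates(
        summarize_table(cancer, 70), summarize_table(control, 70),
        annotation, ScreenConfig(top_n=1),
    )
    assert list(top1.frame["accession"]) == ["P1"]


def test_exclusivity_soundness_on_synthetic_world():
    """No candidate may pass the control expression rule."""
    cfg = SynthQuantConfig(n_proteins=400, n_exclusive_cancer=10, dropout=0.2, seed=3)
    tables, annotation, _ = gen_quant_experiment(cfg)
    config = ScreenConfig(top_n=10 ** 6)
    summaries = {
        k: summarize_table(normalize_table(t), config.detection_threshold)
        for k, t in tables.items()
    }
    result = select_candidates(
        summaries["cancer_a"], summaries["control"], annotation, config
    )
    control = summaries["control"]
    for acc in result.accessions:
        if acc in control.index:
            assert control.loc[acc, "n_detected"] < config.control_min_detected_reps


def test_planted_exclusives_recovered_without_noise_obstacles():
    cfg = SynthQuantConfig(
        n_proteins=400, n_exclusive_cancer=12, dropout=0.0, replicate_cv=0.1, seed=11
    )
    tables, annotation, truth = gen_quant_experiment(cfg)
    summaries = {
        k: summarize_table(normalize_table(t), 70) for k, t in tables.items()
    }
    result = select_candidates(
        summaries["cancer_b"], summaries["control"], annotation,
        ScreenConfig(top_n=12),
    )
    assert result.accessions == set(truth.exclusive_accessions["cancer_b"])
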