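"""4PL dose-response fitting, combination shift and growth-curve comparison."""

import numpy as np
import pytest
from scipy import stats

from memscreen import (
    DoseResponseDataset,
    GrowthCurve,
    compare_growth_curves,
    compare_ic50,
    fit_4pl,
    four_pl,
    viability_from_od,
)
from memscreen.pharm import PharmacologyError, significance_stars
from memscreen.synthdata import (
    SynthDoseConfig,
    gen_dose_response,
    gen_growth_curves,
    study_dose_grid,
)


@pytest.mark.parametrize(
    "od570, od650, vehicle, expected",
    [
        (0.8, 0.1, 0.7, 1.0),
        (0.45, 0.10, 0.70, 0.5),
        (0.05, 0.10, 0.70, 0.0),  # negative corrected signal floors at zero
    ],
)
def test_viability_from_od(od570, od650, vehicle, expected):
    assert viability_from_od(od570, od650, vehicle) == pytest.approx(expected)


def test_viability_rejects_nonpositive_vehicle():
    with pytest.raises(PharmacologyError):
        viability_from_od(0.5, 0.1, 0.0)


@pytest.mark.parametrize(
    "bottom, top, ic50, hill",
    [(0.0, 1.0, 2.3, 1.0), (0.2, 1.1, 0.5, 2.5), (0.4, 0.9, 10.0, 0.7)],
)
def test_four_pl_midpoint_and_monotonicity(bottom, top, ic50, hill):
    """Response at the IC50 is the exact midpoint; the curve is decreasing."""
    assert four_pl(ic50, bottom, top, ic50, hill) == pytest.approx(
        (top + bottom) / 2, rel=1e-12
    )
    x = np.geomspace(0.001, 1000, 50)
    y = four_pl(x, bottom, top, ic50, hill)
    assert (np.diff(y) < 0).all()
    assert y[0] < top and y[0] > y[-1] > bottom


def noise_free_dataset(bottom=0.0, top=1.0, ic50=2.3, hill=1.0, n_exp=1, n_rep=1):
    doses = study_dose_grid()
    mean = four_pl(doses, bottom, top, ic50, hill)
    viability = np.tile(mean[:, None, None], (1, n_exp, n_rep))
    return DoseResponseDataset("drug", doses, viability)


def test_noise_free_roundtrip_recovers_ic50():
    fit = fit_4pl(noise_free_dataset(ic50=2.3), pooled=True)
    assert fit.converged
    assert fit.ic50 == pytest.approx(2.3, rel=1e-6)
    assert fit.bottom == pytest.approx(0.0, abs=1e-6)
    assert fit.top == pytest.approx(1.0, abs=1e-6)
    assert fit.hill_slope == pytest.approx(1.0, rel=1e-6)


def test_refit_of_fitted_curve_is_a_fixed_point():
    """Fitting the curve predicted by a converged fit returns the same fit."""
    datasets, _ = gen_dose_response(SynthDoseConfig(seed=4))
    dataset = datasets[0]
    first = fit_4pl(
        DoseResponseDataset("drug", dataset.concentrations,
                            dataset.viability[:, :1, :]),
        pooled=True,
    )
    predicted = four_pl(dataset.concentrations, first.bottom, first.top,
                        first.ic50, first.hill_slope)
    refit = fit_4pl(
        DoseResponseDataset("drug", dataset.concentrations,
                            predicted[:, None, None]),
        pooled=True,
    )
    assert refit.ic50 == pytest.approx(first.ic50, rel=1e-6)
    assert refit.hill_slope == pytest.approx(first.hill_slope, rel=1e-6)


def test_fit_requires_four_distinct_doses():
    doses = np.array([0.1, 1.0, 10.0])
    data = np.ones((3, 1, 3))
    with pytest.raises(PharmacologyError):
        fit_4pl(DoseResponseDataset("drug", doses, data))


def test_flat_curve_flags_unidentifiable_ic50():
    doses = study_dose_grid()
    data = np.full((len(doses), 1, 3), 1.0)
    fit = fit_4pl(DoseResponseDataset("drug", doses, data))
    assert fit.ic50_unidentifiable


def test_extrapolated_ic50_is_flagged():
    # shallow inhibitor: true IC50 far above the tested ceiling
    fit = fit_4pl(noise_free_dataset(ic50=120.0, hill=1.0), pooled=True)
    assert fit.ic50_extrapolated
    assert fit.ic50 > 30.0


def test_compare_ic50_matches_closed_form_t_test():
    mono = fit_4pl(noise_free_dataset(ic50=2.3), pooled=True)
    combo = fit_4pl(noise_free_dataset(ic50=1.0, bottom=0.4), pooled=True)
    mono.per_experiment_ic50s = np.array([2.3, 2.1, 2.5])
    combo.per_experiment_ic50s = np.array([1.0, 0.9, 1.1])
    result = compare_ic50(mono, combo)
    # pooled-variance two-sample t by hand
    x, y = mono.per_experiment_ic50s, combo.per_experiment_ic50s
    sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 3))
    p_hand = 2 * stats.t.sf(abs(t), df=4)
    assert result.p_value == pytest.approx(p_hand, rel=1e-12)
    assert result.p_value < 0.01
    assert result.fold_shift == pytest.approx(2.3, abs=0.01)
    assert result.max_inhibition_percent == pytest.approx(
        100 * (1 - combo.mean_response.min()), rel=1e-12
    )


def test_compare_ic50_identical_fits():
    fit = fit_4pl(noise_free_dataset(ic50=2.3), pooled=True)
    fit.per_experiment_ic50s = np.array([2.3, 2.2, 2.4])
    result = compare_ic50(fit, fit)
    assert result.fold_shift == pytest.approx(1.0)
    assert result.p_value == pytest.approx(1.0)


def test_compare_ic50_flags_unidentifiable_without_p():
    doses = study_dose_grid()
    flat = fit_4pl(DoseResponseDataset("drug", doses, np.full((8, 3, 3), 1.0)))
    good = fit_4pl(noise_free_dataset(ic50=2.3, n_exp=3, n_rep=3))
    result = compare_ic50(good, flat)
    assert result.flagged
    assert np.isnan(result.p_value)


def test_significance_stars():
    assert significance_stars(0.02) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(0.5) == ""


def test_growth_curve_comparison():
    curves = gen_growth_curves({"A-siRNA": 0.30, "C-siRNA": 0.0},
                               noise_cv=0.05, seed=9)
    results = compare_growth_curves(curves, "NC-siRNA", 72.0)
    p_knockdown, stars = results["A-siRNA"]
    assert p_knockdown < 0.01
    assert stars in ("**", "***")
    p_null, _ = results["C-siRNA"]
    assert p_null > 0.05


def test_growth_curve_single_replicate_gives_na():
    t = np.array([24.0, 48.0, 72.0])
    ref = GrowthCurve("NC-siRNA", t, np.ones((3, 3)))
    single = GrowthCurve("A-siRNA", t, np.ones((3, 1)))
    p, stars = compare_growth_curves([ref, single], "NC-siRNA", 72.0)["A-siRNA"]
    assert np.isnan(p) and stars == ""


def test_growth_curve_missing_timepoint_gives_na():
    ref = GrowthCurve("NC-siRNA", [24.0, 72.0], np.ones((2, 3)))
    other = GrowthCurve("A-siRNA", [24.0, 48.0], np.ones((2, 3)))
    p, _ = compare_growth_curves([ref, other], "NC-siRNA", 72.0)["A-siRNA"]
    assert np.isnan(p)
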