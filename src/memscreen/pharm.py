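"""MTT viability processing, four-parameter logistic IC50 fitting and
combination / knockdown growth comparisons.

The dose-response model is the four-parameter logistic (4PL)

    y(x) = bottom + (top - bottom) / (1 + (x / ic50) ** hill)

with ``x`` the drug concentration in uM and ``y`` the viability fraction
of vehicle control.  With ``hill > 0`` and ``top > bottom`` the curve
decreases from ``top`` at low dose to ``bottom`` at high dose and passes
through the exact midpoint (top + bottom) / 2 at x = ic50.  Fitting is
performed on the log10-concentration scale, per independent experiment by
default, with the per-experiment IC50s pooled as mean +/- SD and compared
between conditions with Student's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats


class PharmacologyError(ValueError):
    """Raised for invalid dose-response or growth-curve inputs."""


@dataclass
class DoseResponseDataset:
    """Viability fractions on a dose grid for one treatment condition.

    ``viability`` has shape (n_concentrations, n_experiments,
    n_replicates); values are fractions of the vehicle-control signal
    (>= 0, may exceed 1 for stimulated wells).
    """

    drug: str
    concentrations: np.ndarray  # uM, strictly positive, ascending
    viability: np.ndarray
    cotreatment: Optional[Tuple[str, float]] = None  # (drug, fixed dose uM)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.ndim == 2:  # single experiment
            self.viability = self.viability[:, None, :]
        if self.concentrations.ndim != 1 or self.viability.ndim != 3:
            raise PharmacologyError("concentrations must be 1-D, viability 3-D")
        if len(self.concentrations) != self.viability.shape[0]:
            raise PharmacologyError("dose grid and viability rows disagree")
        if (self.concentrations <= 0).any():
            raise PharmacologyError("concentrations must be strictly positive")
        if (np.diff(self.concentrations) <= 0).any():
            raise PharmacologyError("concentrations must be sorted ascending")
        if np.nanmin(self.viability) < 0:
            raise PharmacologyError("viability fractions must be >= 0")

    @property
    def n_experiments(self) -> int:
        return self.viability.shape[1]

    @property
    def label(self) -> str:
        if self.cotreatment is None:
            return self.drug
        co_drug, co_dose = self.cotreatment
        return f"{self.drug} + {co_drug} {co_dose:g} uM"

    def mean_response(self) -> np.ndarray:
        """Mean viability per concentration over experiments and replicates."""
        return np.nanmean(self.viability, axis=(1, 2))


@dataclass
class FourPLFit:
    """Fitted 4PL parameters for one condition."""

    bottom: float
    top: float
    hill_slope: float
    ic50: float
    converged: bool
    rss: float
    per_experiment_ic50s: np.ndarray
    concentrations: np.ndarray
    mean_response: np.ndarray
    ic50_unidentifiable: bool = False
    ic50_extrapolated: bool = False  # IC50 beyond the tested dose ceiling

    @property
    def ic50_mean(self) -> float:
        return float(np.mean(self.per_experiment_ic50s))

    @property
    def ic50_sd(self) -> float:
        if len(self.per_experiment_ic50s) < 2:
            return float("nan")
        return float(np.std(self.per_experiment_ic50s, ddof=1))


@dataclass
class CombinationResult:
    """Monotherapy vs combination IC50 shift."""

    ic50_mono: float
    ic50_mono_sd: float
    ic50_combo: float
    ic50_combo_sd: float
    fold_shift: float
    max_inhibition_percent: float
    p_value: float
    flagged: bool = False


@dataclass
class GrowthCurve:
    """Replicate optical densities over time for one treatment group."""

    treatment: str
    timepoints: np.ndarray  # hours, ascending
    od_values: np.ndarray  # shape (n_timepoints, n_replicates)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.od_values = np.asarray(self.od_values, dtype=float)
        if (np.diff(self.timepoints) <= 0).any():
            raise PharmacologyError("timepoints must be sorted ascending")
        if self.od_values.shape[0] != len(self.timepoints):
            raise PharmacologyError("od_values rows must match timepoints")


def viability_from_od(od570: float, od650: float, vehicle_mean: float) -> float:
    """Background-corrected viability fraction, floored at zero.

    ``vehicle_mean`` is the mean background-corrected signal of the
    vehicle-control wells.
    """
    if vehicle_mean <= 0:
        raise PharmacologyError("vehicle mean signal must be positive")
    return max((od570 - od650) / vehicle_mean, 0.0)


def four_pl(x, bottom: float, top: float, ic50: float, hill: float):
    """Evaluate the four-parameter logistic at concentration(s) x."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def _four_pl_log(logx, bottom, top, log_ic50, hill):
    # 4PL on the log10-concentration axis: (x/ic50)^hill = 10^(hill*(logx-logic50))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ic50)))


def _fit_single(
    concentrations: np.ndarray, responses: np.ndarray
) -> Tuple[np.ndarray, bool, float]:
    """Least-squares 4PL fit of one response set; returns (params, ok, rss).

    params = (bottom, top, ic50, hill).  Initialization: top/bottom from
    the extreme mean responses, IC50 at the dose nearest half-maximal
    response, hill = 1.  Bounds: ic50 in [min_dose/100, max_dose*100],
    hill in [0.1, 10].
    """
    logx = np.log10(concentrations)
    mean_by_dose = np.array(
        [responses[concentrations == c].mean() for c in np.unique(concentrations)]
    )
    top0, bottom0 = float(mean_by_dose.max()), float(mean_by_dose.min())
    half = 0.5 * (top0 + bottom0)
    dose_means = np.array([responses[concentrations == c].mean()
                           for c in np.unique(concentrations)])
    ic50_0 = float(np.unique(concentrations)[np.argmin(np.abs(dose_means - half))])
    lo = [-np.inf, -np.inf, np.log10(concentrations.min() / 100.0), 0.1]
    hi = [np.inf, np.inf, np.log10(concentrations.max() * 100.0), 10.0]
    p0 = [bottom0, top0, np.clip(np.log10(ic50_0), lo[2], hi[2]), 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _four_pl_log, logx, responses, p0=p0, bounds=(lo, hi),
                maxfev=10_000,
            )
        ok = True
    except RuntimeError:
        popt, ok = np.asarray(p0), False
    bottom, top, log_ic50, hill = popt
    if top < bottom:  # canonical orientation: top >= bottom
        bottom, top, hill = top, bottom, -hill
    rss = float(np.sum((_four_pl_log(logx, *popt) - responses) ** 2))
    return np.array([bottom, top, 10.0 ** log_ic50, hill]), ok, rss


def fit_4pl(dataset: DoseResponseDataset, pooled: bool = False) -> FourPLFit:
    """Fit the 4PL model to a dose-response dataset.

    By default each independent experiment is fitted separately (on its
    replicate-level points) and the per-experiment IC50s are pooled as
    mean +/- SD; the reported curve parameters come from a fit to all
    points.  With ``pooled=True`` only the all-points fit is performed
    and the per-experiment vector holds that single IC50.

    The IC50 is flagged unidentifiable when the fitted dynamic range
    (top - bottom) is below 5% of the top response, and extrapolated when
    it exceeds the highest tested dose.
    """
    if len(np.unique(dataset.concentrations)) < 4:
        raise PharmacologyError("need at least 4 distinct concentrations")
    n_conc, n_exp, n_rep = dataset.viability.shape
    x_all = np.repeat(dataset.concentrations, n_exp * n_rep)
    y_all = dataset.viability.reshape(n_conc, -1).ravel()
    keep = ~np.isnan(y_all)
    params, ok, rss = _fit_single(x_all[keep], y_all[keep])
    bottom, top, ic50, hill = params

    if pooled or n_exp == 1:
        per_exp = np.array([ic50])
        all_ok = ok
    else:
        per_exp = []
        all_ok = ok
        for e in range(n_exp):
            y = dataset.viability[:, e, :]
            x = np.repeat(dataset.concentrations, n_rep)
            yv = y.ravel()
            m = ~np.isnan(yv)
            p, exp_ok, _ = _fit_single(x[m], yv[m])
            all_ok = all_ok and exp_ok
            per_exp.append(p[2])
        per_exp = np.array(per_exp)

    unidentifiable = (top - bottom) < 0.05 * abs(top) if top != 0 else True
    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        hill_slope=float(hill),
        ic50=float(ic50),
        converged=bool(all_ok),
        rss=rss,
        per_experiment_ic50s=per_exp,
        concentrations=dataset.concentrations.copy(),
        mean_response=dataset.mean_response(),
        ic50_unidentifiable=bool(unidentifiable),
        ic50_extrapolated=bool(ic50 > dataset.concentrations.max()),
    )


def compare_ic50(mono: FourPLFit, combo: FourPLFit) -> CombinationResult:
    """Compare monotherapy and combination fits.

    Reports the IC50 fold-shift (mono/combo), the maximal growth
    inhibition of the combination curve (100 x (1 - min mean viability))
    and a two-sided, equal-variance Student's t-test on the
    per-experiment IC50s.  An unidentifiable IC50 flags the result and
    suppresses the p-value.
    """
    flagged = mono.ic50_unidentifiable or combo.ic50_unidentifiable
    max_inhibition = 100.0 * (1.0 - float(np.min(combo.mean_response)))
    fold = mono.ic50_mean / combo.ic50_mean
    if flagged or len(mono.per_experiment_ic50s) < 2 or len(combo.per_experiment_ic50s) < 2:
        p_value = float("nan")
        flagged = True
    else:
        p_value = float(
            stats.ttest_ind(
                mono.per_experiment_ic50s,
                combo.per_experiment_ic50s,
                equal_var=True,
            ).pvalue
        )
    return CombinationResult(
        ic50_mono=mono.ic50_mean,
        ic50_mono_sd=mono.ic50_sd,
        ic50_combo=combo.ic50_mean,
        ic50_combo_sd=combo.ic50_sd,
        fold_shift=fold,
        max_inhibition_percent=max_inhibition,
        p_value=p_value,
        flagged=flagged,
    )


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_growth_curves(
    groups: Sequence[GrowthCurve],
    reference: str,
    timepoint: float,
) -> Dict[str, Tuple[float, str]]:
    """t-test each group against the reference group at one timepoint.

    Returns {treatment: (p_value, stars)}; groups lacking the timepoint
    or with fewer than 2 replicates yield NaN.
    """
    by_name = {g.treatment: g for g in groups}
    if reference not in by_name:
        raise PharmacologyError(f"reference group {reference!r} not present")

    def values_at(group: GrowthCurve) -> Optional[np.ndarray]:
        idx = np.nonzero(np.isclose(group.timepoints, timepoint))[0]
        if idx.size == 0:
            return None
        vals = group.od_values[idx[0]]
        vals = vals[~np.isnan(vals)]
        return vals if vals.size >= 2 else None

    ref_vals = values_at(by_name[reference])
    out: Dict[str, Tuple[float, str]] = {}
    for name, group in by_name.items():
        if name == reference:
            continue
        vals = values_at(group)
        if vals is None or ref_vals is None:
            out[name] = (float("nan"), "")
            continue
        p = float(stats.ttest_ind(vals, ref_vals, equal_var=True).pvalue)
        out[name] = (p, significance_stars(p))
    return out
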