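"""Plate-quality statistics and acceptance criteria.

Implements the screening-window statistics (LOQ, induction factor,
Z-factor), the 4-parameter logistic standard-curve fit with AC50-window and
R² checks, control-substance checks, replicate CVs, and the plate verdict
with its 10%-of-threshold tolerance rescue rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from statistics import fmean, stdev
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "FourPLFit",
    "CriterionCheck",
    "QCReport",
    "Verdict",
    "QCThresholds",
    "loq",
    "induction_factor",
    "z_factor",
    "fit_standard_curve",
    "FitError",
    "control_checks",
    "cv_checks",
    "plate_verdict",
]


class Verdict(str, Enum):
    PASS = "pass"
    TOLERATED = "tolerated"
    FAIL = "fail"


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    ac50: float
    hill: float
    r_squared: float

    def __post_init__(self):
        if self.ac50 <= 0:
            raise ValueError("ac50 must be positive")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


@dataclass(frozen=True)
class CriterionCheck:
    """One criterion's observed value against its threshold."""

    name: str
    value: float | None
    threshold: float
    direction: str  # "<=" value must not exceed threshold; ">=" must reach it
    passed: bool
    #: |value - threshold| / threshold, used by the tolerance rescue rule.
    relative_excess: float | None = None


def _check(name: str, value: float | None, threshold: float, direction: str) -> CriterionCheck:
    if value is None or not math.isfinite(value):
        return CriterionCheck(name, None, threshold, direction, False, None)
    ok = value <= threshold if direction == "<=" else value >= threshold
    excess = 0.0 if ok else abs(value - threshold) / abs(threshold)
    return CriterionCheck(name, value, threshold, direction, ok, excess)


# Defaults per endpoint family: estrogens / androgens / anti-androgens.
@dataclass(frozen=True)
class QCThresholds:
    loq_max: Mapping[str, float] = field(default_factory=lambda: {
        "estrogens": 20.0, "androgens": 15.0, "antiandrogens": 15.0})
    basal_over_loq_min: Mapping[str, float] = field(default_factory=lambda: {
        "estrogens": 2.5, "androgens": 5.0, "antiandrogens": 5.0})
    basal_window_pct: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "estrogens": (20.0, 80.0), "androgens": (20.0, 80.0),
        "antiandrogens": (40.0, 160.0)})
    r_squared_min: Mapping[str, float] = field(default_factory=lambda: {
        "estrogens": 0.95, "androgens": 0.96, "antiandrogens": 0.96})
    ac50_window: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "estrogens": (6.5e-12, 3e-11), "androgens": (1.2e-10, 4.3e-10),
        "antiandrogens": (2.4e-7, 1.4e-6)})
    induction_factor_min: Mapping[str, float] = field(default_factory=lambda: {
        "estrogens": 8.0, "androgens": 18.0, "antiandrogens": 10.0})
    z_factor_min: Mapping[str, float] = field(default_factory=lambda: {
        "estrogens": 0.5, "androgens": 0.6, "antiandrogens": 0.5})
    # Control-substance criteria (% of DMSO control / % viability).
    forskolin_estrogen_min: float = 150.0
    pfos_androgen_min: float = 115.0
    prochloraz_max: float = 50.0
    menadione_viability_max: float = 20.0
    cv_within_max: float = 30.0
    cv_between_max: float = 30.0
    tolerance: float = 0.10


DEFAULT_THRESHOLDS = QCThresholds()


def loq(vehicle_ri: Sequence[float]) -> float:
    """Limit of quantification: mean + 10 x sample SD of the vehicle %RI."""
    if len(vehicle_ri) < 3:
        raise ValueError("LOQ needs at least 3 vehicle %RI values")
    return fmean(vehicle_ri) + 10.0 * stdev(vehicle_ri)


def induction_factor(mu_pos: float, mu_neg: float) -> float:
    """Ratio of positive- to negative-control mean RLU on a standard curve."""
    if mu_neg <= 0:
        raise ValueError("negative-control mean must be positive")
    return mu_pos / mu_neg


def z_factor(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Screening-window statistic 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|."""
    if mu_pos == mu_neg:
        raise ValueError("positive and negative means must differ")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / abs(mu_pos - mu_neg)


class FitError(RuntimeError):
    pass


def _four_pl_log(logc: np.ndarray, bottom: float, top: float,
                 log_ac50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_ac50 - logc)))


def fit_standard_curve(concentrations: Sequence[float],
                       responses: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit on log10(concentration).

    Requires >= 4 distinct positive concentrations.  Degenerate data (flat
    responses) or non-convergence raise :class:`FitError`; callers treat
    that as a failed curve criterion.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    mask = conc > 0
    conc, resp = conc[mask], resp[mask]
    if len(set(conc.tolist())) < 4:
        raise FitError("need at least 4 distinct positive concentrations")
    if np.ptp(resp) == 0:
        raise FitError("flat responses; cannot fit a sigmoid")
    logc = np.log10(conc)
    lo, hi = float(resp.min()), float(resp.max())
    # Initialize the midpoint from the concentration nearest half-response.
    half = (lo + hi) / 2.0
    log_ac50_0 = float(logc[np.argmin(np.abs(resp - half))])
    # Initial slope sign from the observed trend (antagonist curves fall).
    trend = np.corrcoef(logc, resp)[0, 1]
    p0 = (lo, hi, log_ac50_0, 1.0 if trend >= 0 else -1.0)
    try:
        popt, _ = optimize.curve_fit(
            _four_pl_log, logc, resp, p0=p0, maxfev=20000, xtol=1e-8, ftol=1e-8)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log_ac50, hill = map(float, popt)
    pred = _four_pl_log(logc, *popt)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if not math.isfinite(log_ac50) or not math.isfinite(hill):
        raise FitError("non-finite fit parameters")
    # Report with top/bottom ordered by response direction of the fit.
    return FourPLFit(bottom=bottom, top=top, ac50=10 ** log_ac50,
                     hill=hill, r_squared=min(r2, 1.0))


def control_checks(observed: Mapping[str, float | None],
                   thresholds: QCThresholds = DEFAULT_THRESHOLDS,
                   ) -> dict[str, CriterionCheck]:
    """Check control substances against their acceptance thresholds.

    ``observed`` maps control names to measured values (% of DMSO control
    for the steroidogenesis controls; % viability for menadione). A missing
    control (None) marks that criterion unevaluable, which fails the plate.
    """
    specs = {
        "forskolin_estrogen_induction": (thresholds.forskolin_estrogen_min, ">="),
        "pfos_androgen_induction": (thresholds.pfos_androgen_min, ">="),
        "prochloraz_inhibition": (thresholds.prochloraz_max, "<="),
        "menadione_viability": (thresholds.menadione_viability_max, "<="),
    }
    out = {}
    for name, (thr, direction) in specs.items():
        if name in observed:
            out[name] = _check(name, observed.get(name), thr, direction)
    return out


def cv_checks(per_plate_basal: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Within- and between-plate CVs (%) of the vehicle-control signal.

    Within: worst per-plate CV over the technical replicates.  Between: CV
    of the per-plate basal means across the biological replicates.
    """
    if not per_plate_basal:
        raise ValueError("no basal records")
    within = []
    means = []
    for values in per_plate_basal:
        if len(values) < 2:
            raise ValueError("need >= 2 values per plate for a CV")
        m = fmean(values)
        if m <= 0:
            raise ValueError("non-positive basal mean")
        within.append(100.0 * stdev(values) / m)
        means.append(m)
    if len(means) >= 2:
        between = 100.0 * stdev(means) / fmean(means)
    else:
        between = 0.0
    return max(within), between


@dataclass
class QCReport:
    """All criteria evaluated for one endpoint family on one plate (set)."""

    family: str  # estrogens | androgens | antiandrogens
    checks: dict[str, CriterionCheck]
    fit: FourPLFit | None = None
    loq: float | None = None
    verdict: Verdict = Verdict.FAIL
    tolerated_criteria: list[str] = field(default_factory=list)

    def finalize(self, tolerance: float = 0.10) -> "QCReport":
        self.verdict, self.tolerated_criteria = plate_verdict(self.checks, tolerance)
        return self


def plate_verdict(checks: Mapping[str, CriterionCheck],
                  tolerance: float = 0.10) -> tuple[Verdict, list[str]]:
    """Pass if all criteria pass; tolerated if every failure lies within
    ``tolerance`` (relative) of its threshold; fail otherwise.

    Unevaluable criteria (missing value) always fail the plate outright.
    """
    failing = [c for c in checks.values() if not c.passed]
    if not failing:
        return Verdict.PASS, []
    if any(c.relative_excess is None for c in failing):
        return Verdict.FAIL, []
    if all(c.relative_excess <= tolerance + 1e-12 for c in failing):
        return Verdict.TOLERATED, [c.name for c in failing]
    return Verdict.FAIL, []


def evaluate_standard_curve(concentrations: Sequence[float],
                            responses: Sequence[float],
                            family: str,
                            mu_pos: float, sd_pos: float,
                            mu_neg: float, sd_neg: float,
                            vehicle_ri: Sequence[float],
                            thresholds: QCThresholds = DEFAULT_THRESHOLDS,
                            ) -> QCReport:
    """Bundle the standard-curve criteria for one endpoint family."""
    checks: dict[str, CriterionCheck] = {}
    the_loq = loq(vehicle_ri)
    checks["loq"] = _check("loq", the_loq, thresholds.loq_max[family], "<=")
    checks["induction_factor"] = _check(
        "induction_factor", induction_factor(mu_pos, mu_neg),
        thresholds.induction_factor_min[family], ">=")
    checks["z_factor"] = _check(
        "z_factor", z_factor(mu_pos, sd_pos, mu_neg, sd_neg),
        thresholds.z_factor_min[family], ">=")
    fit = None
    try:
        fit = fit_standard_curve(concentrations, responses)
        checks["r_squared"] = _check("r_squared", fit.r_squared,
                                     thresholds.r_squared_min[family], ">=")
        lo, hi = thresholds.ac50_window[family]
        in_window = lo <= fit.ac50 <= hi
        # Window check: relative excess measured from the nearer edge.
        excess = 0.0 if in_window else min(abs(fit.ac50 - lo) / lo,
                                           abs(fit.ac50 - hi) / hi)
        checks["ac50_window"] = CriterionCheck(
            "ac50_window", fit.ac50, lo if fit.ac50 < lo else hi,
            ">=" if fit.ac50 < lo else "<=", in_window, excess)
    except FitError:
        checks["r_squared"] = CriterionCheck(
            "r_squared", None, thresholds.r_squared_min[family], ">=", False, None)
        checks["ac50_window"] = CriterionCheck(
            "ac50_window", None, thresholds.ac50_window[family][0], ">=", False, None)
    report = QCReport(family=family, checks=checks, fit=fit, loq=the_loq)
    return report.finalize(thresholds.tolerance)
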