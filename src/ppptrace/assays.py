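"""Quantitation and normalization for the non-tracer assays.

Covers isotope-dilution calibration (analyte/internal-standard response
ratio vs. concentration), consumption/production rates per microgram
protein, glycolysis-stress-test metrics from an ECAR trace, and
baseline-normalized fold changes.

The module is unit-agnostic: concentrations, times and protein amounts are
carried through in whatever consistent units the caller uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    CalibrationError,
    IncompleteTraceError,
    InvalidInputError,
    NormalizationError,
)

__all__ = [
    "CalibrationCurve",
    "EcarTrace",
    "fit_calibration",
    "quantify",
    "consumption_rate",
    "production_rate",
    "glycolysis_stress_metrics",
    "fold_change",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Isotope-dilution calibration line: response ratio = slope * conc +
    intercept, with the calibrated concentration interval retained so that
    quantitation outside it can be flagged."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class EcarTrace:
    """An extracellular-acidification-rate time series with the three
    glycolysis-stress-test injections (glucose, oligomycin, 2-DG)."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    injections: tuple[float, float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size == 0:
            raise InvalidInputError("times and values must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        inj = tuple(float(x) for x in self.injections)
        if len(inj) != 3 or not inj[0] < inj[1] < inj[2]:
            raise InvalidInputError("need three ordered injection times")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "values", tuple(v))
        object.__setattr__(self, "injections", inj)

    def phase_values(self) -> dict[str, np.ndarray]:
        """Measurements per assay phase, split at the injection times."""
        t = np.asarray(self.times)
        v = np.asarray(self.values)
        g, o, d = self.injections
        return {
            "pre_glucose": v[t < g],
            "post_glucose": v[(t >= g) & (t < o)],
            "post_oligomycin": v[(t >= o) & (t < d)],
            "post_2dg": v[t >= d],
        }


def fit_calibration(concentrations, response_ratios, analyte: str = "") -> CalibrationCurve:
    """Ordinary least-squares calibration line of response ratio on
    concentration.

    Requires at least three distinct concentration levels (replicate points
    at the same concentration are fine).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(response_ratios, dtype=float)
    if x.size != y.size:
        raise CalibrationError("concentration and ratio vectors differ in length")
    if np.unique(x).size < 3:
        raise CalibrationError("need >= 3 distinct concentration levels")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_range=(float(x.min()), float(x.max())),
    )


def quantify(ratio: float, curve: CalibrationCurve) -> float:
    """Invert the calibration line: concentration = (ratio - intercept) / slope.

    Warns (and floors at zero) for ratios below the intercept, and warns
    when the result falls outside the calibrated concentration range.
    """
    conc = (float(ratio) - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"response ratio {ratio:.4g} below calibration intercept; "
            "concentration clamped to 0",
            stacklevel=2,
        )
        return 0.0
    lo, hi = curve.conc_range
    if conc < lo - 1e-9 or conc > hi + 1e-9:
        warnings.warn(
            f"concentration {conc:.4g} outside calibrated range [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    return conc


def _rate(delta: float, hours: float, protein_ug: float) -> float:
    if hours <= 0:
        raise InvalidInputError("incubation time must be positive")
    if protein_ug <= 0:
        raise NormalizationError("protein amount must be positive")
    return delta / hours / protein_ug


def consumption_rate(sample_conc: float, blank_conc: float, hours: float, protein_ug: float) -> float:
    """Substrate consumption per hour per microgram protein (positive =
    consumed), from sample vs. medium-blank concentrations."""
    return _rate(blank_conc - sample_conc, hours, protein_ug)


def production_rate(sample_conc: float, blank_conc: float, hours: float, protein_ug: float) -> float:
    """Product release per hour per microgram protein (positive = produced),
    e.g. lactate accumulating above the medium blank."""
    return _rate(sample_conc - blank_conc, hours, protein_ug)


def glycolysis_stress_metrics(trace: EcarTrace, phase_stat: str = "mean") -> dict[str, float]:
    """Glycolysis-stress-test metrics from an ECAR trace.

    Definitions follow the standard assay conventions:

    * ``non_glycolytic``     = pre-glucose ECAR
    * ``glycolysis``         = post-glucose ECAR - non_glycolytic
    * ``glycolytic_capacity``= post-oligomycin ECAR - non_glycolytic
    * ``glycolytic_reserve`` = capacity - glycolysis

    ``phase_stat`` selects the per-phase summary: ``"mean"`` over all
    measurements between injections (default) or ``"last"`` (last point
    before the next injection).  A post-2-DG level below baseline is
    reported as-is, not treated as an error.
    """
    phases = trace.phase_values()
    for name, vals in phases.items():
        if vals.size == 0:
            raise IncompleteTraceError(f"no measurements in phase {name!r}")
    if phase_stat == "mean":
        level = {k: float(np.mean(v)) for k, v in phases.items()}
    elif phase_stat == "last":
        level = {k: float(v[-1]) for k, v in phases.items()}
    else:
        raise InvalidInputError(f"unknown phase_stat {phase_stat!r}")
    non_gly = level["pre_glucose"]
    glycolysis = level["post_glucose"] - non_gly
    capacity = level["post_oligomycin"] - non_gly
    return {
        "non_glycolytic": non_gly,
        "glycolysis": glycolysis,
        "glycolytic_capacity": capacity,
        "glycolytic_reserve": capacity - glycolysis,
        "post_2dg": level["post_2dg"],
    }


def fold_change(treated_series, control_series, baseline_index: int = 0) -> np.ndarray:
    """Treated/control fold change after normalizing each series to its own
    baseline value (e.g. the 0 h measurement).

    A fold change below one at late times means the treated signal grew
    less than control - or, if the treated series dropped below its own
    baseline, net loss.
    """
    t = np.asarray(treated_series, dtype=float)
    c = np.asarray(control_series, dtype=float)
    if t.shape != c.shape:
        raise InvalidInputError("treated and control series must have equal length")
    if t[baseline_index] <= 0 or c[baseline_index] <= 0:
        raise NormalizationError("baseline values must be positive")
    return (t / t[baseline_index]) / (c / c[baseline_index])
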