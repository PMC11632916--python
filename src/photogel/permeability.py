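"""Permeability-coefficient estimation from transwell fluorescence series.

Plate-reader signal is converted to acceptor concentration through a linear
standard curve, the most linear contiguous stretch of the time course is
selected, and the permeability coefficient follows from the pseudo-steady
reduction of Fick's law::

    P = (dC_a/dt) * V_a / (A * C_d0)        [m/s]

with dC_a/dt the slope of the linear region, V_a the acceptor volume, A the
gel/membrane area and C_d0 the initial donor concentration (treated as
constant within the linear region; donor depletion is a few percent at the
permeabilities of interest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import TranswellAssay
from .stats import grubbs_test

__all__ = [
    "StandardCurve",
    "PermeabilityResult",
    "fit_standard_curve",
    "to_concentration",
    "select_linear_region",
    "permeability_coefficient",
    "analyze_group",
]


@dataclass
class StandardCurve:
    """OLS line through a fluorescence-vs-concentration calibration table."""

    concentrations: np.ndarray  # mg/mL
    readings: np.ndarray        # RFU
    slope: float                # RFU per (mg/mL)
    intercept: float            # RFU
    r_squared: float


@dataclass
class PermeabilityResult:
    p: float                   # m/s
    dcadt: float               # mg mL^-1 s^-1
    window: tuple[int, int]    # (start idx, stop idx exclusive)
    window_r_squared: float


def fit_standard_curve(concentrations, readings) -> StandardCurve:
    """Ordinary least-squares calibration line (slope, intercept, R^2)."""
    conc = np.asarray(concentrations, dtype=float)
    read = np.asarray(readings, dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    slope, intercept = np.polyfit(conc, read, 1)
    pred = intercept + slope * conc
    sst = float(((read - read.mean()) ** 2).sum())
    ssr = float(((read - pred) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return StandardCurve(conc, read, float(slope), float(intercept), r2)


def to_concentration(assay: TranswellAssay, standard: StandardCurve | None = None) -> np.ndarray:
    """Acceptor concentration series: ``dilution * (reading - intercept)/slope``.

    Negative values (read noise near zero signal) are clipped to 0 with a
    warning.
    """
    if standard is None:
        standard = fit_standard_curve(
            assay.standard_concentrations, assay.standard_readings
        )
    if standard.slope <= 0:
        raise ValueError("standard-curve slope must be positive")
    conc = assay.dilution * (assay.readings - standard.intercept) / standard.slope
    if np.any(conc < 0):
        warnings.warn("negative concentrations clipped to 0", stacklevel=2)
        conc = np.clip(conc, 0.0, None)
    return conc


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    pred = intercept + slope * t
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float(((y - pred) ** 2).sum())
    r2 = 1.0 if sst <= 0 else 1.0 - ssr / sst
    return float(slope), float(intercept), r2


def select_linear_region(times, concentrations, min_points: int = 3) -> tuple[int, int]:
    """Contiguous window of length >= min_points maximizing straight-line R^2.

    Ties (within 1e-12) are broken toward the longer, then the earlier,
    window.  Returns (start index, stop index exclusive).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    n = t.size
    if n < min_points:
        raise ValueError(f"need at least {min_points} samples, got {n}")
    best = None  # (r2, length, -start)
    best_window = None
    for start in range(n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            _, _, r2 = _ols_line(t[start:stop], c[start:stop])
            key = (round(r2 / 1e-12) * 1e-12, stop - start, -start)
            if best is None or key > best:
                best = key
                best_window = (start, stop)
    return best_window


def permeability_coefficient(
    assay: TranswellAssay,
    standard: StandardCurve | None = None,
    min_points: int = 3,
) -> PermeabilityResult:
    """Full single-insert pipeline: standard curve → linear window → P."""
    if assay.area <= 0 or assay.c_donor0 <= 0:
        raise ValueError("area and donor concentration must be positive")
    conc = to_concentration(assay, standard)
    start, stop = select_linear_region(assay.times, conc, min_points=min_points)
    slope_h, _, r2 = _ols_line(assay.times[start:stop], conc[start:stop])
    dcadt = slope_h / 3600.0  # mg mL^-1 s^-1
    p = dcadt * assay.v_acceptor / (assay.area * assay.c_donor0)
    return PermeabilityResult(p=float(p), dcadt=float(dcadt),
                              window=(start, stop), window_r_squared=r2)


def analyze_group(
    assays: list[TranswellAssay],
    remove_outliers: bool = True,
    alpha: float = 0.05,
    **kwargs,
) -> dict:
    """Per-insert permeabilities aggregated to a group mean ± SD (m/s).

    Outliers among replicate coefficients are removed with a single-pass
    Grubbs test at ``alpha`` before aggregation (skipped for n < 3).
    """
    results = [permeability_coefficient(a, **kwargs) for a in assays]
    values = np.array([r.p for r in results])
    cleaned = values
    outlier_index = None
    if remove_outliers and values.size >= 3:
        g = grubbs_test(values, alpha=alpha)
        cleaned = g.cleaned
        outlier_index = g.outlier_index
    return {
        "n": int(cleaned.size),
        "p_mean": float(cleaned.mean()),
        "p_sd": float(np.std(cleaned, ddof=1)) if cleaned.size > 1 else 0.0,
        "per_insert": results,
        "outlier_index": outlier_index,
    }
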