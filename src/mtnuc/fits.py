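"""The assay's quantification chain.

From filtered event tables to the headline kinetic quantities:

* cumulative filament counts at a fixed set of time points (the manual
  counting protocol, 10 points per movie);
* the nucleation rate r_nuc as the ordinary-least-squares slope of count
  versus time, per field;
* the cooperativity of templated nucleation as the exponent of a power law
  r_nuc = A * c^n fitted across a tubulin dilution series, with the
  critical-nucleus size estimated as one to two times that exponent;
* the empirical detection threshold (lowest concentration yielding on
  average >= 1 visible filament per field within a 20-min window);
* the elongation threshold as the x-intercept of the speed-versus-
  concentration line;
* per-template nucleation efficiency within a time window; and
* fold-stimulation of nucleation across a MAP dose series.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CountSeries",
    "FitResult",
    "build_count_series",
    "fit_nucleation_rate",
    "fit_power_law",
    "critical_nucleus_range",
    "detect_min_concentration",
    "fit_speed_line",
    "fraction_nucleated",
    "fold_stimulation",
]

DEFAULT_N_TIMEPOINTS = 10
DETECTION_WINDOW_S = 1200.0


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Generic regression output."""

    params: Dict[str, float]
    stderr: Dict[str, float]
    r_squared: float
    residuals: np.ndarray
    method: str


@dataclasses.dataclass(frozen=True)
class CountSeries:
    """Cumulative filament counts per field at fixed time points."""

    timepoints: np.ndarray         # s
    counts: np.ndarray             # cumulative filaments per field
    field_area: float = 164.0 * 164.0   # um^2
    replicate: int = 0

    def __post_init__(self):
        c = np.asarray(self.counts)
        if (c < 0).any() or (np.diff(c) < 0).any():
            raise ValueError("counts must be nonnegative and nondecreasing")


def build_count_series(events: pd.DataFrame,
                       n_timepoints: int = DEFAULT_N_TIMEPOINTS,
                       duration: Optional[float] = None,
                       field_area: float = 164.0 * 164.0,
                       replicate: int = 0) -> CountSeries:
    """Cumulative counts of (already filtered) events at equal time spacing.

    Time points are ``duration/n * {1..n}`` so the final count equals the
    total number of events, mirroring counting a movie to its end.
    """
    if duration is None:
        duration = float(events.attrs.get("config", {}).get("duration", 0.0))
        if duration <= 0.0:
            raise ValueError("duration not given and not present in metadata")
    tp = duration * np.arange(1, n_timepoints + 1) / n_timepoints
    t = np.sort(np.asarray(events["t_nucleation"], dtype=float)) if len(events) else np.array([])
    counts = np.searchsorted(t, tp, side="right").astype(float)
    return CountSeries(timepoints=tp, counts=counts, field_area=field_area,
                       replicate=replicate)


def fit_nucleation_rate(series: CountSeries) -> Tuple[float, FitResult]:
    """Nucleation rate r_nuc (filaments/field/s): OLS slope of count vs time."""
    if series.timepoints.size < 3:
        raise ValueError("need >= 3 timepoints for a rate fit")
    res = stats.linregress(series.timepoints, series.counts)
    fitted = res.intercept + res.slope * series.timepoints
    return float(res.slope), FitResult(
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        stderr={"slope": float(res.stderr), "intercept": float(res.intercept_stderr)},
        r_squared=float(res.rvalue ** 2),
        residuals=series.counts - fitted,
        method="ols")


def fit_power_law(rates: Mapping[float, float]) -> Tuple[float, float, FitResult]:
    """Fit r_nuc = A * c^n across concentrations; returns (A, n, fit).

    Nonlinear least squares initialised from the log-log linear regression;
    the log-log estimate is reported alongside in the fit parameters.
    Nonpositive rates are excluded with a warning.
    """
    c = np.array(sorted(rates.keys()), dtype=float)
    r = np.array([rates[k] for k in sorted(rates.keys())], dtype=float)
    good = r > 0
    if not good.all():
        logger.warning("excluding %d nonpositive rates from power-law fit",
                       int((~good).sum()))
    c, r = c[good], r[good]
    if c.size < 3:
        raise ValueError("need >= 3 concentrations with positive rates")

    loglog = stats.linregress(np.log(c), np.log(r))
    a0, n0 = float(np.exp(loglog.intercept)), float(loglog.slope)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(
            lambda x, a, n: a * np.power(x, n), c, r, p0=[a0, n0],
            maxfev=10000)
    amplitude, exponent = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    fitted = amplitude * c ** exponent
    ss_res = float(np.sum((r - fitted) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    return amplitude, exponent, FitResult(
        params={"amplitude": amplitude, "exponent": exponent,
                "loglog_amplitude": a0, "loglog_exponent": n0},
        stderr={"amplitude": float(perr[0]), "exponent": float(perr[1])},
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        residuals=r - fitted,
        method="nls(loglog-init)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def critical_nucleus_range(exponent: float) -> Tuple[int, int]:
    """Critical-nucleus size range: one to two times the power-law exponent.

    The exponent of r_nuc versus tubulin concentration bounds the number of
    tubulins in the minimal stable assembly on the template; both bounds are
    rounded half-up to integers.
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    return _round_half_up(exponent), _round_half_up(2.0 * exponent)


def detect_min_concentration(
        series_by_conc: Mapping[float, Sequence[CountSeries]],
        window: float = DETECTION_WINDOW_S) -> Optional[float]:
    """Lowest concentration with >= 1 visible filament per field on average.

    For each concentration the replicate-mean cumulative count at the end
    of the window is evaluated; the lowest tested concentration whose mean
    is >= 1 is returned, or None when no concentration qualifies.
    """
    for conc in sorted(series_by_conc.keys()):
        means = []
        for s in series_by_conc[conc]:
            within = s.timepoints <= window + 1e-9
            means.append(float(s.counts[within][-1]) if within.any() else 0.0)
        if np.mean(means) >= 1.0:
            return float(conc)
    return None


def fit_speed_line(speeds: Mapping[float, float]
                   ) -> Tuple[float, float, FitResult]:
    """Line fit of mean growth speed vs concentration; returns
    (slope, x_intercept, fit).

    The x-intercept is the critical tubulin concentration for elongation.
    Raises on a flat line, where the intercept is undefined.
    """
    c = np.array(sorted(speeds.keys()), dtype=float)
    v = np.array([speeds[k] for k in sorted(speeds.keys())], dtype=float)
    if c.size < 2:
        raise ValueError("need >= 2 concentrations")
    res = stats.linregress(c, v)
    if res.slope == 0.0:
        raise ValueError("flat speed line: x-intercept undefined")
    fitted = res.intercept + res.slope * c
    return float(res.slope), float(-res.intercept / res.slope), FitResult(
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        stderr={"slope": float(res.stderr), "intercept": float(res.intercept_stderr)},
        r_squared=float(res.rvalue ** 2),
        residuals=v - fitted,
        method="ols")


def fraction_nucleated(events: pd.DataFrame, n_templates: int,
                       window: float = 540.0) -> float:
    """Fraction of templates that fired a surface event within the window."""
    if n_templates <= 0:
        raise ValueError("n_templates must be positive")
    if len(events) == 0:
        return 0.0
    surface = events[events["origin"] == "surface"]
    return float((surface["t_nucleation"] <= window).sum()) / float(n_templates)


def fold_stimulation(rates: Mapping[float, float],
                     reference: float = 0.0
                     ) -> Tuple[Dict[float, float], float]:
    """Nucleation fold-change of each dose over the reference dose.

    Returns the per-dose fold factors and the maximum fold observed.
    """
    if reference not in rates:
        raise ValueError(f"reference dose {reference!r} not in rates")
    r0 = rates[reference]
    if r0 <= 0:
        raise ValueError("reference rate must be positive")
    folds = {float(d): float(r / r0) for d, r in rates.items()}
    return folds, max(folds.values())
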