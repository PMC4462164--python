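"""Voltage-trace analysis: current density, peak statistics, coulombic accounting.

An MFC records voltage across a known load resistor; dividing by the
resistance and the electrode area gives the current density J (uA/cm^2)
plotted in the field's standard figures.  Integrating the current (A)
over time (s) gives charge in Coulombs, and dividing by the elementary
charge converts charge to a number of transferred electrons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants, stats

from .config import InputError

#: elementary charge, C (exact SI value)
ELEMENTARY_CHARGE = constants.elementary_charge


@dataclass
class CurrentTrace:
    """Raw voltage-vs-time record across the external resistor."""

    time_s: np.ndarray
    voltage_V: np.ndarray
    resistor_ohm: float
    electrode_area_cm2: float
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_V = np.asarray(self.voltage_V, dtype=float)
        if self.time_s.size < 2:
            raise InputError("trace needs at least 2 samples")
        if self.time_s.size != self.voltage_V.size:
            raise InputError("time and voltage must have equal length")
        if self.time_s[0] < 0:
            raise InputError("negative time values are not allowed")
        if not np.all(np.diff(self.time_s) > 0):
            raise InputError("times must be strictly increasing")
        if self.resistor_ohm <= 0 or self.electrode_area_cm2 <= 0:
            raise InputError("resistor and electrode area must be > 0")


@dataclass
class CurrentDensitySeries:
    """Current density J over time, the quantity reported on trace figures."""

    time_h: np.ndarray
    j_uA_per_cm2: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.j_uA_per_cm2 = np.asarray(self.j_uA_per_cm2, dtype=float)
        if self.time_h.size != self.j_uA_per_cm2.size:
            raise InputError("time and density must have equal length")


@dataclass
class ChargeSummary:
    """Integrated charge on a time window and its electron equivalent."""

    q_coulomb: float
    n_electrons: float
    t_start_h: float
    t_end_h: float


def to_current_density(trace: CurrentTrace) -> CurrentDensitySeries:
    """Convert a voltage trace to current density via Ohm's law.

    J[i] = (V[i] / R) / A, expressed in uA/cm^2; time converted s -> h.
    """
    j = trace.voltage_V / trace.resistor_ohm / trace.electrode_area_cm2 * 1e6
    return CurrentDensitySeries(trace.time_s / 3600.0, j, label=trace.label)


def integrate_charge(series: CurrentDensitySeries, area_cm2: float,
                     t_start_h: float | None = None,
                     t_end_h: float | None = None) -> ChargeSummary:
    """Trapezoidal charge integral of the current (A) over seconds.

    The window end points are linearly interpolated when they fall
    between samples.  Exact on piecewise-linear traces sampled at their
    breakpoints.
    """
    if area_cm2 <= 0:
        raise InputError("electrode area must be > 0")
    t = series.time_h
    if t_start_h is None:
        t_start_h = float(t[0])
    if t_end_h is None:
        t_end_h = float(t[-1])
    if t_end_h <= t_start_h:
        raise InputError("empty or inverted integration window")
    if t_start_h < t[0] - 1e-12 or t_end_h > t[-1] + 1e-12:
        raise InputError("integration window outside trace support")

    inside = (t > t_start_h) & (t < t_end_h)
    t_win = np.concatenate(([t_start_h], t[inside], [t_end_h]))
    j_win = np.interp(t_win, t, series.j_uA_per_cm2)
    current_A = j_win * 1e-6 * area_cm2
    q = float(np.trapezoid(current_A, t_win * 3600.0))
    return ChargeSummary(q_coulomb=q, n_electrons=q / ELEMENTARY_CHARGE,
                         t_start_h=t_start_h, t_end_h=t_end_h)


def peak_current_density(series: CurrentDensitySeries,
                         smoothing_window_h: float = 1.0) -> tuple[float, float]:
    """Maximum of the moving-average-smoothed density and its time.

    A centred moving average of width ``smoothing_window_h`` suppresses
    sampling noise; width 0 returns the raw maximum.  Partial windows at
    the trace edges use the samples available.
    """
    if series.time_h.size == 0:
        raise InputError("empty series")
    if smoothing_window_h < 0:
        raise InputError("smoothing window must be >= 0")
    span_h = series.time_h[-1] - series.time_h[0]
    if smoothing_window_h > span_h:
        raise InputError("smoothing window longer than trace")
    j = series.j_uA_per_cm2
    if smoothing_window_h > 0 and series.time_h.size > 1:
        dt = float(np.median(np.diff(series.time_h)))
        n = max(1, int(round(smoothing_window_h / dt)))
        j = (pd.Series(j).rolling(n, center=True, min_periods=1)
             .mean().to_numpy())
    i = int(np.argmax(j))
    return float(j[i]), float(series.time_h[i])


def initial_rise_rate(series: CurrentDensitySeries,
                      fit_fraction_of_peak: float = 0.9) -> float:
    """Slope (uA/cm^2/h) of the initial current onset.

    Least-squares line through the segment from the first sample above
    5% of the peak to the first sample reaching ``fit_fraction_of_peak``
    of the peak, excluding lag and plateau curvature.  Exact on a linear
    ramp.
    """
    if not 0.0 < fit_fraction_of_peak <= 1.0:
        raise InputError("fit_fraction_of_peak must lie in (0, 1]")
    j = series.j_uA_per_cm2
    peak = float(np.max(j)) if j.size else 0.0
    if peak <= 0:
        raise InputError("series never rises; rise rate undefined")
    above_lo = np.nonzero(j > 0.05 * peak)[0]
    above_hi = np.nonzero(j >= fit_fraction_of_peak * peak)[0]
    lo, hi = int(above_lo[0]), int(above_hi[0])
    if hi - lo < 1:
        raise InputError("no rising segment; rise rate undefined")
    seg = slice(lo, hi + 1)
    fit = stats.linregress(series.time_h[seg], j[seg])
    return float(fit.slope)


def replicate_summary(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator; 0 when n = 1) of replicates."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("need at least one value")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd
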