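"""Pressure-trace kinetics: rates, extrema, active-window integration, growth.

The analysis chain for one closed-batch conversion segment is

    resample (30-min grid) -> MER from dp/dt -> smooth -> active window
    -> integral summaries (MER_global, MER_total) + extrema (MER_max, k_min)
    -> turnover statistics

MER is the methane evolution rate in mmol per litre of liquid per hour.
Because 4 moles of gas vanish per mole of CH4 formed (water condensed),

    MER(t) = -(dp/dt) * V_gas / (4 R T V_liquid)

with dp/dt estimated by central differences on the resampled grid.  The
stoichiometric companions are CUR = MER (1 CO2 per CH4) and HUR = 4 MER
(4 H2 per CH4).  Biomass formation is neglected as a carbon sink.

k_min is the most negative slope of the pressure curve (bar/h); its
timestamp marks the moment of fastest conversion and coincides with the
MER peak on clean traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gas_model import (
    BAR_PER_PA,
    R_GAS,
    GasComposition,
    VesselSpec,
    residual_pressure_full_conversion,
    turnover_fraction,
)
from .io_formats import GCResult, ODSeries, PressureSeries

__all__ = [
    "NoActivePhaseError",
    "RateSeries",
    "KineticsResult",
    "GrowthResult",
    "resample_series",
    "mer_from_pressure",
    "smooth_series",
    "k_min",
    "detect_active_window",
    "summarize_kinetics",
    "mer_from_gc",
    "growth_stats",
]

#: Default analysis grid spacing (hours): raw 5-min logs resampled to 30 min.
DEFAULT_INTERVAL_H = 0.5
#: Default centered moving-average window (points on the 30-min grid).
DEFAULT_SMOOTH_WINDOW = 5
#: Default horizontal cut (mmol L^-1 h^-1) locating x_start / x_end.
DEFAULT_ACTIVE_THRESHOLD = 0.1
#: Default relative tolerance on the full-conversion residual pressure.
DEFAULT_FULL_CONVERSION_TOL = 0.02
#: Pressure rises above this (bar) inside one segment are treated as
#: repressurization events and rejected.  Genuine repressurizations raise
#: the pressure by several bar; sensor noise stays well below this bound.
DEFAULT_NOISE_TOL = 0.3


class NoActivePhaseError(ValueError):
    """Raised when the smoothed MER curve never exceeds the activity threshold."""


@dataclass
class RateSeries:
    """Volumetric conversion rates on a regular time grid.

    cur (CO2 uptake) equals mer and hur (H2 uptake) equals 4*mer by the
    reaction stoichiometry; they are stored explicitly for output tables.
    """

    times: np.ndarray
    mer: np.ndarray
    cur: np.ndarray = field(default=None)  # type: ignore[assignment]
    hur: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mer = np.asarray(self.mer, dtype=float)
        if self.cur is None:
            self.cur = self.mer.copy()
        if self.hur is None:
            self.hur = 4.0 * self.mer
        if not (np.isfinite(self.mer).all() and np.isfinite(self.times).all()):
            raise ValueError("rate series contains non-finite values")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class KineticsResult:
    """Derived kinetic quantities for one conversion run (one vessel, one cycle)."""

    vessel_id: str
    cycle: int
    mer_max: float  # mmol L^-1 h^-1, peak of the smoothed MER curve
    t_mer_max: float  # h
    mer_global: float  # mmol L^-1 h^-1, active-window average
    mer_total: float  # mmol L^-1 h^-1, whole-run average
    k_min: float  # bar h^-1, signed (most negative slope)
    t_k_min: float  # h
    turnover_max: float  # percent
    turnover_rate_max: float  # percent h^-1
    time_to_full_conversion: float | None  # h, None if never reached
    x_start: float  # h
    x_end: float  # h
    delta_t: float  # h


@dataclass
class GrowthResult:
    """Interval growth rates and the biomass increase rate from an OD series.

    The biomass increase rate compares each interval's instantaneous
    log-growth against the culture average, scaled by how far the culture
    is from its maximum density:

        rate = mean_i [ OD_max * mu_i / (OD_i * mu_average) ]

    A homogeneously growing culture keeps this near OD_max/OD; unbalanced
    growth inflates individual terms.
    """

    mu_series: np.ndarray  # h^-1, one per interval
    mu_max: float
    mu_average: float
    od_max: float
    biomass_increase_rate: float  # nan when undefined (no net growth)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.biomass_increase_rate)


def resample_series(series: PressureSeries, interval: float = DEFAULT_INTERVAL_H) -> PressureSeries:
    """Linear-interpolate a trace onto a regular grid from first to last timestamp."""
    if interval <= 0:
        raise ValueError(f"interval={interval} h must be positive")
    t0, t1 = series.times[0], series.times[-1]
    n = int(np.floor((t1 - t0) / interval + 1e-9)) + 1
    if n < 2:
        raise ValueError("interval exceeds the span of the series")
    grid = t0 + interval * np.arange(n)
    values = np.interp(grid, series.times, series.pressures)
    return PressureSeries(series.vessel_id, grid, values, vessel=series.vessel)


def _dpdt(series: PressureSeries) -> np.ndarray:
    """Central-difference slope, one-sided at the ends (bar/h)."""
    if len(series) < 3:
        raise ValueError("need at least 3 points for slope estimation")
    return np.gradient(series.pressures, series.times)


def mer_from_pressure(
    series: PressureSeries,
    vessel: VesselSpec,
    noise_tol: float = DEFAULT_NOISE_TOL,
) -> RateSeries:
    """Convert a single-segment pressure trace to a volumetric MER series.

    Raises if the segment contains a pressure rise larger than ``noise_tol``
    bar: such jumps are repressurization events that must be split off by
    RCB segmentation first.
    """
    rises = np.diff(series.pressures)
    if rises.size and rises.max() > noise_tol:
        raise ValueError(
            f"pressure rise of {rises.max():.3g} bar inside a conversion segment "
            f"(> noise tolerance {noise_tol} bar); run RCB segmentation first"
        )
    temperature = vessel.t_incubation
    dpdt = _dpdt(series)
    # mol of gas per bar of headspace pressure at T
    moles_per_bar = (1.0 / BAR_PER_PA) * (vessel.v_gas * 1e-3) / (R_GAS * temperature)
    mer = -dpdt * moles_per_bar / 4.0 / vessel.v_liquid * 1e3  # mmol L^-1 h^-1
    return RateSeries(series.times.copy(), mer)


def smooth_series(rates: RateSeries, window: int = DEFAULT_SMOOTH_WINDOW) -> RateSeries:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window={window} must be an odd positive integer")
    n = len(rates)
    if window > n:
        raise ValueError(f"window={window} exceeds series length {n}")
    half = window // 2
    cumsum = np.concatenate(([0.0], np.cumsum(rates.mer)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smoothed = (cumsum[hi] - cumsum[lo]) / (hi - lo)
    return RateSeries(rates.times.copy(), smoothed)


def k_min(series: PressureSeries) -> tuple[float, float]:
    """Most negative pressure slope (bar/h, signed) and its timestamp.

    Ties break toward the earliest time.
    """
    dpdt = _dpdt(series)
    idx = int(np.argmin(dpdt))  # argmin returns the first minimum
    return float(dpdt[idx]), float(series.times[idx])


def _crossing(t0: float, y0: float, t1: float, y1: float, level: float) -> float:
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level`` (y0 != y1)."""
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_active_window(
    smoothed: RateSeries, threshold: float = DEFAULT_ACTIVE_THRESHOLD
) -> tuple[float, float]:
    """Locate the active conversion phase as threshold crossings of smoothed MER.

    x_start is the first up-crossing of ``threshold`` and x_end the last
    down-crossing, both linearly interpolated between grid points; a series
    that starts or ends above the threshold uses the span boundary.  Raises
    :class:`NoActivePhaseError` if the curve never exceeds the threshold
    (no growth).
    """
    if threshold <= 0:
        raise ValueError(f"threshold={threshold} must be positive")
    t, y = smoothed.times, smoothed.mer
    above = y > threshold
    if not above.any():
        raise NoActivePhaseError(
            f"no active phase detected: smoothed MER never exceeds {threshold}"
        )
    i0 = int(np.argmax(above))
    i1 = int(len(y) - 1 - np.argmax(above[::-1]))
    if i0 == 0:
        x_start = float(t[0])
    else:
        x_start = _crossing(t[i0 - 1], y[i0 - 1], t[i0], y[i0], threshold)
    if i1 == len(y) - 1:
        x_end = float(t[-1])
    else:
        x_end = _crossing(t[i1], y[i1], t[i1 + 1], y[i1 + 1], threshold)
    return x_start, x_end


def _integral_over(times: np.ndarray, values: np.ndarray, a: float, b: float) -> float:
    """Trapezoid integral of a piecewise-linear curve over [a, b] (a <= b)."""
    grid = times[(times > a) & (times < b)]
    xs = np.concatenate(([a], grid, [b]))
    ys = np.interp(xs, times, values)
    return float(np.trapezoid(ys, xs))


def summarize_kinetics(
    series: PressureSeries,
    vessel: VesselSpec,
    threshold: float = DEFAULT_ACTIVE_THRESHOLD,
    interval: float = DEFAULT_INTERVAL_H,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    full_conversion_tol: float = DEFAULT_FULL_CONVERSION_TOL,
    composition: GasComposition | None = None,
    cycle: int = 1,
    noise_tol: float = DEFAULT_NOISE_TOL,
) -> KineticsResult:
    """Run the full chain on one conversion segment and collect all statistics.

    Turnover statistics use the *raw* pressure extrema (they are invariant
    to resampling and smoothing); rate statistics use the smoothed MER
    curve on the analysis grid.
    """
    if composition is None:
        composition = GasComposition()
    resampled = resample_series(series, interval)
    rates = mer_from_pressure(resampled, vessel, noise_tol=noise_tol)
    smoothed = smooth_series(rates, min(smooth_window, len(rates) - (len(rates) + 1) % 2))
    x_start, x_end = detect_active_window(smoothed, threshold)

    delta_t = x_end - x_start
    if delta_t > 0:
        mer_global = _integral_over(smoothed.times, smoothed.mer, x_start, x_end) / delta_t
    else:
        mer_global = float(np.interp(x_start, smoothed.times, smoothed.mer))
    total_span = smoothed.times[-1] - smoothed.times[0]
    mer_total = float(np.trapezoid(smoothed.mer, smoothed.times)) / total_span

    i_max = int(np.argmax(smoothed.mer))
    mer_max = float(smoothed.mer[i_max])
    t_mer_max = float(smoothed.times[i_max])

    slope_min, t_slope_min = k_min(resampled)

    p0 = float(series.pressures[0])
    p_min = float(series.pressures.min())
    turnover_max = 100.0 * turnover_fraction(p0, p_min, composition)
    # d(turnover %)/dt on the analysis grid; percent treated as dimensionless
    turnover_pct = 100.0 * np.array(
        [turnover_fraction(p0, p, composition) for p in resampled.pressures]
    )
    turnover_rate_max = float(np.gradient(turnover_pct, resampled.times).max())

    p_res = residual_pressure_full_conversion(p0, composition)
    reached = resampled.pressures <= p_res * (1.0 + full_conversion_tol)
    time_to_full = float(resampled.times[int(np.argmax(reached))]) if reached.any() else None

    return KineticsResult(
        vessel_id=series.vessel_id,
        cycle=cycle,
        mer_max=mer_max,
        t_mer_max=t_mer_max,
        mer_global=mer_global,
        mer_total=mer_total,
        k_min=slope_min,
        t_k_min=t_slope_min,
        turnover_max=turnover_max,
        turnover_rate_max=turnover_rate_max,
        time_to_full_conversion=time_to_full,
        x_start=x_start,
        x_end=x_end,
        delta_t=delta_t,
    )


def mer_from_gc(
    gc: GCResult,
    p_end: float,
    vessel: VesselSpec,
    duration: float,
    temperature: float | None = None,
) -> float:
    """Whole-run MER from the end-point GC methane fraction.

    MER_GC = y_CH4 * n(p_end) / (V_liquid * duration) in mmol L^-1 h^-1.
    The gas amount defaults to the measurement temperature (bottles are
    equilibrated to room temperature before offline sampling).
    """
    from .gas_model import moles_from_pressure

    if duration <= 0:
        raise ValueError(f"duration={duration} h must be positive")
    if p_end < 0:
        raise ValueError(f"p_end={p_end} bar must be non-negative")
    if temperature is None:
        temperature = vessel.t_measurement
    n_ch4 = gc.y_ch4 * moles_from_pressure(p_end, vessel, temperature)
    return n_ch4 * 1e3 / (vessel.v_liquid * duration)


def growth_stats(od: ODSeries) -> GrowthResult:
    """Per-interval specific growth rates and the biomass increase rate.

    mu_i = ln(OD_{i+1}/OD_i) / (t_{i+1}-t_i).  The biomass increase rate
    averages OD_max*mu_i/(OD_i*mu_average) over intervals, with OD_i taken
    at the interval start.  Undefined (nan) when the culture shows no net
    growth (mu_average = 0).
    """
    if np.any(od.od <= 0):
        raise ValueError("growth statistics require strictly positive OD values")
    if len(od) < 2:
        raise ValueError("need at least 2 OD points")
    dt = np.diff(od.times)
    mu = np.log(od.od[1:] / od.od[:-1]) / dt
    mu_average = float(mu.mean())
    od_max = float(od.od.max())
    if mu_average == 0.0:
        rate = float("nan")
    else:
        rate = float(np.mean(od_max * mu / (od.od[:-1] * mu_average)))
    return GrowthResult(
        mu_series=mu,
        mu_max=float(mu.max()),
        mu_average=mu_average,
        od_max=od_max,
        biomass_increase_rate=rate,
    )
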