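"""Amperometric biosensor calibration, conversion, normalization, detrending.

A sensor is calibrated on the bench against known analyte steps: the mean
current change per injection, divided by the step size, gives the sensor's
sensitivity (nA/mM). A valid sensor responds step-wise to the analyte and
not to the interferant (ascorbate). Recorded currents are then converted to
concentration, binned to 10 s, expressed as percent of the 24-h mean, and
linearly detrended when the fitted trend excursion exceeds 10 percentage
points over the day.
"""
from __future__ import annotations

import numpy as np

from .errors import CalibrationFailure, InputError
from .synth import CurrentTrace
from .types import CalibrationRecord, ConcentrationSeries

__all__ = ["calibrate", "current_to_concentration",
           "normalize_percent_of_mean", "detrend_if_needed"]


def calibrate(trace: CurrentTrace, injection_plan: list[tuple[float, str, float]],
              stabilization_s: float = 60.0,
              interferant_bound_frac: float = 0.05,
              analyte: str = "lactate") -> CalibrationRecord:
    """Derive a sensor's sensitivity constant from a calibration trace.

    Each injection's step response is the mean current over the stabilized
    window before the *next* event minus the mean over the window just
    before the injection. Sensitivity is the mean of (analyte step /
    step_mM). The sensor passes iff every analyte step is positive and the
    largest interferant response is below ``interferant_bound_frac`` times
    the mean analyte step.
    """
    plan = sorted(injection_plan, key=lambda e: e[0])
    analyte_events = [e for e in plan if e[1] == "analyte"]
    interferant_events = [e for e in plan if e[1] != "analyte"]
    if len(analyte_events) < 2 or len(interferant_events) < 1:
        raise InputError("plan needs >= 2 analyte and >= 1 interferant injections")
    t = trace.time_s
    if t[-1] < plan[-1][0] + stabilization_s:
        raise InputError("trace does not cover all injections plus stabilization")

    def window_mean(end: float) -> float:
        mask = (t >= end - stabilization_s) & (t < end)
        if not mask.any():
            raise InputError("insufficient stabilization window")
        return float(trace.current_nA[mask].mean())

    times = [e[0] for e in plan] + [t[-1] + trace.time_s[1] - trace.time_s[0]
                                    if t.size > 1 else t[-1] + 1.0]
    steps = {}
    for i, (t_i, kind, step_mM) in enumerate(plan):
        pre = window_mean(t_i)
        post = window_mean(times[i + 1])
        steps[i] = post - pre

    a_steps = np.array([steps[i] for i, e in enumerate(plan) if e[1] == "analyte"])
    i_steps = np.array([steps[i] for i, e in enumerate(plan) if e[1] != "analyte"])
    a_sizes = np.array([e[2] for e in plan if e[1] == "analyte"], dtype=float)
    if np.any(a_steps <= 0):
        raise CalibrationFailure("non-positive analyte step response")
    if np.any(a_sizes <= 0):
        raise InputError("analyte injections must state a positive step_mM")
    sensitivity = float(np.mean(a_steps / a_sizes))
    baseline = window_mean(plan[0][0])
    passed = bool(np.max(np.abs(i_steps)) <
                  interferant_bound_frac * float(np.mean(a_steps)))
    return CalibrationRecord(baseline, a_steps, i_steps, sensitivity,
                             passed, analyte)


def current_to_concentration(trace: CurrentTrace,
                             calibration: CalibrationRecord,
                             baseline_nA: float | None = None,
                             bin_s: float = 10.0) -> ConcentrationSeries:
    """Convert current to concentration and average into 10-s bins.

    concentration = (current - baseline) / sensitivity. The baseline
    defaults to the sensor's calibration offset (current at zero analyte);
    an in-vivo baseline can be supplied instead.
    """
    if not calibration.passed:
        raise CalibrationFailure(
            "refusing to convert with a failed calibration (interferant response)")
    base = calibration.baseline_nA if baseline_nA is None else baseline_nA
    conc = (trace.current_nA - base) / calibration.sensitivity_nA_per_mM

    per_bin = int(round(bin_s * trace.rate_hz))
    n_bins = conc.size // per_bin
    if n_bins == 0:
        raise InputError("trace shorter than one bin")
    binned = conc[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    starts = trace.time_s[0] + np.arange(n_bins) * bin_s
    return ConcentrationSeries(starts, binned, bin_s, calibration.analyte)


def normalize_percent_of_mean(series: ConcentrationSeries,
                              window_h: float = 24.0) -> ConcentrationSeries:
    """Percent-of-mean normalization over a full window, plus hourly bins.

    percent = 100 * bin / mean over the window; hourly values average the
    per-hour bins (360 of them for 10-s bins).
    """
    n_needed = int(round(window_h * 3600.0 / series.bin_length_s))
    if series.concentration_mM.size < n_needed:
        raise InputError(f"series does not cover the {window_h}-h window")
    window = series.concentration_mM[:n_needed]
    mean = window.mean()
    if mean <= 0:
        raise InputError("window mean must be positive for normalization")
    percent = 100.0 * series.concentration_mM / mean

    per_hour = int(round(3600.0 / series.bin_length_s))
    n_hours = percent.size // per_hour
    hour_means = percent[: n_hours * per_hour].reshape(n_hours, per_hour).mean(axis=1)
    return ConcentrationSeries(series.bin_start_s, series.concentration_mM,
                               series.bin_length_s, series.analyte,
                               percent=percent, hour_means=hour_means,
                               detrended=series.detrended)


def detrend_if_needed(series: ConcentrationSeries,
                      drift_bound_frac: float = 0.10) -> ConcentrationSeries:
    """Remove a linear drift when its fitted excursion exceeds the bound.

    A least-squares line is fit to the percent-of-mean series; when the
    fitted change from start to end exceeds ``drift_bound_frac * 100``
    percentage points the line is subtracted and 100 re-added, otherwise
    the series is returned unchanged. The ``detrended`` flag records which
    branch ran. The 24-h mean of 100% is preserved.
    """
    if series.percent is None:
        raise InputError("normalize_percent_of_mean must run before detrending")
    y = series.percent
    x = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    excursion = abs(slope * (y.size - 1))
    if excursion <= drift_bound_frac * 100.0:
        return ConcentrationSeries(series.bin_start_s, series.concentration_mM,
                                   series.bin_length_s, series.analyte,
                                   percent=y, hour_means=series.hour_means,
                                   detrended=False)
    fitted = slope * x + intercept
    detrended = y - fitted + y.mean()
    per_hour = int(round(3600.0 / series.bin_length_s))
    n_hours = detrended.size // per_hour
    hour_means = detrended[: n_hours * per_hour].reshape(n_hours, per_hour).mean(axis=1)
    return ConcentrationSeries(series.bin_start_s, series.concentration_mM,
                               series.bin_length_s, series.analyte,
                               percent=detrended, hour_means=hour_means,
                               detrended=True)
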