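"""Transition-locked and challenge-locked metabolite dynamics.

Qualifying sleep/wake transitions are switches between a NREM bout lasting
at least 5 min and a wake bout lasting at least 10 min (either direction).
REM epochs are merged into the surrounding sleep (counted as NREM) before
bout measurement, since transition analysis concerns the wake/NREM axis.
Analyte responses are expressed as percent change from the 60-s
pre-transition baseline over the 5 min following the switch, in 10-s bins.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .errors import InputError
from .types import (ChallengeResult, ConcentrationSeries, Hypnogram,
                    TransitionEvent)
from .scoring import segment_bouts

logger = logging.getLogger(__name__)

__all__ = ["find_transitions", "transition_response", "injection_response",
            "state_metabolite_correlation"]

NREM_MIN_S = 5 * 60.0
WAKE_MIN_S = 10 * 60.0
BASELINE_S = 60.0
RESPONSE_S = 300.0
RESPONSE_BIN_S = 10.0


def merge_rem_into_nrem(hypnogram: Hypnogram) -> Hypnogram:
    """Relabel REM epochs as NREM for wake/sleep bout measurement."""
    labels = hypnogram.labels.copy()
    labels[labels == "REM"] = "NREM"
    return Hypnogram(labels, hypnogram.epoch_length, hypnogram.start_zt)


def find_transitions(hypnogram: Hypnogram,
                     nrem_min_s: float = NREM_MIN_S,
                     wake_min_s: float = WAKE_MIN_S) -> list[TransitionEvent]:
    """Qualifying NREM<->WAKE switches, in time order.

    A NREM->WAKE event requires the preceding NREM bout >= 5 min and the
    following wake bout >= 10 min; WAKE->NREM is symmetric. REM epochs are
    merged into NREM first. Transition time is the start of the first epoch
    of the new state.
    """
    hyp = merge_rem_into_nrem(hypnogram)
    bouts = segment_bouts(hyp)
    t0 = hyp.start_zt * 3600.0
    events: list[TransitionEvent] = []
    min_s = {"WAKE": wake_min_s, "NREM": nrem_min_s}
    for prev, nxt in zip(bouts, bouts[1:]):
        if {prev.state, nxt.state} != {"WAKE", "NREM"}:
            continue
        if prev.n_epochs * hyp.epoch_length < min_s[prev.state]:
            continue
        if nxt.n_epochs * hyp.epoch_length < min_s[nxt.state]:
            continue
        events.append(TransitionEvent(
            direction=f"{prev.state}->{nxt.state}",
            time_s=t0 + nxt.start_epoch * hyp.epoch_length))
    return events


def _pct_change_curve(series: ConcentrationSeries, t_event: float,
                      baseline_s: float, response_s: float) -> tuple[float, np.ndarray] | None:
    """Percent change from the pre-event baseline, per bin, or None if
    the series does not cover [t-baseline, t+response)."""
    t = series.bin_start_s
    bl = series.bin_length_s
    pre = (t >= t_event - baseline_s) & (t < t_event)
    post = (t >= t_event) & (t < t_event + response_s)
    n_post = int(round(response_s / bl))
    if pre.sum() < int(round(baseline_s / bl)) or post.sum() < n_post:
        return None
    baseline = float(series.concentration_mM[pre].mean())
    if baseline == 0:
        return None
    curve = 100.0 * (series.concentration_mM[post][:n_post] - baseline) / baseline
    return baseline, curve


def transition_response(events: list[TransitionEvent],
                        series: ConcentrationSeries,
                        baseline_s: float = BASELINE_S,
                        response_s: float = RESPONSE_S) -> dict:
    """Populate events with % change curves; mean +/- SEM per direction.

    Events whose [t - 60 s, t + 5 min) window is not fully covered by the
    series are dropped with a warning. Returns
    {direction: {"mean": curve, "sem": curve, "n": count}} over 10-s bins.
    """
    kept: list[TransitionEvent] = []
    for ev in events:
        res = _pct_change_curve(series, ev.time_s, baseline_s, response_s)
        if res is None:
            logger.warning("dropping event at t=%.0f s: incomplete coverage",
                           ev.time_s)
            continue
        ev.baseline_mM, ev.pct_change = res
        kept.append(ev)
    out = {}
    for direction in ("NREM->WAKE", "WAKE->NREM"):
        curves = np.array([ev.pct_change for ev in kept
                           if ev.direction == direction])
        if curves.size == 0:
            continue
        out[direction] = {
            "mean": curves.mean(axis=0),
            "sem": curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0])
            if curves.shape[0] > 1 else np.full(curves.shape[1], np.nan),
            "n": curves.shape[0],
        }
    return out


def injection_response(series: ConcentrationSeries, hypnogram: Hypnogram,
                       injections: list[tuple[float, str]],
                       baseline_s: float = 600.0,
                       response_s: float = 3600.0) -> ChallengeResult:
    """Challenge responses relative to saline.

    Per injection: percent change from its own 10-min pre-injection baseline
    in 10-s bins. ``pct_max_change`` = (peak % change over treatment
    injections) - (peak % change over saline injections), in percentage
    points. ``delta_pct_wake`` compares % of epochs awake in the response
    window against the baseline window.
    """
    saline = [t for t, kind in injections if kind == "saline"]
    treated = [(t, kind) for t, kind in injections if kind != "saline"]
    if not saline:
        raise InputError("a saline arm is required (normalization undefined)")
    if not treated:
        raise InputError("at least one treatment injection is required")
    treatment = treated[0][1]

    def curves_for(times: list[float]) -> list[np.ndarray]:
        out = []
        for t_i in times:
            res = _pct_change_curve(series, t_i, baseline_s, response_s)
            if res is None:
                logger.warning("injection at t=%.0f s lacks coverage", t_i)
                continue
            out.append(res[1])
        return out

    saline_curves = curves_for(saline)
    treatment_curves = curves_for([t for t, _ in treated])
    if not saline_curves or not treatment_curves:
        raise InputError("insufficient series coverage around injections")
    peak_treat = float(np.mean([c.max() for c in treatment_curves]))
    peak_sal = float(np.mean([c.max() for c in saline_curves]))

    # wake fraction around treatment injections
    ep_t = hypnogram.epoch_times()
    deltas = []
    for t_i, _ in treated:
        pre = (ep_t >= t_i - baseline_s) & (ep_t < t_i)
        post = (ep_t >= t_i) & (ep_t < t_i + response_s)
        if pre.any() and post.any():
            pct = lambda m: 100.0 * np.mean(hypnogram.labels[m] == "WAKE")
            deltas.append(pct(post) - pct(pre))
    delta_wake = float(np.mean(deltas)) if deltas else None

    return ChallengeResult(treatment=treatment,
                           pct_max_change=peak_treat - peak_sal,
                           treatment_curves=treatment_curves,
                           saline_curves=saline_curves,
                           delta_pct_wake=delta_wake)


def state_metabolite_correlation(hourly_states, hourly_percent) -> dict:
    """Pearson correlation of hourly minutes-in-state vs hourly analyte level.

    ``hourly_states`` is the state_minutes_per_hour table;
    ``hourly_percent`` an hourly percent-of-mean array (or a
    ConcentrationSeries carrying hour_means). Returns
    {state: (r, p)} with NaN for zero-variance inputs.
    """
    if isinstance(hourly_percent, ConcentrationSeries):
        if hourly_percent.hour_means is None:
            raise InputError("series has no hourly means; normalize first")
        y_full = np.asarray(hourly_percent.hour_means, dtype=float)
    else:
        y_full = np.asarray(hourly_percent, dtype=float)
    n = min(len(hourly_states), y_full.size)
    if n < 3:
        raise InputError("need >= 3 paired hourly observations")
    y = y_full[:n]
    out = {}
    for s in ("WAKE", "NREM", "REM"):
        x = hourly_states[s].to_numpy()[:n]
        if np.std(x) == 0 or np.std(y) == 0:
            out[s] = (np.nan, np.nan)
            continue
        r, p = stats.pearsonr(x, y)
        out[s] = (float(r), float(p))
    return out
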