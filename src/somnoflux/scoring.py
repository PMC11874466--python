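"""Automatic sleep staging from EEG/EMG and hypnogram summaries.

Scoring follows the standard rodent criteria: wake has high-amplitude EMG;
NREM has delta-dominant EEG with low EMG; REM has theta-dominant EEG with
muscle atonia (very low EMG). The scorer is a deterministic threshold rule
over per-epoch features, with thresholds derived from the recording itself
so that recordings of different absolute gain score identically.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .types import ARTIFACT, Bout, EpochFeatures, Hypnogram, SignalTrace, STATES

logger = logging.getLogger(__name__)

__all__ = [
    "compute_epoch_features",
    "ScoringThresholds",
    "derive_thresholds",
    "score_epochs",
    "state_minutes_per_hour",
    "segment_bouts",
    "hann_periodogram",
]

#: 1-Hz feature bins span 0.5-50 Hz; the first bin is the half-bin [0.5, 1).
FEATURE_EDGES = np.concatenate(([0.5], np.arange(1.0, 51.0)))


def hann_periodogram(x: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-windowed periodogram with window power-normalization.

    Normalized so that a pure sinusoid of amplitude A at an on-bin frequency
    contributes total power A^2/2 (summing its three leakage bins), and so
    that the total over all bins equals the Hann-weighted mean square of the
    signal (Parseval).

    Returns (frequencies, power) with power in the square of the input unit.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    w = np.hanning(n)
    denom = n * np.sum(w * w)
    spec = np.fft.rfft(x * w, axis=-1)
    p = (np.abs(spec) ** 2) / denom
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return freqs, np.squeeze(p)


def compute_epoch_features(eeg: SignalTrace, emg: SignalTrace,
                           epoch_length: float = 10.0) -> EpochFeatures:
    """Per-epoch 1-Hz-binned EEG power (0.5-50 Hz) and EMG RMS.

    The EEG periodogram uses a Hann window (FFT length = epoch samples, no
    zero-padding, 0.1 Hz native resolution for 10-s epochs at 250 Hz); 1-Hz
    bins sum the FFT bins whose center lies in [f, f+1). EMG RMS is computed
    on the mean-subtracted epoch.
    """
    if abs(eeg.duration_s - emg.duration_s) > 1e-9:
        raise InputError("EEG and EMG must cover the same duration")
    L = int(round(epoch_length * eeg.rate_hz))
    if abs(epoch_length * eeg.rate_hz - L) > 1e-9 or eeg.n_samples % L != 0:
        raise InputError("duration must be an integer number of epochs")
    n_epochs = eeg.n_samples // L

    eeg_ep = eeg.samples.reshape(n_epochs, L)
    freqs, p = hann_periodogram(eeg_ep, eeg.rate_hz)
    p = np.atleast_2d(p)

    edges = FEATURE_EDGES
    n_bins = edges.size - 1
    bin_power = np.zeros((n_epochs, n_bins))
    idx = np.searchsorted(edges, freqs, side="right") - 1
    valid = (freqs >= edges[0]) & (freqs < edges[-1])
    for b in range(n_bins):
        sel = valid & (idx == b)
        if sel.any():
            bin_power[:, b] = p[:, sel].sum(axis=1)

    Le = int(round(epoch_length * emg.rate_hz))
    emg_ep = emg.samples.reshape(-1, Le)
    centered = emg_ep - emg_ep.mean(axis=1, keepdims=True)
    emg_rms = np.sqrt(np.mean(centered * centered, axis=1))

    return EpochFeatures(edges, bin_power, emg_rms, epoch_length)


@dataclass
class ScoringThresholds:
    """Thresholds for the rule-based scorer.

    wake_emg: EMG RMS above this -> WAKE.
    rem_ratio: theta/delta power ratio above this (with EMG atonia) -> REM.
    rem_emg: EMG RMS must be below this for REM.
    """

    wake_emg: float
    rem_ratio: float = 2.0
    rem_emg: float = 0.0


def _two_means_split(values: np.ndarray) -> float:
    """Deterministic 1-D 2-means threshold on log values.

    Initialized at the 10th/90th percentiles; returns the midpoint of the
    converged cluster means, back-transformed. Robust to the relative sizes
    of the low- and high-EMG clusters, unlike a fixed percentile.
    """
    x = np.log(np.maximum(values, 1e-12))
    lo, hi = np.percentile(x, [10.0, 90.0])
    if hi - lo < 1e-9:
        return float(np.exp(hi))
    for _ in range(100):
        thr = (lo + hi) / 2.0
        lo_new = x[x <= thr].mean()
        hi_new = x[x > thr].mean()
        if np.isclose(lo_new, lo) and np.isclose(hi_new, hi):
            break
        lo, hi = lo_new, hi_new
    return float(np.exp((lo + hi) / 2.0))


def derive_thresholds(features: EpochFeatures,
                      rem_ratio: float = 2.0,
                      rem_emg_percentile: float = 20.0,
                      wake_emg_percentile: float | None = None
                      ) -> ScoringThresholds:
    """Data-driven thresholds from the recording's own EMG distribution.

    The wake/sleep EMG cut defaults to the midpoint (in log space) between
    the two clusters of a deterministic 2-means split of epoch EMG RMS,
    which is insensitive to how much of the recording is wake; pass
    ``wake_emg_percentile`` to use a fixed percentile instead. The REM
    atonia bound is the 20th percentile of EMG RMS.
    """
    if wake_emg_percentile is not None:
        wake_emg = float(np.percentile(features.emg_rms, wake_emg_percentile))
    else:
        wake_emg = _two_means_split(features.emg_rms)
    rem_emg = float(np.percentile(features.emg_rms, rem_emg_percentile))
    return ScoringThresholds(wake_emg=wake_emg, rem_ratio=rem_ratio,
                             rem_emg=rem_emg)


def score_epochs(features: EpochFeatures,
                 thresholds: ScoringThresholds | None = None,
                 start_zt: float = 0.0) -> Hypnogram:
    """Threshold scorer: WAKE by EMG, then REM by theta/delta + atonia, else NREM.

    A smoothing pass relabels REM epochs not preceded by NREM or REM as
    NREM (REM is physiologically entered from NREM).
    """
    if features.n_epochs == 0:
        raise InputError("empty feature sequence")
    if thresholds is None:
        thresholds = derive_thresholds(features)
    delta = features.band_power(0.5, 4.0)
    theta = features.band_power(4.0, 8.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.maximum(delta, 1e-30), np.inf)

    labels = np.empty(features.n_epochs, dtype=object)
    wake = features.emg_rms > thresholds.wake_emg
    rem = (~wake) & (ratio > thresholds.rem_ratio) & \
        (features.emg_rms < thresholds.rem_emg)
    labels[:] = "NREM"
    labels[rem] = "REM"
    labels[wake] = "WAKE"

    # smoothing: REM must be preceded by NREM or REM
    for i in range(labels.size):
        if labels[i] == "REM" and (i == 0 or labels[i - 1] == "WAKE"):
            labels[i] = "NREM"
    return Hypnogram(labels, epoch_length=features.epoch_length, start_zt=start_zt)


def state_minutes_per_hour(hypnogram: Hypnogram) -> pd.DataFrame:
    """Minutes per ZT hour in each state; rows sum to 60.

    ARTIFACT epochs count as missing: the three state totals within each
    hour are renormalized to 60 min. A partial trailing hour is trimmed
    with a logged warning.
    """
    per_hour = int(round(3600.0 / hypnogram.epoch_length))
    n_hours = hypnogram.n_epochs // per_hour
    if n_hours == 0:
        raise InputError("hypnogram shorter than one hour")
    if hypnogram.n_epochs % per_hour:
        logger.warning("trimming partial trailing hour (%d epochs)",
                       hypnogram.n_epochs % per_hour)
    rows = []
    for h in range(n_hours):
        chunk = hypnogram.labels[h * per_hour:(h + 1) * per_hour]
        counts = {s: int(np.sum(chunk == s)) for s in STATES}
        valid = sum(counts.values())
        zt = (hypnogram.start_zt + h) % 24.0
        if valid == 0:
            rows.append({"zt_hour": zt, **{s: np.nan for s in STATES}})
            continue
        # minutes = count * epoch_min, renormalized so the hour sums to 60
        epoch_min = hypnogram.epoch_length / 60.0
        factor = 60.0 / (valid * epoch_min)
        rows.append({"zt_hour": zt,
                     **{s: counts[s] * epoch_min * factor for s in STATES}})
    return pd.DataFrame(rows)


def segment_bouts(hypnogram: Hypnogram) -> list[Bout]:
    """Maximal same-state runs, in order; concatenation reproduces the input."""
    labels = hypnogram.labels
    bouts: list[Bout] = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            bouts.append(Bout(str(labels[start]), start, i,
                              hypnogram.epoch_length))
            start = i
    return bouts
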