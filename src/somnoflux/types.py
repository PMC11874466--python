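"""Core data containers shared across the analysis stages.

Time convention: all timestamps are seconds since ZT0 (lights-on) of
recording day 1; ZT0-12 is the light period, ZT12-24 dark. Epoch indexing
is 0-based with half-open intervals in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sleep/wake state labels. ARTIFACT is accepted on input but never emitted
#: by the automatic scorer.
STATES = ("WAKE", "NREM", "REM")
ARTIFACT = "ARTIFACT"
VALID_LABELS = STATES + (ARTIFACT,)


@dataclass
class Hypnogram:
    """Sequence of per-epoch sleep/wake state labels.

    Parameters
    ----------
    labels
        One label per scoring epoch, each in ``{"WAKE","NREM","REM","ARTIFACT"}``.
    epoch_length
        Epoch duration in seconds (10 s by convention).
    start_zt
        Zeitgeber time of the first epoch, in hours.
    """

    labels: np.ndarray
    epoch_length: float = 10.0
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length

    def epoch_times(self) -> np.ndarray:
        """Start time of each epoch, seconds since ZT0."""
        return self.start_zt * 3600.0 + np.arange(self.n_epochs) * self.epoch_length


@dataclass
class SignalTrace:
    """Uniformly sampled single-channel signal (EEG or EMG), in microvolts."""

    samples: np.ndarray
    rate_hz: float
    start_zt: float = 0.0
    channel: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class EpochFeatures:
    """Per-epoch spectral and EMG features for a whole recording.

    ``bin_power`` holds absolute power (uV^2) in 1-Hz bins spanning
    0.5-50 Hz: the first bin covers [0.5, 1) Hz, subsequent bins [f, f+1).
    ``emg_rms`` is the root-mean-square of the mean-subtracted EMG epoch.
    """

    bin_edges: np.ndarray          # (n_bins + 1,) Hz
    bin_power: np.ndarray          # (n_epochs, n_bins) uV^2
    emg_rms: np.ndarray            # (n_epochs,) uV
    epoch_length: float = 10.0

    @property
    def n_epochs(self) -> int:
        return int(self.bin_power.shape[0])

    def band_power(self, low: float, high: float) -> np.ndarray:
        """Sum of the 1-Hz bins whose interval lies inside [low, high)."""
        lo = np.maximum(self.bin_edges[:-1], low)
        hi = np.minimum(self.bin_edges[1:], high)
        mask = lo < hi
        return self.bin_power[:, mask].sum(axis=1)

    def total_power(self) -> np.ndarray:
        return self.bin_power.sum(axis=1)


@dataclass
class Bout:
    """Maximal run of consecutive epochs in one state."""

    state: str
    start_epoch: int
    end_epoch: int      # exclusive
    epoch_length: float = 10.0

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_length / 60.0


@dataclass
class ConcentrationSeries:
    """Calibrated analyte concentration in uniform bins.

    ``percent`` is each bin as a percent of the mean over the normalization
    window (set by :func:`somnoflux.biosensor.normalize_percent_of_mean`);
    ``hour_means`` are hourly averages of the percent series.
    """

    bin_start_s: np.ndarray
    concentration_mM: np.ndarray
    bin_length_s: float = 10.0
    analyte: str = "lactate"
    percent: np.ndarray | None = None
    hour_means: np.ndarray | None = None
    detrended: bool = False

    def __post_init__(self) -> None:
        self.bin_start_s = np.asarray(self.bin_start_s, dtype=float)
        self.concentration_mM = np.asarray(self.concentration_mM, dtype=float)
        if self.bin_start_s.shape != self.concentration_mM.shape:
            raise ValueError("bin times and concentrations must align")
        if self.bin_start_s.size >= 2:
            steps = np.diff(self.bin_start_s)
            if not np.allclose(steps, self.bin_length_s, rtol=0, atol=1e-9):
                raise ValueError("bins must be uniform")


@dataclass
class CalibrationRecord:
    """Result of an amperometric sensor calibration run."""

    baseline_nA: float
    analyte_steps_nA: np.ndarray
    interferant_steps_nA: np.ndarray
    sensitivity_nA_per_mM: float
    passed: bool
    analyte: str = "lactate"


@dataclass
class TransitionEvent:
    """A qualifying sleep/wake state switch.

    ``pct_change`` holds the percent change from the 60-s pre-transition
    baseline at each 10-s bin over the 5 min following the switch (30 bins).
    """

    direction: str                 # "NREM->WAKE" or "WAKE->NREM"
    time_s: float                  # boundary: first epoch of the new state
    baseline_mM: float | None = None
    pct_change: np.ndarray | None = None


@dataclass
class ChallengeResult:
    """Injection-challenge summary for one treatment against saline."""

    treatment: str
    pct_max_change: float          # peak %change(treatment) - peak %change(saline)
    treatment_curves: list = field(default_factory=list)
    saline_curves: list = field(default_factory=list)
    delta_pct_wake: float | None = None


@dataclass
class RhythmResult:
    """Outcome of a rhythmicity test on one time-course."""

    p: float
    period: float
    lag: float
    amplitude: float
    tau: float | None = None
    statistic: float | None = None
    q: float | None = None
    rhythmic: bool | None = None
    mesor: float | None = None
    degenerate: bool = False


@dataclass
class TimeCourse:
    """Replicated observations on a grid of zeitgeber times.

    ``zt`` gives one entry per observation (so replicated timepoints repeat),
    matching ``values`` element-for-element.
    """

    zt: np.ndarray
    values: np.ndarray
    series_id: str = ""

    def __post_init__(self) -> None:
        self.zt = np.asarray(self.zt, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.zt.shape != self.values.shape:
            raise ValueError("zt and values must align")
        if self.zt.size == 0:
            raise ValueError("empty time course")

    def collapse_replicates(self) -> "TimeCourse":
        """Mean value per distinct timepoint, in time order."""
        t = np.unique(self.zt)
        v = np.array([self.values[self.zt == ti].mean() for ti in t])
        return TimeCourse(t, v, self.series_id)
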