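"""Synthetic coupled sleep/metabolite recordings with known ground truth.

The generator emulates the kind of data produced by tethered EEG/EMG +
amperometric biosensor recordings in mice: a Markov-chain hypnogram with
separate light- and dark-period transition matrices, state-dependent
band-limited EEG noise and white-noise EMG, interstitial-fluid analyte
concentrations that relax first-order toward state-dependent targets with
a 24-h sinusoidal component, and a linear amperometric sensor with gain,
offset, drift and Gaussian noise. Isotope-labeling tables with configured
labeled fractions round out the downstream stages.

Two default parameter sets ship with the package: a "WT"-like animal and a
"KO"-like one with globally dampened EEG power (scale 0.7), halved
state-to-lactate rate constants (sluggish transitions) and a 2-h delayed
diurnal acrophase.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import Hypnogram, SignalTrace, STATES

__all__ = [
    "SimConfig",
    "CurrentTrace",
    "default_sim_config",
    "simulate_hypnogram",
    "synthesize_eeg_emg",
    "synthesize_biosensor",
    "synthesize_calibration_trace",
    "synthesize_isotopologue_table",
]

#: EEG bands used by the generator (must match the analysis defaults).
GEN_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

_STATE_IDX = {s: i for i, s in enumerate(STATES)}


@dataclass
class CurrentTrace:
    """Raw amperometric sensor output: current (nA) sampled uniformly."""

    time_s: np.ndarray
    current_nA: np.ndarray
    analyte: str = "lactate"
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if self.time_s.shape != self.current_nA.shape:
            raise ConfigurationError("time and current arrays must align")


@dataclass
class SimConfig:
    """All knobs of the coupled sleep/metabolite simulator.

    Transition matrices are per-epoch probabilities over (WAKE, NREM, REM);
    the WAKE->REM entry is forced to zero (REM is only enterable from NREM)
    and the row renormalized. Band amplitudes are per-band RMS in uV;
    ``power_scale`` multiplies every EEG band amplitude globally. Lactate
    kinetics: dC/dt = k_state * (C_target(state) + D(t) - C) with the diurnal
    term D(t) = A * cos(2*pi*(t - acrophase)/24 h). The sensor maps
    concentration to current linearly with gain (nA/mM), offset (nA), drift
    (nA/h) and additive Gaussian noise (nA).
    """

    genotype_label: str = "WT"
    epoch_length_s: float = 10.0
    eeg_rate_hz: float = 250.0
    sensor_rate_hz: float = 1.0
    transition_matrix_light: np.ndarray = None
    transition_matrix_dark: np.ndarray = None
    band_amplitudes: dict = None          # state -> {band: uV RMS}
    emg_rms: dict = None                  # state -> uV
    power_scale: float = 1.0
    lactate_targets: dict = None          # state -> mM
    lactate_rate: dict = None             # state -> 1/min
    glucose_targets: dict = None
    glucose_rate: dict = None
    diurnal_amplitude: float = 0.15       # mM
    diurnal_acrophase: float = 14.0       # ZT h
    sensor_gain: float = 20.0             # nA per mM
    sensor_offset: float = 5.0            # nA
    drift_slope: float = 0.05             # nA per hour
    noise_sd: float = 0.2                 # nA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix_light is not None:
            self.transition_matrix_light = _validate_matrix(
                np.asarray(self.transition_matrix_light, dtype=float))
        if self.transition_matrix_dark is not None:
            self.transition_matrix_dark = _validate_matrix(
                np.asarray(self.transition_matrix_dark, dtype=float))
        for name in ("sensor_gain", "power_scale", "diurnal_amplitude",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.lactate_rate is not None:
            if any(k < 0 for k in self.lactate_rate.values()):
                raise ConfigurationError("rate constants must be >= 0")

    def targets_for(self, analyte: str) -> tuple[dict, dict]:
        if analyte == "lactate":
            return self.lactate_targets, self.lactate_rate
        if analyte == "glucose":
            return self.glucose_targets, self.glucose_rate
        raise ConfigurationError(f"no kinetics configured for {analyte!r}")


def _validate_matrix(m: np.ndarray) -> np.ndarray:
    if m.shape != (3, 3):
        raise ConfigurationError("transition matrix must be 3x3 over (WAKE, NREM, REM)")
    if np.any(m < 0):
        raise ConfigurationError("transition probabilities must be >= 0")
    # REM only enterable from NREM: zero the WAKE->REM entry, renormalize.
    m = m.copy()
    m[0, 2] = 0.0
    rows = m.sum(axis=1)
    if np.any(rows <= 0):
        raise ConfigurationError("each transition-matrix row needs positive mass")
    m = m / rows[:, None]
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
        raise ConfigurationError("transition-matrix rows must sum to 1")
    return m


# Light period is sleep-dominant in mice (~60% NREM), dark wake-dominant.
_LIGHT_MATRIX = np.array([
    [0.960, 0.040, 0.000],   # WAKE
    [0.016, 0.970, 0.014],   # NREM
    [0.045, 0.055, 0.900],   # REM
])
_DARK_MATRIX = np.array([
    [0.985, 0.015, 0.000],
    [0.028, 0.964, 0.008],
    [0.060, 0.060, 0.880],
])

_BAND_AMPLITUDES = {
    "WAKE": {"delta": 10.0, "theta": 15.0, "alpha": 10.0, "beta": 8.0, "gamma": 8.0},
    "NREM": {"delta": 40.0, "theta": 15.0, "alpha": 8.0, "beta": 5.0, "gamma": 4.0},
    "REM":  {"delta": 8.0,  "theta": 30.0, "alpha": 6.0, "beta": 4.0, "gamma": 4.0},
}
_EMG_RMS = {"WAKE": 30.0, "NREM": 8.0, "REM": 3.0}

# ISF lactate rises with wake and falls during sleep; targets in mM are
# illustrative magnitudes in the physiological ~1-2 mM range.
_LACTATE_TARGETS = {"WAKE": 1.5, "NREM": 1.1, "REM": 1.1}
_LACTATE_RATE_WT = {"WAKE": 0.5, "NREM": 0.5, "REM": 0.5}   # 1/min
# ISF glucose moves opposite to lactate across sleep/wake.
_GLUCOSE_TARGETS = {"WAKE": 1.0, "NREM": 1.25, "REM": 1.25}
_GLUCOSE_RATE_WT = {"WAKE": 0.35, "NREM": 0.35, "REM": 0.35}


def default_sim_config(genotype: str = "WT", seed: int = 0) -> SimConfig:
    """Default parameter sets for a "WT"-like or "KO"-like animal.

    The knockout set dampens global EEG power (scale 0.7, with theta
    additionally reduced and gamma increased in relative terms), halves
    the metabolite rate constants, and delays the diurnal acrophase by 2 h.
    """
    cfg = SimConfig(
        genotype_label=genotype,
        transition_matrix_light=_LIGHT_MATRIX,
        transition_matrix_dark=_DARK_MATRIX,
        band_amplitudes={s: dict(b) for s, b in _BAND_AMPLITUDES.items()},
        emg_rms=dict(_EMG_RMS),
        lactate_targets=dict(_LACTATE_TARGETS),
        lactate_rate=dict(_LACTATE_RATE_WT),
        glucose_targets=dict(_GLUCOSE_TARGETS),
        glucose_rate=dict(_GLUCOSE_RATE_WT),
        seed=seed,
    )
    if genotype.upper() in ("KO", "KIR6.2-KO", "KNOCKOUT"):
        bands = {s: dict(b) for s, b in _BAND_AMPLITUDES.items()}
        for s in bands:
            # dampened overall power with a shifted theta:gamma balance
            bands[s]["theta"] *= np.sqrt(0.7)
            bands[s]["gamma"] *= np.sqrt(1.3)
        cfg = replace(
            cfg,
            genotype_label=genotype,
            power_scale=0.7,
            band_amplitudes=bands,
            lactate_rate={s: k / 2.0 for s, k in _LACTATE_RATE_WT.items()},
            glucose_rate={s: k / 2.0 for s, k in _GLUCOSE_RATE_WT.items()},
            diurnal_acrophase=16.0,
        )
    return cfg


def simulate_hypnogram(config: SimConfig, duration_h: float,
                       seed: int | None = None) -> Hypnogram:
    """Markov-chain hypnogram with light/dark transition matrices.

    The light matrix drives ZT0-12, the dark matrix ZT12-24 (by the epoch's
    start time modulo 24 h). The chain starts in WAKE.
    """
    if duration_h <= 0:
        raise ConfigurationError("duration must be positive")
    n_epochs_f = duration_h * 3600.0 / config.epoch_length_s
    n_epochs = int(round(n_epochs_f))
    if abs(n_epochs_f - n_epochs) > 1e-9:
        raise ConfigurationError("duration must be a whole number of epochs")
    if config.transition_matrix_light is None or config.transition_matrix_dark is None:
        raise ConfigurationError("both transition matrices are required")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # Pre-draw cumulative-probability lookups for speed.
    cum = {
        "light": np.cumsum(config.transition_matrix_light, axis=1),
        "dark": np.cumsum(config.transition_matrix_dark, axis=1),
    }
    u = rng.random(n_epochs)
    labels = np.empty(n_epochs, dtype=object)
    state = 0  # WAKE
    epoch_h = config.epoch_length_s / 3600.0
    for i in range(n_epochs):
        zt = (i * epoch_h) % 24.0
        c = cum["light"] if zt < 12.0 else cum["dark"]
        state = int(np.searchsorted(c[state], u[i], side="right"))
        state = min(state, 2)
        labels[i] = STATES[state]
    return Hypnogram(labels, epoch_length=config.epoch_length_s, start_zt=0.0)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 3-state chain (leading left eigenvector)."""
    vals, vecs = np.linalg.eig(np.asarray(matrix, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    return v / v.sum()


def _shaped_band_noise(rng: np.random.Generator, n_epochs: int, n_ext: int,
                       rate: float, low: float, high: float) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS per (extended) epoch row.

    Spectral shaping: white noise -> rFFT -> zero bins outside [low, high)
    -> inverse transform -> rescale each row to unit RMS.
    """
    white = rng.standard_normal((n_epochs, n_ext))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_ext, d=1.0 / rate)
    mask = (freqs >= low) & (freqs < high)
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=n_ext, axis=1)
    rms = np.sqrt(np.mean(x * x, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def synthesize_eeg_emg(hypnogram: Hypnogram, config: SimConfig,
                       seed: int | None = None) -> tuple[SignalTrace, SignalTrace]:
    """State-dependent EEG (sum of band-limited noise) and white-noise EMG.

    Each epoch's EEG is the sum of five independent band-limited Gaussian
    components scaled so the in-band RMS equals band_amplitude * power_scale.
    Epochs are joined with 0.5-s power-complementary (sin/cos) cross-fades
    to avoid boundary clicks; the fades are power-preserving in expectation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_epochs = hypnogram.n_epochs
    rate = config.eeg_rate_hz
    L = int(round(config.epoch_length_s * rate))
    fade = int(round(0.25 * rate))          # half-fade each side of a boundary
    n_ext = L + 2 * fade
    n_total = n_epochs * L

    amp = np.zeros((n_epochs, len(GEN_BANDS)))
    states = hypnogram.labels
    for j, band in enumerate(GEN_BANDS):
        for s in STATES:
            amp[states == s, j] = config.band_amplitudes[s][band] * config.power_scale

    # Extended epochs, each scaled to its exact per-band RMS, then
    # overlap-added with quadrature (cos/sin) ramps at the seams.
    epochs_ext = np.zeros((n_epochs, n_ext))
    for j, (low, high) in enumerate(GEN_BANDS.values()):
        if np.all(amp[:, j] == 0):
            # keep the random stream position fixed regardless of amplitudes
            comp = _shaped_band_noise(rng, n_epochs, n_ext, rate, low, high)
            continue
        comp = _shaped_band_noise(rng, n_epochs, n_ext, rate, low, high)
        epochs_ext += comp * amp[:, j][:, None]

    theta = np.linspace(0.0, np.pi / 2.0, 2 * fade, endpoint=False)
    rise, fall = np.sin(theta), np.cos(theta)
    win = np.ones(n_ext)
    win[:2 * fade] = rise
    win[-2 * fade:] = fall
    eeg = np.zeros(n_total + 2 * fade)
    for i in range(n_epochs):
        w = win.copy()
        if i == 0:
            w[:2 * fade] = 1.0
        if i == n_epochs - 1:
            w[-2 * fade:] = 1.0
        eeg[i * L: i * L + n_ext] += epochs_ext[i] * w
    eeg = eeg[fade: fade + n_total]

    sigma = np.zeros(n_epochs)
    for s in STATES:
        sigma[states == s] = config.emg_rms[s]
    emg = rng.standard_normal((n_epochs, L)) * sigma[:, None]
    emg = emg.reshape(-1)

    start_zt = hypnogram.start_zt
    return (SignalTrace(eeg, rate, start_zt, "EEG"),
            SignalTrace(emg, rate, start_zt, "EMG"))


def diurnal_component(t_s: np.ndarray | float, amplitude_mM: float,
                      acrophase_h: float) -> np.ndarray | float:
    """24-h sinusoid D(t) = A cos(2 pi (t - acrophase)/24 h), t in seconds."""
    return amplitude_mM * np.cos(2.0 * np.pi * (t_s / 3600.0 - acrophase_h) / 24.0)


def synthesize_biosensor(hypnogram: Hypnogram, config: SimConfig,
                         analyte: str = "lactate", seed: int | None = None,
                         c0: float | None = None) -> CurrentTrace:
    """Amperometric current trace from state-coupled first-order kinetics.

    Concentration relaxes toward C_target(state) + D(t) with per-state rate
    k (1/min), integrated with the exact exponential update over each
    1/sensor_rate interval (the target held at its interval-midpoint value).
    Current = gain*C + offset + drift*t + Gaussian noise.
    """
    targets, rates = config.targets_for(analyte)
    if any(r <= 0 for r in rates.values()):
        raise ConfigurationError("rate constants must be > 0 for all states")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = 1.0 / config.sensor_rate_hz
    n = int(round(hypnogram.duration_s * config.sensor_rate_hz))
    t0 = hypnogram.start_zt * 3600.0
    t = t0 + np.arange(n) * dt

    epoch_of = np.minimum((np.arange(n) * dt / hypnogram.epoch_length).astype(int),
                          hypnogram.n_epochs - 1)
    k_per_s = np.array([rates[s] / 60.0 for s in hypnogram.labels], dtype=float)[epoch_of]
    tgt = np.array([targets[s] for s in hypnogram.labels], dtype=float)[epoch_of]
    d_mid = diurnal_component(t + dt / 2.0, config.diurnal_amplitude,
                              config.diurnal_acrophase)
    decay = np.exp(-k_per_s * dt)

    conc = np.empty(n)
    c = (tgt[0] + diurnal_component(t[0], config.diurnal_amplitude,
                                    config.diurnal_acrophase)) if c0 is None else c0
    for i in range(n):
        conc[i] = c
        T = tgt[i] + d_mid[i]
        c = T + (c - T) * decay[i]

    current = (config.sensor_gain * conc + config.sensor_offset
               + config.drift_slope * (t - t0) / 3600.0)
    if config.noise_sd > 0:
        current = current + rng.normal(0.0, config.noise_sd, n)
    return CurrentTrace(t, current, analyte, config.sensor_rate_hz)


def synthesize_calibration_trace(config: SimConfig,
                                 injection_plan: list[tuple[float, str, float]],
                                 seed: int | None = None,
                                 stabilization_s: float = 120.0,
                                 response_tau_s: float = 15.0,
                                 duration_s: float | None = None
                                 ) -> tuple[CurrentTrace, list]:
    """Benchtop calibration trace: stepwise analyte injections plus interferant.

    Each analyte injection raises the bath concentration by ``step_mM``; the
    sensor approaches the new plateau first-order with time constant
    ``response_tau_s``. A valid sensor shows no response to the interferant
    injection, so interferant steps contribute only noise.
    """
    plan = sorted(injection_plan, key=lambda e: e[0])
    times = [e[0] for e in plan]
    if any(t2 - t1 < stabilization_s for t1, t2 in zip(times, times[1:])):
        raise ConfigurationError(
            "injections must be separated by at least the stabilization window")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    end = (times[-1] + 2 * stabilization_s) if duration_s is None else duration_s
    dt = 1.0 / config.sensor_rate_hz
    n = int(round(end * config.sensor_rate_hz))
    t = np.arange(n) * dt

    conc = np.zeros(n)
    for t_i, kind, step_mM in plan:
        if kind != "analyte":
            continue
        after = t >= t_i
        conc[after] += step_mM * (1.0 - np.exp(-(t[after] - t_i) / response_tau_s))
    current = (config.sensor_gain * conc + config.sensor_offset
               + config.drift_slope * t / 3600.0)
    if config.noise_sd > 0:
        current = current + rng.normal(0.0, config.noise_sd, n)
    return CurrentTrace(t, current, "calibration", config.sensor_rate_hz), plan


def default_calibration_plan(step_mM: float = 1.0, start_s: float = 300.0,
                             spacing_s: float = 300.0) -> list:
    """Two analyte steps, one interferant, two more analyte steps."""
    kinds = ["analyte", "analyte", "interferant", "analyte", "analyte"]
    return [(start_s + i * spacing_s, k, step_mM if k == "analyte" else 0.0)
            for i, k in enumerate(kinds)]


def synthesize_isotopologue_table(group_params: dict, n_per_group: int = 8,
                                  noise_cv: float = 0.1, seed: int = 0,
                                  carbon_counts: dict | None = None) -> pd.DataFrame:
    """Per-sample isotopologue abundances with configured labeled fractions.

    ``group_params`` maps metabolite -> {"total": pool, "fractions":
    {group: labeled fraction}}. The labeled pool is placed in the fully
    labeled isotopologue M+n (n = carbon count), the rest in M+0; each
    abundance is then multiplied by mean-preserving log-normal noise with
    the given coefficient of variation.
    """
    from .sirm import CARBON_COUNTS
    counts = CARBON_COUNTS if carbon_counts is None else carbon_counts
    if n_per_group < 2:
        raise ConfigurationError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    rows = []
    groups = sorted({g for p in group_params.values() for g in p["fractions"]})
    for metabolite, params in group_params.items():
        total = float(params["total"])
        n_c = counts[metabolite]
        for group in groups:
            frac = float(params["fractions"][group])
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"labeled fraction for {metabolite}/{group} outside [0,1]")
            for s in range(n_per_group):
                sample = f"{group}_{s + 1}"
                for iso, ab in ((0, total * (1.0 - frac)), (n_c, total * frac)):
                    if sigma > 0:
                        ab *= rng.lognormal(-sigma ** 2 / 2.0, sigma)
                    rows.append((metabolite, iso, sample, group, ab))
    return pd.DataFrame(rows, columns=["metabolite", "isotopologue", "sample",
                                       "group", "abundance"])
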