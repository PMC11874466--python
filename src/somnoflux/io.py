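"""File readers and writers: EDF for signals, CSV for everything else.

All CSVs are written with a fixed float format so that identical inputs
produce byte-identical files. The EDF writer emits a minimal but standard
EDF file (ASCII header + 16-bit integer records) that round-trips through
standard polysomnography readers; reading goes through ``mne`` when an EDF
path is given.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .synth import CurrentTrace
from .types import ConcentrationSeries, Hypnogram, SignalTrace

__all__ = ["write_edf", "read_eeg_emg", "write_hypnogram", "read_hypnogram",
           "write_current_trace", "read_current_trace",
           "write_concentration", "write_isotopologue_table",
           "read_isotopologue_table", "read_timecourses", "write_csv"]

FLOAT_FMT = "%.10g"


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV write used for every tabular output."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, eeg: SignalTrace, emg: SignalTrace,
              patient_id: str = "X", recording_id: str = "somnoflux") -> None:
    """Write a two-channel (EEG, EMG) EDF file with 1-s data records.

    Samples are scaled to the full 16-bit digital range per channel; the
    quantization step is (physical range)/65535.
    """
    if eeg.rate_hz != emg.rate_hz or eeg.n_samples != emg.n_samples:
        raise InputError("EEG and EMG must share rate and length")
    rate = int(round(eeg.rate_hz))
    n_records = eeg.n_samples // rate
    if n_records * rate != eeg.n_samples:
        raise InputError("signal length must be a whole number of seconds")

    channels = [(eeg, "EEG"), (emg, "EMG")]
    phys_min, phys_max, digital = [], [], []
    for sig, _ in channels:
        lo = float(np.min(sig.samples)) if sig.n_samples else -1.0
        hi = float(np.max(sig.samples)) if sig.n_samples else 1.0
        if hi <= lo:
            hi = lo + 1.0
        scale = 65535.0 / (hi - lo)
        dig = np.round((sig.samples - lo) * scale - 32768.0).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(dig)

    ns = len(channels)
    header_bytes = 256 * (1 + ns)
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field(patient_id, 80))
        f.write(_edf_field(recording_id, 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field("1", 8))
        f.write(_edf_field(ns, 4))
        for _, name in channels:
            f.write(_edf_field(name, 16))
        for _ in channels:
            f.write(_edf_field("AgAgCl electrode", 80))
        for _ in channels:
            f.write(_edf_field("uV", 8))
        for lo in phys_min:
            f.write(_edf_field(f"{lo:.8g}"[:8], 8))
        for hi in phys_max:
            f.write(_edf_field(f"{hi:.8g}"[:8], 8))
        for _ in channels:
            f.write(_edf_field(-32768, 8))
        for _ in channels:
            f.write(_edf_field(32767, 8))
        for _ in channels:
            f.write(_edf_field("", 80))
        for _ in channels:
            f.write(_edf_field(rate, 8))
        for _ in channels:
            f.write(_edf_field("", 32))
        for r in range(n_records):
            for dig in digital:
                f.write(dig[r * rate:(r + 1) * rate].tobytes())


def read_eeg_emg(path) -> tuple[SignalTrace, SignalTrace]:
    """Read paired EEG/EMG from an EDF file or a CSV.

    CSV schema: columns ``zt_seconds``, ``eeg_uV``, ``emg_uV`` with a
    uniform time step. EDF files are read with mne; the first two signal
    channels are taken as EEG and EMG. Non-250-Hz inputs are accepted.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if len(raw.ch_names) < 2:
            raise InputError("EDF must contain at least two signal channels")
        rate = float(raw.info["sfreq"])
        data = raw.get_data(units="uV") if raw.get_montage() is None else raw.get_data()
        return (SignalTrace(data[0], rate, 0.0, "EEG"),
                SignalTrace(data[1], rate, 0.0, "EMG"))
    df = pd.read_csv(path)
    required = {"zt_seconds", "eeg_uV", "emg_uV"}
    if not required.issubset(df.columns):
        raise InputError(f"signal CSV must have columns {sorted(required)}")
    t = df["zt_seconds"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError("signal CSV too short")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise InputError("signal CSV must be uniformly sampled")
    rate = 1.0 / steps[0]
    start_zt = t[0] / 3600.0
    return (SignalTrace(df["eeg_uV"].to_numpy(float), rate, start_zt, "EEG"),
            SignalTrace(df["emg_uV"].to_numpy(float), rate, start_zt, "EMG"))


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    t = hypnogram.epoch_times()
    df = pd.DataFrame({"epoch_index": np.arange(hypnogram.n_epochs),
                       "zt_seconds": t, "label": hypnogram.labels})
    write_csv(df, path)


def read_hypnogram(path, epoch_length: float = 10.0) -> Hypnogram:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InputError("hypnogram CSV needs a 'label' column")
    start_zt = 0.0
    if "zt_seconds" in df.columns and len(df):
        start_zt = float(df["zt_seconds"].iloc[0]) / 3600.0
        if len(df) > 1:
            epoch_length = float(df["zt_seconds"].iloc[1] - df["zt_seconds"].iloc[0])
    return Hypnogram(df["label"].to_numpy(object), epoch_length, start_zt)


def write_current_trace(trace: CurrentTrace, path) -> None:
    write_csv(pd.DataFrame({"zt_seconds": trace.time_s,
                            "current_nA": trace.current_nA}), path)


def read_current_trace(path, analyte: str = "lactate") -> CurrentTrace:
    df = pd.read_csv(path)
    required = {"zt_seconds", "current_nA"}
    if not required.issubset(df.columns):
        raise InputError(f"biosensor CSV must have columns {sorted(required)}")
    t = df["zt_seconds"].to_numpy(float)
    rate = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    return CurrentTrace(t, df["current_nA"].to_numpy(float), analyte, rate)


def write_concentration(series: ConcentrationSeries, path) -> None:
    n = series.bin_start_s.size
    hour = (series.bin_start_s // 3600.0).astype(int)
    df = pd.DataFrame({"bin_start_s": series.bin_start_s,
                       "mM": series.concentration_mM})
    if series.percent is not None:
        df["percent"] = series.percent
        df["hour"] = hour
        if series.hour_means is not None:
            df["hour_mean"] = [series.hour_means[h] if h < series.hour_means.size
                               else np.nan for h in hour - hour[0]]
    write_csv(df, path)


def write_isotopologue_table(table: pd.DataFrame, path) -> None:
    write_csv(table, path)


def read_isotopologue_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    from .sirm import validate_table
    return validate_table(df)


def read_timecourses(path) -> list:
    """Read a time-course CSV (series_id, zt, replicate, value)."""
    from .types import TimeCourse
    df = pd.read_csv(path)
    required = {"series_id", "zt", "value"}
    if not required.issubset(df.columns):
        raise InputError(f"time-course CSV must have columns {sorted(required)}")
    return [TimeCourse(sub["zt"].to_numpy(float), sub["value"].to_numpy(float),
                       str(sid))
            for sid, sub in df.groupby("series_id", sort=True)]
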