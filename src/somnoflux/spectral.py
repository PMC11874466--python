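"""State-resolved EEG spectra, relative band powers, and theta:gamma ratio.

Absolute power is the mean per-epoch Hann periodogram (1-Hz bins) over a
state's non-artifact epochs. Relative power is computed per epoch as each
band's share of that epoch's total 0.5-50 Hz power, then averaged within
state — so per-state relative powers always sum to 100% and are invariant
to global rescaling of the signal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .types import ARTIFACT, EpochFeatures, Hypnogram, STATES

logger = logging.getLogger(__name__)

__all__ = ["BandDefinition", "DEFAULT_BANDS", "state_power_spectra",
           "relative_band_power", "theta_gamma_ratio"]


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float


#: Standard rodent EEG bands; contiguous, covering 0.5-50 Hz.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


def _check_alignment(features: EpochFeatures, hypnogram: Hypnogram) -> None:
    if features.n_epochs != hypnogram.n_epochs:
        raise InputError("features and hypnogram must align epoch-for-epoch")


def state_power_spectra(features: EpochFeatures,
                        hypnogram: Hypnogram) -> pd.DataFrame:
    """Mean absolute power per 1-Hz bin for each state.

    Artifact epochs are excluded; a state with zero scorable epochs is
    omitted with a logged warning. Returns a tidy frame
    (state, freq_low, freq_high, power_uV2).
    """
    _check_alignment(features, hypnogram)
    rows = []
    edges = features.bin_edges
    for s in STATES:
        mask = hypnogram.labels == s
        if not mask.any():
            logger.warning("state %s has no epochs; omitted from spectra", s)
            continue
        mean_p = features.bin_power[mask].mean(axis=0)
        for b in range(mean_p.size):
            rows.append({"state": s, "freq_low": edges[b],
                         "freq_high": edges[b + 1], "power_uV2": mean_p[b]})
    return pd.DataFrame(rows)


def relative_band_power(features: EpochFeatures, hypnogram: Hypnogram,
                        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
                        ) -> pd.DataFrame:
    """Absolute and relative (% of 0.5-50 Hz total) band power per state.

    Relative shares are computed per epoch then averaged within state;
    epochs with zero total power are excluded with a warning. Returns a
    tidy frame (state, band, abs_power_uV2, rel_power_pct).
    """
    _check_alignment(features, hypnogram)
    lo = min(b.low for b in bands)
    hi = max(b.high for b in bands)
    if lo > features.bin_edges[0] + 1e-9 or hi < features.bin_edges[-1] - 1e-9:
        raise InputError("bands must cover the full 0.5-50 Hz feature range")

    band_abs = np.column_stack([features.band_power(b.low, b.high) for b in bands])
    total = band_abs.sum(axis=1)
    ok = total > 0
    if not ok.all():
        logger.warning("excluding %d zero-power epochs", int(np.sum(~ok)))

    rows = []
    for s in STATES:
        mask = (hypnogram.labels == s) & ok
        if not mask.any():
            continue
        shares = band_abs[mask] / total[mask, None] * 100.0
        for j, b in enumerate(bands):
            rows.append({"state": s, "band": b.name,
                         "abs_power_uV2": band_abs[mask, j].mean(),
                         "rel_power_pct": shares[:, j].mean()})
    return pd.DataFrame(rows)


def theta_gamma_ratio(band_table: pd.DataFrame) -> pd.Series:
    """Relative-theta / relative-gamma per state; NaN where gamma is zero."""
    piv = band_table.pivot(index="state", columns="band", values="rel_power_pct")
    if "theta" not in piv or "gamma" not in piv:
        raise InputError("band table must contain theta and gamma")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = piv["theta"] / piv["gamma"]
    ratio[piv["gamma"] <= 0] = np.nan
    ratio.name = "theta_gamma_ratio"
    return ratio
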