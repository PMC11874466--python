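"""End-to-end pipeline chaining simulation through every analysis stage.

``run_pipeline`` executes simulate -> score -> spectra -> biosensor ->
transitions -> rhythms -> sirm (each stage optional), writing per-stage
CSVs, a JSON summary and a log that records package version, seed and a
hash of the configuration. Reruns with identical config and seed produce
byte-identical CSVs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError, SomnofluxError
from . import io as sfio
from .biosensor import (calibrate, current_to_concentration,
                        detrend_if_needed, normalize_percent_of_mean)
from .rhythms import cosinor_fit, jtk_test
from .scoring import compute_epoch_features, score_epochs, \
    state_minutes_per_hour
from .sirm import bin_pathways, compare_groups, fractional_enrichment
from .spectral import relative_band_power, state_power_spectra, \
    theta_gamma_ratio
from .synth import (default_calibration_plan, default_sim_config,
                    simulate_hypnogram, synthesize_biosensor,
                    synthesize_calibration_trace, synthesize_eeg_emg,
                    synthesize_isotopologue_table)
from .transitions import find_transitions, state_metabolite_correlation, \
    transition_response
from .types import TimeCourse

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "score", "spectra", "biosensor", "transitions",
           "rhythms", "sirm")


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    With ``simulate`` enabled the synthetic generator supplies all inputs;
    otherwise file paths must be given for the stages requested.
    """

    out_dir: str = "somnoflux_out"
    seed: int = 0
    genotype: str = "WT"
    duration_h: float = 24.0
    stages: tuple = _STAGES
    write_edf: bool = False
    # analysis thresholds
    detrend_bound_frac: float = 0.10
    fdr_threshold: float = 0.01
    grubbs_alpha: float = 0.05
    # external inputs (bypass simulation)
    eeg_emg_path: str | None = None
    hypnogram_path: str | None = None
    biosensor_path: str | None = None
    isotopologue_path: str | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the summary dict written to disk.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained.
    """
    for path_attr in ("eeg_emg_path", "hypnogram_path", "biosensor_path",
                      "isotopologue_path"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise InputError(f"{path_attr} does not exist: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.digest(), "stages": {}}
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("somnoflux")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("somnoflux %s seed=%d config=%s", __version__, config.seed,
                config.digest())

    state: dict = {}
    try:
        for stage in config.stages:
            try:
                _run_stage(stage, config, state, out, summary)
            except SomnofluxError:
                raise
            except Exception as exc:  # noqa: BLE001 - name the failing stage
                raise SomnofluxError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True, default=float)
        root.removeHandler(handler)
        handler.close()
    return summary


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path,
               summary: dict) -> None:
    sim = default_sim_config(config.genotype, seed=config.seed)

    if stage == "simulate":
        hyp = simulate_hypnogram(sim, config.duration_h, seed=config.seed)
        eeg, emg = synthesize_eeg_emg(hyp, sim, seed=config.seed + 1)
        trace = synthesize_biosensor(hyp, sim, "lactate", seed=config.seed + 2)
        cal_trace, plan = synthesize_calibration_trace(
            sim, default_calibration_plan(), seed=config.seed + 3)
        state.update(truth_hypnogram=hyp, eeg=eeg, emg=emg, trace=trace,
                     cal_trace=cal_trace, cal_plan=plan)
        sfio.write_hypnogram(hyp, out / "truth_hypnogram.csv")
        sfio.write_current_trace(trace, out / "biosensor_raw.csv")
        sfio.write_current_trace(cal_trace, out / "calibration_trace.csv")
        if config.write_edf:
            sfio.write_edf(out / "signals.edf", eeg, emg)
        summary["stages"]["simulate"] = {"n_epochs": hyp.n_epochs}
        return

    if stage == "score":
        if "eeg" not in state and config.eeg_emg_path:
            state["eeg"], state["emg"] = sfio.read_eeg_emg(config.eeg_emg_path)
        if "eeg" in state:
            feats = compute_epoch_features(state["eeg"], state["emg"])
            state["features"] = feats
            hyp = score_epochs(feats)
            state["hypnogram"] = hyp
        elif config.hypnogram_path:
            state["hypnogram"] = sfio.read_hypnogram(config.hypnogram_path)
        else:
            raise InputError("score stage needs signals or an external hypnogram")
        hyp = state["hypnogram"]
        sfio.write_hypnogram(hyp, out / "hypnogram.csv")
        mph = state_minutes_per_hour(hyp)
        sfio.write_csv(mph, out / "state_minutes_per_hour.csv")
        state["minutes_per_hour"] = mph
        info = {"n_epochs": hyp.n_epochs}
        if "truth_hypnogram" in state:
            agree = float(np.mean(hyp.labels == state["truth_hypnogram"].labels))
            info["agreement_with_truth"] = agree
        summary["stages"]["score"] = info
        return

    if stage == "spectra":
        if "features" not in state or "hypnogram" not in state:
            raise InputError("spectra stage needs scored features")
        spectra = state_power_spectra(state["features"], state["hypnogram"])
        band = relative_band_power(state["features"], state["hypnogram"])
        ratio = theta_gamma_ratio(band)
        sfio.write_csv(spectra, out / "state_spectra.csv")
        sfio.write_csv(band, out / "band_power.csv")
        sfio.write_csv(ratio.reset_index(), out / "theta_gamma_ratio.csv")
        summary["stages"]["spectra"] = {
            "theta_gamma_ratio": {s: float(v) for s, v in ratio.items()}}
        return

    if stage == "biosensor":
        if "trace" not in state and config.biosensor_path:
            state["trace"] = sfio.read_current_trace(config.biosensor_path)
        if "cal_trace" not in state:
            cal_trace, plan = synthesize_calibration_trace(
                sim, default_calibration_plan(), seed=config.seed + 3)
            state["cal_trace"], state["cal_plan"] = cal_trace, plan
        record = calibrate(state["cal_trace"], state["cal_plan"])
        series = current_to_concentration(state["trace"], record)
        span_h = series.concentration_mM.size * series.bin_length_s / 3600.0
        series = normalize_percent_of_mean(series, window_h=min(24.0, span_h))
        series = detrend_if_needed(series, config.detrend_bound_frac)
        state["series"] = series
        sfio.write_concentration(series, out / "concentration.csv")
        summary["stages"]["biosensor"] = {
            "sensitivity_nA_per_mM": record.sensitivity_nA_per_mM,
            "passed": record.passed, "detrended": series.detrended}
        return

    if stage == "transitions":
        if "hypnogram" not in state or "series" not in state:
            raise InputError("transitions stage needs a hypnogram and a series")
        events = find_transitions(state["hypnogram"])
        curves = transition_response(events, state["series"])
        rows = [{"time_s": ev.time_s, "direction": ev.direction,
                 "baseline_mM": ev.baseline_mM,
                 **{f"pct_change_bin_{i + 1}": v
                    for i, v in enumerate(ev.pct_change)}}
                for ev in events if ev.pct_change is not None]
        sfio.write_csv(pd.DataFrame(rows), out / "transition_events.csv")
        corr = state_metabolite_correlation(state["minutes_per_hour"],
                                            state["series"])
        sfio.write_csv(pd.DataFrame(
            [{"state": s, "pearson_r": r, "p": p} for s, (r, p) in corr.items()]),
            out / "state_metabolite_correlation.csv")
        summary["stages"]["transitions"] = {
            "n_events": len(rows),
            **{d: {"n": c["n"], "pct_change_5min": float(c["mean"][-1])}
               for d, c in curves.items()}}
        return

    if stage == "rhythms":
        if "series" not in state or state["series"].hour_means is None:
            raise InputError("rhythms stage needs hourly biosensor data")
        hm = state["series"].hour_means
        tc = TimeCourse(np.arange(hm.size, dtype=float) % 24.0, hm, "lactate")
        res = jtk_test(tc)
        mesor, amplitude, acro = cosinor_fit(tc)
        sfio.write_csv(pd.DataFrame([{
            "series_id": "lactate_hourly", "p": res.p, "period": res.period,
            "lag": res.lag, "amplitude": amplitude, "tau": res.tau,
            "mesor": mesor, "acrophase": acro}]), out / "rhythms.csv")
        summary["stages"]["rhythms"] = {"p": res.p, "acrophase_h": acro,
                                        "amplitude_pct": amplitude}
        return

    if stage == "sirm":
        if config.isotopologue_path:
            table = sfio.read_isotopologue_table(config.isotopologue_path)
        else:
            from .sirm import DEFAULT_BINS
            params = {}
            for b, frac_wt, frac_ko in (("glycolysis", 0.2, 0.4),
                                        ("TCA", 0.15, 0.15),
                                        ("neurotransmitter synthesis", 0.2, 0.1),
                                        ("amino acid synthesis", 0.1, 0.1)):
                for met in DEFAULT_BINS[b]:
                    params[met] = {"total": 100.0,
                                   "fractions": {"WT": frac_wt, "KO": frac_ko}}
            table = synthesize_isotopologue_table(params, seed=config.seed + 4)
        enr = fractional_enrichment(table)
        binned = bin_pathways(enr)
        comparison = compare_groups(binned)
        sfio.write_csv(enr, out / "enrichment.csv")
        sfio.write_csv(binned, out / "pathway_bins.csv")
        sfio.write_csv(comparison, out / "pathway_comparison.csv")
        summary["stages"]["sirm"] = {
            row["bin"]: {"p_interaction": float(row["p_interaction"]),
                         "labeled_diff": float(row["labeled_diff"])}
            for _, row in comparison.iterrows()}
        return

    raise InputError(f"unknown stage {stage!r}")
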