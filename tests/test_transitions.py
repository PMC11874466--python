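"""Transition detection, transition-locked responses, challenges, correlations."""
import numpy as np
import pytest

import somnoflux as sf
from somnoflux.errors import InputError
from somnoflux.scoring import state_minutes_per_hour
from somnoflux.synth import default_calibration_plan
from conftest import random_hypnogram


def _hyp(spec):
    """Build a hypnogram from (state, minutes) pairs."""
    labels = []
    for state, minutes in spec:
        labels += [state] * int(minutes * 6)
    return sf.Hypnogram(np.array(labels, dtype=object))


def brute_force_transitions(hypnogram):
    """Independent oracle: scan every epoch boundary, measure run lengths
    directly in both directions on the REM-merged label sequence."""
    lab = np.where(hypnogram.labels == "REM", "NREM", hypnogram.labels)
    t0 = hypnogram.start_zt * 3600.0
    need = {"WAKE": 60, "NREM": 30}   # epochs: 10 min wake, 5 min NREM
    events = []
    for i in range(1, lab.size):
        if lab[i] == lab[i - 1]:
            continue
        back = 0
        j = i - 1
        while j >= 0 and lab[j] == lab[i - 1]:
            back += 1
            j -= 1
        fwd = 0
        j = i
        while j < lab.size and lab[j] == lab[i]:
            fwd += 1
            j += 1
        if back >= need[lab[i - 1]] and fwd >= need[lab[i]]:
            events.append((f"{lab[i - 1]}->{lab[i]}",
                           t0 + i * hypnogram.epoch_length))
    return events


class TestFindTransitions:
    def test_both_criteria_met(self):
        hyp = _hyp([("WAKE", 12), ("NREM", 6), ("WAKE", 12)])
        ev = sf.find_transitions(hyp)
        assert [e.direction for e in ev] == ["WAKE->NREM", "NREM->WAKE"]

    def test_short_nrem_bout_excluded(self):
        hyp = _hyp([("WAKE", 12), ("NREM", 4), ("WAKE", 12)])
        assert sf.find_transitions(hyp) == []

    def test_rem_merges_into_nrem_bout(self):
        hyp = _hyp([("WAKE", 12), ("NREM", 3), ("REM", 3), ("WAKE", 12)])
        ev = sf.find_transitions(hyp)
        assert [e.direction for e in ev] == ["WAKE->NREM", "NREM->WAKE"]

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            hyp = random_hypnogram(rng, 500, p_stay=0.97)
            got = [(e.direction, e.time_s) for e in sf.find_transitions(hyp)]
            assert got == brute_force_transitions(hyp), trial


class TestTransitionResponse:
    def _series(self, values):
        v = np.asarray(values, dtype=float)
        return sf.ConcentrationSeries(np.arange(v.size) * 10.0, v, 10.0)

    def test_constant_series_zero_curves(self):
        hyp = _hyp([("WAKE", 12), ("NREM", 6), ("WAKE", 12)])
        ev = sf.find_transitions(hyp)
        out = sf.transition_response(ev, self._series(np.full(200, 2.0)))
        for d in out:
            assert np.allclose(out[d]["mean"], 0.0)

    def test_linear_rise_reaches_ten_percent(self):
        """Baseline 2.0 mM rising linearly to 2.2 mM at +5 min -> +10%."""
        hyp = _hyp([("WAKE", 12), ("NREM", 6), ("WAKE", 12)])
        ev = [e for e in sf.find_transitions(hyp) if e.direction == "NREM->WAKE"]
        t_ev = ev[0].time_s
        vals = np.full(200, 2.0)
        idx = (np.arange(200) * 10.0 - t_ev) / 300.0
        post = (idx >= 0)
        vals[post] = 2.0 + 0.2 * np.minimum(idx[post] + 10.0 / 300.0, 1.0)
        out = sf.transition_response(ev, self._series(vals))
        assert out["NREM->WAKE"]["mean"][-1] == pytest.approx(10.0)

    def test_gain_invariance(self, wt_day, wt_series, wt_config):
        """% change curves are unchanged by an affine sensor recalibration."""
        ev1 = sf.find_transitions(wt_day["hypnogram"])
        out1 = sf.transition_response(ev1, wt_series)
        scaled = sf.ConcentrationSeries(wt_series.bin_start_s,
                                        wt_series.concentration_mM * 3.7,
                                        wt_series.bin_length_s)
        ev2 = sf.find_transitions(wt_day["hypnogram"])
        out2 = sf.transition_response(ev2, scaled)
        for d in out1:
            assert np.allclose(out1[d]["mean"], out2[d]["mean"])

    def test_wt_rises_faster_than_ko(self):
        """Halved rate constant slows the NREM->wake lactate rise."""
        from somnoflux.synth import synthesize_calibration_trace
        wins = 0
        for seed in range(20):
            final = {}
            for g in ("WT", "KO"):
                cfg = sf.default_sim_config(g)
                hyp = sf.simulate_hypnogram(cfg, 24.0, seed=seed)
                trace = sf.synthesize_biosensor(hyp, cfg, seed=seed + 100)
                cal, plan = synthesize_calibration_trace(
                    cfg, default_calibration_plan(), seed=seed + 200)
                series = sf.current_to_concentration(trace, sf.calibrate(cal, plan))
                out = sf.transition_response(sf.find_transitions(hyp), series)
                final[g] = out["NREM->WAKE"]["mean"][-1] \
                    if "NREM->WAKE" in out else np.nan
            if np.isfinite(final["WT"]) and np.isfinite(final["KO"]) \
                    and final["WT"] > final["KO"]:
                wins += 1
        assert wins >= 19


class TestInjectionResponse:
    def _series_with_bumps(self, bumps, n=2000):
        vals = np.full(n, 2.0)
        t = np.arange(n) * 10.0
        for t_i, height in bumps:
            sel = (t >= t_i) & (t < t_i + 1800.0)
            vals[sel] += height
        return sf.ConcentrationSeries(t, vals, 10.0)

    def _flat_hyp(self, n=2000):
        return sf.Hypnogram(np.array(["WAKE"] * (n // 6 * 6), dtype=object))

    def test_pct_max_change_arithmetic(self):
        series = self._series_with_bumps([(3000.0, 1.0), (12000.0, 0.2)])
        res = sf.injection_response(series, self._flat_hyp(),
                                    [(3000.0, "glucose"), (12000.0, "saline")])
        assert res.pct_max_change == pytest.approx(50.0 - 10.0)

    def test_identical_arms_cancel(self):
        series = self._series_with_bumps([(3000.0, 0.5), (12000.0, 0.5)])
        res = sf.injection_response(series, self._flat_hyp(),
                                    [(3000.0, "glucose"), (12000.0, "saline")])
        assert res.pct_max_change == pytest.approx(0.0)

    def test_missing_saline_arm_rejected(self):
        series = self._series_with_bumps([(3000.0, 0.5)])
        with pytest.raises(InputError):
            sf.injection_response(series, self._flat_hyp(),
                                  [(3000.0, "glucose")])

    def test_uncoupled_challenge_moves_glucose_not_lactate(self):
        """A glucose bolus without glucose->lactate coupling: positive
        glucose % max change, near-zero lactate response and wake shift."""
        glucose = self._series_with_bumps([(3000.0, 1.0), (12000.0, 0.0)])
        lactate = self._series_with_bumps([])
        hyp = self._flat_hyp()
        inj = [(3000.0, "glucose"), (12000.0, "saline")]
        res_g = sf.injection_response(glucose, hyp, inj)
        res_l = sf.injection_response(lactate, hyp, inj)
        assert res_g.pct_max_change > 10.0
        assert abs(res_l.pct_max_change) < 1.0
        assert res_g.delta_pct_wake == pytest.approx(0.0)


class TestStateMetaboliteCorrelation:
    def test_perfect_proportionality(self):
        rng = np.random.default_rng(0)
        wake = rng.random(24) * 60
        tab = sf.state_minutes_per_hour(
            random_hypnogram(rng, 8640, p_stay=0.95))
        tab["WAKE"] = wake
        r, p = sf.state_metabolite_correlation(tab, wake * 2.0)["WAKE"]
        assert r == pytest.approx(1.0)

    def test_constant_analyte_is_missing(self):
        rng = np.random.default_rng(1)
        tab = sf.state_minutes_per_hour(random_hypnogram(rng, 8640))
        out = sf.state_metabolite_correlation(tab, np.full(24, 100.0))
        assert all(np.isnan(v[0]) for v in out.values())

    def test_wake_positive_nrem_negative_across_seeds(self):
        from somnoflux.synth import synthesize_calibration_trace
        hits = 0
        for seed in range(20):
            cfg = sf.default_sim_config("WT")
            hyp = sf.simulate_hypnogram(cfg, 24.0, seed=seed)
            trace = sf.synthesize_biosensor(hyp, cfg, seed=seed + 300)
            cal, plan = synthesize_calibration_trace(
                cfg, default_calibration_plan(), seed=seed + 400)
            series = sf.normalize_percent_of_mean(
                sf.current_to_concentration(trace, sf.calibrate(cal, plan)))
            corr = sf.state_metabolite_correlation(
                state_minutes_per_hour(hyp), series)
            if corr["WAKE"][0] > 0 and corr["NREM"][0] < 0:
                hits += 1
        assert hits >= 19
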