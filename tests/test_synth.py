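"""Generator ground-truth properties: occupancy, band power, kinetics."""
import numpy as np
import pytest
from dataclasses import replace

import somnoflux as sf
from somnoflux.errors import ConfigurationError
from somnoflux.synth import (default_calibration_plan, stationary_distribution,
                             synthesize_calibration_trace)

ALL_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def _uniform_config(**kwargs):
    cfg = sf.default_sim_config("WT")
    return replace(cfg, **kwargs)


class TestSimulateHypnogram:
    def test_absorbing_wake_stays_wake(self, wt_config):
        m = np.array([[1.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])
        cfg = replace(wt_config, transition_matrix_light=m,
                      transition_matrix_dark=m)
        hyp = sf.simulate_hypnogram(cfg, 1.0, seed=0)
        assert set(hyp.labels) == {"WAKE"}

    def test_24h_gives_8640_epochs(self, wt_config):
        hyp = sf.simulate_hypnogram(wt_config, 24.0, seed=0)
        assert hyp.n_epochs == 8640

    def test_rem_never_follows_wake(self, wt_config):
        hyp = sf.simulate_hypnogram(wt_config, 24.0, seed=3)
        lab = hyp.labels
        prev_wake = lab[:-1] == "WAKE"
        assert not np.any((lab[1:] == "REM") & prev_wake)

    def test_occupancy_matches_stationary_distribution(self, wt_config):
        """Empirical occupancy of a long single-matrix chain agrees with the
        leading eigenvector of the transition matrix within 3 binomial SEs
        (inflated for autocorrelation by the mean bout length)."""
        m = wt_config.transition_matrix_light
        cfg = replace(wt_config, transition_matrix_dark=m)
        n = 10 ** 6
        hyp = sf.simulate_hypnogram(cfg, n * 10 / 3600.0, seed=11)
        pi = stationary_distribution(m)
        # effective sample size: epochs / mean sojourn length per state
        for i, s in enumerate(sf.STATES):
            occ = np.mean(hyp.labels == s)
            sojourn = 1.0 / (1.0 - m[i, i])
            se = np.sqrt(pi[i] * (1 - pi[i]) / (n / sojourn))
            assert abs(occ - pi[i]) < 3 * se, (s, occ, pi[i])

    def test_non_stochastic_matrix_rejected(self, wt_config):
        with pytest.raises(ConfigurationError):
            replace(wt_config,
                    transition_matrix_light=np.full((3, 3), -0.1))

    def test_same_seed_bit_identical(self, wt_config):
        a = sf.simulate_hypnogram(wt_config, 2.0, seed=5)
        b = sf.simulate_hypnogram(wt_config, 2.0, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestSynthesizeEegEmg:
    def test_zero_amplitudes_give_zero_eeg(self, wt_config):
        bands = {s: {b: 0.0 for b in ALL_BANDS} for s in sf.STATES}
        cfg = replace(wt_config, band_amplitudes=bands)
        hyp = sf.Hypnogram(np.array(["WAKE"] * 6, dtype=object))
        eeg, _ = sf.synthesize_eeg_emg(hyp, cfg, seed=0)
        assert np.allclose(eeg.samples, 0.0)

    def test_sample_count(self, wt_config):
        hyp = sf.simulate_hypnogram(wt_config, 1.0, seed=0)
        eeg, emg = sf.synthesize_eeg_emg(hyp, wt_config, seed=0)
        assert eeg.n_samples == emg.n_samples == 900_000

    def test_theta_only_rem_power(self, wt_config):
        """Pure-theta epochs carry 4-8 Hz power within 5% of amplitude^2."""
        bands = {s: {b: 0.0 for b in ALL_BANDS} for s in sf.STATES}
        for s in sf.STATES:
            bands[s]["theta"] = 10.0
        cfg = replace(wt_config, band_amplitudes=bands)
        hyp = sf.Hypnogram(np.array(["REM"] * 360, dtype=object))
        eeg, emg = sf.synthesize_eeg_emg(hyp, cfg, seed=7)
        feats = sf.compute_epoch_features(eeg, emg)
        theta = feats.band_power(4.0, 8.0).mean()
        assert abs(theta - 100.0) < 5.0

    def test_same_seed_bit_identical(self, wt_config):
        hyp = sf.Hypnogram(np.array(["NREM"] * 12, dtype=object))
        a, _ = sf.synthesize_eeg_emg(hyp, wt_config, seed=9)
        b, _ = sf.synthesize_eeg_emg(hyp, wt_config, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestSynthesizeBiosensor:
    def test_fixed_point_is_flat(self, wt_config):
        cfg = replace(wt_config, noise_sd=0.0, drift_slope=0.0,
                      diurnal_amplitude=0.0)
        hyp = sf.Hypnogram(np.array(["WAKE"] * 60, dtype=object))
        tr = sf.synthesize_biosensor(hyp, cfg, seed=0,
                                     c0=cfg.lactate_targets["WAKE"])
        expected = cfg.sensor_gain * cfg.lactate_targets["WAKE"] + cfg.sensor_offset
        assert np.allclose(tr.current_nA, expected, atol=1e-12)

    def test_closed_form_exponential_approach(self, wt_config):
        """C(t) = C_target (1 - e^{-kt}) from C(0)=0, to 1e-9 relative."""
        cfg = replace(wt_config, noise_sd=0.0, drift_slope=0.0,
                      diurnal_amplitude=0.0)
        hyp = sf.Hypnogram(np.array(["WAKE"] * 360, dtype=object))
        tr = sf.synthesize_biosensor(hyp, cfg, seed=0, c0=0.0)
        conc = (tr.current_nA - cfg.sensor_offset) / cfg.sensor_gain
        k = cfg.lactate_rate["WAKE"] / 60.0
        expected = cfg.lactate_targets["WAKE"] * (1 - np.exp(-k * tr.time_s))
        rel = np.abs(conc[1:] - expected[1:]) / expected[1:]
        assert rel.max() < 1e-9

    def test_zero_gain_decouples_states(self, wt_config):
        cfg = replace(wt_config, sensor_gain=0.0, noise_sd=0.0)
        hyp_w = sf.Hypnogram(np.array(["WAKE"] * 60, dtype=object))
        hyp_n = sf.Hypnogram(np.array(["NREM"] * 60, dtype=object))
        a = sf.synthesize_biosensor(hyp_w, cfg, seed=1)
        b = sf.synthesize_biosensor(hyp_n, cfg, seed=1)
        assert np.array_equal(a.current_nA, b.current_nA)


class TestCalibrationTrace:
    def test_plateaus_track_gain(self, wt_config):
        cfg = replace(wt_config, sensor_gain=20.0, sensor_offset=10.0,
                      noise_sd=0.0, drift_slope=0.0)
        plan = [(300.0, "analyte", 1.0), (600.0, "analyte", 1.0)]
        tr, _ = synthesize_calibration_trace(cfg, plan, seed=0)
        assert abs(tr.current_nA[595] - 30.0) < 0.1
        assert abs(tr.current_nA[-1] - 50.0) < 0.1

    def test_interferant_step_is_flat(self, wt_config):
        cfg = replace(wt_config, noise_sd=0.0, drift_slope=0.0)
        plan = [(300.0, "analyte", 1.0), (600.0, "interferant", 1.0),
                (900.0, "analyte", 1.0)]
        tr, _ = synthesize_calibration_trace(cfg, plan, seed=0)
        assert abs(tr.current_nA[890] - tr.current_nA[595]) < 1e-6

    def test_five_step_arithmetic(self, wt_config):
        cfg = replace(wt_config, sensor_gain=8.0, sensor_offset=10.0,
                      noise_sd=0.0, drift_slope=0.0)
        plan = [(300.0 + 300 * i, "analyte", 0.5) for i in range(5)]
        tr, _ = synthesize_calibration_trace(cfg, plan, seed=0)
        assert abs(tr.current_nA[-1] - 30.0) < 0.05

    def test_overlapping_injections_rejected(self, wt_config):
        with pytest.raises(ConfigurationError):
            synthesize_calibration_trace(
                wt_config, [(300.0, "analyte", 1.0), (310.0, "analyte", 1.0)])


class TestIsotopologueTable:
    def test_zero_fraction_all_m0(self):
        params = {"lactate": {"total": 100.0, "fractions": {"WT": 0.0}}}
        tab = sf.synthesize_isotopologue_table(params, n_per_group=2,
                                               noise_cv=0.0, seed=0)
        labeled = tab[tab["isotopologue"] > 0]["abundance"]
        assert np.allclose(labeled, 0.0)

    def test_exact_split_without_noise(self):
        params = {"lactate": {"total": 100.0, "fractions": {"WT": 0.25}}}
        tab = sf.synthesize_isotopologue_table(params, n_per_group=2,
                                               noise_cv=0.0, seed=0)
        m0 = tab[tab["isotopologue"] == 0]["abundance"]
        m3 = tab[tab["isotopologue"] == 3]["abundance"]
        assert np.allclose(m0, 75.0) and np.allclose(m3, 25.0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.synthesize_isotopologue_table(
                {"lactate": {"total": 1.0, "fractions": {"WT": 1.5}}})
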