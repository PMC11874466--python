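"""Rhythm tests (JTK exact null, umbrella permutation), cosinor, Grubbs, PPI."""
import itertools
import math

import numpy as np
import pytest

import somnoflux as sf
from somnoflux.errors import InputError
from somnoflux.rhythms import _cosine_reference, _exact_jtk_p, _kendall_s

T12 = np.arange(12) * 2.0


class TestJtkExactNull:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n):
        """Exact p for a single template equals the tail probability from
        enumerating all n! permutations of the data."""
        rng = np.random.default_rng(0)
        t = np.arange(n) * 2.0
        y = _cosine_reference(t, 24.0, 4.0)
        for _ in range(10):
            x = rng.standard_normal(n)
            p, _tau = _exact_jtk_p(x, y)
            s_obs = _kendall_s(x, y)
            cnt = sum(_kendall_s(np.array(perm), y) >= s_obs
                      for perm in itertools.permutations(x))
            assert p == pytest.approx(cnt / math.factorial(n), abs=1e-12)

    def test_noiseless_cosine_recovers_lag(self):
        x = np.cos(2 * np.pi * (T12 - 8.0) / 24.0)
        r = sf.jtk_test(sf.TimeCourse(T12, x))
        assert r.lag == pytest.approx(8.0)
        assert r.p < 0.01

    def test_constant_series_degenerate(self):
        r = sf.jtk_test(sf.TimeCourse(T12, np.full(12, 3.0)))
        assert r.p == 1.0 and r.tau == 0.0 and r.degenerate

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(12)
        p1 = sf.jtk_test(sf.TimeCourse(T12, x)).p
        p2 = sf.jtk_test(sf.TimeCourse(T12, np.exp(x))).p
        assert p1 == p2

    def test_type_one_error_single_template(self):
        """Exact conditional p-values give near-nominal size at alpha=0.05."""
        rng = np.random.default_rng(10)
        rej = sum(sf.jtk_test(sf.TimeCourse(T12, rng.standard_normal(12)),
                              lags=[8.0]).p < 0.05
                  for _ in range(1000))
        assert 0.0365 <= rej / 1000 <= 0.0635

    def test_type_one_error_scanned_grid_bounded(self):
        """The Bonferroni-corrected lag scan never exceeds nominal size."""
        rng = np.random.default_rng(11)
        n = 400
        rej = sum(sf.jtk_test(sf.TimeCourse(T12, rng.standard_normal(12))).p
                  < 0.05 for _ in range(n))
        assert rej / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)


class TestUmbrella:
    def test_perfect_umbrella_hits_permutation_floor(self):
        x = -np.abs(T12 - 10.0)
        r = sf.umbrella_test(sf.TimeCourse(T12, x), n_perm=10000, seed=1)
        assert r.p <= 12.5 / 10001.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(12)
        p1 = sf.umbrella_test(sf.TimeCourse(T12, x), n_perm=2000, seed=3).p
        p2 = sf.umbrella_test(sf.TimeCourse(T12, np.exp(x)),
                              n_perm=2000, seed=3).p
        assert p1 == p2

    def test_type_one_error_bounded(self):
        rng = np.random.default_rng(7)
        n = 250
        rej = sum(sf.umbrella_test(sf.TimeCourse(T12, rng.standard_normal(12)),
                                   n_perm=1000, seed=s).p < 0.05
                  for s in range(n))
        assert rej / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)

    def test_detects_rhythm_at_three_sigma(self):
        """A 24-h profile peaking near ZT10-12 with n=2 replicates and
        amplitude 3x the noise SD is called rhythmic at q < 0.01."""
        rng = np.random.default_rng(8)
        t = np.repeat(T12, 2)
        hits = 0
        for s in range(10):
            x = 10 + 3.0 * np.cos(2 * np.pi * (t - 11.0) / 24.0) \
                + rng.standard_normal(t.size)
            res = sf.test_many([sf.TimeCourse(t, x)], method="umbrella",
                               fdr_threshold=0.01, n_perm=10000, seed=s)
            hits += res[0].rhythmic
        assert hits >= 9


class TestCosinor:
    def test_exact_recovery(self):
        x = 10 + 3 * np.cos(2 * np.pi * (T12 - 6.0) / 24.0)
        m, a, phi = sf.cosinor_fit(sf.TimeCourse(T12, x))
        assert m == pytest.approx(10.0, abs=1e-8)
        assert a == pytest.approx(3.0, abs=1e-8)
        assert phi == pytest.approx(6.0, abs=1e-8)

    def test_flat_series_zero_amplitude(self):
        m, a, phi = sf.cosinor_fit(sf.TimeCourse(T12, np.full(12, 7.0)))
        assert m == pytest.approx(7.0) and a == pytest.approx(0.0)
        assert np.isnan(phi)

    def test_time_shift_moves_acrophase_not_amplitude(self):
        rng = np.random.default_rng(9)
        x = 5 + 2 * np.cos(2 * np.pi * (T12 - 9.0) / 24.0) \
            + rng.normal(0, 0.2, 12)
        _, a1, p1 = sf.cosinor_fit(sf.TimeCourse(T12, x))
        _, a2, p2 = sf.cosinor_fit(sf.TimeCourse(T12 + 5.0, x))
        assert a1 == pytest.approx(a2, abs=1e-9)
        assert (p2 - p1) % 24.0 == pytest.approx(5.0, abs=1e-6)

    def test_acrophase_accuracy_under_noise(self):
        """Mean absolute acrophase error < 1 h at A=2, sd=0.5, 12 points."""
        rng = np.random.default_rng(12)
        errs = []
        for _ in range(20):
            x = 2 * np.cos(2 * np.pi * (T12 - 15.0) / 24.0) \
                + rng.normal(0, 0.5, 12)
            _, _, phi = sf.cosinor_fit(sf.TimeCourse(T12, x))
            d = abs(phi - 15.0)
            errs.append(min(d, 24 - d))
        assert np.mean(errs) < 1.0

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(InputError):
            sf.cosinor_fit(sf.TimeCourse(np.array([0.0, 6.0]),
                                         np.array([1.0, 2.0])))


class TestGrubbs:
    def test_removes_planted_outlier(self):
        kept, removed = sf.grubbs_filter([1, 1, 1, 1, 10])
        assert list(removed) == [10.0]
        assert list(kept) == [1.0, 1.0, 1.0, 1.0]

    def test_clean_sequence_untouched(self):
        kept, removed = sf.grubbs_filter([1, 2, 3, 4, 5])
        assert removed.size == 0 and kept.size == 5

    def test_matches_t_quantile_critical_value(self):
        """G = 1.789 for (1,1,1,1,10) exceeds the alpha=0.05, n=5 critical
        value 1.715 computed from the t quantile."""
        from scipy import stats
        x = np.array([1.0, 1, 1, 1, 10])
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        t = stats.t.ppf(1 - 0.05 / 10, 3)
        crit = 4 / np.sqrt(5) * np.sqrt(t ** 2 / (3 + t ** 2))
        assert g == pytest.approx(1.789, abs=1e-3)
        assert crit == pytest.approx(1.715, abs=1e-3)
        assert g > crit

    def test_identical_values_kept(self):
        kept, removed = sf.grubbs_filter([2.0, 2.0, 2.0, 2.0])
        assert removed.size == 0

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            sf.grubbs_filter([1.0, 2.0])


class TestPercentPpi:
    @pytest.mark.parametrize("alone,prepulse,expected",
                             [(100.0, 40.0, 60.0), (80.0, 80.0, 0.0),
                              (100.0, 0.0, 100.0)])
    def test_formula(self, alone, prepulse, expected):
        assert sf.percent_ppi(alone, prepulse) == pytest.approx(expected)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(InputError):
            sf.percent_ppi(0.0, 10.0)
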