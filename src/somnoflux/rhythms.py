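"""Nonparametric circadian rhythm detection and related estimators.

Two rank-based rhythm tests are provided. The JTK-style test matches a
time-course against phase-shifted cosine templates via Kendall's S, with
p-values from the exact null distribution of S conditioned on the
template's tie pattern (computed by dynamic-programming convolution of
Mann-Whitney distributions — the Jonckheere-Terpstra decomposition) and
Bonferroni correction across the (period, lag) grid. The umbrella-style
test uses a Mack-Wolfe rise-then-fall statistic with seeded Monte-Carlo
permutation p-values, scanning candidate peak positions.

Also here: cosinor least-squares fitting (mesor/amplitude/acrophase),
the single-pass two-sided Grubbs outlier test, BH false-discovery-rate
adjustment across multiple series, and the prepulse-inhibition formula.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import InputError
from .types import RhythmResult, TimeCourse

__all__ = ["jtk_test", "umbrella_test", "cosinor_fit", "grubbs_filter",
           "percent_ppi", "bh_fdr", "test_many"]


# ---------------------------------------------------------------------------
# Exact null machinery for Kendall's S against a tied reference
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mann_whitney_counts(m: int, n: int) -> tuple:
    """Number of arrangements with Mann-Whitney count u, u = 0..m*n."""
    if m == 0 or n == 0:
        return (1,)
    a = _mann_whitney_counts(m - 1, n)  # shifted by n
    b = _mann_whitney_counts(m, n - 1)
    out = [0] * (m * n + 1)
    for u, c in enumerate(a):
        out[u + n] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


@lru_cache(maxsize=None)
def _jt_null_pmf(group_sizes: tuple) -> np.ndarray:
    """Exact pmf of the Jonckheere-Terpstra statistic for given group sizes.

    J = sum over ordered group pairs of between-group Mann-Whitney counts;
    its permutation null is the convolution of independent MW distributions
    (Terpstra's decomposition). Returned as a normalized float array over
    J = 0..sum_{a<b} n_a n_b.
    """
    pmf = np.array([1.0])
    m = 0
    for n_a in group_sizes:
        if m > 0 and n_a > 0:
            counts = np.array(_mann_whitney_counts(m, n_a), dtype=float)
            pmf = np.convolve(pmf, counts / counts.sum())
        m += n_a
    return pmf


def _kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    diff_x = np.sign(x[:, None] - x[None, :])
    diff_y = np.sign(y[:, None] - y[None, :])
    return int(np.sum(np.triu(diff_x * diff_y, k=1)))


def _exact_jtk_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided exact p = P(S >= s_obs) for Kendall S of x against the
    reference y, conditioning on y's tie pattern; returns (p, tau_b).

    Requires untied x; with ties in x a tie-corrected normal approximation
    is used instead.
    """
    n = x.size
    s_obs = _kendall_s(x, y)
    pairs = n * (n - 1) // 2
    # tie-pair counts
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    tx = int(np.sum(cx * (cx - 1) // 2))
    ty = int(np.sum(cy * (cy - 1) // 2))
    denom = np.sqrt((pairs - tx) * (pairs - ty))
    tau = s_obs / denom if denom > 0 else 0.0

    if tx == 0:
        order = np.argsort(y, kind="stable")
        sizes = tuple(int(c) for c in
                      np.unique(np.sort(y), return_counts=True)[1])
        pmf = _jt_null_pmf(sizes)
        max_j = pmf.size - 1          # = sum_{a<b} n_a n_b
        # S = 2J - max_j  (x untied, pairs within a y-group contribute 0)
        j_obs = (s_obs + max_j) / 2.0
        j_lo = int(np.ceil(j_obs - 1e-9))
        p = float(pmf[j_lo:].sum())
        return min(p, 1.0), tau

    # ties in the data: tie-corrected normal approximation for S
    var = _kendall_var_tied(n, cx, cy)
    if var <= 0:
        return 1.0, 0.0
    z = (s_obs - np.sign(s_obs) * 1.0) / np.sqrt(var)  # continuity correction
    return float(stats.norm.sf(z)), tau


def _kendall_var_tied(n: int, cx: np.ndarray, cy: np.ndarray) -> float:
    """Variance of Kendall's S under permutation with ties in both margins."""
    def v(c):
        return (np.sum(c * (c - 1) * (2 * c + 5)),
                np.sum(c * (c - 1) * (c - 2)),
                np.sum(c * (c - 1)))
    v1x, v2x, v3x = v(cx.astype(float))
    v1y, v2y, v3y = v(cy.astype(float))
    n = float(n)
    var = ((n * (n - 1) * (2 * n + 5) - v1x - v1y) / 18.0
           + v2x * v2y / (9.0 * n * (n - 1) * (n - 2))
           + v3x * v3y / (2.0 * n * (n - 1)))
    return var


def _cosine_reference(t: np.ndarray, period: float, lag: float) -> np.ndarray:
    ref = np.cos(2.0 * np.pi * (t - lag) / period)
    # snap near-equal reference values to exact ties (symmetric timepoints)
    return np.round(ref, 9)


def jtk_test(tc: TimeCourse, periods=(24.0,), lags=None,
             exact_p: bool = True) -> RhythmResult:
    """JTK-style rhythm test: Kendall S against cosine templates.

    Replicates are collapsed to per-timepoint means before testing. For
    each (period, lag) the one-sided exact p of S is computed; the reported
    p is the grid minimum Bonferroni-multiplied by the grid size (capped at
    1). Amplitude and mesor come from the cosinor fit at the best period.
    """
    col = tc.collapse_replicates()
    t, x = col.zt, col.values
    if np.unique(x).size == 1:
        return RhythmResult(p=1.0, period=float(periods[0]), lag=0.0,
                            amplitude=0.0, tau=0.0, degenerate=True)
    combos = []
    for period in periods:
        if lags is None:
            step = float(np.min(np.diff(np.unique(t)))) if t.size > 1 else period
            lag_grid = np.arange(0.0, period, step)
        else:
            lag_grid = np.asarray(lags, dtype=float)
        for lag in lag_grid:
            combos.append((float(period), float(lag)))

    best = None
    for period, lag in combos:
        y = _cosine_reference(t, period, lag)
        p1, tau = _exact_jtk_p(x, y)
        if best is None or p1 < best[0]:
            best = (p1, period, lag, tau)
    p1, period, lag, tau = best
    p = min(1.0, p1 * len(combos))
    mesor, amplitude, acro = cosinor_fit(tc, period=period)
    return RhythmResult(p=p, period=period, lag=lag, amplitude=amplitude,
                        tau=tau, mesor=mesor)


# ---------------------------------------------------------------------------
# Umbrella (rise-then-fall) permutation test
# ---------------------------------------------------------------------------

def _umbrella_pairs(group_of: np.ndarray, order: np.ndarray, peak_pos: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) where the umbrella alternative with the given peak
    position expects x_i < x_j is FALSE -- we return pairs oriented
    (expected-smaller, expected-larger)."""
    lo_idx, hi_idx = [], []
    k = order.size
    for a in range(k):
        for b in range(a + 1, k):
            ia = np.where(group_of == order[a])[0]
            ib = np.where(group_of == order[b])[0]
            if b <= peak_pos:
                first, second = ia, ib       # ascending limb
            elif a >= peak_pos:
                first, second = ib, ia       # descending limb
            else:
                continue                     # pair straddles the peak
            gi, gj = np.meshgrid(first, second, indexing="ij")
            lo_idx.append(gi.ravel())
            hi_idx.append(gj.ravel())
    return np.concatenate(lo_idx), np.concatenate(hi_idx)


def umbrella_test(tc: TimeCourse, period: float = 24.0, peak_grid=None,
                  n_perm: int = 10000, seed: int = 0) -> RhythmResult:
    """Mack-Wolfe umbrella test over candidate peak positions.

    Timepoints (mod period) form ordered groups; for each candidate peak
    the statistic counts concordant pairs on the rising limb up to the peak
    plus concordant pairs on the falling limb after it (ties count 1/2).
    The permutation p (>= ``n_perm`` shuffles, seeded) is minimized over
    peaks with Bonferroni correction.
    """
    t = np.mod(tc.zt, period)
    x = tc.values.astype(float)
    if np.unique(x).size == 1:
        return RhythmResult(p=1.0, period=period, lag=0.0, amplitude=0.0,
                            tau=0.0, degenerate=True)
    uniq = np.unique(t)
    group_of = np.searchsorted(uniq, t)
    order = np.arange(uniq.size)
    peaks = range(uniq.size) if peak_grid is None else \
        [int(np.argmin(np.abs(uniq - p))) for p in peak_grid]

    rng = np.random.default_rng(seed)
    n = x.size
    perms = np.empty((n_perm, n), dtype=int)
    for r in range(n_perm):
        perms[r] = rng.permutation(n)
    xp = x[perms]                               # (n_perm, n)

    best = None
    for peak in peaks:
        lo, hi = _umbrella_pairs(group_of, order, peak)
        a_obs = float(np.sum(x[hi] > x[lo]) + 0.5 * np.sum(x[hi] == x[lo]))
        a_perm = (np.sum(xp[:, hi] > xp[:, lo], axis=1)
                  + 0.5 * np.sum(xp[:, hi] == xp[:, lo], axis=1))
        p = (1.0 + float(np.sum(a_perm >= a_obs - 1e-12))) / (1.0 + n_perm)
        if best is None or p < best[0]:
            best = (p, peak, a_obs)
    p, peak, a_obs = best
    n_peaks = len(list(peaks)) if not isinstance(peaks, range) else peaks.stop
    p_adj = min(1.0, p * n_peaks)
    mesor, amplitude, acro = cosinor_fit(tc, period=period)
    return RhythmResult(p=p_adj, period=period, lag=float(uniq[peak]),
                        amplitude=amplitude, statistic=a_obs, mesor=mesor)


# ---------------------------------------------------------------------------
# Cosinor, Grubbs, PPI, FDR
# ---------------------------------------------------------------------------

def cosinor_fit(tc: TimeCourse, period: float = 24.0
                ) -> tuple[float, float, float]:
    """Least-squares cosinor fit: value = M + A*cos(2*pi*(t - phi)/period).

    Returns (mesor, amplitude >= 0, acrophase in [0, period)). Acrophase is
    NaN when the amplitude is numerically zero.
    """
    t, x = tc.zt, tc.values
    if np.unique(t).size < 3:
        raise InputError("cosinor needs >= 3 distinct timepoints")
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise InputError("collinear cosinor design")
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    mesor, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    if amplitude < 1e-12:
        return float(mesor), amplitude, float("nan")
    acro = float(np.mod(np.arctan2(bs, bc) / w, period))
    return float(mesor), amplitude, acro


def grubbs_filter(values, alpha: float = 0.05
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass two-sided Grubbs outlier test.

    G = max |x - mean| / sd is compared against the t-based critical value
    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}. At most one value is removed per call; a zero
    sample standard deviation removes nothing.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise InputError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return x, np.array([])
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit ** 2 / (n - 2 + t_crit ** 2))
    if g <= g_crit:
        return x, np.array([])
    i = int(np.argmax(dev))
    return np.delete(x, i), x[i:i + 1]


def percent_ppi(asr_startle_alone: float, asr_prepulse_startle: float) -> float:
    """%PPI = 100 * (ASR_startle_alone - ASR_prepulse+startle) / ASR_startle_alone."""
    if asr_startle_alone <= 0:
        raise InputError("startle-alone response must be positive")
    return 100.0 * (asr_startle_alone - asr_prepulse_startle) / asr_startle_alone


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def test_many(courses: list[TimeCourse], method: str = "jtk",
              fdr_threshold: float = 0.01, **kwargs) -> list[RhythmResult]:
    """Run a rhythm test on several series and BH-adjust across them.

    Each result's ``rhythmic`` flag is q < ``fdr_threshold``.
    """
    fn = {"jtk": jtk_test, "umbrella": umbrella_test}[method]
    results = [fn(tc, **kwargs) for tc in courses]
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.rhythmic = bool(q < fdr_threshold)
    return results
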