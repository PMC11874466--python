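# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic generator does and does not emulate.

## Time conventions

All timestamps are seconds since ZT0 (lights-on) of day 1; ZT0–12 is the
light period. Epochs are 10 s, 0-based, half-open. Sampling: 250 Hz for
EEG/EMG, 1 Hz for biosensors, 10-s bins for concentrations, 1-h bins for
diurnal summaries.

## Synthetic generator

**Hypnogram.** A three-state Markov chain over (WAKE, NREM, REM) with one
transition per 10-s epoch and separate light/dark matrices. The WAKE→REM
entry is forced to zero and the row renormalized: physiologically, REM is
entered from NREM. Default matrices give stationary occupancies of roughly
33/59/8% (light) and 67/31/2% (dark) — sleep-dominant light phase,
wake-dominant dark phase, REM concentrated in the light, as in mice. Mean
bout lengths fall in the 4–10 min range typical of fragmented rodent
sleep.

**EEG/EMG.** Each epoch's EEG is the sum of five independent band-limited
Gaussian components (δ/θ/α/β/γ), produced by Fourier-domain masking of
white noise and rescaled so each component's in-band RMS exactly equals
its configured amplitude × the global power scale. Epochs are joined with
0.5-s sin/cos (power-complementary) cross-fades to avoid boundary clicks;
the fades trade ≤ ~2% of edge-epoch band power for continuity, which is
why band-power checks use a 5% tolerance. EMG is white noise with
per-state RMS. Default amplitudes make wake flat/high-EMG, NREM
delta-dominant, REM theta-dominant with atonia. No spindles, K-complexes,
electrode artifacts, or inter-animal variability beyond the seed are
modeled — scorer accuracy on this generator is an upper bound, not an
estimate of accuracy on real recordings.

**Analyte kinetics.** Concentration relaxes first-order toward a
state-dependent target plus a 24-h sinusoid:
dC/dt = k_state·(C_target(state) + D(t) − C),
D(t) = A·cos(2π(t − φ)/24 h). Integration uses the exact exponential
update per 1-s interval (target held at its interval midpoint), so the
noiseless path matches the closed form to machine precision and numerical
integration error cannot contaminate tests. Defaults: lactate targets
1.5 mM (wake) / 1.1 mM (sleep) in the physiological ~1–2 mM range, k =
0.5 min⁻¹ (WT), diurnal amplitude 0.15 mM with acrophase ZT14. Glucose
moves oppositely (higher target in sleep). The paper-scale coupling
constants are not published anywhere; these magnitudes are illustrative
and chosen once for realism, and all downstream claims are about contrasts
(WT vs KO) rather than absolute values.

**Sensor model.** current = gain·C + offset + drift·t + N(0, σ²), with
defaults 20 nA/mM, 5 nA, 0.05 nA/h, 0.2 nA. Calibration traces step the
bath concentration with a 15-s first-order sensor response; an ideal
sensor shows zero interferant response, so interferant steps carry noise
only.

**KO-like parameter set.** Global EEG power scale 0.7 with theta further
scaled by √0.7 and gamma by √1.3 (dampened power with a shifted θ:γ
balance), metabolite rate constants halved (sluggish state transitions),
diurnal acrophase delayed 2 h. These mirror the qualitative knockout
phenotype without asserting unpublished magnitudes.

**Isotopologue tables.** Labeled pools sit entirely in the fully labeled
species M+n (n = carbon count) and the remainder in M+0, then every
abundance is multiplied by mean-preserving log-normal noise with the
requested CV. Partial isotopologues and natural-abundance ¹³C are not
simulated; the analysis counts any M+i (i ≥ 1) as labeled, so it is
insensitive to that simplification.

## Sleep scoring

Per-epoch features: Hann-windowed periodogram, FFT length = epoch samples
(2,500 at 250 Hz; 0.1-Hz native resolution), no zero-padding, normalized
so a pure on-bin sinusoid of amplitude A yields total power A²/2 and the
spectrum sums to the Hann-weighted mean square (Parseval). 1-Hz feature
bins sum FFT bins whose center lies in [f, f+1); the first bin spans only
0.5–1 Hz, so the five bands tile 0.5–50 Hz with widths 3.5/4/5/17/20 Hz.
EMG RMS is computed on the mean-subtracted epoch.

Scoring rule (in precedence order): EMG RMS above the wake threshold →
WAKE; else θ/δ power ratio > 2.0 with EMG below the atonia bound → REM;
else NREM. A smoothing pass relabels REM epochs not preceded by NREM/REM.
The wake threshold is derived from the recording itself as the midpoint
(in log space) between the two clusters of a deterministic 1-D 2-means
split of epoch EMG RMS. A fixed-percentile threshold was considered and
rejected: with a strongly bimodal EMG distribution, an order statistic
sits on a cliff — whenever wake occupancy crosses the complementary
percentile, the threshold jumps between clusters and scoring collapses.
The cluster midpoint is invariant to occupancy. The atonia bound is the
20th percentile of EMG RMS (REM occupancy is well below 20%, so this
lands inside the sleep cluster). ARTIFACT labels are accepted on input,
never emitted; artifact epochs are excluded from spectra and hour
summaries are renormalized to 60 min.

## Spectra

Absolute state spectra are arithmetic means of per-epoch periodograms over
the state's non-artifact epochs. Relative band power is computed per epoch
(each band's share of that epoch's 0.5–50 Hz total) and then averaged
within state, rather than as a ratio of state-mean powers: shares then sum
to exactly 100% per state and are robust to between-epoch power
differences. Relative powers are invariant to global signal rescaling;
absolute powers scale with its square — this is the mechanism separating
"dampened absolute power" from altered spectral composition.

## Biosensor processing

Calibration: step response per injection = mean current over the
stabilized window before the next event minus the window before the
injection; sensitivity = mean(step/step_mM); a sensor passes iff all
analyte steps are positive and the largest interferant response is below
5% of the mean analyte step (the acceptance bound is configurable; the
qualitative requirement is "no response to the interferant").
Concentration = (current − baseline)/sensitivity, averaged into 10-s bins.
Percent-of-mean normalizes by the 24-h mean; hourly values average the 360
bins per hour. Detrending fits one least-squares line to the percent
series and removes it (re-adding the mean) only when the fitted
start-to-end excursion exceeds 10 percentage points. The fitted-trend
criterion, not the raw max, is used because the raw max of a 1-Hz noisy
series is noise-dominated; linear detrending matches the default behavior
class of the common numerical tools. Detrending preserves the 24-h mean
exactly. Note the detrend branch can also fire on genuinely asymmetric
diurnal profiles (the fitted line of a cosine over one period is not flat
unless the phase is symmetric); rank-based rhythm tests and sign-based
correlation claims are insensitive to this.

Units: concentrations are reported in mM throughout (the literature mixes
nM and mM labels for these sensors; the mM scale is the physiologically
sensible one for ISF lactate/glucose).

## Transitions and challenges

REM epochs are merged into NREM before bout measurement (transition
analysis concerns the wake/NREM axis and REM bouts are embedded in sleep);
bouts are maximal runs with no bridging of brief interruptions. A
qualifying switch needs NREM ≥ 5 min on one side and wake ≥ 10 min on the
other. Percent change uses the 60-s pre-transition baseline and thirty
10-s bins after the switch; the transition time is the first epoch of the
new state. Because percent change is a ratio, curves are invariant to
affine sensor recalibration. Injection challenges use a 10-min baseline;
"% max change" is a difference of peak percent changes (treatment −
saline) in percentage points, keeping units consistent.

## Rhythm tests

**JTK-style.** Replicates are collapsed to timepoint means (the
convention of the upstream implementations; it costs power but matches
reported outputs). For each (period, lag) on a grid (default period 24 h,
lags at the sampling interval), Kendall's S is computed between the data
and a cosine template. With untied data the null distribution of S
conditioned on the template's tie pattern is exact: ordering timepoints by
template value makes S an affine function of the Jonckheere–Terpstra
statistic, whose permutation null is the convolution of independent
Mann–Whitney distributions (computed by dynamic programming, cached per
tie pattern). Template values are rounded to 9 decimals so symmetric
timepoints tie exactly; tied data fall back to a tie-corrected normal
approximation (all-tied series report p = 1, flagged degenerate). The
reported p is the one-sided grid minimum × grid size (Bonferroni, capped
at 1); because the lag statistics are positively correlated, the scanned
test is conservative — its size is below nominal, while the
single-template exact test has size ≈ α. Amplitude and mesor come from
the cosinor fit at the optimal period.

**Umbrella.** For each candidate peak position the Mack–Wolfe statistic
counts concordant pairs on the rising limb up to the peak plus the falling
limb after it (ties ½; pairs straddling the peak excluded), with p from
≥ 10⁴ seeded Monte-Carlo permutations (floor 1/(n_perm+1)), minimized over
peaks with Bonferroni. BH-FDR is applied across series; rhythmic means
q < 0.01. Both tests are rank-based and hence invariant to monotone
transforms of the data.

**Cosinor.** Linear least squares on [1, cos ωt, sin ωt]; amplitude
= √(β_c² + β_s²) ≥ 0, acrophase = atan2(β_s, β_c)/ω mod period, undefined
(NaN) at zero amplitude. Amplitude is invariant to time-origin shifts;
acrophase shifts accordingly.

**Grubbs.** Single-pass, two-sided, α = 0.05: G = max|x − x̄|/s against
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t = t_{α/(2n), n−2}; at most one
removal per call (single-pass is the conservative reading where iteration
is unspecified); s = 0 removes nothing.

## Isotope tracing

Labeled = Σ_{i≥1} M+i, unlabeled = M+0, fraction = labeled/total (missing
when the pool is zero); the fully labeled fraction M+n is reported
alongside since figures often distinguish unlabeled vs fully labeled
pools. Pathway bins sum labeled abundance over member metabolites and
also report the unweighted mean fraction (the aggregation convention is
not standardized; both readings are emitted). Natural-abundance
correction is not applied; a hook exists but defaults off. Group
comparison is a two-way ANOVA (group × labeling status) per bin via
OLS/type-II sums of squares, with the labeled-pool group difference
reported as the effect direction.

## Problem sizes and numerical choices

Simulation-based checks use: one 24-h recording (8,640 epochs) for scorer
recovery; 20 paired WT/KO days for transition contrasts; 50 calibration
traces for sensitivity recovery; 1,000 null series (12 timepoints) for
test size; 30 replicates for isotope-tracing sign recovery; 1,000 random
hypnograms against the brute-force transition oracle. These sizes give
binomial/Monte-Carlo resolution comfortably finer than the thresholds
asserted, at about a minute of total compute. Seeds are explicit
everywhere; identical seed + config is bit-identical, and pipeline CSVs
are written with a fixed float format so reruns are byte-identical.

## Known limitations

- The scorer is a two-threshold rule tuned to the generator's feature
  separation; real recordings with movement artifacts, drifting EMG
  baselines, or cataplexy-like states will need threshold review or an
  external hypnogram (supported on input).
- The generator's state-to-metabolite coupling constants are illustrative;
  only contrasts between parameter sets are meaningful.
- The umbrella test implements the rise/fall alternative with Monte-Carlo
  p-values; it is not a full reimplementation of longitudinal/
  independent-design rhythm frameworks.
- EDF output is minimal (two channels, 1-s records, 16-bit); annotations
  and discontinuous records are out of scope.
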