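# Methods

This note documents the models, parameter choices and numerical decisions
behind `ectohrv`, and what the synthetic experiments can and cannot say
about real recordings.

## Synthetic cohort model

Each subject's interbeat intervals follow an additive sinusoid model,

    IBI_n = mean_ibi + A_LF sin(2π f_LF t_{n-1} + φ_LF)
                     + A_HF sin(2π f_HF t_{n-1} + φ_HF) + ε_n,

with `t_{n-1}` the previous beat's cumulative occurrence time,
`ε_n ~ N(0, σ²)` independent per beat, and the two phases drawn uniformly
per subject. Beats accumulate until the configured record duration is
exceeded. The model is deliberately simple: it places power where a
resting short-term HRV analysis looks for it (a Mayer-wave-like LF line, a
respiratory-sinus-arrhythmia-like HF line, broadband beat-to-beat noise)
without simulating the cardiac conduction system or an
integral-pulse-frequency-modulation stage (noted as a possible extension).

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| n_subjects | 28 | cohort size of the emulated study population |
| duration | 1200 s | 20-minute supine resting records |
| mean_ibi | 1010 ms | resting heart rate ≈ 59 bpm, young adults |
| f_LF / f_HF | 0.10 / 0.25 Hz | centers of the conventional LF and HF bands |
| A_LF / A_HF | 50 / 40 ms | see variance budget below |
| noise_sd σ | 25 ms | see variance budget below |

The amplitudes follow a closed-form variance budget: a sinusoid of
amplitude A contributes A²/2 to the interval variance, so
SDNN ≈ √(50²/2 + 40²/2 + 25²) ≈ 51.7 ms, matching a healthy-young-adult
resting SDNN of ~52 ms at AVNN ≈ 1010 ms; the implied RMSSD ≈ 55–60 ms is
likewise age-typical. The config validator requires
`mean_ibi > A_LF + A_HF + 4σ` so intervals stay positive.

Seeding: one master seed per cohort; per-subject streams are spawned
sequentially from `SeedSequence(seed)`, and inside a sweep each
(subject, repetition, rate) cell gets its own child stream keyed by
`(repetition, rate×10)`. Any single cell of the protocol is therefore
reproducible in isolation, and a fixed seed reproduces the whole cohort
bitwise.

Before any injection, records pass the same threshold screen used during
restoration, with violating intervals deleted (repeated to a fixpoint so
the screen is idempotent). On the Gaussian generator this is a no-op —
successive ratios beyond ±24.5 % would be >4σ events — but it keeps the
pipeline identical for externally supplied interval files.

## Error injection

At error rate *r* (fraction of beats), the number of errors per repetition
is `round(r · n_beats)` (half away from zero; the rounding convention is a
package choice). The miss/false split is `n_miss = round(u · n_total)`
with `u ~ Uniform[0, 1]` redrawn each repetition. Missed-beat indices are
sampled without replacement from interior beats so each deletion merges
two defined intervals; false-beat positions are uniform on the open gap,
with gaps indexed on the post-deletion sequence so an inserted beat can
never be deleted in the same repetition. An optional refractory margin
(`min_gap_fraction`) is available but off by default. Bookkeeping holds
exactly: `|beats out| = |beats in| − n_miss + n_false`.

## Flagging and restoration

Interval *n* is ectopic when it falls outside
`(0.675·ref, 1.245·ref)` — a decrease of more than 32.5 % or an increase of
more than 24.5 %. The default reference is the raw previous interval
`IBI_{n-1}`. An alternative "last accepted interval" reference is
config-exposed but not the default: a split half whose fraction exceeds
0.675 is accepted by any threshold of this family, and with a last-accepted
reference it traps the comparator low so that every subsequent normal
interval (ratio > 1.245 against the trapped value) is flagged — a cascade
to the end of the record. The raw-previous reference re-anchors within one
or two intervals and keeps flagging local.

Restoration replaces flagged intervals in place (series length preserved):
NNI takes the nearest unflagged value by index distance (ties to the
earlier value, i.e. "previous interval" for an isolated interior flag);
LI evaluates the straight line through the bracketing unflagged neighbors;
CSI evaluates a not-a-knot cubic spline through all unflagged
(index, value) points. Boundary runs are filled by the nearest value (NNI)
or extrapolated (LI/CSI). A `delete` mode drops flagged intervals instead,
shortening the series. The x-coordinate is the interval index rather than
cumulative time — consistent with interpolating "adjacent intervals" and
independent of the corrupted time axis.

## HRV metrics

Time domain uses the sample (n−1) standard-deviation convention
throughout; pNN50's denominator is the number of successive differences.
Two identities tie the implementations together and are asserted in tests:
`SD1 = SDSD/√2` and `RMSSD² = mean(d)² + population-variance(d)`.

Frequency domain: a cubic spline is fitted to (interval end time,
interval) pairs and evaluated on a 4 Hz grid spanning the record; mean and
linear trend are removed; band powers are integrated from a one-sided
unwindowed periodogram. Evaluating the spline directly on the 4 Hz grid is
numerically identical to evaluating on an intermediate 1 kHz grid and
decimating (the coarse grid points are a subset); the two-stage path
exists behind a config flag and a test asserts the equivalence. Total
power is defined in-band (VLF+LF+HF, 0.0033–0.4 Hz), so
`nLF = LF/(TP−VLF)` and `nHF = HF/(TP−VLF)` sum to one; a full-Nyquist TP
and a Welch/Hann estimator are config options. Records shorter than two
VLF periods (~606 s) trigger a warning, not an error. If a pathological
restored series contains a non-positive interval, the spectral block
returns NaN rather than fabricating a time axis.

ApEn uses embedding m = 2, tolerance r = 0.2 × sample SD, Chebyshev
distance, self-matches included; a zero-variance series returns 0 by
convention. The vectorized implementation is asserted equal (1e-10) to a
literal triple-loop definition for n ≤ 200.

## Sweep statistics

The paired unit is the subject: repetitions are averaged per subject
(n_reps = 30 by default) and the 28 per-subject values are compared with
the per-subject ectopic-free values. A per-repetition pairing mode exists
behind config. Normality of the paired differences is tested with the
Lilliefors (estimated-parameter Kolmogorov–Smirnov) correction; the gate
sends normal-looking differences to a paired t-test and the rest to the
Wilcoxon signed-rank test, both two-sided at α = 0.05. No multiple-testing
correction is applied across the rate grid; instead an optional
sustained-run rule (`sustained_k` consecutive significant rates) is
available to suppress single-rate flukes in onset estimates. %FC is
reported on the ratio scale (identity = 100). Correlations are Pearson by
default (Spearman behind a flag), computed at the onset rate. Injections
at a given rate are drawn once and shared by all restoration arms, so the
arms differ only downstream of restoration. At rate 0 the pipeline output
equals the screened clean series exactly, so %FC is exactly 100 and no
test is significant, by construction rather than by approximation.

Checkpointing writes one CSV per (method, rate) cell so an interrupted
sweep resumes without recomputation.

## Problem sizes used by the shipped experiments

The acceptance script runs the full study conditions — 28 subjects,
20-minute records, 30 repetitions — scanning from 0.1 % upward with early
stopping once every profiled metric's onset is confirmed. The
directional interpolation experiment in the test suite runs a reduced
design chosen as a package default for its experiments: 10 subjects,
10-minute records, 10 repetitions, a 0.1–5 % grid at 0.1 % steps, three
cohort seeds, sustained-run onsets (k = 3).

## What the synthetic experiments do and do not show

They show: the *structural* sensitivity of each metric family to beat
errors. A single merged interval at one beat in a thousand (0.1 %) shifts
the successive-difference metrics (SDSD, RMSSD, SD1) and HF power far
outside sampling noise, so their significance onsets sit at the grid floor
without restoration; restoration collapses the distortion magnitude from
tens-to-thousands of percent to a few percent.

They do not show: realistic onset *values* for restored data. The
generator produces homogeneous subjects with Gaussian noise, so the paired
test across subjects has almost no between-subject variance in its
differences and detects even the small deterministic residue restoration
leaves behind (the threshold band cannot flag a split half with fraction
> 0.675, and interpolation removes the noise component of every value it
replaces). On real cohorts, between-subject and between-session
variability masks sub-percent residues and restored onsets land at
error rates of one to a few percent. Consequently the strict separation
"restored onset > raw onset" holds on this generator only where the
residue stays below the (very high) detection power of the homogeneous
cohort; several variance-type metrics go significant at the grid floor in
both arms even though their restored distortion is ~100× smaller. The
%FC magnitudes, not the onset gap, carry the practical message on
synthetic data.

Other known limitations: no pathological arrhythmia morphology (the model
targets detection errors, not electrophysiology); no ECG waveform or QRS
detection stage (the pipeline starts from beat annotations); SDANN and the
SDNN index are out of scope (long-term metrics); no detrended fluctuation
analysis; no Lomb–Scargle spectral estimator.
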