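# ectohrv

**How many missed or spurious heartbeat detections can an HRV analysis
tolerate?** `ectohrv` is a simulation toolkit for quantifying the effect of
beat-detection errors ("ectopic beats" in the broad sense: any interval
anomaly caused by a missed or falsely detected QRS complex) on
heart-rate-variability metrics, and for measuring how much of that damage
threshold-based removal plus interpolation can repair.

It is aimed at people who build or validate beat detectors, ambulatory/
wearable ECG pipelines, or HRV analysis software, and who need a concrete
error budget: *at what beat-error rate does each HRV metric first become
statistically distinguishable from its clean value, with and without
artifact correction?*

## What the pipeline does

1. **Synthetic resting cohort** — ectopic-free interbeat-interval (IBI)
   series (default 28 subjects, 20-minute records) from an additive
   sinusoid model: mean interval 1010 ms, LF (0.1 Hz) and HF (0.25 Hz)
   oscillations plus Gaussian beat-to-beat noise, calibrated to
   SDNN ≈ 52 ms.
2. **Error injection** — at error rate *r*, `round(r · n_beats)` errors per
   repetition, randomly split between *missed* beats (delete a beat, the
   two flanking intervals merge) and *false* beats (insert a beat at a
   uniform position inside a gap, the interval splits).
3. **Restoration** — intervals outside the acceptance band
   `0.675·IBI_{n-1} < IBI_n < 1.245·IBI_n-1` are flagged and either deleted
   or replaced by nearest-neighbor (NNI), linear (LI), or cubic-spline
   (CSI) interpolation over the interval index.
4. **HRV metrics** — time domain (AVNN, SDNN, SDSD, RMSSD, NN50, pNN50),
   frequency domain from a 4 Hz spline-resampled, detrended tachogram
   periodogram (TP, VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz,
   LF/HF, nLF, nHF), and non-linear (Poincaré SD1/SD2, approximate entropy
   ApEn(m=2, r=0.2·SD)).
5. **Sweep statistics** — per metric × restoration method × rate: the
   percentage of fractional change %FC = 100 · test/reference, a
   normality-gated paired test (Lilliefors gate; paired *t* or Wilcoxon
   signed-rank, α = 0.05) across subjects, the significance **onset** (first
   significant rate on the 0.1 %-step grid), and the cohort correlation at
   the onset rate.

## Worked example

```python
import ectohrv as e

cohort = e.generate_cohort(e.CohortConfig(seed=1))        # 28 subjects
cfg = e.SweepConfig(rate_grid=(0.0, 0.5, 1.0, 2.0), n_reps=30,
                    methods=("none", "LI"), metrics=("RMSSD", "HF"), seed=1)
res = e.run_sweep(cohort, cfg)
print(res.stats[["method", "rate", "metric", "mean_fc", "p_value",
                 "significant"]])
```

prints (abridged):

```
method  rate metric      mean_fc      p_value  significant
  none   0.0  RMSSD   100.000000 1.000000e+00        False
  none   0.5  RMSSD   179.799149 7.450581e-09         True
  none   1.0     HF 37511.097471 2.082559e-17         True
    LI   0.5  RMSSD   101.413807 2.618681e-32         True
    LI   1.0     HF   107.322811 3.271690e-36         True
```

Reading it: at a 0.5 % beat-error rate with no correction, RMSSD is already
inflated by ~80 % and HF power explodes (a single merged interval is a huge
spectral impulse), while linear interpolation keeps both within a few
percent of their clean values — the distortion removed by restoration is
enormous even when both arms are statistically distinguishable from clean.
A single-record metric suite is available as
`e.all_metrics(cohort[0].ibi())`, e.g. AVNN 1008.1 ms, SDNN 51.9 ms,
RMSSD 58.5 ms, HF 1074 ms², ApEn 1.70 for the first synthetic subject.

A thin CLI wraps the same library calls:

```bash
ectohrv generate --subjects 28 --seed 1 --out cohort/
ectohrv metrics cohort/beats_S01.txt
ectohrv sweep --config run.yaml --out report/
```

## Layout

- `src/ectohrv/cohort.py` — synthetic cohort generator and pre-cleaning screen
- `src/ectohrv/injection.py` — miss/false error plans and application
- `src/ectohrv/restoration.py` — threshold flagging, NNI/LI/CSI repair
- `src/ectohrv/metrics.py` — the HRV metric suite
- `src/ectohrv/sweep.py` — the rate sweep, paired statistics, onset tables
- `src/ectohrv/io.py`, `src/ectohrv/cli.py` — text/CSV/YAML I/O and the CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
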