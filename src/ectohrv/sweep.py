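"""Error-rate sweep, fractional change, and significance-onset profiling.

The protocol: for each beat-error rate on a grid, each subject's clean
record is corrupted ``n_reps`` times (independent miss/false plans), each
corrupted series is optionally restored (threshold flag + interpolation),
the HRV metrics are computed, repetitions are aggregated per subject, and
the cohort's paired values are compared with the ectopic-free values.

Per (metric, restoration method, rate) the sweep records the mean
percentage of fractional change %FC = 100 * test / reference, a
normality-gated paired p-value (Lilliefors-corrected Kolmogorov-Smirnov on
the paired differences; paired t-test when normality is not rejected,
Wilcoxon signed-rank otherwise), and a significance flag.  The *onset* of
a metric under a method is the smallest grid rate at which the difference
is significant (optionally required to persist over ``sustained_k``
consecutive rates); the correlation table reports the Pearson correlation
between cohort reference and test values at that onset rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from . import __version__
from .cohort import QRSSequence, screen_preexisting
from .injection import inject, plan_errors
from .metrics import METRIC_FIELDS, SpectralConfig, all_metrics
from .restoration import IBISeries, ThresholdRule, restore

__all__ = [
    "SweepConfig",
    "SweepResult",
    "default_rate_grid",
    "fractional_change",
    "paired_significance",
    "aggregate_reps",
    "find_onset",
    "correlation_at_rate",
    "run_sweep",
    "export_report",
]


def default_rate_grid(start: float = 0.0, stop: float = 50.0,
                      step: float = 0.1) -> Tuple[float, ...]:
    """Beat-error-rate grid in percent (default 0-50 % in 0.1 % steps)."""
    n = int(round((stop - start) / step))
    return tuple(round(start + i * step, 10) for i in range(n + 1))


@dataclass(frozen=True)
class SweepConfig:
    """Sweep settings.

    rate_grid : beat-error rates in percent, sorted, within [0, 50].
    n_reps : injection repetitions per subject and rate.
    alpha : significance level of the paired test.
    methods : restoration arms; "none" is the raw ectopic path.
    metrics : metric fields to profile (subset of METRIC_FIELDS).
    seed : master seed; every (subject, rate, repetition) cell derives an
        independent stream from it, so any cell is reproducible alone.
    aggregate : "subject_mean" pairs per-subject means over repetitions
        (one pair per subject); "per_rep" pairs every repetition with its
        subject's reference value.
    normality_alpha : level of the Lilliefors normality gate.
    sustained_k : number of consecutive significant rates required to call
        an onset (1 = first significant rate).
    stop_at_onset : stop scanning a method's rates once every profiled
        metric has a confirmed onset (the stats table then covers only the
        scanned prefix).
    correlation : "pearson" or "spearman".
    """

    rate_grid: Tuple[float, ...] = field(default_factory=default_rate_grid)
    n_reps: int = 30
    alpha: float = 0.05
    methods: Tuple[str, ...] = ("none", "NNI", "LI", "CSI")
    metrics: Tuple[str, ...] = METRIC_FIELDS
    seed: int = 0
    aggregate: str = "subject_mean"
    normality_alpha: float = 0.05
    sustained_k: int = 1
    stop_at_onset: bool = False
    correlation: str = "pearson"
    apen_m: int = 2
    min_gap_fraction: float = 0.0
    flag_reference: str = "previous"

    def __post_init__(self) -> None:
        grid = tuple(float(r) for r in self.rate_grid)
        if grid != tuple(sorted(grid)):
            raise ValueError("rate_grid must be sorted ascending")
        if grid and (grid[0] < 0 or grid[-1] > 50):
            raise ValueError("rates must lie in [0, 50] percent")
        object.__setattr__(self, "rate_grid", grid)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.aggregate not in ("subject_mean", "per_rep"):
            raise ValueError("aggregate must be 'subject_mean' or 'per_rep'")
        if self.sustained_k < 1:
            raise ValueError("sustained_k must be >= 1")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")
        unknown = set(self.metrics) - set(METRIC_FIELDS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")


@dataclass
class SweepResult:
    """Tables produced by :func:`run_sweep`.

    values : per (method, rate, metric, subject): aggregated value,
        reference value and %FC.
    stats : per (method, rate, metric): mean %FC, p-value, test used,
        significance flag, number of pairs.
    onsets : per (metric, method): first significant rate (NaN if never).
    correlations : per (metric, method): correlation between cohort
        reference and test values at the onset rate.
    """

    values: pd.DataFrame
    stats: pd.DataFrame
    onsets: pd.DataFrame
    correlations: pd.DataFrame
    config: Dict

    def onset_table(self) -> pd.DataFrame:
        return self.onsets.pivot(index="metric", columns="method", values="onset")

    def onset_of(self, metric: str, method: str) -> Optional[float]:
        row = self.onsets[(self.onsets.metric == metric)
                          & (self.onsets.method == method)]
        if row.empty:
            return None
        v = row.onset.iloc[0]
        return None if pd.isna(v) else float(v)


def fractional_change(v_test: float, v_ref: float) -> float:
    """%FC = 100 * v_test / v_ref; NaN when the reference is zero."""
    if not np.isfinite(v_ref) or not np.isfinite(v_test) or v_ref == 0:
        return np.nan
    if v_test == v_ref:
        return 100.0
    return 100.0 * v_test / v_ref


def _paired_t(d: np.ndarray) -> float:
    """Two-sided paired-t p-value from the differences."""
    n = d.size
    t = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(n))
    return float(2.0 * sps.t.sf(abs(t), n - 1))


def paired_significance(
    ref_values: np.ndarray,
    test_values: np.ndarray,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    force: Optional[str] = None,
) -> Tuple[float, str]:
    """Normality-gated paired comparison of two per-subject vectors.

    The paired differences are tested for normality with the Lilliefors
    (estimated-parameter Kolmogorov-Smirnov) test; a paired t-test is used
    when normality is not rejected at ``normality_alpha``, the Wilcoxon
    signed-rank test otherwise.  ``force`` ("t" or "wilcoxon") bypasses
    the gate.  Returns (two-sided p, name of the test used).  All-zero
    differences return (1.0, "degenerate").
    """
    ref = np.asarray(ref_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if ref.shape != test.shape or ref.ndim != 1:
        raise ValueError("ref and test must be matching 1-d vectors")
    ok = np.isfinite(ref) & np.isfinite(test)
    ref, test = ref[ok], test[ok]
    if ref.size < 3:
        return np.nan, "insufficient"
    d = test - ref
    if np.all(d == 0):
        return 1.0, "degenerate"
    if np.std(d, ddof=1) == 0:
        # identical non-zero shift in every pair: maximally significant
        return 0.0, "degenerate"
    if force == "t":
        return _paired_t(d), "paired_t"
    if force == "wilcoxon":
        return float(sps.wilcoxon(d, zero_method="wilcox").pvalue), "wilcoxon"
    if force is not None:
        raise ValueError("force must be None, 't' or 'wilcoxon'")
    if d.size >= 4:
        try:
            _, p_norm = lilliefors(d, dist="norm")
        except Exception:
            p_norm = 0.0
        normal = p_norm > normality_alpha
    else:
        normal = True  # too few pairs for the gate; default to t
    if normal:
        return _paired_t(d), "paired_t"
    return float(sps.wilcoxon(d, zero_method="wilcox").pvalue), "wilcoxon"


def aggregate_reps(per_rep_values: Sequence[float]) -> float:
    """Per-subject summary over repetitions: the (NaN-aware) mean."""
    v = np.asarray(per_rep_values, dtype=float)
    if v.size == 0:
        raise ValueError("no repetition values to aggregate")
    return float(np.nanmean(v)) if np.any(np.isfinite(v)) else np.nan


def find_onset(
    rates: Sequence[float],
    p_values: Sequence[float],
    alpha: float = 0.05,
    sustained_k: int = 1,
) -> Optional[float]:
    """Smallest rate whose p-value (and the next ``sustained_k - 1``
    rates') falls below ``alpha``; None if no such run exists.

    Rates must be sorted ascending and exclude the zero-error rate.
    """
    rates = list(rates)
    p = list(p_values)
    if len(rates) != len(p):
        raise ValueError("rates and p_values must have equal length")
    if not rates:
        raise ValueError("empty rate/p-value map")
    run = 0
    for i, pv in enumerate(p):
        if np.isfinite(pv) and pv < alpha:
            run += 1
            if run >= sustained_k:
                return float(rates[i - sustained_k + 1])
        else:
            run = 0
    return None


def correlation_at_rate(
    ref_values: Sequence[float],
    test_values: Sequence[float],
    kind: str = "pearson",
) -> float:
    """Cohort correlation between reference and test metric values."""
    ref = np.asarray(ref_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    ok = np.isfinite(ref) & np.isfinite(test)
    ref, test = ref[ok], test[ok]
    if ref.size < 3 or np.std(ref) == 0 or np.std(test) == 0:
        return np.nan
    if kind == "spearman":
        return float(sps.spearmanr(ref, test).statistic)
    return float(sps.pearsonr(ref, test).statistic)


def _rate_key(rate_pct: float) -> int:
    return int(round(rate_pct * 10))


def _cell_path(checkpoint_dir: Path, method: str, rate_pct: float) -> Path:
    return checkpoint_dir / f"cell_{method}_{_rate_key(rate_pct):04d}.csv"


def _metrics_dict(series: IBISeries, cfg: SweepConfig,
                  spectral: SpectralConfig) -> Dict[str, float]:
    return all_metrics(series, spectral=spectral, fields=cfg.metrics,
                       apen_m=cfg.apen_m).to_dict()


def run_sweep(
    cohort: Sequence[QRSSequence],
    config: SweepConfig = SweepConfig(),
    spectral: SpectralConfig = SpectralConfig(),
    rule: ThresholdRule = ThresholdRule(),
    checkpoint_dir: Optional[Union[str, Path]] = None,
    progress: bool = False,
) -> SweepResult:
    """Run the full injection/restoration/metrics/statistics protocol.

    The clean reference per subject is the screened (pre-cleaned) interval
    series; injections at a given rate are drawn once and shared by every
    restoration arm, mirroring a single ectopic dataset feeding all
    restorations.  Deterministic given ``config.seed``.  When
    ``checkpoint_dir`` is set, each (method, rate) cell's per-repetition
    values are written to one CSV and reloaded on re-runs, so an
    interrupted sweep resumes where it stopped.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    subjects = [q.subject_id for q in cohort]
    metric_list = list(config.metrics)
    clean: Dict[str, IBISeries] = {
        q.subject_id: screen_preexisting(q.ibi(), rule) for q in cohort
    }
    ref: Dict[str, Dict[str, float]] = {
        sid: _metrics_dict(s, config, spectral) for sid, s in clean.items()
    }
    ref_vec = {m: np.array([ref[sid][m] for sid in subjects]) for m in metric_list}

    master = SeedSequence(config.seed)
    subject_ss = {sid: s for sid, s in zip(subjects, master.spawn(len(subjects)))}
    # one child stream per (subject, repetition, rate) so any cell can be
    # regenerated independently of scan order
    def cell_rng(sid: str, rep: int, rate_pct: float):
        base = subject_ss[sid]
        return default_rng(SeedSequence(
            entropy=base.entropy, spawn_key=(rep, _rate_key(rate_pct))
        ))

    value_rows: List[tuple] = []
    stat_rows: List[tuple] = []
    # onset bookkeeping for early stopping
    consec = {meth: {m: 0 for m in metric_list} for meth in config.methods}
    onset: Dict[str, Dict[str, Optional[float]]] = {
        meth: {m: None for m in metric_list} for meth in config.methods
    }
    finished = {meth: False for meth in config.methods}

    for rate in config.rate_grid:
        running = [meth for meth in config.methods
                   if not (config.stop_at_onset and finished[meth])]
        if not running:
            break
        if progress:
            print(f"[sweep] rate {rate:.1f}% methods {running}", flush=True)

        if rate == 0.0:
            # zero-error repetitions reproduce the screened clean series
            # exactly (the plan is empty and the screened series re-passes
            # the threshold rule), so the aggregate equals the reference
            for meth in running:
                for m in metric_list:
                    for sid in subjects:
                        rv = ref[sid][m]
                        value_rows.append((meth, rate, m, sid, rv, rv,
                                           fractional_change(rv, rv)))
                    stat_rows.append((meth, rate, m, 100.0, 1.0, "degenerate",
                                      False, len(subjects)))
            continue

        # per-repetition corrupted series, shared across restoration arms
        need_compute = [meth for meth in running if ckpt is None
                        or not _cell_path(ckpt, meth, rate).exists()]
        injected: Dict[str, List[IBISeries]] = {}
        if need_compute:
            frac = rate / 100.0
            for q in cohort:
                reps = []
                for rep in range(config.n_reps):
                    rng = cell_rng(q.subject_id, rep, rate)
                    plan = plan_errors(q.n_beats, frac, rng,
                                       min_gap_fraction=config.min_gap_fraction)
                    series = inject(q, plan).ibi()
                    series.repetition = rep
                    series.rate = rate
                    reps.append(series)
                injected[q.subject_id] = reps

        for meth in running:
            if ckpt is not None and _cell_path(ckpt, meth, rate).exists():
                cell = pd.read_csv(_cell_path(ckpt, meth, rate))
            else:
                rows = []
                for sid in subjects:
                    for rep, series in enumerate(injected[sid]):
                        restored = (series if meth == "none"
                                    else restore(series, rule, meth,
                                                 reference=config.flag_reference))
                        vals = _metrics_dict(restored, config, spectral)
                        for m in metric_list:
                            rows.append((sid, rep, m, vals[m]))
                cell = pd.DataFrame(rows,
                                    columns=["subject", "rep", "metric", "value"])
                if ckpt is not None:
                    cell.to_csv(_cell_path(ckpt, meth, rate), index=False)

            for m in metric_list:
                sub = cell[cell.metric == m]
                agg = np.array([
                    aggregate_reps(sub[sub.subject == sid].value.to_numpy())
                    for sid in subjects
                ])
                fc = np.array([fractional_change(a, ref_vec[m][i])
                               for i, a in enumerate(agg)])
                for i, sid in enumerate(subjects):
                    value_rows.append((meth, rate, m, sid, agg[i],
                                       ref_vec[m][i], fc[i]))
                if config.aggregate == "per_rep":
                    test = sub.sort_values(["subject", "rep"]).value.to_numpy()
                    refp = np.repeat(
                        [ref[sid][m] for sid in subjects], config.n_reps)
                    p, used = paired_significance(
                        refp, test, config.alpha, config.normality_alpha)
                    n_pairs = test.size
                else:
                    p, used = paired_significance(
                        ref_vec[m], agg, config.alpha, config.normality_alpha)
                    n_pairs = len(subjects)
                sig = bool(np.isfinite(p) and p < config.alpha)
                stat_rows.append((meth, rate, m, float(np.nanmean(fc)),
                                  p, used, sig, n_pairs))
                if onset[meth][m] is None:
                    consec[meth][m] = consec[meth][m] + 1 if sig else 0
                    if consec[meth][m] >= config.sustained_k:
                        onset[meth][m] = round(
                            rate - (config.sustained_k - 1) * _grid_step(config),
                            10)
            if all(onset[meth][m] is not None for m in metric_list):
                finished[meth] = True

    values = pd.DataFrame(value_rows, columns=[
        "method", "rate", "metric", "subject", "value", "ref_value", "pct_fc"])
    stats = pd.DataFrame(stat_rows, columns=[
        "method", "rate", "metric", "mean_fc", "p_value", "test_used",
        "significant", "n_pairs"])

    onset_rows = []
    corr_rows = []
    for meth in config.methods:
        for m in metric_list:
            sub = stats[(stats.method == meth) & (stats.metric == m)
                        & (stats.rate > 0)].sort_values("rate")
            o = (find_onset(sub.rate.to_list(), sub.p_value.to_list(),
                            config.alpha, config.sustained_k)
                 if len(sub) else None)
            onset_rows.append((m, meth, np.nan if o is None else o))
            if o is not None:
                at = values[(values.method == meth) & (values.metric == m)
                            & (values.rate == o)]
                r = correlation_at_rate(at.ref_value.to_numpy(),
                                        at.value.to_numpy(),
                                        kind=config.correlation)
            else:
                r = np.nan
            corr_rows.append((m, meth, np.nan if o is None else o, r))

    onsets = pd.DataFrame(onset_rows, columns=["metric", "method", "onset"])
    correlations = pd.DataFrame(
        corr_rows, columns=["metric", "method", "onset", "correlation"])
    cfg_dict = asdict(config)
    cfg_dict["spectral"] = asdict(spectral)
    cfg_dict["threshold_rule"] = asdict(rule)
    return SweepResult(values, stats, onsets, correlations, cfg_dict)


def _grid_step(config: SweepConfig) -> float:
    grid = [r for r in config.rate_grid if r > 0]
    if len(grid) >= 2:
        return grid[1] - grid[0]
    return 0.0


def export_report(result: SweepResult, out_dir: Union[str, Path]) -> List[Path]:
    """Write the sweep tables and run metadata as CSV/JSON files.

    Deterministic: re-exporting the same result is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("values", result.values), ("stats", result.stats),
                     ("onsets", result.onsets),
                     ("correlations", result.correlations)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    meta = {
        "package": "ectohrv",
        "version": __version__,
        "config": result.config,
    }
    meta_path = out / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str)
                         + "\n")
    written.append(meta_path)
    return written
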