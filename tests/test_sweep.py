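"""Sweep statistics: %FC, paired tests, onsets, correlations, protocol."""

import numpy as np
import pytest
from scipy import stats as sps

from ectohrv import (
    SweepConfig,
    aggregate_reps,
    correlation_at_rate,
    default_rate_grid,
    export_report,
    find_onset,
    fractional_change,
    paired_significance,
    run_sweep,
)


class TestFractionalChange:
    def test_identity_is_100(self):
        assert fractional_change(57.3, 57.3) == 100.0

    def test_ratio_scale(self):
        assert fractional_change(110.0, 100.0) == pytest.approx(110.0)

    def test_zero_reference_is_missing(self):
        assert np.isnan(fractional_change(5.0, 0.0))


class TestPairedSignificance:
    def test_identical_vectors_not_significant(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p, used = paired_significance(v, v)
        assert p == 1.0 and used == "degenerate"

    def test_clear_shift_is_significant(self, rng):
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        test = ref + 10.0 + rng.normal(0, 0.01, 5)
        p, _ = paired_significance(ref, test)
        assert p < 0.05

    def test_t_branch_matches_textbook_formula(self):
        """Hand-computed paired t on d = [1,-1,1,-1,1,1]: t = dbar/(s/sqrt(n))."""
        ref = np.zeros(6)
        test = np.array([1.0, -1.0, 1.0, -1.0, 1.0, 1.0])
        p, used = paired_significance(ref, test, force="t")
        d = test - ref
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        p_hand = 2 * sps.t.sf(abs(t_stat), 5)
        assert used == "paired_t"
        assert p == pytest.approx(p_hand, abs=1e-12)
        # cross-check against the library's independent implementation
        assert p == pytest.approx(sps.ttest_rel(test, ref).pvalue, abs=1e-10)

    def test_normality_gate_switches_to_wilcoxon(self, rng):
        ref = np.zeros(40)
        # strongly skewed differences fail the Lilliefors gate
        test = rng.exponential(1.0, 40) ** 3 + 0.1
        _, used = paired_significance(ref, test)
        assert used == "wilcoxon"

    def test_constant_nonzero_shift_degenerate_significant(self):
        ref = np.arange(5.0)
        p, used = paired_significance(ref, ref + 2.0)
        assert p == 0.0 and used == "degenerate"


class TestAggregateAndOnset:
    def test_aggregate_mean(self):
        assert aggregate_reps([1.0, 2.0, 3.0]) == 2.0
        assert aggregate_reps([7.0] * 30) == 7.0

    def test_onset_cases(self):
        rates = [0.1, 0.2, 0.3, 0.4]
        assert find_onset(rates, [0.01, 0.01, 0.01, 0.01]) == 0.1
        assert find_onset(rates, [0.5, 0.5, 0.5, 0.5]) is None
        assert find_onset(rates, [0.9, 0.9, 0.01, 0.01]) == 0.3

    def test_onset_sustained_run_rule(self):
        rates = [0.1, 0.2, 0.3, 0.4, 0.5]
        p = [0.01, 0.9, 0.01, 0.01, 0.01]
        assert find_onset(rates, p, sustained_k=1) == 0.1
        assert find_onset(rates, p, sustained_k=2) == 0.3
        assert find_onset(rates, p, sustained_k=4) is None

    def test_onset_rejects_mismatched_input(self):
        with pytest.raises(ValueError):
            find_onset([0.1], [0.1, 0.2])
        with pytest.raises(ValueError):
            find_onset([], [])


class TestCorrelation:
    def test_identical_vectors(self):
        assert correlation_at_rate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == \
            pytest.approx(1.0)

    def test_negation_about_mean(self):
        x = np.array([1.0, 2.0, 3.0])
        assert correlation_at_rate(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert correlation_at_rate(x, y) == pytest.approx(r_hand, abs=1e-10)
        assert r_hand == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_zero_variance_is_missing(self):
        assert np.isnan(correlation_at_rate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestRateGrid:
    def test_default_grid_spans_0_to_50(self):
        grid = default_rate_grid()
        assert grid[0] == 0.0 and grid[-1] == 50.0 and len(grid) == 501
        assert np.allclose(np.diff(grid), 0.1)


@pytest.fixture(scope="module")
def tiny_sweep(small_cohort_module):
    cfg = SweepConfig(rate_grid=(0.0, 2.0), n_reps=3,
                      methods=("none", "NNI"),
                      metrics=("AVNN", "RMSSD", "SDNN"), seed=5)
    return run_sweep(small_cohort_module, cfg), cfg


@pytest.fixture(scope="module")
def small_cohort_module():
    from ectohrv import CohortConfig, generate_cohort
    return generate_cohort(CohortConfig(n_subjects=4, duration=300.0, seed=7))


class TestRunSweep:
    def test_zero_rate_fc_is_exactly_100_and_not_significant(self, tiny_sweep):
        res, _ = tiny_sweep
        at0 = res.stats[res.stats.rate == 0.0]
        assert (at0.mean_fc == 100.0).all()
        assert (~at0.significant).all()
        v0 = res.values[res.values.rate == 0.0]
        assert (v0.pct_fc == 100.0).all()

    def test_deterministic_given_seed(self, small_cohort_module, tiny_sweep):
        res, cfg = tiny_sweep
        res2 = run_sweep(small_cohort_module, cfg)
        assert res.values.equals(res2.values)
        assert res.stats.equals(res2.stats)

    def test_methods_share_reference_and_differ_downstream(self, tiny_sweep):
        res, _ = tiny_sweep
        v = res.values[res.values.rate == 2.0]
        none = v[v.method == "none"].set_index(["metric", "subject"])
        nni = v[v.method == "NNI"].set_index(["metric", "subject"])
        assert (none.ref_value == nni.ref_value).all()
        assert not np.allclose(none.value, nni.value)

    def test_export_report_roundtrip(self, tiny_sweep, tmp_path):
        res, cfg = tiny_sweep
        files = export_report(res, tmp_path / "a")
        names = {f.name for f in files}
        assert {"values.csv", "stats.csv", "onsets.csv",
                "correlations.csv", "metadata.json"} <= names
        # onset table has one row per (metric, method)
        import pandas as pd
        onsets = pd.read_csv(tmp_path / "a" / "onsets.csv")
        assert len(onsets) == len(cfg.metrics) * len(cfg.methods)
        # re-export is byte-identical
        export_report(res, tmp_path / "b")
        for f in files:
            assert (tmp_path / "b" / f.name).read_bytes() == f.read_bytes()
        meta = (tmp_path / "a" / "metadata.json").read_text()
        assert '"seed": 5' in meta

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_sweep([], SweepConfig(rate_grid=(0.0,)))

    def test_checkpoint_resume_matches_fresh_run(self, small_cohort_module,
                                                 tmp_path):
        cfg = SweepConfig(rate_grid=(0.0, 1.0), n_reps=2, methods=("none",),
                          metrics=("RMSSD",), seed=9)
        fresh = run_sweep(small_cohort_module, cfg)
        ck = tmp_path / "ck"
        first = run_sweep(small_cohort_module, cfg, checkpoint_dir=ck)
        resumed = run_sweep(small_cohort_module, cfg, checkpoint_dir=ck)
        for res in (first, resumed):
            assert np.allclose(res.stats.p_value, fresh.stats.p_value,
                               equal_nan=True)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SweepConfig(rate_grid=(2.0, 1.0))
        with pytest.raises(ValueError):
            SweepConfig(metrics=("RMSSD", "nonsense"))
        with pytest.raises(ValueError):
            SweepConfig(alpha=1.5)

    def test_rmssd_fc_rises_with_rate_without_restoration(
            self, small_cohort_module):
        """Cohort-mean RMSSD %FC grows with the error rate over 0-5%."""
        cfg = SweepConfig(rate_grid=(0.0, 1.0, 3.0, 5.0), n_reps=4,
                          methods=("none",), metrics=("RMSSD",), seed=11)
        res = run_sweep(small_cohort_module, cfg)
        fc = res.stats.sort_values("rate").mean_fc.to_numpy()
        assert np.all(np.diff(fc) > -1.0)  # non-decreasing within MC slack
        assert fc[-1] > fc[0]
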