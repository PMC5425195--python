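"""Frequentist change-point detectors: brute-force oracles, invariances,
null calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgonset.changepoint import (
    AmocConfig,
    CpmConfig,
    amoc_detect,
    batch_cpm_detect,
    sequential_cpm_detect,
    two_sample_statistic,
)
from emgonset.calibration import batch_null_quantile, sequential_threshold_curve
from emgonset.io import EmgRecording

FS = 1.0


def rec(x):
    return EmgRecording(np.asarray(x, dtype=float), fs=FS)


def amoc_bruteforce(x, statistic):
    """Exhaustive split scan of the Gaussian log-likelihood improvement."""
    n = len(x)
    best, bestk = -np.inf, None
    rss0 = np.sum((x - x.mean()) ** 2)
    for k in range(2, n - 1):
        a, b = x[:k], x[k:]
        if statistic == "mean":
            rss1 = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
            s = n * np.log(rss0 / rss1) if rss1 > 0 else np.inf
        elif statistic == "variance":
            mu = x.mean()
            v1 = np.mean((a - mu) ** 2)
            v2 = np.mean((b - mu) ** 2)
            if v1 <= 0 or v2 <= 0:
                continue
            s = n * np.log(rss0 / n) - k * np.log(v1) - (n - k) * np.log(v2)
        else:
            v1 = np.var(a)
            v2 = np.var(b)
            if v1 <= 0 or v2 <= 0:
                continue
            s = n * np.log(rss0 / n) - k * np.log(v1) - (n - k) * np.log(v2)
        if s > best:
            best, bestk = s, k
    return best, bestk


class TestAmoc:
    def test_step_in_mean_found_exactly(self, rng):
        x = np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 1e-9, 20)
        res = amoc_detect(rec(x), AmocConfig(statistic="mean"))
        assert res.detected and res.index == 10

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(10, 200))
    def test_matches_bruteforce_scan(self, seed, n):
        g = np.random.default_rng(seed)
        x = g.standard_normal(n)
        x[n // 2 :] += g.uniform(0, 3)
        for statistic in ("mean", "variance", "meanvar"):
            res = amoc_detect(
                rec(x), AmocConfig(statistic=statistic, penalty=-1e18)
            )
            _, bestk = amoc_bruteforce(x, statistic)
            assert res.detected and res.index == bestk

    def test_null_false_detection_rate(self):
        g = np.random.default_rng(5)
        fp = sum(
            amoc_detect(rec(g.standard_normal(200)), AmocConfig("mean")).detected
            for _ in range(400)
        )
        assert fp / 400 <= 0.10

    def test_variance_change_found(self):
        # the common mean is estimated, so at n=20 the boundary blurs by a
        # sample or two; detection itself is near-certain
        detected = 0
        near = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            x = np.r_[g.normal(0, 0.01, 10), g.normal(0, 1, 10)]
            res = amoc_detect(rec(x), AmocConfig(statistic="variance"))
            if res.detected:
                detected += 1
                near += abs(res.index - 10) <= 2
        assert detected >= 95
        assert near >= 90

    def test_zero_variance_series(self):
        res = amoc_detect(rec(np.ones(50)), AmocConfig("mean"))
        assert not res.detected and "zero-variance" in res.note


class TestTwoSampleStatistics:
    def test_student_zero_for_identical_halves(self):
        x = np.r_[np.arange(4.0), np.arange(4.0)]
        assert two_sample_statistic(x, 4, "Student") == 0.0

    def test_mannwhitney_matches_pair_counting(self):
        # x = 1..8, split 4: U = #{(i,j): x_i > x_j} = 0 for the first sample
        x = np.arange(1.0, 9.0)
        u = sum(xi > xj for xi in x[:4] for xj in x[4:])
        assert u == 0
        w4 = 1 + 2 + 3 + 4  # rank sum of the first sample
        expect = abs(w4 - 4 * 9 / 2) / np.sqrt(4 * 4 * 9 / 12.0)
        assert two_sample_statistic(x, 4, "MannWhitney") == pytest.approx(expect)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mannwhitney_pair_counting_property(self, seed):
        g = np.random.default_rng(seed)
        x = g.standard_normal(30)
        k = int(g.integers(3, 27))
        u = sum(xi > xj for xi in x[:k] for xj in x[k:])
        l = 30 - k
        # U = W_k - k(k+1)/2; standardized as |W_k - E W_k| / sd
        w = u + k * (k + 1) / 2
        expect = abs(w - k * 31 / 2) / np.sqrt(k * l * 31 / 12.0)
        assert two_sample_statistic(x, k, "MannWhitney") == pytest.approx(expect)

    def test_ks_zero_for_identical_empirical_distributions(self):
        x = np.r_[np.arange(5.0), np.arange(5.0)]
        assert two_sample_statistic(x, 5, "KolmogorovSmirnov") == 0.0

    @pytest.mark.parametrize("model", ["MannWhitney", "Mood", "CramerVonMises", "KolmogorovSmirnov"])
    def test_rank_statistics_monotone_invariant(self, model, rng):
        x = rng.standard_normal(40)
        for k in (10, 20, 31):
            a = two_sample_statistic(x, k, model)
            b = two_sample_statistic(np.exp(x), k, model)
            assert a == pytest.approx(b, abs=1e-10)

    @pytest.mark.parametrize("model", ["Student", "Bartlett", "GLR"])
    def test_parametric_statistics_affine_invariant(self, model, rng):
        x = rng.standard_normal(40)
        for k in (10, 25):
            a = two_sample_statistic(x, k, model)
            b = two_sample_statistic(3.0 * x - 7.0, k, model)
            assert a == pytest.approx(b, rel=1e-9)

    def test_exponential_model_rejects_negative_data(self):
        x = np.r_[-1.0, np.arange(20.0)]
        with pytest.raises(ValueError, match="rectif"):
            two_sample_statistic(x, 10, "GLR_Exponential")


class TestBatchCpm:
    def test_step_detected_near_true_change(self):
        hits = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            x = np.r_[g.normal(0, 1, 250), g.normal(3, 1, 250)]
            res = batch_cpm_detect(rec(x), CpmConfig(mode="batch", model="Student"))
            if res.detected and abs(res.index - 250) <= 10:
                hits += 1
        assert hits >= 48

    def test_false_positive_rate_near_alpha(self):
        g = np.random.default_rng(11)
        cfg = CpmConfig(mode="batch", model="Student")
        fp = sum(
            batch_cpm_detect(rec(g.standard_normal(500)), cfg).detected
            for _ in range(600)
        )
        assert 0.02 <= fp / 600 <= 0.08

    def test_constant_series_not_detected(self):
        res = batch_cpm_detect(rec(np.ones(100)), CpmConfig(mode="batch"))
        assert not res.detected

    def test_decision_affine_invariant(self, rng):
        x = rng.standard_normal(300)
        x[150:] += 1.5
        cfg = CpmConfig(mode="batch", model="GLR")
        a = batch_cpm_detect(rec(x), cfg)
        b = batch_cpm_detect(rec(5.0 * x + 2.0), cfg)
        assert a.detected == b.detected and a.index == b.index

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="startup"):
            batch_cpm_detect(rec(np.zeros(30)), CpmConfig(mode="batch"))

    def test_onset_respects_startup_bounds(self, rng):
        x = rng.standard_normal(200)
        x[5:] += 4.0  # change inside the startup guard
        res = batch_cpm_detect(rec(x), CpmConfig(mode="batch", model="Student"))
        if res.detected:
            assert 20 <= res.index <= 180


class TestSequentialCpm:
    def test_threshold_monotone_in_arl0(self):
        h_lo = sequential_threshold_curve("Student", 370.0, 1024)
        h_hi = sequential_threshold_curve("Student", 5000.0, 1024)
        t = np.arange(40, 1024)
        assert np.all(h_hi[t] >= h_lo[t])

    def test_mean_run_length_near_arl0(self):
        # ARL0 = 370: mean run length of in-control streams within 15%
        g = np.random.default_rng(2024)
        cfg = CpmConfig(mode="sequential", model="Student", arl0=370.0)
        runs = []
        for _ in range(500):
            x = g.standard_normal(3000)
            res = sequential_cpm_detect(rec(x), cfg)
            if res.detected:
                t = int(res.note.split("t=")[1])
            else:
                t = 3000
            runs.append(t)
        arl = np.mean(runs)
        assert abs(arl / 370.0 - 1.0) < 0.15

    def test_step_changepoint_estimate_accurate(self):
        # ARL0 must comfortably exceed the 300-sample in-control prefix,
        # otherwise false alarms dominate regardless of implementation
        hits = 0
        n_run = 60
        for seed in range(n_run):
            g = np.random.default_rng(seed)
            x = np.r_[g.normal(0, 1, 300), g.normal(5, 1, 300)]
            res = sequential_cpm_detect(
                rec(x), CpmConfig(mode="sequential", model="MannWhitney", arl0=50000.0)
            )
            if res.detected and abs(res.index - 300) <= 15:
                hits += 1
        assert hits >= 0.90 * n_run

    def test_in_control_stream_usually_unsignalled_at_50000(self):
        g = np.random.default_rng(7)
        cfg = CpmConfig(mode="sequential", model="Student", arl0=50000.0)
        alarms = sum(
            sequential_cpm_detect(rec(g.standard_normal(1000)), cfg).detected
            for _ in range(50)
        )
        # per-stream alarm probability ~ 1000/50000 = 2%
        assert alarms <= 5

    def test_sequential_model_validation(self):
        with pytest.raises(ValueError, match="not a sequential"):
            CpmConfig(mode="sequential", model="KolmogorovSmirnov")
        with pytest.raises(ValueError, match="not a batch"):
            CpmConfig(mode="batch", model="GLR_Exponential")
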