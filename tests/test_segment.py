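"""Change-point segmentation, dwell extraction and trace-quality metrics."""

import numpy as np
import pytest

from opencomplex import (
    Segmentation,
    TraceConfig,
    allan_deviation,
    correlation_time,
    detect_changepoints,
    detrend,
    extract_dwells,
    label_segments,
    render_trace,
    segment_trace,
    simulate_trajectory,
    true_dwells,
)


def _best_single_split(z):
    """Exhaustive single-split oracle: index minimizing total L1 cost."""
    def cost(x):
        return np.abs(x - np.median(x)).sum()
    n = len(z)
    costs = [cost(z[:i]) + cost(z[i:]) for i in range(1, n)]
    return 1 + int(np.argmin(costs))


class TestDetect:
    def test_constant_series_has_no_breakpoints(self):
        assert detect_changepoints(np.full(400, 7.0), penalty=1.0).size == 0

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            detect_changepoints(np.array([]), penalty=1.0)

    def test_noiseless_step_found_exactly(self):
        z = np.concatenate([np.zeros(500), np.full(500, 73.0)])
        bps = detect_changepoints(z, penalty=1.0, min_size=2)
        assert list(bps) == [500]
        assert _best_single_split(z) == 500

    def test_noisy_step_matches_single_split_oracle(self, rng):
        z = np.concatenate([np.zeros(300), np.full(300, 73.0)])
        z = z + rng.normal(0, 7.9, size=600)
        bps = detect_changepoints(z, penalty=1.0, min_size=2)
        oracle = _best_single_split(z)
        assert any(abs(b - oracle) <= 1 for b in bps)

    def test_offset_invariance(self, rng):
        z = np.concatenate([np.zeros(200), np.full(250, 73.0), np.zeros(150)])
        z = z + rng.normal(0, 7.9, size=600)
        a = detect_changepoints(z, penalty=1.0)
        b = detect_changepoints(z + 12345.6, penalty=1.0)
        np.testing.assert_array_equal(a, b)

    def test_transition_count_non_increasing_in_penalty(self, rng, fixture_rates):
        traj = simulate_trajectory(fixture_rates, 400.0, seed=3)
        tr = render_trace(traj, TraceConfig(rates=fixture_rates,
                                            duration=400.0, seed=4))
        counts = [detect_changepoints(tr.z, penalty=p).size
                  for p in (0.3, 1.0, 3.0, 10.0)]
        assert counts == sorted(counts, reverse=True)

    def test_recovers_true_transitions(self, fixture_rates):
        # >= 95% of true transitions bounding dwells > 1 s recovered
        # within +-2 samples at the default SNR (73 nm jump, 7.9 nm noise)
        hits, total = 0, 0
        for seed in (10, 11):
            traj = simulate_trajectory(fixture_rates, 1000.0, seed=seed)
            cfg = TraceConfig(rates=fixture_rates, duration=1000.0,
                              seed=seed + 100)
            tr = render_trace(traj, cfg)
            bps = detect_changepoints(tr.z, penalty=1.0, min_size=2)
            dw = true_dwells(traj)
            f_eff = cfg.f_s_eff
            # transition times between dwells, flanked by long dwells
            starts = np.cumsum(np.concatenate(([0.0], dw.durations[:-1])))
            for i in range(1, len(dw)):
                if dw.durations[i - 1] > 1.0 and dw.durations[i] > 1.0:
                    total += 1
                    idx = starts[i] * f_eff
                    if np.any(np.abs(bps - idx) <= 2):
                        hits += 1
        assert total > 50
        assert hits / total >= 0.95


class TestLabel:
    def test_two_clean_levels_perfectly_labeled(self):
        z = np.concatenate([np.full(100, 300.0), np.full(80, 227.0),
                            np.full(120, 300.0)])
        seg = label_segments(z, [100, 180])
        assert seg.labels == ["CS", "OS", "CS"]
        np.testing.assert_allclose(seg.levels, [300.0, 227.0, 300.0])

    def test_trace_without_openings_is_all_cs(self, rng):
        z = 300.0 + rng.normal(0, 7.9, 500)
        seg = label_segments(z, detect_changepoints(z, penalty=1.0))
        assert set(seg.labels) == {"CS"}

    def test_adjacent_same_label_segments_merged(self, rng):
        z = np.concatenate([np.full(100, 300.0), np.full(100, 227.0)])
        seg = label_segments(z, [50, 100, 150])  # spurious extra breakpoints
        assert seg.labels == ["CS", "OS"]
        assert list(seg.breakpoints) == [100]

    def test_sample_label_accuracy_on_synthetic_trace(self, fixture_rates):
        traj = simulate_trajectory(fixture_rates, 1500.0, seed=21)
        cfg = TraceConfig(rates=fixture_rates, duration=1500.0, seed=22)
        tr = render_trace(traj, cfg)
        seg, _ = segment_trace(tr, t_min=0.0)
        # per-sample labels vs ground truth
        pred_open = np.zeros(len(tr.z), dtype=bool)
        bounds = seg.bounds
        for i, lab in enumerate(seg.labels):
            if lab == "OS":
                pred_open[bounds[i]:bounds[i + 1]] = True
        true_open = np.isin(traj.state_at(tr.t), ("RP_I", "RP_O"))
        assert (pred_open == true_open).mean() >= 0.98


class TestExtract:
    def test_middle_dwell_only_is_retained(self):
        seg = Segmentation(n_samples=300, breakpoints=[100, 200],
                           labels=["CS", "OS", "CS"],
                           levels=[300.0, 227.0, 300.0])
        dw = extract_dwells(seg, f_s_eff=5.8, t_min=0.0)
        uncens = dw.durations[~dw.censored]
        assert uncens.size == 1
        assert uncens[0] == pytest.approx(100 / 5.8, abs=1e-10)  # 17.24 s

    def test_zero_cutoff_retains_all_uncensored(self):
        seg = Segmentation(n_samples=50, breakpoints=[10, 20, 35],
                           labels=["CS", "OS", "CS", "OS"],
                           levels=[300, 227, 300, 227])
        dw = extract_dwells(seg, f_s_eff=5.8, t_min=0.0)
        assert len(dw) == 4
        assert (~dw.censored).sum() == 2

    def test_short_interior_dwell_merged_into_neighbors(self):
        seg = Segmentation(n_samples=500, breakpoints=[200, 202, 300],
                           labels=["CS", "OS", "CS", "OS"],
                           levels=[300, 227, 300, 227])
        dw = extract_dwells(seg, f_s_eff=5.8, t_min=1.0)
        # the 2-sample OS dwell (0.34 s) is dropped; CS neighbors merge
        assert list(dw.labels) == ["CS", "OS"]
        assert dw.durations[0] == pytest.approx(300 / 5.8)

    @staticmethod
    def _apply_tmin(labels, durations, censored, t_min):
        """Oracle: the t_min discard-and-merge rule on the true dwell record
        (sub-cutoff excursions are invisible to any detector, so the fair
        ground-truth count applies the same lumping)."""
        labels, durations, censored = (list(labels), list(durations),
                                       list(censored))
        while True:
            interior = [i for i in range(1, len(durations) - 1)
                        if durations[i] < t_min]
            if not interior:
                break
            i = min(interior, key=lambda k: durations[k])
            durations[i - 1:i + 2] = [durations[i - 1] + durations[i]
                                      + durations[i + 1]]
            censored[i - 1:i + 2] = [censored[i - 1] or censored[i + 1]]
            labels[i - 1:i + 2] = [labels[i - 1]]
        return sum(1 for d, c in zip(durations, censored)
                   if not c and d >= t_min)

    def test_retained_count_tracks_ground_truth(self, fixture_rates):
        t_min = 0.4
        got, want = 0, 0
        for seed in (31, 32, 33):
            traj = simulate_trajectory(fixture_rates, 2000.0, seed=seed)
            cfg = TraceConfig(rates=fixture_rates, duration=2000.0,
                              seed=seed + 50)
            _, dw = segment_trace(render_trace(traj, cfg), t_min=t_min)
            td = true_dwells(traj)
            got += (~dw.censored).sum()
            want += self._apply_tmin(td.labels, td.durations, td.censored,
                                     t_min)
        assert got == pytest.approx(want, rel=0.05)


class TestQualityMetrics:
    def test_allan_of_constant_series_is_zero(self):
        taus, sig = allan_deviation(np.full(256, 5.0), f_s=58.0)
        np.testing.assert_allclose(sig, 0.0, atol=1e-12)

    def test_allan_white_noise_slope(self, rng):
        z = rng.normal(0, 10.0, 2 ** 14)
        taus, sig = allan_deviation(z, f_s=58.0)
        keep = slice(0, len(taus) - 4)  # top octaves have too few blocks
        slope = np.polyfit(np.log(taus[keep]), np.log(sig[keep]), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_allan_correlated_noise_decays_beyond_correlation_time(self, rng):
        # AR(1) noise with ~0.5 s correlation time
        f_s, t_c = 58.0, 0.5
        phi = np.exp(-1.0 / (f_s * t_c))
        e = rng.normal(0, 1.0, 2 ** 15)
        z = np.zeros_like(e)
        for i in range(1, len(e)):
            z[i] = phi * z[i - 1] + e[i]
        taus, sig = allan_deviation(z, f_s)
        tail = sig[(taus > 3 * t_c) & (taus < taus[-3])]
        assert np.all(np.diff(tail) < 1e-12)  # monotone decay, no minimum

    def test_correlation_time_of_ar1_noise(self, rng):
        f_s, t_c = 58.0, 0.5
        phi = np.exp(-1.0 / (f_s * t_c))
        e = rng.normal(0, 1.0, 2 ** 16)
        z = np.zeros_like(e)
        for i in range(1, len(e)):
            z[i] = phi * z[i - 1] + e[i]
        est = correlation_time(z, f_s)
        assert est == pytest.approx(t_c, rel=0.25)

    def test_detrend_removes_strong_drift(self, rng):
        f_s = 5.8
        t = np.arange(2000) / f_s
        z = 300.0 + 1.5 * t + rng.normal(0, 7.9, 2000)
        zc, slope = detrend(z, f_s)
        assert slope == pytest.approx(1.5, rel=0.05)
        assert abs(np.polyfit(t, zc, 1)[0]) < 0.05

    def test_detrend_leaves_weak_drift(self, rng):
        f_s = 5.8
        z = 300.0 + rng.normal(0, 7.9, 2000)
        zc, slope = detrend(z, f_s)
        np.testing.assert_array_equal(z, zc)
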