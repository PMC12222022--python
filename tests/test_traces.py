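import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nociscope.simulate import transient_kernel
from nociscope.traces import (
    SPONTANEOUS_PARAMS,
    DetectionParams,
    TraceError,
    activity_maps,
    compute_dff,
    detect_transients,
    spontaneous_activity,
    subtract_background,
)

from _oracles import detect_by_definition
from conftest import make_kernel_trace


class TestSubtractBackground:
    def test_constant_annulus_is_identity(self, rng):
        f = rng.uniform(100, 200, 100)
        ann = np.full(100, 55.0)
        assert np.array_equal(subtract_background(f, ann), f)

    def test_r_zero_is_identity(self, rng):
        f = rng.uniform(100, 200, 100)
        ann = rng.uniform(50, 80, 100)
        assert np.array_equal(subtract_background(f, ann, r=0.0), f)

    def test_recovers_constructed_contamination(self, rng):
        """A cell contaminated by half the annulus fluctuation is restored
        sample-wise once the median-centred annulus is subtracted at r=0.5."""
        true = rng.uniform(100, 120, 500)
        ann = rng.uniform(40, 60, 500)
        fluct = ann - np.median(ann)
        contaminated = true + 0.5 * fluct
        rec = subtract_background(contaminated, ann, r=0.5)
        np.testing.assert_allclose(rec, true, rtol=0, atol=1e-10)

    def test_length_mismatch_raises(self):
        with pytest.raises(TraceError, match="length"):
            subtract_background(np.ones(5), np.ones(6))


class TestComputeDff:
    def test_constant_series_is_zero(self):
        dff = compute_dff(np.full(200, 42.0))
        assert np.allclose(dff, 0.0)

    def test_arithmetic_identity(self):
        f = np.full(50, 100.0)
        f[25] = 110.0
        dff = compute_dff(f, method="prestim_mean", prestim_samples=10)
        assert dff[25] == pytest.approx(10.0)

    def test_recovers_injected_step(self):
        """Forward-simulate a 20% step over an F0=200 baseline and invert."""
        f = np.full(200, 200.0)
        f[100:150] *= 1.20
        dff = compute_dff(f, method="prestim_mean", prestim_samples=50)
        assert dff[120] == pytest.approx(20.0, abs=1e-9)

    def test_nonpositive_baseline_flags_cell(self):
        with pytest.raises(TraceError, match="cell_7"):
            compute_dff(np.full(20, -5.0), cell_id="cell_7")

    def test_baseline_is_per_episode(self):
        f = np.concatenate([np.full(100, 100.0), np.full(100, 200.0)])
        ep = np.repeat([0, 1], 100)
        dff = compute_dff(f, episode_ids=ep)
        assert np.allclose(dff, 0.0)


class TestDetectTransients:
    def test_flat_trace_has_no_transients(self):
        assert detect_transients(np.zeros(300)) == []

    def test_empty_trace(self):
        assert detect_transients(np.array([])) == []

    def test_subthreshold_absolute_peak_rejected(self):
        """A smooth bump peaking at 3.9% fails the 4% absolute-peak rule even
        though its prominence clears 4% is irrelevant -- both must hold."""
        t, x = make_kernel_trace(100, 5.0, [(5.0, 3.9)])
        assert detect_transients(x, params=DetectionParams(3.0, 4.0, 0.6)) == []
        # a sampled peak exactly at 4.0% passes (thresholds are minima, inclusive)
        x = np.zeros(100)
        x[50] = 4.0
        det = detect_transients(x, params=DetectionParams(3.0, 4.0, 0.6))
        assert len(det) == 1

    def test_amplitude_is_peak_minus_preceding_minimum(self):
        t, x = make_kernel_trace(200, 5.0, [(10.0, 12.0)])
        x += 2.0  # constant offset must not change the amplitude
        det = detect_transients(x)
        assert len(det) == 1
        tr = det[0]
        assert tr.amplitude == pytest.approx(12.0, rel=0.02)
        assert tr.onset_time < tr.peak_time <= tr.end_time

    def test_matches_brute_force_oracle_exactly(self, rng):
        """On random noisy traces with injected events, detections must equal
        the exhaustive prominence-by-definition oracle: same peak indices,
        same prominences, same amplitudes."""
        fs = 5.0
        for _ in range(200):
            n = 300
            n_ev = rng.integers(0, 6)
            events = [
                (float(rng.uniform(1, n / fs - 3)), float(rng.uniform(4, 20)))
                for _ in range(n_ev)
            ]
            _, x = make_kernel_trace(n, fs, events, noise_sd=1.0, rng=rng)
            det = detect_transients(x, fs=fs)
            ref = detect_by_definition(x, fs, 4.0, 4.0, 0.6)
            assert [tr.peak_index for tr in det] == [p for p, _, _ in ref]
            assert [tr.prominence for tr in det] == pytest.approx(
                [pr for _, pr, _ in ref], abs=0
            )
            assert [tr.amplitude for tr in det] == pytest.approx(
                [a for _, _, a in ref], abs=0
            )

    def test_detection_does_not_cross_episode_boundaries(self):
        """A peak whose rise starts in the previous episode takes its onset at
        the episode start, and episode-edge samples are never peaks."""
        x = np.zeros(100)
        x[48:52] = [5.0, 9.0, 9.5, 3.0]  # straddles the boundary at sample 50
        ep = np.repeat([0, 1], 50)
        det = detect_transients(x, episode_ids=ep)
        for tr in det:
            assert ep[tr.onset_index] == ep[tr.peak_index] == ep[tr.end_index]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=1.5, max_value=8.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, k, seed):
        """Scaling a trace by k scales every amplitude by exactly k for events
        passing thresholds at both scales."""
        r = np.random.default_rng(seed)
        events = [(float(r.uniform(2, 50)), float(r.uniform(8, 25))) for _ in range(4)]
        _, x = make_kernel_trace(300, 5.0, events, noise_sd=0.5, rng=r)
        d1 = {tr.peak_index: tr.amplitude for tr in detect_transients(x)}
        dk = {tr.peak_index: tr.amplitude for tr in detect_transients(k * x)}
        common = set(d1) & set(dk)
        assert common  # events far above threshold survive both scales
        for p in common:
            assert dk[p] == pytest.approx(k * d1[p], rel=1e-12)

    def test_refractory_interval_enforced(self, rng):
        """No two returned peaks are closer than the inter-peak interval."""
        for _ in range(50):
            x = rng.normal(0, 6, 200)  # pathological: dense suprathreshold noise
            det = detect_transients(x, params=DetectionParams(4.0, 4.0, 0.6))
            times = [tr.peak_time for tr in det]
            assert all(b - a >= 0.6 - 0.1 for a, b in zip(times, times[1:]))

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.2, 0.5, 0.6, 0.8])
        with pytest.raises(TraceError, match="non-uniform"):
            detect_transients(np.zeros(5), t=t)

    def test_recovery_and_false_positive_rates(self, rng):
        """At default 1% noise, >=95% of events with amplitude >= 2x the
        absolute-peak threshold are found, and event-free noise produces
        <= 1 false event per 100 s."""
        fs, n = 5.0, 525  # 105 s
        found = total = 0
        for _ in range(100):
            events = [(float(10 + 20 * k + rng.uniform(0, 5)), 8.0) for k in range(5)]
            _, x = make_kernel_trace(n, fs, events, noise_sd=1.0, rng=rng)
            det = detect_transients(x, fs=fs)
            for t0, _ in events:
                total += 1
                if any(abs(tr.peak_time - t0) < 1.5 for tr in det):
                    found += 1
        assert found / total >= 0.95
        false = sum(
            len(detect_transients(rng.normal(0, 1.0, n), fs=fs)) for _ in range(100)
        )
        assert false / 100 <= 1.05  # per 105-s trace ~ 1 per 100 s


class TestSpontaneousActivity:
    def test_no_transients_gives_zero(self):
        assert spontaneous_activity(np.zeros(500), [(0.0, 100.0)]) == 0.0

    def test_sum_identity_of_injected_amplitudes(self):
        _, x = make_kernel_trace(500, 5.0, [(10.0, 5.0), (40.0, 7.0), (70.0, 8.0)])
        total = spontaneous_activity(x, [(0.0, 100.0)])
        assert total == pytest.approx(20.0, rel=0.02)

    def test_short_windows_warn_and_report(self):
        with pytest.warns(UserWarning, match="40.*105"):
            spontaneous_activity(
                np.zeros(500), [(0.0, 40.0)], required_duration=105.0
            )

    def test_poisson_mean_matches_analytic_expectation(self, rng):
        """Mean summed amplitude over many cells sits in the 99% CI of
        rate * duration * E[amplitude]."""
        fs, dur, rate, amp = 5.0, 105.0, 3.0 / 60.0, 10.0
        n = int(dur * fs)
        sums = []
        for _ in range(400):
            times = np.cumsum(rng.exponential(1 / rate, 30))
            events = [(float(t0), amp) for t0 in times if t0 < dur - 3]
            _, x = make_kernel_trace(n, fs, events, noise_sd=0.5, rng=rng)
            sums.append(spontaneous_activity(x, [(0.0, dur)], fs=fs))
        # windows truncated 3 s before the end when placing events
        mu = rate * (dur - 3) * amp
        sd = np.sqrt(rate * (dur - 3) * amp**2)  # compound-Poisson variance
        half = 2.576 * sd / np.sqrt(len(sums))
        assert abs(np.mean(sums) - mu) < half + 0.12 * mu  # CI + small detection bias


class TestActivityMaps:
    def test_constant_stack_gives_zero_maps(self):
        stack = np.full((20, 8, 8), 7.0)
        sd, diff = activity_maps(stack, (0, 20), (0, 10), (10, 20))
        assert np.allclose(sd, 0) and np.allclose(diff, 0)

    def test_single_pixel_step(self):
        stack = np.zeros((20, 4, 4))
        stack[10:, 2, 1] = 10.0
        _, diff = activity_maps(stack, (0, 20), (0, 10), (10, 20))
        assert diff[2, 1] == pytest.approx(10.0)
        diff[2, 1] = 0
        assert np.allclose(diff, 0)

    def test_random_stack_matches_naive_reference(self, rng):
        stack = rng.normal(0, 1, (30, 6, 5))
        sd, diff = activity_maps(stack, (5, 25), (0, 12), (12, 30))
        ref_sd = np.empty((6, 5))
        ref_diff = np.empty((6, 5))
        for i in range(6):
            for j in range(5):
                ref_sd[i, j] = np.std(stack[5:25, i, j])
                ref_diff[i, j] = stack[12:30, i, j].mean() - stack[0:12, i, j].mean()
        np.testing.assert_allclose(sd, ref_sd, atol=1e-12)
        np.testing.assert_allclose(diff, ref_diff, atol=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(TraceError, match="empty|outside"):
            activity_maps(np.zeros((10, 2, 2)), (5, 5), (0, 5), (5, 10))
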