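"""Channel counting: segmentation exactness, unitary estimation, recovery."""

import itertools

import numpy as np
import pytest

from azquant import counting
from azquant.counting import (
    BleachTrace,
    Movie,
    StepModel,
    aggregate_counts,
    correct_drift,
    count_channels,
    count_channels_from_trace,
    default_penalty,
    detect_steps,
    estimate_unitary_intensity,
    extract_roi_trace,
    segment_trace,
)
from azquant.synthetic import BleachSimConfig, simulate_bleach_movie, simulate_bleach_trace


def make_trace(values, onset=0):
    values = np.asarray(values, dtype=float)
    return BleachTrace(values, np.arange(values.size) * 0.05, uv_onset_frame=onset)


# ---------------------------------------------------------------------------
# exact segmentation oracles


def oracle_best_segmentation(values, penalty, max_changes):
    """Independent exact search: minimum penalized cost over all change-point
    placements with at most ``max_changes`` changes, by brute-force
    enumeration (itertools)."""
    x = np.asarray(values, dtype=float)
    n = x.size

    def seg_cost(i, j):
        seg = x[i:j]
        return float(((seg - seg.mean()) ** 2).sum())

    best = (seg_cost(0, n), ())
    for k in range(1, max_changes + 1):
        for cps in itertools.combinations(range(1, n), k):
            bounds = (0, *cps, n)
            cost = sum(seg_cost(b0, b1) for b0, b1 in zip(bounds[:-1], bounds[1:]))
            cost += k * penalty
            if cost < best[0] - 1e-12:
                best = (cost, cps)
    return best


def oracle_kdp_segmentation(values, penalty, max_changes):
    """Independent exact search via k-constrained dynamic programming: for
    each number of changes k compute the unconstrained-best cost, then
    minimize cost + k * penalty. Exhaustive over all placements, but
    computed by a different algorithm than the penalized recursion."""
    x = np.asarray(values, dtype=float)
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):
        return (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / (j - i)

    c = np.full((max_changes + 1, n + 1), np.inf)
    for j in range(1, n + 1):
        c[0, j] = cost(0, j)
    for k in range(1, max_changes + 1):
        for j in range(k + 1, n + 1):
            c[k, j] = min(c[k - 1, s] + cost(s, j) for s in range(k, j))
    totals = c[:, n] + penalty * np.arange(max_changes + 1)
    k_best = int(np.argmin(totals))
    return float(totals[k_best]), k_best


class TestSegmentation:
    def test_noiseless_staircase_exact_steps(self, noiseless_staircase):
        (trace, truth), cfg = noiseless_staircase(3)
        model = detect_steps(make_trace(trace, onset=cfg.uv_onset_frame))
        assert model.n_steps == 4  # conversion jump + 3 bleach steps
        amps = model.step_amplitudes
        assert amps[0] == pytest.approx(3 * cfg.unitary_intensity)
        assert np.allclose(amps[1:], -cfg.unitary_intensity)

    def test_flat_noisy_trace_has_no_steps(self):
        rng = np.random.default_rng(3)
        trace = make_trace(rng.normal(100, 5, size=400))
        model = detect_steps(trace)
        assert model.n_steps == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="20 frames"):
            detect_steps(make_trace(np.zeros(30), onset=20))

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError, match="penalty"):
            detect_steps(make_trace(np.zeros(100)), penalty=0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration_small(self, seed):
        """On short traces the penalized search equals full enumeration of
        all change-point placements minimizing the same objective."""
        rng = np.random.default_rng(seed)
        n = 40
        n_steps = int(rng.integers(0, 4))
        cps_true = np.sort(rng.choice(np.arange(5, n - 5), size=n_steps, replace=False))
        levels = rng.integers(0, 5, size=n_steps + 1) * 100.0
        x = np.empty(n)
        bounds = [0, *cps_true.tolist(), n]
        for b0, b1, lev in zip(bounds[:-1], bounds[1:], levels):
            x[b0:b1] = lev
        x += rng.normal(0, 8.0, size=n)
        penalty = 2 * 64.0 * np.log(n)
        cps, obj = segment_trace(x, penalty)
        oracle_cost, oracle_cps = oracle_best_segmentation(x, penalty, max_changes=4)
        assert len(cps) <= 4
        assert obj == pytest.approx(oracle_cost, abs=1e-6)
        assert tuple(cps) == oracle_cps

    def test_step_count_recovery_at_snr5(self):
        """10-step traces at SNR 5: detected count within +-1 of truth in at
        least 80% of seeded traces."""
        rng = np.random.default_rng(77)
        hits = 0
        n_traces = 60
        for _ in range(n_traces):
            n = 500
            cps = np.sort(rng.choice(np.arange(10, n - 10), size=10, replace=False))
            x = np.zeros(n)
            level = 10.0 * 100
            bounds = [0, *cps.tolist(), n]
            levels = np.linspace(10, 0, 12)[:11] * 100
            for b0, b1, lev in zip(bounds[:-1], bounds[1:], levels):
                x[b0:b1] = lev
            x += rng.normal(0, 100 / 5, size=n)
            model = detect_steps(make_trace(x))
            if abs(model.n_steps - 10) <= 1:
                hits += 1
        assert hits / n_traces >= 0.8


class TestUnitaryEstimation:
    def _model_trace(self, amps_sequence, seg_len=20, lead=300):
        """Build a noiseless piecewise trace whose steps all lie in the
        second half (after a long leading plateau); returns
        (StepModel, BleachTrace)."""
        levels = [1000.0]
        for a in amps_sequence:
            levels.append(levels[-1] - a)
        lengths = [lead] + [seg_len] * len(amps_sequence)
        values = np.repeat(levels, lengths).astype(float)
        cps = lead + np.arange(len(amps_sequence)) * seg_len
        trace = make_trace(values, onset=0)
        model = StepModel(change_points=cps, segment_levels=np.array(levels))
        return model, trace

    def test_smallest_mode_median(self):
        """Amplitudes {u, u, 2u, u}: unitary is u from the 3-event mode."""
        u = 50.0
        model, trace = self._model_trace([u, u, 2 * u, u])
        unitary, n_events = estimate_unitary_intensity(model, trace)
        assert unitary == pytest.approx(u)
        assert n_events == 3

    def test_identical_amplitudes(self):
        u = 80.0
        model, trace = self._model_trace([u, u, u, u, u])
        unitary, n_events = estimate_unitary_intensity(model, trace)
        assert unitary == pytest.approx(u)
        assert n_events == 5

    def test_no_late_events_unavailable(self):
        values = np.concatenate([np.full(200, 500.0), np.full(400, 0.0)])
        trace = make_trace(values, onset=0)
        model = StepModel(change_points=np.array([200]),
                          segment_levels=np.array([500.0, 0.0]))
        unitary, n_events = estimate_unitary_intensity(model, trace)
        assert n_events == 0 and np.isnan(unitary)

    def test_parameter_recovery_within_10pct(self):
        """True unitary 100, trace SNR 10: median estimate within 10%."""
        cfg = BleachSimConfig(channels_per_az=10, unitary_intensity=100.0,
                              noise_sd=10.0, n_frames=2000, uv_onset_frame=200,
                              seed=0)
        estimates = []
        children = np.random.SeedSequence(21).spawn(40)
        for ch in children:
            trace, _ = simulate_bleach_trace(cfg, ch)
            bt = make_trace(trace, onset=cfg.uv_onset_frame)
            model = detect_steps(bt)
            u, n = estimate_unitary_intensity(model, bt)
            if n > 0:
                estimates.append(u)
        assert len(estimates) >= 30
        assert np.median(estimates) == pytest.approx(100.0, rel=0.10)


class TestCounting:
    def test_ratio_arithmetic(self):
        model, trace = TestUnitaryEstimation()._model_trace([50.0] * 4)
        est = count_channels(trace, model, unitary=50.0)
        assert est.n_channels == pytest.approx(1000.0 / 50.0)

    def test_no_signal_flagged(self):
        values = np.zeros(400)
        trace = make_trace(values, onset=100)
        model = StepModel(change_points=np.array([], dtype=int),
                          segment_levels=np.array([0.0]))
        est = count_channels(trace, model, unitary=50.0)
        assert est.n_channels == 0.0
        assert not est.qc_pass and "no signal" in est.qc_reasons

    def test_nonpositive_unitary_rejected(self):
        model, trace = TestUnitaryEstimation()._model_trace([50.0])
        with pytest.raises(ValueError, match="unitary"):
            count_channels(trace, model, unitary=0.0)

    @pytest.mark.parametrize("true_n", [2, 5, 9])
    def test_noiseless_staircase_counts_exact(self, noiseless_staircase, true_n):
        (trace, truth), cfg = noiseless_staircase(
            true_n, seed=13 + true_n, n_frames=1500, bleach_rate=0.002,
            require_late_event=True,
        )
        est = count_channels_from_trace(make_trace(trace, onset=cfg.uv_onset_frame))
        assert est.qc_pass
        assert est.n_channels == pytest.approx(true_n, abs=1e-9)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1e3])
    def test_scale_invariance(self, noiseless_staircase, scale):
        """Multiplying the trace by c scales peak and unitary by c and leaves
        the count unchanged to 1e-9 relative."""
        (trace, _), cfg = noiseless_staircase(
            4, seed=20, n_frames=1500, bleach_rate=0.002, require_late_event=True
        )
        t1 = make_trace(trace, onset=cfg.uv_onset_frame)
        t2 = make_trace(trace * scale, onset=cfg.uv_onset_frame)
        e1 = count_channels_from_trace(t1, penalty=default_penalty(t1.intensity) + 1.0)
        e2 = count_channels_from_trace(t2, penalty=(default_penalty(t1.intensity) + 1.0) * scale**2)
        assert e2.peak_intensity == pytest.approx(e1.peak_intensity * scale, rel=1e-9)
        assert e2.unitary_intensity == pytest.approx(e1.unitary_intensity * scale, rel=1e-9)
        assert e2.n_channels == pytest.approx(e1.n_channels, rel=1e-9)

    def test_error_degrades_monotonically_with_noise(self):
        """Mean absolute counting error is non-decreasing across noise levels
        0, u/20, u/10, u/5 (fixed seeds, fixed true count)."""
        maes = []
        for noise in (0.0, 5.0, 10.0, 20.0):
            errs = []
            children = np.random.SeedSequence(31).spawn(50)
            cfg = BleachSimConfig(channels_per_az=10, unitary_intensity=100.0,
                                  noise_sd=noise, n_frames=1200,
                                  uv_onset_frame=120, seed=0)
            for ch in children:
                trace, truth = simulate_bleach_trace(cfg, ch)
                est = count_channels_from_trace(make_trace(trace, onset=120))
                if np.isfinite(est.n_channels):
                    errs.append(abs(est.n_channels - truth.attrs["n_channels"]))
            maes.append(np.mean(errs))
        assert all(b >= a - 0.05 for a, b in zip(maes, maes[1:]))


class TestRoiExtraction:
    def test_uniform_frame_gives_zero(self):
        movie = Movie(np.full((10, 20, 20), 7.0), uv_onset_frame=0)
        trace = extract_roi_trace(movie, (10, 10))
        assert np.allclose(trace.intensity, 0.0)

    def test_single_bright_pixel(self):
        frames = np.zeros((5, 21, 21))
        frames[:, 10, 10] = 42.0
        trace = extract_roi_trace(Movie(frames, uv_onset_frame=0), (10, 10))
        assert np.allclose(trace.intensity, 42.0)

    def test_border_center_rejected(self):
        movie = Movie(np.zeros((5, 20, 20)), uv_onset_frame=0)
        with pytest.raises(ValueError, match="border"):
            extract_roi_trace(movie, (1, 10))

    def test_pre_onset_trace_near_zero(self):
        cfg = BleachSimConfig(n_az=1, noise_sd=2.0, n_frames=300,
                              uv_onset_frame=100, seed=2)
        arr, truth = simulate_bleach_movie(cfg)
        movie = Movie(arr, uv_onset_frame=100)
        r, c = int(truth.row[0]), int(truth.col[0])
        trace = extract_roi_trace(movie, (r, c))
        pre = trace.intensity[:100]
        assert abs(pre.mean()) <= 3 * cfg.noise_sd * np.sqrt(25)


class TestDriftCorrection:
    def test_zero_drift_shifts_small(self):
        cfg = BleachSimConfig(n_az=2, n_frames=30, uv_onset_frame=5, noise_sd=1.0,
                              conversion_rate=1.0, bleach_rate=0.0,
                              blink_off_rate=0.0, seed=3)
        arr, _ = simulate_bleach_movie(cfg)
        _, shifts = correct_drift(Movie(arr, uv_onset_frame=5))
        assert np.abs(shifts[5:]).max() <= 0.1

    def test_linear_drift_recovered(self):
        cfg = BleachSimConfig(n_az=4, n_frames=60, uv_onset_frame=10, noise_sd=1.0,
                              drift_per_frame=(0.05, 0.0), conversion_rate=1.0,
                              bleach_rate=0.0, blink_off_rate=0.0, seed=3)
        arr, _ = simulate_bleach_movie(cfg)
        _, shifts = correct_drift(Movie(arr, uv_onset_frame=10))
        est = shifts[10:, 0] - shifts[10:, 0].mean()
        true = -0.05 * np.arange(10, 60)
        true = true - true.mean()
        assert np.abs(est - true).max() <= 0.2

    def test_integer_translation_inverse(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 40)) * 100
        shifted = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
        stack = np.stack([img] * 4 + [shifted])
        _, shifts = correct_drift(Movie(stack, uv_onset_frame=0), upsample_factor=1)
        assert tuple(shifts[4]) == (-3.0, 2.0)

    def test_all_zero_movie_skipped_with_warning(self):
        movie = Movie(np.zeros((5, 20, 20)), uv_onset_frame=0)
        with pytest.warns(UserWarning, match="skipped"):
            out, shifts = correct_drift(movie)
        assert np.all(shifts == 0)


class TestAggregation:
    def _est(self, n):
        return counting.ChannelCountEstimate(
            peak_intensity=n * 100, unitary_intensity=100.0, n_channels=float(n),
            n_unitary_events=5, qc_pass=True,
        )

    def test_animal_mean(self):
        ests = [self._est(v) for v in [9, 10, 11] * 10]
        per_animal, per_geno = aggregate_counts(
            ests, ["a1"] * 30, ["ctrl"] * 30
        )
        assert per_animal.mean_channels.iloc[0] == pytest.approx(10.0)
        assert not per_animal.below_minimum.iloc[0]
        assert per_geno.mean_channels.iloc[0] == pytest.approx(10.0)

    def test_small_animal_flagged(self):
        ests = [self._est(10)] * 10
        per_animal, _ = aggregate_counts(ests, ["a1"] * 10, ["ctrl"] * 10)
        assert per_animal.below_minimum.iloc[0]

    def test_qc_failures_excluded_and_counted(self):
        bad = counting.ChannelCountEstimate(0, float("nan"), float("nan"), 0, False,
                                            ("no signal",))
        ests = [self._est(10)] * 31 + [bad]
        per_animal, _ = aggregate_counts(ests, ["a1"] * 32, ["ctrl"] * 32)
        assert per_animal.n_az.iloc[0] == 31
        assert per_animal.n_excluded.iloc[0] == 1
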