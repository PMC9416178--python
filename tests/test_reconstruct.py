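"""Wavelet level selection, approximation, extremum chain, spline."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rfbreath as rb
from rfbreath.reconstruct import Extremum


def make_extrema(values, dt=1.0):
    kinds = ["max" if i % 2 else "min" for i in range(len(values))]
    return [Extremum(time=i * dt, value=float(v), kind=k, index=i)
            for i, (v, k) in enumerate(zip(values, kinds))]


class TestSelectLevels:
    def test_reader_sampling_rate(self):
        plan = rb.select_levels(23.1674)
        assert plan.omega == (4, 5)
        assert plan.n == 5

    def test_exact_boundary(self):
        plan = rb.select_levels(9.6)
        assert plan.omega == (3, 4)
        assert plan.n == 4

    def test_low_rate(self):
        plan = rb.select_levels(2.0)
        assert plan.omega == (0, 1)
        assert plan.n == 1

    def test_too_slow_rejected(self):
        with pytest.raises(rb.InvalidSamplingRateError):
            rb.select_levels(0.5)

    def test_matches_brute_force_enumeration(self):
        # literal rule: admissible e with lo <= Fs/2**e <= hi, then
        # argmin of f(n) = Fs/2**n - 2*Frr over members with f >= 0
        rng = np.random.default_rng(42)
        for fs in rng.uniform(0.7, 100.0, 200):
            omega = [e for e in range(13) if 0.6 <= fs / 2 ** e <= 2.0]
            feasible = [e for e in omega if fs / 2 ** e - 0.6 >= 0]
            expected = min(feasible, key=lambda e: fs / 2 ** e - 0.6)
            plan = rb.select_levels(float(fs))
            assert plan.n == expected, f"Fs={fs}"
            assert plan.omega == tuple(omega)


class TestApproximation:
    def test_constant_input_scaled_constant(self):
        plan = rb.select_levels(23.1674)
        coeffs, times = rb.approximation(np.full(500, 3.0), plan)
        np.testing.assert_allclose(coeffs, 3.0 * 2 ** (plan.n / 2), rtol=1e-8)
        assert times[1] - times[0] == pytest.approx(2 ** plan.n / plan.fs)

    def test_slow_sine_survives(self):
        fs = 23.17
        plan = rb.select_levels(fs)
        t = np.arange(0, 60, 1 / fs)
        coeffs, _ = rb.approximation(np.sin(2 * np.pi * 0.25 * t), plan)
        eff_fs = fs / 2 ** plan.n
        spec = np.abs(np.fft.rfft(coeffs - coeffs.mean(), 4096))
        freqs = np.fft.rfftfreq(4096, 1 / eff_fs)
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.02)

    def test_white_noise_smoothed(self):
        plan = rb.select_levels(23.17)
        smaller = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(600)
            approx, _ = rb.approximation(x, plan, decimated=False)
            smaller += approx.var() < x.var()
        assert smaller == 20

    def test_too_short_rejected(self):
        plan = rb.select_levels(23.17)
        with pytest.raises(rb.InsufficientDataError):
            rb.approximation(np.ones(10), plan)


class TestDetectExtrema:
    def test_single_peak(self):
        ex = rb.detect_extrema([0, 1, 0], [0.0, 1.0, 2.0])
        assert len(ex) == 1
        assert ex[0].kind == "max" and ex[0].index == 1

    def test_monotone_ramp_has_none(self):
        assert rb.detect_extrema(np.arange(50), np.arange(50)) == []

    def test_sine_three_periods(self):
        t = np.arange(0, 3, 0.01)
        ex = rb.detect_extrema(np.sin(2 * np.pi * t), t)
        kinds = [e.kind for e in ex]
        assert kinds.count("max") == 3 and kinds.count("min") == 3
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_plateau_reports_first_sample(self):
        ex = rb.detect_extrema([0, 2, 2, 2, 0], np.arange(5.0))
        assert len(ex) == 1
        assert ex[0].index == 1 and ex[0].kind == "max"

    def test_too_short_is_empty(self):
        assert rb.detect_extrema([1, 2], [0, 1]) == []


class TestFilterExtrema:
    def test_full_swing_all_kept(self):
        # threshold = 0.5 * (2 - (-2)) = 2; every swing is 4
        ex = make_extrema([-2, 2, -2, 2])
        assert rb.filter_extrema(ex) == ex

    def test_small_swing_dropped(self):
        ex = make_extrema([-2, 2, -2, 2])
        runt = Extremum(time=3.5, value=0.5, kind="max", index=9)
        filtered = rb.filter_extrema(ex + [runt])
        assert runt not in filtered
        assert filtered[:4] == ex

    def test_empty(self):
        assert rb.filter_extrema([]) == []

    def test_noop_when_gaps_exceed_threshold(self):
        ex = make_extrema([-3, 3, -3.5, 2.5, -2.8, 3.2])
        assert rb.filter_extrema(ex) == ex

    def test_invalid_alpha(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.filter_extrema(make_extrema([0, 1]), alpha=0.0)


class TestDifferenceAndAlternation:
    def test_alternating_unchanged(self):
        D = rb.difference(make_extrema([2, -2, 2]))
        np.testing.assert_allclose(D.d, [-4, 4])
        out = rb.enforce_alternation(D)
        assert out.extrema == D.extrema

    def test_same_sign_pair_drops_middle(self):
        D = rb.difference(make_extrema([0, 3, 5]))
        np.testing.assert_allclose(D.d, [3, 2])
        out = rb.enforce_alternation(D)
        assert [e.value for e in out.extrema] == [0, 5]
        np.testing.assert_allclose(out.d, [5])

    def test_single_extremum_empty_differences(self):
        D = rb.difference(make_extrema([1.0]))
        assert D.L == 0 and D.d.size == 0
        assert rb.enforce_alternation(D).L == 0

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=0, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_alternation_invariant_holds(self, values):
        out = rb.enforce_alternation(rb.difference(make_extrema(values)))
        d = out.d
        signs = np.sign(d)
        assert all(signs[i] * signs[i + 1] == -1 for i in range(len(d) - 1))


class TestSplineWaveform:
    def test_two_knots_is_straight_line(self):
        t, y = rb.spline_waveform(make_extrema([1.0, 3.0], dt=2.0), fs_out=10.0)
        np.testing.assert_allclose(y, 1.0 + t, atol=1e-9)

    def test_passes_through_knots(self):
        ex = make_extrema([-1, 2, -3, 4, -2], dt=1.7)
        t, y = rb.spline_waveform(ex, fs_out=10.0)
        from scipy.interpolate import CubicSpline
        cs = CubicSpline([e.time for e in ex], [e.value for e in ex],
                         bc_type="natural")
        for e in ex:
            assert cs(e.time) == pytest.approx(e.value, abs=1e-9)

    def test_reconstructs_sine_from_its_extremes(self):
        fr = 0.25
        n_half = 10
        times = (2 * np.arange(n_half) + 1) / (4 * fr)  # extremum times of the sine
        values = np.sin(2 * np.pi * fr * times)
        ex = [Extremum(time=float(t), value=float(v),
                       kind="max" if v > 0 else "min", index=i)
              for i, (t, v) in enumerate(zip(times, values))]
        t, y = rb.spline_waveform(ex, fs_out=20.0)
        truth = np.sin(2 * np.pi * fr * t)
        r = np.corrcoef(y, truth)[0, 1]
        assert r > 0.95

    def test_single_knot_rejected(self):
        with pytest.raises(rb.InsufficientDataError):
            rb.spline_waveform(make_extrema([1.0]))


def test_breath_cycle_count_matches_truth(chest_epc):
    """End to end: reconstructed maxima count ~ true rate x duration."""
    from conftest import make_single_tag_scenario
    for seed in range(3):
        fr, duration = 0.25, 60.0
        sc = make_single_tag_scenario(fr, seed=seed, noise_sigma=0.05)
        streams, _ = rb.simulate_streams(sc, duration)
        rep = rb.analyze_tag(streams[chest_epc])
        n_max = sum(1 for e in rep.diffs.extrema if e.kind == "max")
        assert abs(n_max - fr * duration) <= 1
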