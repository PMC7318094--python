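import numpy as np
import pytest

from neofba.bursts import (
    BurstSet,
    average_burst_shape,
    burst_feature_vector,
    detect_bursts,
    envelope,
    shape_asymmetry,
    shape_sharpness,
)
from neofba.registry import feature_names

FS = 256.0


def brute_force_bursts(env, fs, thr, min_s, gap_s):
    """Independent oracle: per-sample scan with merge and min-duration logic."""
    runs = []
    in_run = False
    for i, v in enumerate(env):
        if v > thr and not in_run:
            start, in_run = i, True
        elif v <= thr and in_run:
            runs.append([start, i])
            in_run = False
    if in_run:
        runs.append([start, len(env)])
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < gap_s * fs:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    return [(s, e) for s, e in merged if e - s >= min_s * fs]


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        assert np.allclose(envelope(np.zeros(1000), FS), 0.0)

    def test_pure_tone_envelope_matches_amplitude(self):
        t = np.arange(int(20 * FS)) / FS
        env = envelope(30.0 * np.sin(2 * np.pi * 10 * t), FS)
        core = env[int(2 * FS): -int(2 * FS)]
        assert np.all(np.abs(core - 30.0) < 0.05 * 30.0)

    def test_am_tone_envelope_tracks_modulator(self):
        t = np.arange(int(30 * FS)) / FS
        mod = 10.0 + 8.0 * np.sin(2 * np.pi * 0.3 * t)
        env = envelope(mod * np.sin(2 * np.pi * 8 * t), FS)
        core = slice(int(2 * FS), -int(2 * FS))
        rho = np.corrcoef(env[core], mod[core])[0, 1]
        assert rho > 0.95


class TestDetectBursts:
    def test_single_rectangular_burst(self):
        env = np.zeros(int(40 * FS))
        env[int(10 * FS): int(20 * FS)] = 10.0
        bs = detect_bursts(env, FS, threshold_uv=1.5, min_burst_s=0.5, merge_gap_s=0.2)
        assert len(bs.bursts) == 1
        b = bs.bursts[0]
        assert b.onset_s == pytest.approx(10.0, abs=1 / FS)
        assert b.duration_s == pytest.approx(10.0, abs=2 / FS)
        assert b.peak_uv == 10.0
        assert b.area_uv_s == pytest.approx(100.0, rel=0.01)

    def test_short_gap_merged(self):
        env = np.zeros(int(10 * FS))
        env[int(2 * FS): int(4 * FS)] = 10.0
        env[int(4 * FS) + 5: int(6 * FS)] = 10.0  # 0.02 s gap
        bs = detect_bursts(env, FS, threshold_uv=1.5, min_burst_s=0.5, merge_gap_s=0.05)
        assert len(bs.bursts) == 1

    def test_all_subthreshold_empty(self):
        bs = detect_bursts(np.ones(1000), FS, threshold_uv=5.0)
        assert bs.bursts == []

    def test_brute_force_oracle_agreement(self):
        """Exact boundary agreement with a per-sample scan on random envelopes."""
        rng = np.random.default_rng(1234)
        for _ in range(300):
            n = int(rng.integers(200, 2000))
            env = rng.gamma(1.0, 8.0, n)
            thr = float(rng.uniform(2, 25))
            min_s = float(rng.uniform(0.0, 1.0))
            gap_s = float(rng.uniform(0.0, 0.5))
            bs = detect_bursts(env, FS, thr, min_s, gap_s)
            oracle = brute_force_bursts(env, FS, thr, min_s, gap_s)
            got = [(int(round(b.onset_s * FS)),
                    int(round(b.onset_s * FS)) + int(round(b.duration_s * FS)))
                   for b in bs.bursts]
            assert got == oracle

    def test_bursts_ordered_and_disjoint(self):
        rng = np.random.default_rng(5)
        env = rng.gamma(1.0, 10.0, 5000)
        bs = detect_bursts(env, FS, 10.0)
        ends = [b.onset_s + b.duration_s for b in bs.bursts]
        for b_next, end_prev in zip(bs.bursts[1:], ends):
            assert b_next.onset_s >= end_prev

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        env = rng.gamma(1.5, 10.0, 4000)
        c = 3.0
        b1 = detect_bursts(env, FS, 12.0)
        b2 = detect_bursts(c * env, FS, c * 12.0)
        np.testing.assert_allclose(b2.durations, b1.durations)
        np.testing.assert_allclose(b2.onsets, b1.onsets)
        np.testing.assert_allclose(b2.peaks, c * b1.peaks, rtol=1e-12)
        np.testing.assert_allclose(b2.areas, c * b1.areas, rtol=1e-12)


def triangle(L=100, peak=0.5):
    u = np.linspace(0, 1, L)
    return np.where(u < peak, u / max(peak, 1e-12),
                    (1 - u) / max(1 - peak, 1e-12))


class TestAverageShape:
    def bs_from_segments(self, segments, fs=FS):
        env = np.zeros(10)
        bursts = []
        t = 0.0
        chunks = []
        for seg in segments:
            gap = np.zeros(int(2 * fs))
            chunks.extend([gap, np.asarray(seg)])
            t += len(gap) / fs
            from neofba.bursts import Burst

            bursts.append(Burst(onset_s=t, duration_s=len(seg) / fs,
                                peak_uv=float(np.max(seg)),
                                area_uv_s=float(np.sum(seg) / fs)))
            t += len(seg) / fs
        env = np.concatenate(chunks + [np.zeros(int(fs))])
        return BurstSet(bursts, fs, env)

    def test_single_triangular_burst_identity(self):
        tri = 20.0 * triangle(L=512)
        bs = self.bs_from_segments([tri])
        shape = average_burst_shape(bs, L=100)
        np.testing.assert_allclose(shape, triangle(L=100), atol=0.02)
        assert shape.max() == pytest.approx(1.0)

    def test_identical_bursts_average_to_one(self):
        tri = 20.0 * triangle(L=512, peak=0.3)
        one = average_burst_shape(self.bs_from_segments([tri]), L=100)
        many = average_burst_shape(self.bs_from_segments([tri] * 5), L=100)
        np.testing.assert_allclose(many, one, atol=1e-12)

    def test_mirror_mixture_is_symmetric(self):
        seg = 20.0 * triangle(L=512, peak=0.2)
        bs = self.bs_from_segments([seg, seg[::-1]])
        shape = average_burst_shape(bs, L=100)
        assert abs(shape_asymmetry(shape)) < 1e-12

    def test_no_bursts_returns_none(self):
        bs = BurstSet([], FS, np.zeros(1000))
        assert average_burst_shape(bs) is None


class TestAsymmetry:
    def test_symmetric_triangle_zero(self):
        assert abs(shape_asymmetry(triangle())) < 1e-12

    def test_pure_decay_is_minus_one_third(self):
        u = np.linspace(0, 1, 100)
        assert shape_asymmetry(1 - u) == pytest.approx(-1 / 3, abs=1e-6)

    def test_time_reversal_negates(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.uniform(0.05, 1.0, 100)
            s /= s.max()
            assert shape_asymmetry(s[::-1]) == pytest.approx(-shape_asymmetry(s), abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = rng.uniform(0.0, 1.0, 100) + 1e-6
            assert -1 < shape_asymmetry(s) < 1

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            shape_asymmetry(np.zeros(100))


class TestSharpness:
    def test_triangle_positive_and_slope_determined(self):
        L = 101
        s = triangle(L=L, peak=0.5)
        # interior peak: second difference is -(rise+fall slope)*h
        h = 1 / (L - 1)
        expect = (1 / 0.5 + 1 / 0.5) * h / h**2
        assert shape_sharpness(s) == pytest.approx(expect, rel=0.01)
        assert shape_sharpness(s) > 0

    def test_plateau_zero(self):
        u = np.linspace(0, 1, 100)
        s = np.minimum(1.0, np.where(u < 0.3, u / 0.3, np.where(u > 0.7, (1 - u) / 0.3, 1.0)))
        assert shape_sharpness(s) == pytest.approx(0.0, abs=1e-9)

    def test_scaling_linearity(self):
        s = triangle(L=100, peak=0.4)
        assert shape_sharpness(3.0 * s) == pytest.approx(3.0 * shape_sharpness(s))


class TestBurstFeatures:
    def test_periodic_bursts_rate_and_fraction(self):
        fs = FS
        period, dur = 5.0, 1.0
        n = int(600 * fs)
        env = np.zeros(n)
        t0 = 0
        while t0 + dur * fs <= n:
            env[int(t0): int(t0 + dur * fs)] = 30.0
            t0 += period * fs
        bs = detect_bursts(env, fs, threshold_uv=1.5, min_burst_s=0.5, merge_gap_s=0.1)
        feats = burst_feature_vector(bs)
        assert feats["burst.rate_per_min"] == pytest.approx(12.0, rel=0.02)
        assert feats["burst.time_in_burst_frac"] == pytest.approx(0.2, rel=0.02)
        assert feats["burst.ibi_median_s"] == pytest.approx(4.0, abs=0.05)

    def test_power_law_slope_recovery(self):
        rng = np.random.default_rng(77)
        # durations from a Pareto with CCDF exponent -1.5
        durs = 0.5 * (1 + rng.pareto(1.5, 5000))
        from neofba.bursts import Burst

        bursts = [Burst(onset_s=float(10 * i), duration_s=float(d),
                        peak_uv=10.0, area_uv_s=float(10 * d)) for i, d in enumerate(durs)]
        bs = BurstSet(bursts, FS, np.zeros(100))
        feats = burst_feature_vector(bs)
        assert feats["burst.duration_ccdf_slope"] == pytest.approx(-1.5, abs=0.1)

    def test_area_duration_exponent_exact_square(self):
        from neofba.bursts import Burst

        rng = np.random.default_rng(8)
        durs = rng.uniform(0.5, 8.0, 200)
        bursts = [Burst(onset_s=float(20 * i), duration_s=float(d),
                        peak_uv=1.0, area_uv_s=float(d**2)) for i, d in enumerate(durs)]
        bs = BurstSet(bursts, FS, np.zeros(100))
        feats = burst_feature_vector(bs)
        assert feats["burst.area_duration_exponent"] == pytest.approx(2.0, abs=1e-9)

    def test_exactly_forty_named_features(self):
        rng = np.random.default_rng(4)
        env = rng.gamma(1.5, 12.0, int(120 * FS))
        feats = burst_feature_vector(detect_bursts(env, FS, 15.0))
        assert sorted(feats) == sorted(feature_names("burst"))
        assert len(feats) == 40

    def test_amplitude_scale_equivariance_of_features(self):
        rng = np.random.default_rng(10)
        # structured envelope: quiet background with irregular bursts
        n = int(300 * FS)
        env = np.full(n, 5.0)
        t = 0
        while t < n - int(3 * FS):
            dur = int(rng.uniform(0.6, 3.0) * FS)
            amp = rng.uniform(25.0, 80.0)
            env[t: t + dur] += amp * np.sin(np.linspace(0, np.pi, dur))
            t += dur + int(rng.uniform(2.0, 10.0) * FS)
        c = 2.5
        f1 = burst_feature_vector(detect_bursts(env, FS, 15.0))
        f2 = burst_feature_vector(detect_bursts(c * env, FS, c * 15.0))
        assert f2["burst.rate_per_min"] == f1["burst.rate_per_min"]
        assert f2["burst.ibi_median_s"] == f1["burst.ibi_median_s"]
        assert f2["burst.shape_asymmetry"] == pytest.approx(f1["burst.shape_asymmetry"], abs=1e-12)
        assert f2["burst.peak_p50_uv"] == pytest.approx(c * f1["burst.peak_p50_uv"])
        assert f2["burst.log_area_mean"] == pytest.approx(f1["burst.log_area_mean"] + np.log10(c))
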