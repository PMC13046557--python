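"""Summary metrics: totals, peaks, Poincaré descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glossography import (
    AnalysisConfig,
    MotionParams,
    detect_peaks,
    glossography_summary,
    implied_std,
    path_length,
    poincare,
    simulate_session,
    summarize_series,
)
from oracles import enumerate_peaks, poincare_pairs

# reference (SD1, SD2, Std) triples reported for a 4-day clinical recording
CLINICAL_TRIPLES = [
    (5.85, 80.55, 57.15),
    (1.13, 41.54, 29.40),
    (0.61, 18.87, 13.36),
    (0.46, 6.49, 4.61),
]


class TestSummarizeSeries:
    def test_hand_arithmetic(self):
        total, rng_, mean, std = summarize_series([1.0, 2.0, 3.0])
        assert total == 6.0 and rng_ == 2.0 and mean == 2.0
        assert std == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_series(self):
        total, rng_, mean, std = summarize_series(np.full(50, 3.5))
        assert total == pytest.approx(3.5 * 50)
        assert rng_ == 0.0 and std == 0.0

    def test_homogeneity_and_mean_total_identity(self, rng):
        s = rng.normal(5.0, 2.0, 400)
        base = summarize_series(s)
        scaled = summarize_series(10.0 * s)
        for a, b in zip(scaled, base):
            assert a == pytest.approx(10.0 * b)
        assert base.mean * len(s) == pytest.approx(base.total, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            summarize_series([1.0])


class TestDetectPeaks:
    def test_two_simple_peaks(self):
        ps = detect_peaks([0, 1, 0, 2, 0], min_prominence=0.5, min_distance=1)
        assert ps.indices.tolist() == [1, 3]

    def test_monotone_ramp_has_no_peaks(self):
        assert detect_peaks(np.arange(20.0), 0.0, 1).count == 0

    def test_distance_suppression_keeps_higher_peak(self):
        ps = detect_peaks([0, 1, 0, 2, 0], min_prominence=0.0, min_distance=3)
        assert ps.indices.tolist() == [3]

    def test_matches_enumeration_oracle_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(8, 30))
            s = np.cumsum(rng.normal(0, 1, n))
            for _ in range(int(rng.integers(0, 3))):  # inject plateaus
                i = int(rng.integers(1, n - 1))
                s[i] = s[i - 1]
            prom = float(rng.choice([0.0, 0.3, 1.0, 2.0]))
            dist = int(rng.choice([1, 2, 3, 5]))
            got = detect_peaks(s, prom, dist).indices.tolist()
            assert got == enumerate_peaks(s, prom, dist)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50), min_size=8, max_size=40),
        st.sampled_from([0.0, 1.0, 2.0, 5.0]),
        st.integers(-200, 200),
    )
    def test_offset_invariance_of_prominence(self, values, prom, offset):
        # integer-valued series and offsets keep the arithmetic exact,
        # so the mathematical invariance is testable bitwise
        s = np.asarray(values, dtype=float)
        a = detect_peaks(s, prom, 2).indices
        b = detect_peaks(s + offset, prom, 2).indices
        np.testing.assert_array_equal(a, b)

    def test_count_monotone_in_thresholds(self, rng):
        s = np.cumsum(rng.normal(0, 1, 500))
        counts_prom = [detect_peaks(s, p, 1).count for p in [0.0, 0.5, 1.0, 2.0, 4.0]]
        assert counts_prom == sorted(counts_prom, reverse=True)
        counts_dist = [detect_peaks(s, 0.0, d).count for d in [1, 2, 4, 8, 16]]
        assert counts_dist == sorted(counts_dist, reverse=True)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            detect_peaks([0, 1, 0], -1.0, 1)
        with pytest.raises(ValueError):
            detect_peaks([0, 1, 0], 0.0, 0)


class TestPoincare:
    def test_constant_series(self):
        pc = poincare(np.full(20, 7.0))
        assert pc.sd1 == 0.0 and pc.sd2 == 0.0

    def test_alternating_series_closed_form(self):
        # odd length -> the n-1 successive differences are a balanced set
        # of ±2 (mean 0, std 2), so sd1 = 2/sqrt2; sums are all 0 -> sd2 = 0
        s = np.concatenate([np.tile([1.0, -1.0], 10), [1.0]])
        pc = poincare(s, lag=1)
        assert pc.sd1 == pytest.approx(np.sqrt(2.0))
        assert pc.sd2 == pytest.approx(0.0, abs=1e-12)

    def test_ramp_against_pair_enumeration(self):
        s = np.array([0.0, 1.0, 2.0, 3.0])
        pc = poincare(s, lag=1)
        sd1, sd2 = poincare_pairs(s, lag=1)
        assert pc.sd1 == pytest.approx(sd1, abs=1e-12)
        assert pc.sd2 == pytest.approx(sd2, abs=1e-12)
        assert pc.sd1 == pytest.approx(0.0, abs=1e-12)
        assert pc.sd2 == pytest.approx(np.sqrt(2) * np.std([0.5, 1.5, 2.5]))

    def test_random_series_against_pair_enumeration(self, rng):
        s = rng.normal(0, 3, 60)
        for lag in (1, 2, 5):
            pc = poincare(s, lag=lag)
            sd1, sd2 = poincare_pairs(s, lag=lag)
            assert pc.sd1 == pytest.approx(sd1, abs=1e-10)
            assert pc.sd2 == pytest.approx(sd2, abs=1e-10)

    def test_identity_with_variance_on_long_series(self, rng):
        s = rng.normal(10, 4, 2000)
        pc = poincare(s)
        assert pc.sd1**2 + pc.sd2**2 == pytest.approx(2 * s.var(), rel=0.01)

    def test_too_short(self):
        with pytest.raises(ValueError):
            poincare([1.0, 2.0], lag=1)


class TestImpliedStd:
    @pytest.mark.parametrize("sd1, sd2, std", CLINICAL_TRIPLES)
    def test_reproduces_reported_std(self, sd1, sd2, std):
        assert implied_std(sd1, sd2) == pytest.approx(std, rel=0.005)

    def test_zero(self):
        assert implied_std(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            implied_std(-1.0, 1.0)

    def test_consistent_with_poincare_on_data(self, rng):
        s = rng.normal(0, 2, 5000)
        pc = poincare(s)
        assert implied_std(pc.sd1, pc.sd2) == pytest.approx(s.std(), rel=0.01)


def test_path_length_of_unit_square():
    assert path_length([0, 1, 1, 0], [0, 0, 1, 1]) == pytest.approx(3.0)


class TestGlossographySummary:
    def test_static_face_all_zero(self, static_session):
        tongue, face = glossography_summary(static_session)
        for block in (tongue, face):
            assert block.total == 0.0
            assert block.range == 0.0
            assert block.std == 0.0
        assert tongue.peaks == 0
        assert tongue.sd1 == 0.0 and tongue.sd2 == 0.0
        assert tongue.n_frames == 100

    def test_recovers_injected_burst_count(self):
        params = MotionParams(
            seed=11, jitter_sd=1.0, burst_amp=50.0, drift_amp=0.0,
            dropout_prob=0.0, burst_times_s=[3.0, 9.0, 15.0, 21.0, 27.0],
        )
        session, truth = simulate_session(params, label="d")
        tongue, _ = glossography_summary(session)
        assert tongue.peaks == truth.n_bursts == 5

    def test_total_and_range_scale_with_burst_amplitude(self):
        # noise-free so the series is exactly the burst envelope
        base = dict(seed=5, jitter_sd=0.0, drift_amp=0.0, dropout_prob=0.0,
                    burst_times_s=[5.0, 15.0, 25.0])
        s1, _ = simulate_session(MotionParams(burst_amp=20.0, **base))
        s2, _ = simulate_session(MotionParams(burst_amp=40.0, **base))
        t1, _ = glossography_summary(s1)
        t2, _ = glossography_summary(s2)
        assert t2.total == pytest.approx(2 * t1.total, rel=1e-9)
        assert t2.range == pytest.approx(2 * t1.range, rel=1e-9)

    def test_per_second_total_normalises_duration(self):
        base = dict(seed=4, jitter_sd=0.0, drift_amp=0.0, dropout_prob=0.0,
                    burst_rate=0.0)
        s_short, _ = simulate_session(MotionParams(duration_s=10.0, **base))
        s_long, _ = simulate_session(MotionParams(duration_s=30.0, **base))
        t_short, _ = glossography_summary(s_short)
        t_long, _ = glossography_summary(s_long)
        assert t_short.per_second_total == pytest.approx(
            t_short.total / 10.0
        )
        assert t_long.per_second_total == pytest.approx(t_long.total / 30.0)

    def test_missing_reference_rejected(self, static_session):
        cfg = AnalysisConfig(landmarks=["nose", "ear"], reference="ear")
        with pytest.raises(ValueError):
            glossography_summary(static_session, cfg)
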