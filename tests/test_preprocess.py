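"""Baseline estimation, heartbeat segmentation, and RR-interval features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scalobeat.preprocess import (
    PRE_SAMPLES,
    SEGMENT_LENGTH,
    SignalTooShortError,
    build_heartbeats,
    compute_rr_features,
    estimate_baseline,
    remove_baseline,
    segment_heartbeats,
)
from scalobeat.records import BeatAnnotation, ECGRecord

FS = 360.0


def _sliding_median_oracle(signal, width):
    """Brute-force reference: median over a symmetric-padded window."""
    half = width // 2
    padded = np.pad(signal, half, mode="symmetric")
    return np.array(
        [np.median(padded[i : i + width]) for i in range(signal.size)]
    )


def _cascade_oracle(signal):
    return _sliding_median_oracle(_sliding_median_oracle(signal, 71), 215)


@settings(max_examples=10, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(220, 800))
def test_baseline_matches_bruteforce_median_cascade(seed, n):
    signal = np.random.default_rng(seed).standard_normal(n)
    np.testing.assert_array_equal(
        estimate_baseline(signal, FS), _cascade_oracle(signal)
    )


def test_baseline_of_constant_is_constant():
    signal = np.full(1000, 3.25)
    np.testing.assert_array_equal(estimate_baseline(signal, FS), signal)
    np.testing.assert_array_equal(remove_baseline(signal, FS), np.zeros(1000))


def test_baseline_tracks_slow_sinusoid_and_rejects_spikes():
    t = np.arange(3600) / FS
    wander = 0.5 * np.sin(2 * np.pi * 0.3 * t)
    signal = wander.copy()
    signal[::300] += 2.0  # narrow spikes, QRS-like outliers
    baseline = estimate_baseline(signal, FS)
    # reflect padding distorts the ends; judge tracking away from them
    interior = slice(108, -108)
    assert np.max(np.abs(baseline - wander)[interior]) < 0.05
    np.testing.assert_array_equal(baseline, _cascade_oracle(signal))


def test_baseline_output_length_equals_input_length():
    for n in (215, 216, 1000):
        assert estimate_baseline(np.random.default_rng(n).standard_normal(n), FS).size == n


def test_removal_is_invariant_to_dc_offset():
    rng = np.random.default_rng(0)
    signal = rng.standard_normal(800)
    np.testing.assert_allclose(
        remove_baseline(signal + 0.5, FS), remove_baseline(signal, FS), atol=1e-12
    )


def test_zero_signal_stays_zero():
    np.testing.assert_array_equal(remove_baseline(np.zeros(500), FS), np.zeros(500))


def test_too_short_signal_raises():
    with pytest.raises(SignalTooShortError):
        estimate_baseline(np.zeros(100), FS)  # < 215-sample window


def _ann(idx):
    return BeatAnnotation(idx, "N", "N")


def test_segment_window_alignment_and_boundaries():
    signal = np.arange(200, dtype=float)
    kept, dropped = segment_heartbeats(signal, [_ann(90)])
    assert dropped == 0 and len(kept) == 1
    seg = kept[0][1]
    assert seg.shape == (SEGMENT_LENGTH,)
    np.testing.assert_array_equal(seg, signal)  # offsets 0..199 exactly

    _, dropped = segment_heartbeats(signal, [_ann(89)])  # window starts at -1
    assert dropped == 1
    _, dropped = segment_heartbeats(signal, [_ann(91)])  # window ends at 201
    assert dropped == 1


def test_segment_r_peak_lands_at_offset_90():
    rng = np.random.default_rng(1)
    signal = rng.standard_normal(650000)
    kept, _ = segment_heartbeats(signal, [_ann(5000)])
    assert kept[0][1][PRE_SAMPLES] == signal[5000]


def test_segment_count_conservation():
    signal = np.zeros(2000)
    beats = [_ann(i) for i in (10, 90, 500, 1000, 1950)]
    kept, dropped = segment_heartbeats(signal, beats)
    assert len(kept) + dropped == len(beats)


def test_rr_features_of_perfectly_regular_rhythm_are_null():
    r = np.arange(20) * 288  # RR = 0.8 s at 360 Hz
    feats = compute_rr_features(r, FS, 10)
    np.testing.assert_allclose(feats[[0, 1, 3]], 0.0, atol=1e-12)
    assert feats[2] == pytest.approx(1.0)


def test_rr_features_hand_computed_example():
    # R at samples 3600, 3888, 4320: intervals 288 and 432 samples
    r = np.array([3600, 3888, 4320])
    feats = compute_rr_features(r, FS, 1, mean_rr=0.0)  # raw, unadjusted
    assert feats[0] == pytest.approx(0.8)
    assert feats[1] == pytest.approx(1.2)
    assert feats[2] == pytest.approx(0.8 / 1.2)


def test_rr_ratio_uses_raw_intervals_even_after_adjustment():
    r = np.array([0, 288, 432, 720, 1008])
    adjusted = compute_rr_features(r, FS, 1)
    raw = compute_rr_features(r, FS, 1, mean_rr=0.0)
    assert adjusted[2] == raw[2]  # ratio-RR is never mean-adjusted


def test_rr_duplicate_r_indices_raise():
    with pytest.raises(ValueError, match="non-increasing"):
        compute_rr_features(np.array([0, 100, 100, 300]), FS, 2)


def test_first_and_last_beats_are_rejected():
    r = np.array([0, 100, 200])
    for pos in (0, 2):
        with pytest.raises(ValueError):
            compute_rr_features(r, FS, pos)


def test_local_rr_uses_up_to_ten_preceding_intervals():
    rng = np.random.default_rng(3)
    r = np.cumsum(rng.integers(250, 400, size=30))
    intervals = np.diff(r) / FS
    feats = compute_rr_features(r, FS, 15, mean_rr=0.0)
    assert feats[3] == pytest.approx(intervals[5:15].mean())
    # early beat: fewer than ten intervals exist, use what is there
    feats = compute_rr_features(r, FS, 3, mean_rr=0.0)
    assert feats[3] == pytest.approx(intervals[:3].mean())


def test_mean_adjustment_recovers_record_average_rr():
    rng = np.random.default_rng(4)
    r = np.cumsum(rng.integers(250, 400, size=50))
    intervals = np.diff(r) / FS
    mean_rr = intervals.mean()
    raw_prev = np.array(
        [compute_rr_features(r, FS, i, mean_rr=0.0)[0] for i in range(1, 49)]
    )
    adj_prev = np.array(
        [compute_rr_features(r, FS, i)[0] for i in range(1, 49)]
    )
    assert raw_prev.mean() - adj_prev.mean() == pytest.approx(mean_rr)


def test_build_heartbeats_conservation_and_labels(short_record):
    record, annotations = short_record
    heartbeats, log = build_heartbeats(record, annotations)
    assert log.n_kept + log.n_boundary_dropped + log.n_edge_dropped == log.n_input
    assert log.n_kept == len(heartbeats)
    assert log.n_edge_dropped >= 2  # first and last beat always go
    for hb in heartbeats:
        assert hb.segment.shape == (SEGMENT_LENGTH,)
        assert np.all(np.isfinite(hb.rr_features))
        assert hb.rr_features[2] > 0
        assert hb.label in {"N", "SVEB", "VEB", "F"}


def test_build_heartbeats_on_too_few_beats():
    record = ECGRecord("x", np.zeros(1000), FS)
    beats, log = build_heartbeats(record, [_ann(500)])
    assert beats == [] and log.n_edge_dropped == 1
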