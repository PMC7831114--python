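"""Baseline-wander removal, heartbeat segmentation, and RR-interval features.

Baseline wander (respiration/movement drift, < ~0.5 Hz) is estimated by a
cascade of two median filters — 200 ms then 600 ms wide — and subtracted
from the raw signal. Median filtering tracks the slow baseline while
rejecting the QRS complexes as outliers, without the phase distortion of
IIR/FIR high-pass filters.

Each annotated beat is cut to a fixed 200-sample window, 90 samples before
through 110 samples after the R peak (at 360 Hz: 250 ms before, 306 ms
after), which spans the P-QRS-T complex. Four RR-interval features
accompany each segment: previous-RR, post-RR, their ratio, and local-RR
(mean of up to ten preceding intervals); previous-, post- and local-RR have
the record-average RR subtracted to cancel inter-patient heart-rate
differences (ratio-RR is already dimensionless and left raw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .records import BeatAnnotation, ECGRecord

__all__ = [
    "Heartbeat",
    "SegmentationLog",
    "SignalTooShortError",
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "estimate_baseline",
    "remove_baseline",
    "segment_heartbeats",
    "compute_rr_features",
    "build_heartbeats",
]

PRE_SAMPLES = 90
POST_SAMPLES = 110
SEGMENT_LENGTH = PRE_SAMPLES + POST_SAMPLES

BASELINE_WINDOWS_MS = (200.0, 600.0)
LOCAL_RR_COUNT = 10


class SignalTooShortError(ValueError):
    """Signal shorter than the largest median-filter window."""


@dataclass
class Heartbeat:
    """One segmented beat: waveform window, RR features, class label."""

    segment: np.ndarray  # 200 samples, mV, R peak at offset 90
    rr_features: np.ndarray  # (previous, post, ratio, local), seconds
    label: str  # AAMI class
    source_record: str
    r_index: int


@dataclass
class SegmentationLog:
    """Beat bookkeeping for one record."""

    record_id: str
    n_input: int = 0
    n_kept: int = 0
    n_boundary_dropped: int = 0  # window ran off the signal ends
    n_edge_dropped: int = 0  # first/last beat: RR neighbour missing
    per_class: dict[str, int] = field(default_factory=dict)


def _median_window(width_ms: float, fs: float) -> int:
    """Window width in samples, forced odd for an unambiguous median."""
    w = int(round(width_ms * fs / 1000.0))
    if w % 2 == 0:
        w -= 1
    return max(w, 1)


def estimate_baseline(signal: np.ndarray, fs: float) -> np.ndarray:
    """Baseline estimate: 200 ms median filter, then 600 ms on its output.

    Reflect padding keeps the output the same length as the input without
    biasing the ends toward zero.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if fs <= 0:
        raise ValueError("fs must be positive")
    windows = [_median_window(ms, fs) for ms in BASELINE_WINDOWS_MS]
    if signal.size < max(windows):
        raise SignalTooShortError(
            f"signal of {signal.size} samples is shorter than the "
            f"{max(windows)}-sample median window"
        )
    out = signal
    for w in windows:
        out = median_filter(out, size=w, mode="reflect")
    return out


def remove_baseline(signal: np.ndarray, fs: float) -> np.ndarray:
    """Baseline-corrected signal: input minus its median-cascade baseline."""
    signal = np.asarray(signal, dtype=np.float64)
    return signal - estimate_baseline(signal, fs)


def segment_heartbeats(
    signal: np.ndarray, beats: list[BeatAnnotation]
) -> tuple[list[tuple[BeatAnnotation, np.ndarray]], int]:
    """Cut the fixed window around each R peak.

    Returns ``(kept, n_dropped)`` where kept pairs each surviving beat with
    its 200-sample segment (``segment[90]`` is the annotated R sample).
    Beats whose window would cross the signal boundary are dropped, not
    errors.
    """
    signal = np.asarray(signal, dtype=np.float64)
    kept: list[tuple[BeatAnnotation, np.ndarray]] = []
    dropped = 0
    for beat in beats:
        lo = beat.sample_index - PRE_SAMPLES
        hi = beat.sample_index + POST_SAMPLES
        if lo < 0 or hi > signal.size:
            dropped += 1
            continue
        kept.append((beat, signal[lo:hi].copy()))
    return kept, dropped


def compute_rr_features(
    r_indices: np.ndarray,
    fs: float,
    beat_position: int,
    *,
    mean_rr: float | None = None,
) -> np.ndarray:
    """RR features for the beat at ``beat_position`` in a record's R series.

    previous-RR and post-RR are the intervals to the neighbouring beats;
    ratio-RR = previous/post (raw); local-RR is the mean of up to ten
    preceding intervals. previous-, post- and local-RR then have the
    record-average interval subtracted. The first and last beats of a record
    have no neighbour and are rejected.
    """
    r = np.asarray(r_indices, dtype=np.int64)
    if r.size < 2:
        raise ValueError("need at least two beats to form RR intervals")
    if not (0 < beat_position < r.size - 1):
        raise ValueError(
            f"beat {beat_position} has no RR neighbour (record ends)"
        )
    intervals = np.diff(r) / fs  # intervals[i] = RR ending at beat i+1
    if np.any(intervals <= 0):
        bad = int(np.flatnonzero(intervals <= 0)[0])
        raise ValueError(
            f"non-increasing R indices at beats {bad}..{bad + 1} "
            f"(samples {r[bad]}, {r[bad + 1]})"
        )
    if mean_rr is None:
        mean_rr = float(intervals.mean())
    prev_rr = intervals[beat_position - 1]
    post_rr = intervals[beat_position]
    ratio_rr = prev_rr / post_rr
    lo = max(0, beat_position - LOCAL_RR_COUNT)
    local_rr = float(intervals[lo:beat_position].mean())
    return np.array(
        [prev_rr - mean_rr, post_rr - mean_rr, ratio_rr, local_rr - mean_rr]
    )


def build_heartbeats(
    record: ECGRecord, beats: list[BeatAnnotation]
) -> tuple[list[Heartbeat], SegmentationLog]:
    """Full per-record preprocessing: correct baseline, segment, attach RR.

    RR intervals are computed over the complete (Q-filtered) beat sequence
    before any segmentation drop, so a beat lost to a boundary window still
    contributes its intervals to its neighbours.
    """
    log = SegmentationLog(record.record_id, n_input=len(beats))
    if len(beats) < 2:
        log.n_edge_dropped = len(beats)
        return [], log
    corrected = remove_baseline(record.signal, record.fs)
    r_indices = np.array([b.sample_index for b in beats], dtype=np.int64)
    mean_rr = float(np.mean(np.diff(r_indices)) / record.fs)
    out: list[Heartbeat] = []
    for pos, beat in enumerate(beats):
        if pos == 0 or pos == len(beats) - 1:
            log.n_edge_dropped += 1
            continue
        lo = beat.sample_index - PRE_SAMPLES
        hi = beat.sample_index + POST_SAMPLES
        if lo < 0 or hi > corrected.size:
            log.n_boundary_dropped += 1
            continue
        rr = compute_rr_features(r_indices, record.fs, pos, mean_rr=mean_rr)
        out.append(
            Heartbeat(
                segment=corrected[lo:hi].copy(),
                rr_features=rr,
                label=beat.aami_class,
                source_record=record.record_id,
                r_index=beat.sample_index,
            )
        )
        log.per_class[beat.aami_class] = log.per_class.get(beat.aami_class, 0) + 1
    log.n_kept = len(out)
    return out, log
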