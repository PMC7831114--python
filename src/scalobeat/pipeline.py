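"""End-to-end glue: records -> heartbeats -> scalogram tensors -> model.

Also provides the on-disk cache used by the CLI: one ``.npz`` per record
(segments, RR features, labels, R indices), lossless and keyed by
record id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluate, model as model_mod, preprocess, wavelets
from .model import HeartbeatCNN, TrainConfig
from .preprocess import Heartbeat, SegmentationLog
from .records import BeatAnnotation, ECGRecord

__all__ = [
    "BeatTensors",
    "label_index",
    "heartbeats_to_tensors",
    "records_to_tensors",
    "save_cache",
    "load_cache",
    "run_experiment",
]

LABELS = evaluate.CLASSES  # (N, SVEB, VEB, F)
_LABEL_INDEX = {c: i for i, c in enumerate(LABELS)}


def label_index(label: str) -> int:
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise ValueError(f"label {label!r} is not one of {LABELS}") from None


@dataclass
class BeatTensors:
    """Stacked model inputs for a set of heartbeats."""

    x: np.ndarray  # (B, 1, 100, 100) scalogram images
    rr: np.ndarray  # (B, 4)
    y: np.ndarray  # (B,) integer labels
    record_ids: np.ndarray  # (B,) source record of each beat

    def __len__(self) -> int:
        return self.x.shape[0]


def heartbeats_to_tensors(
    heartbeats: list[Heartbeat],
    wavelet: str = "mexh",
    normalize: bool = True,
) -> BeatTensors:
    """Transform segmented beats into scalogram images + RR features."""
    n = len(heartbeats)
    x = np.empty((n, 1, wavelets.N_SCALES, wavelets.N_SCALES))
    rr = np.empty((n, 4))
    y = np.empty(n, dtype=np.int64)
    ids = np.empty(n, dtype=object)
    for i, hb in enumerate(heartbeats):
        x[i, 0] = wavelets.scalogram_image(
            hb.segment, wavelet=wavelet, normalize=normalize
        )
        rr[i] = hb.rr_features
        y[i] = label_index(hb.label)
        ids[i] = hb.source_record
    return BeatTensors(x, rr, y, ids.astype(str))


def records_to_tensors(
    records: list[tuple[ECGRecord, list[BeatAnnotation]]],
    wavelet: str = "mexh",
    normalize: bool = True,
) -> tuple[BeatTensors, list[SegmentationLog]]:
    """Preprocess and transform a list of (record, annotations) pairs."""
    from .records import filter_beats

    beats: list[Heartbeat] = []
    logs: list[SegmentationLog] = []
    for record, annotations in records:
        hb, log = preprocess.build_heartbeats(record, filter_beats(annotations))
        beats.extend(hb)
        logs.append(log)
    return heartbeats_to_tensors(beats, wavelet, normalize), logs


# -- per-record preprocessing cache -----------------------------------------

def save_cache(cache_dir: str | Path, record_id: str, heartbeats: list[Heartbeat]) -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{record_id}.npz"
    np.savez_compressed(
        path,
        segments=np.array([hb.segment for hb in heartbeats]),
        rr=np.array([hb.rr_features for hb in heartbeats]),
        labels=np.array([hb.label for hb in heartbeats]),
        r_indices=np.array([hb.r_index for hb in heartbeats], dtype=np.int64),
    )
    return path


def load_cache(cache_dir: str | Path, record_id: str) -> list[Heartbeat]:
    path = Path(cache_dir) / f"{record_id}.npz"
    with np.load(path, allow_pickle=False) as data:
        return [
            Heartbeat(
                segment=data["segments"][i],
                rr_features=data["rr"][i],
                label=str(data["labels"][i]),
                source_record=record_id,
                r_index=int(data["r_indices"][i]),
            )
            for i in range(data["labels"].shape[0])
        ]


def run_experiment(
    train_records: list[tuple[ECGRecord, list[BeatAnnotation]]],
    test_records: list[tuple[ECGRecord, list[BeatAnnotation]]],
    *,
    wavelet: str = "mexh",
    train_cfg: TrainConfig | None = None,
    model_seed: int = 0,
) -> dict:
    """Train on one set of patients, evaluate on disjoint patients.

    Returns a dict with the trained model, confusion matrix, metrics report,
    test accuracy, and the training log.
    """
    train_cfg = train_cfg or TrainConfig()
    train_t, train_logs = records_to_tensors(train_records, wavelet)
    test_t, test_logs = records_to_tensors(test_records, wavelet)
    overlap = set(train_t.record_ids) & set(test_t.record_ids)
    if overlap:
        raise ValueError(f"patients appear on both sides of the split: {overlap}")
    net = HeartbeatCNN(seed=model_seed)
    history = model_mod.train(net, train_t.x, train_t.rr, train_t.y, train_cfg)
    pred = model_mod.predict(net, test_t.x, test_t.rr)
    true_labels = [LABELS[i] for i in test_t.y]
    pred_labels = [LABELS[i] for i in pred]
    cm = evaluate.confusion(true_labels, pred_labels)
    report = evaluate.metrics_report(cm)
    accuracy = float((pred == test_t.y).mean())
    return {
        "model": net,
        "history": history,
        "confusion": cm,
        "report": report,
        "test_accuracy": accuracy,
        "train_size": len(train_t),
        "test_size": len(test_t),
        "segmentation_logs": train_logs + test_logs,
    }
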