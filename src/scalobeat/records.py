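"""Record loading, AAMI class mapping, and the inter-patient DS1/DS2 split.

The MIT-BIH arrhythmia database annotates beats with single-character
symbols; following the AAMI recommendation these collapse into five
super-classes (N, SVEB, VEB, F, Q). The Q (unknown/paced) class is so rare
that it is excluded from classification, as are the four paced records
102, 104, 107 and 217. Training and evaluation use the de Chazal
inter-patient partition: two disjoint 22-record sets with similar beat-type
proportions, DS1 for training and DS2 for testing, so no patient appears on
both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import wfdb_io

__all__ = [
    "AAMI_CLASSES",
    "ECGRecord",
    "BeatAnnotation",
    "DatasetSplit",
    "DataConfig",
    "PACED_RECORDS",
    "ExcludedRecordError",
    "LeadAbsentError",
    "UnknownSymbolError",
    "map_symbol_to_aami",
    "filter_beats",
    "make_split",
    "read_record",
]

AAMI_CLASSES = ("N", "SVEB", "VEB", "F", "Q")

# Beat symbol -> AAMI super-class.
SYMBOL_TO_AAMI = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "SVEB", "a": "SVEB", "J": "SVEB", "S": "SVEB",
    "V": "VEB", "E": "VEB",
    "F": "F",
    "Q": "Q", "f": "Q", "/": "Q",
}

BEAT_SYMBOLS = frozenset(SYMBOL_TO_AAMI)

PACED_RECORDS = frozenset({"102", "104", "107", "217"})

# de Chazal inter-patient partition of the 44 non-paced records.
DS1_RECORDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
DS2_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


class ExcludedRecordError(ValueError):
    """Requested record is on the exclusion list (paced beats)."""


class LeadAbsentError(ValueError):
    """The preferred lead is not present in the record."""


class UnknownSymbolError(ValueError):
    """Beat symbol has no AAMI class assignment."""


@dataclass
class ECGRecord:
    """A single-lead ECG signal in mV with its sampling rate."""

    record_id: str
    signal: np.ndarray
    fs: float
    lead_name: str = "MLII"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"record {self.record_id}: non-finite samples")


@dataclass(frozen=True)
class BeatAnnotation:
    """An annotated R peak: 0-based sample index, MIT symbol, AAMI class."""

    sample_index: int
    symbol: str
    aami_class: str


@dataclass(frozen=True)
class DatasetSplit:
    ds1_record_ids: frozenset[str]
    ds2_record_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.ds1_record_ids & self.ds2_record_ids:
            raise ValueError("DS1 and DS2 must be disjoint")
        overlap = (self.ds1_record_ids | self.ds2_record_ids) & PACED_RECORDS
        if overlap:
            raise ValueError(f"paced records in split: {sorted(overlap)}")


@dataclass
class DataConfig:
    """Where the WFDB database lives and how it is partitioned."""

    data_dir: Path = Path(".")
    ds1_records: tuple[str, ...] = DS1_RECORDS
    ds2_records: tuple[str, ...] = DS2_RECORDS
    excluded_records: frozenset[str] = PACED_RECORDS
    lead_preference: str = "MLII"


def map_symbol_to_aami(symbol: str) -> str:
    """Map an MIT-BIH beat symbol to its AAMI super-class.

    Raises :class:`UnknownSymbolError` for anything outside the beat-symbol
    table; an unknown symbol is never silently treated as normal.
    """
    try:
        return SYMBOL_TO_AAMI[symbol]
    except KeyError:
        raise UnknownSymbolError(
            f"symbol {symbol!r} has no AAMI class assignment"
        ) from None


def filter_beats(beats: list[BeatAnnotation]) -> list[BeatAnnotation]:
    """Drop Q-class (unknown/paced) beats, preserving order."""
    return [b for b in beats if b.aami_class != "Q"]


def make_split(
    ds1: tuple[str, ...] = DS1_RECORDS, ds2: tuple[str, ...] = DS2_RECORDS
) -> DatasetSplit:
    """The inter-patient train/test partition (de Chazal convention)."""
    return DatasetSplit(frozenset(ds1), frozenset(ds2))


def read_record(
    data_dir: str | Path,
    record_id: str,
    *,
    lead_preference: str = "MLII",
    excluded: frozenset[str] = PACED_RECORDS,
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Read one WFDB record and its beat annotations.

    Selects the preferred lead (ML II for MIT-BIH); raises
    :class:`LeadAbsentError` if it is missing rather than silently falling
    back to another lead. Non-beat annotations (rhythm changes, noise marks,
    aux notes) are dropped; surviving beats carry their AAMI class.
    """
    if record_id in excluded:
        raise ExcludedRecordError(
            f"record {record_id} is excluded (paced beats)"
        )
    record_path = Path(data_dir) / record_id
    try:
        header, physical = wfdb_io.read_signals(record_path)
    except wfdb_io.WfdbError as exc:
        raise wfdb_io.WfdbError(f"record {record_id}: {exc}") from exc
    descriptions = [sig.description for sig in header.signals]
    try:
        channel = descriptions.index(lead_preference)
    except ValueError:
        raise LeadAbsentError(
            f"record {record_id}: lead {lead_preference!r} not found "
            f"(available: {descriptions})"
        ) from None
    record = ECGRecord(
        record_id=record_id,
        signal=physical[:, channel],
        fs=header.fs,
        lead_name=lead_preference,
    )
    raw = wfdb_io.read_annotations(record_path.with_suffix(".atr"))
    beats = [
        BeatAnnotation(sample, symbol, SYMBOL_TO_AAMI[symbol])
        for sample, symbol in raw
        if symbol in BEAT_SYMBOLS and 0 <= sample < record.signal.size
    ]
    return record, beats
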