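"""Minimal reader/writer for the WFDB file family used by the MIT-BIH database.

Supports exactly what ambulatory single/dual-lead arrhythmia records need:
``.hea`` text headers, ``.dat`` signal files in format 212 (two 12-bit
two's-complement samples packed into three bytes), and ``.atr`` annotation
files in the MIT annotation format (10-bit time deltas with 6-bit type codes,
plus the SKIP/AUX/NUM/SUB/CHN escape codes).

Signal amplitudes cross this boundary in physical units (mV); digital-to-
physical conversion uses the per-signal gain (adu/mV) and baseline from the
header.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SignalInfo",
    "WfdbError",
    "read_header",
    "read_signals",
    "read_annotations",
    "write_record",
    "write_annotations",
]


class WfdbError(IOError):
    """Raised when WFDB files are missing, inconsistent, or unsupported."""


# MIT annotation type codes <-> symbols (ecgcodes convention).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    """One signal-specification line of a ``.hea`` header."""

    filename: str
    fmt: int
    gain: float  # adu per physical unit (mV)
    baseline: int  # adu value corresponding to 0 mV
    adc_res: int
    adc_zero: int
    description: str


@dataclass
class Header:
    record_id: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalInfo] = field(default_factory=list)


def read_header(path: str | Path) -> Header:
    path = Path(path)
    if not path.exists():
        raise WfdbError(f"header file not found: {path}")
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tokens = lines[0].split()
    record_id = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    header = Header(record_id, n_sig, fs, n_samples)
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int("".join(ch for ch in tok[1] if ch.isdigit()) or 0)
        gain, baseline = 200.0, None
        if len(tok) > 2:
            gfield = tok[2].split("/")[0]
            if "(" in gfield:
                gain = float(gfield[: gfield.index("(")])
                baseline = int(gfield[gfield.index("(") + 1 : gfield.index(")")])
            else:
                gain = float(gfield)
        if gain == 0:
            gain = 200.0
        adc_res = int(tok[3]) if len(tok) > 3 else 12
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else ""
        header.signals.append(
            SignalInfo(tok[0], fmt, gain, baseline, adc_res, adc_zero, description)
        )
    return header


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    data = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = len(data) // 3
    data = data[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    first = ((data[:, 1] & 0x0F) << 8) | data[:, 0]
    second = ((data[:, 1] & 0xF0) << 4) | data[:, 2]
    values = np.empty(2 * n_triplets, dtype=np.int32)
    values[0::2] = first
    values[1::2] = second
    values[values >= 2048] -= 4096  # 12-bit two's complement
    return values[:n_values]


def _pack_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint32)
    a, b = v[0::2], v[1::2]
    out = np.empty((a.size, 3), dtype=np.uint8)
    out[:, 0] = a & 0xFF
    out[:, 1] = ((b >> 8) << 4) | (a >> 8)
    out[:, 2] = b & 0xFF
    return out.tobytes()


def read_signals(record_path: str | Path) -> tuple[Header, np.ndarray]:
    """Read all channels of a record; returns (header, physical mV array).

    The returned array has shape ``(n_samples, n_sig)``.
    """
    record_path = Path(record_path)
    header = read_header(record_path.with_suffix(".hea"))
    if any(sig.fmt != 212 for sig in header.signals):
        raise WfdbError(
            f"record {header.record_id}: only format 212 is supported "
            f"(got {[sig.fmt for sig in header.signals]})"
        )
    dat_path = record_path.parent / header.signals[0].filename
    if not dat_path.exists():
        raise WfdbError(f"signal file not found: {dat_path}")
    raw = dat_path.read_bytes()
    n_values = header.n_samples * header.n_sig
    values = _unpack_212(raw, n_values)
    if values.size < n_values:
        raise WfdbError(
            f"record {header.record_id}: signal file truncated "
            f"({values.size} < {n_values} samples)"
        )
    digital = values.reshape(header.n_samples, header.n_sig)
    physical = np.empty(digital.shape, dtype=np.float64)
    for ch, sig in enumerate(header.signals):
        physical[:, ch] = (digital[:, ch] - sig.baseline) / sig.gain
    return header, physical


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file as ``[(sample_index, symbol), ...]``.

    Escape codes (SKIP/NUM/SUB/CHN/AUX) are consumed; annotations whose type
    code has no symbol are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise WfdbError(f"annotation file not found: {path}")
    raw = path.read_bytes()
    words = struct.unpack(f"<{len(raw) // 2}H", raw[: (len(raw) // 2) * 2])
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i < len(words):
        word = words[i]
        code, delta = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and delta == 0:
            break  # end of annotation stream
        if code == _SKIP:
            if i + 1 >= len(words):
                raise WfdbError(f"truncated SKIP in {path}")
            t += (words[i] << 16) + words[i + 1]
            i += 2
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += (delta + 1) // 2  # aux string, padded to even length
        else:
            t += delta
            symbol = _CODE_TO_SYMBOL.get(code)
            if symbol is not None:
                out.append((t, symbol))
    return out


def write_annotations(path: str | Path, annotations: list[tuple[int, str]]) -> None:
    """Write ``[(sample_index, symbol), ...]`` as an MIT-format file."""
    words: list[int] = []
    prev = 0
    for sample, symbol in annotations:
        if symbol not in _SYMBOL_TO_CODE:
            raise WfdbError(f"no MIT annotation code for symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise WfdbError("annotations must be in non-decreasing time order")
        if delta > 1023:
            words.extend([(_SKIP << 10), delta >> 16, delta & 0xFFFF])
            delta = 0
        words.append((_SYMBOL_TO_CODE[symbol] << 10) | delta)
        prev = sample
    words.append(0)  # EOF marker
    Path(path).write_bytes(struct.pack(f"<{len(words)}H", *words))


def write_record(
    out_dir: str | Path,
    record_id: str,
    signal: np.ndarray,
    fs: float,
    *,
    lead_name: str = "MLII",
    annotations: list[tuple[int, str]] | None = None,
    gain: float = 200.0,
    baseline: int = 1024,
) -> Path:
    """Write a single-lead record (.hea/.dat and optional .atr) under out_dir.

    The default gain/baseline reproduce the MIT-BIH digitization: 200 adu/mV
    around a 1024 adu baseline, 11-bit ADC over a 10 mV range (1 LSB = 5 uV).
    Returns the record path (without extension).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size == 0:
        raise WfdbError("signal must be a non-empty 1-D array")
    digital = np.rint(signal * gain + baseline).astype(np.int32)
    digital = np.clip(digital, -2048, 2047)
    (out_dir / f"{record_id}.dat").write_bytes(_pack_212(digital))
    header = (
        f"{record_id} 1 {fs:g} {signal.size}\n"
        f"{record_id}.dat 212 {gain:g}({baseline})/mV 11 {baseline} "
        f"{digital[0]} 0 0 {lead_name}\n"
    )
    (out_dir / f"{record_id}.hea").write_text(header)
    if annotations is not None:
        write_annotations(out_dir / f"{record_id}.atr", sorted(annotations))
    return out_dir / record_id
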