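"""Synthetic annotated single-lead ECG records in WFDB format.

The generator emulates the data regime the pipeline is built for: a 360 Hz
single-lead signal of quasi-periodic P-QRS-T complexes with per-beat R-peak
annotations, additive low-frequency baseline wander, white measurement
noise, and class-dependent morphology and rhythm:

* ``normal``   — full P-QRS-T, regular RR (symbol ``N``);
* ``pvc``      — premature ventricular contraction: wide, high-amplitude
  QRS, no P wave, inverted T, shortened preceding RR and a compensatory
  pause (symbol ``V``, AAMI class VEB);
* ``apb``      — atrial premature beat: near-normal morphology with an
  early, smaller P wave, shortened preceding RR and a compensatory pause
  (symbol ``A``, AAMI class SVEB) — distinguishable from normals mainly by
  rhythm, which exercises the RR-feature fusion path.

Each wave is a Gaussian bump; each synthetic "patient" draws its own
template perturbation so an inter-patient split is meaningful at toy scale.
Records round-trip through the same WFDB reader used for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import wfdb_io
from .records import BeatAnnotation, ECGRecord, SYMBOL_TO_AAMI

__all__ = ["SynthSpec", "generate_record", "write_wfdb", "generate_database"]

CLASS_SYMBOLS = {"normal": "N", "pvc": "V", "apb": "A"}

# (amplitude mV, center offset s relative to R, width s) per wave
_NORMAL_WAVES = (
    (0.12, -0.20, 0.025),  # P
    (-0.10, -0.026, 0.010),  # Q
    (1.00, 0.0, 0.012),  # R
    (-0.18, 0.028, 0.011),  # S
    (0.30, 0.28, 0.055),  # T
)
_PVC_WAVES = (
    (1.35, 0.0, 0.034),  # wide, tall R; no P
    (-0.45, 0.055, 0.030),  # deep slurred S
    (-0.32, 0.30, 0.070),  # discordant (inverted) T
)
_APB_WAVES = (
    (0.08, -0.16, 0.020),  # early, flattened P
    (-0.10, -0.026, 0.010),
    (0.95, 0.0, 0.012),
    (-0.18, 0.028, 0.011),
    (0.28, 0.27, 0.050),
)
_TEMPLATES = {"normal": _NORMAL_WAVES, "pvc": _PVC_WAVES, "apb": _APB_WAVES}

PREMATURITY = 0.70  # preceding RR multiplier for premature beats
COMPENSATORY_PAUSE = 1.35  # following RR multiplier after a premature beat


@dataclass
class SynthSpec:
    """Parameters of one synthetic record (one "patient")."""

    record_id: str = "s000"
    fs: float = 360.0
    duration: float = 60.0  # seconds
    heart_rate: float = 72.0  # bpm
    rr_jitter: float = 0.03  # fractional sd of each RR interval
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.80, "pvc": 0.10, "apb": 0.10}
    )
    wander_amplitude: float = 0.10  # mV
    wander_frequency: float = 0.30  # Hz (respiration band, <= 0.5)
    noise_sd: float = 0.02  # mV white noise
    patient_variation: float = 0.10  # per-patient template perturbation sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mixture must sum to 1, got {total}")
        unknown = set(self.class_mix) - set(_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown beat classes: {sorted(unknown)}")
        if self.heart_rate * self.duration / 60.0 < 2:
            raise ValueError("spec yields fewer than two beats")


def _patient_templates(spec: SynthSpec, rng: np.random.Generator):
    """Per-patient perturbed copies of the class wave templates."""
    v = spec.patient_variation
    out = {}
    for cls, waves in _TEMPLATES.items():
        out[cls] = [
            (
                amp * (1.0 + v * rng.standard_normal()),
                center + 0.15 * v * rng.standard_normal() * abs(center),
                max(width * (1.0 + v * rng.standard_normal()), 0.004),
            )
            for amp, center, width in waves
        ]
    return out


def generate_record(spec: SynthSpec) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Render one annotated record; deterministic for a fixed spec.seed."""
    rng = np.random.default_rng(spec.seed)
    templates = _patient_templates(spec, rng)
    base_rr = 60.0 / spec.heart_rate

    classes = list(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])

    # Rhythm: draw beat classes first, then build the RR sequence so that a
    # premature beat shortens its preceding interval and stretches the next.
    beat_times: list[float] = []
    beat_classes: list[str] = []
    t = 0.5  # lead-in so the first window fits
    prev_premature = False
    while t < spec.duration - 0.5:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        if beat_times:
            rr = base_rr * (1.0 + spec.rr_jitter * rng.standard_normal())
            if cls in ("pvc", "apb"):
                rr *= PREMATURITY
            if prev_premature:
                rr *= COMPENSATORY_PAUSE
            rr = max(rr, 0.25)
            t = beat_times[-1] + rr
            if t >= spec.duration - 0.5:
                break
        beat_times.append(t)
        beat_classes.append(cls)
        prev_premature = cls in ("pvc", "apb")
    if len(beat_times) < 2:
        raise ValueError("spec too short to place two beats")

    n = int(round(spec.fs * spec.duration))
    time = np.arange(n) / spec.fs
    signal = np.zeros(n)
    for beat_t, cls in zip(beat_times, beat_classes):
        lo = max(int((beat_t - 0.6) * spec.fs), 0)
        hi = min(int((beat_t + 0.6) * spec.fs) + 1, n)
        tt = time[lo:hi] - beat_t
        for amp, center, width in templates[cls]:
            signal[lo:hi] += amp * np.exp(-((tt - center) ** 2) / (2 * width**2))

    if spec.wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += spec.wander_amplitude * np.sin(
            2 * np.pi * spec.wander_frequency * time + phase
        )
    if spec.noise_sd > 0:
        signal += spec.noise_sd * rng.standard_normal(n)

    record = ECGRecord(spec.record_id, signal, spec.fs, lead_name="MLII")
    annotations = [
        BeatAnnotation(
            int(round(beat_t * spec.fs)),
            CLASS_SYMBOLS[cls],
            SYMBOL_TO_AAMI[CLASS_SYMBOLS[cls]],
        )
        for beat_t, cls in zip(beat_times, beat_classes)
    ]
    return record, annotations


def write_wfdb(
    record: ECGRecord, annotations: list[BeatAnnotation], out_dir
) -> None:
    """Emit .hea/.dat/.atr files readable by :func:`records.read_record`."""
    wfdb_io.write_record(
        out_dir,
        record.record_id,
        record.signal,
        record.fs,
        lead_name=record.lead_name,
        annotations=[(b.sample_index, b.symbol) for b in annotations],
    )


def generate_database(
    n_records: int, base_spec: SynthSpec | None = None, seed: int = 0
) -> list[tuple[ECGRecord, list[BeatAnnotation]]]:
    """Several synthetic "patients": distinct seeds, ids s000, s001, ...

    Each record derives its own seed from ``seed`` so patients differ in
    template draws, rhythm jitter, and noise.
    """
    base = base_spec or SynthSpec()
    out = []
    for i in range(n_records):
        spec = replace(base, record_id=f"s{i:03d}", seed=seed * 1009 + i)
        out.append(generate_record(spec))
    return out
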