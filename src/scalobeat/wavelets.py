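"""Continuous wavelet transform and time-frequency scalograms.

The CWT of a signal x(t) at scale a and translation b is

    C(a, b) = (1 / sqrt(a)) * integral x(t) phi((t - b) / a) dt

where phi is the mother wavelet. A scale converts to frequency through the
wavelet's center frequency Fc: F = Fc * fs / a (Hz, for a sampled signal).

The Mexican hat wavelet — the negated, normalized second derivative of a
Gaussian —

    phi(t) = 2 / (sqrt(3) * pi^(1/4)) * exp(-t^2 / 2) * (1 - t^2)

is the default mother wavelet: its shape resembles the QRS complex, which
empirically matters for ECG scalograms. The real Morlet wavelet and the
4th/8th Gaussian-derivative wavelets are provided for comparison.

A 200-sample heartbeat segment becomes a 100x200 scalogram over integer
scales 1..100 (about 0.9-90 Hz at 360 Hz with the Mexican hat, covering the
0-50 Hz band where ECG energy concentrates), then is decimated along time
to 100x100 for the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import correlate1d
from scipy.special import eval_hermite

__all__ = [
    "WaveletSpec",
    "Scalogram",
    "WAVELETS",
    "mexh",
    "morl",
    "gaus",
    "cwt",
    "scale_to_frequency",
    "frequency_to_scale",
    "build_scalogram",
    "resample_scalogram",
    "normalize_minmax",
    "scalogram_image",
]

N_SCALES = 100
SEGMENT_LENGTH = 200
SUPPORT = 8.0  # phi(t) ~ 0 for |t| > 8 for all wavelets here

_MEXH_NORM = 2.0 / (math.sqrt(3.0) * math.pi**0.25)


def mexh(t):
    """Mexican hat wavelet, unit L2 norm."""
    t = np.asarray(t, dtype=np.float64)
    return _MEXH_NORM * np.exp(-(t**2) / 2.0) * (1.0 - t**2)


def morl(t):
    """Real Morlet wavelet: cos(5t) * exp(-t^2/2)."""
    t = np.asarray(t, dtype=np.float64)
    return np.cos(5.0 * t) * np.exp(-(t**2) / 2.0)


def _gaus_norm(n: int) -> float:
    # L2 norm of d^n/dt^n exp(-t^2) = H_n(t) exp(-t^2) (up to sign),
    # via fine-grid quadrature over the effective support.
    t = np.linspace(-SUPPORT, SUPPORT, 1 << 14)
    g = eval_hermite(n, t) * np.exp(-(t**2))
    return float(np.sqrt(np.trapezoid(g**2, t)))


_GAUS_NORMS = {4: _gaus_norm(4), 8: _gaus_norm(8)}


def gaus(t, n: int):
    """n-th derivative-of-Gaussian wavelet, unit L2 norm."""
    t = np.asarray(t, dtype=np.float64)
    sign = -1.0 if n % 2 else 1.0
    return sign * eval_hermite(n, t) * np.exp(-(t**2)) / _GAUS_NORMS[n]


@dataclass(frozen=True)
class WaveletSpec:
    """A mother wavelet: evaluator phi(t) plus its center frequency Fc."""

    name: str
    center_frequency: float
    evaluator: Callable[[np.ndarray], np.ndarray]


WAVELETS: dict[str, WaveletSpec] = {
    "mexh": WaveletSpec("mexh", 0.25, mexh),
    "morl": WaveletSpec("morl", 0.8125, morl),
    "gaus4": WaveletSpec("gaus4", 0.5, lambda t: gaus(t, 4)),
    "gaus8": WaveletSpec("gaus8", 0.6, lambda t: gaus(t, 8)),
}


@dataclass
class Scalogram:
    """CWT coefficients, rows indexed by scale and columns by time."""

    coefficients: np.ndarray  # (n_scales, n_samples), signed
    scales: np.ndarray
    fs: float
    frequencies: np.ndarray = field(init=False)
    wavelet: str = "mexh"

    def __post_init__(self) -> None:
        spec = WAVELETS[self.wavelet]
        self.frequencies = scale_to_frequency(self.scales, self.fs, spec)


def _resolve(wavelet: str | WaveletSpec) -> WaveletSpec:
    if isinstance(wavelet, WaveletSpec):
        return wavelet
    try:
        return WAVELETS[wavelet]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {wavelet!r}; choose from {sorted(WAVELETS)}"
        ) from None


def scale_to_frequency(a, fs: float, wavelet: str | WaveletSpec = "mexh"):
    """Pseudo-frequency (Hz) of scale a: F = Fc * fs / a."""
    spec = _resolve(wavelet)
    a = np.asarray(a, dtype=np.float64)
    if np.any(a <= 0):
        raise ValueError("scale must be positive")
    return spec.center_frequency * fs / a


def frequency_to_scale(f, fs: float, wavelet: str | WaveletSpec = "mexh"):
    """Inverse of :func:`scale_to_frequency`: a = Fc * fs / F."""
    spec = _resolve(wavelet)
    f = np.asarray(f, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return spec.center_frequency * fs / f


def cwt(
    x: np.ndarray,
    fs: float,
    scales,
    wavelet: str | WaveletSpec = "mexh",
) -> Scalogram:
    """Sampled CWT of a 1-D signal at the given scales.

    Each row is the correlation of the (zero-extended) signal with the
    scale-dilated sampled wavelet, normalized by 1/sqrt(a); time is measured
    in samples, so scales are in samples as well.
    """
    spec = _resolve(wavelet)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    scales = np.atleast_1d(np.asarray(scales, dtype=np.float64))
    if np.any(scales < 1):
        raise ValueError("scales must be >= 1 (sub-sample scales are not resolvable)")
    coeffs = np.empty((scales.size, x.size))
    for row, a in enumerate(scales):
        half = int(math.ceil(SUPPORT * a))
        kernel = spec.evaluator(np.arange(-half, half + 1) / a)
        coeffs[row] = correlate1d(x, kernel, mode="constant", cval=0.0) / math.sqrt(a)
    return Scalogram(coeffs, scales, fs, wavelet=spec.name)


def build_scalogram(
    segment: np.ndarray, fs: float = 360.0, wavelet: str | WaveletSpec = "mexh"
) -> Scalogram:
    """100-scale scalogram of one 200-sample heartbeat (scales 1..100)."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.shape != (SEGMENT_LENGTH,):
        raise ValueError(
            f"expected a segment of shape ({SEGMENT_LENGTH},), got {segment.shape}"
        )
    return cwt(segment, fs, np.arange(1, N_SCALES + 1), wavelet)


def resample_scalogram(scalogram: Scalogram | np.ndarray) -> np.ndarray:
    """Halve the time axis of a 100x200 scalogram to 100x100.

    Adjacent column pairs are averaged (factor-2 decimation with anti-alias
    averaging): exact on constants and symmetric under time reversal.
    """
    mat = (
        scalogram.coefficients
        if isinstance(scalogram, Scalogram)
        else np.asarray(scalogram, dtype=np.float64)
    )
    if mat.shape != (N_SCALES, SEGMENT_LENGTH):
        raise ValueError(
            f"expected shape ({N_SCALES}, {SEGMENT_LENGTH}), got {mat.shape}"
        )
    return 0.5 * (mat[:, 0::2] + mat[:, 1::2])


def normalize_minmax(mat: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant matrix maps to all zeros."""
    mat = np.asarray(mat, dtype=np.float64)
    lo, hi = mat.min(), mat.max()
    if hi == lo:
        return np.zeros_like(mat)
    return (mat - lo) / (hi - lo)


def scalogram_image(
    segment: np.ndarray,
    fs: float = 360.0,
    wavelet: str | WaveletSpec = "mexh",
    normalize: bool = True,
) -> np.ndarray:
    """100x100 classifier input for one heartbeat segment.

    Signed CWT coefficients at scales 1..100, time-decimated to 100 columns,
    then (by default) min-max normalized per heartbeat; the network's first
    batch-norm layer removes residual scale effects.
    """
    mat = resample_scalogram(build_scalogram(segment, fs, wavelet))
    return normalize_minmax(mat) if normalize else mat
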