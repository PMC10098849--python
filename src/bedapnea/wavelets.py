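"""Wavelet band separation of respiration and BCG from one pressure channel.

A level-5 discrete wavelet transform with the Daubechies-5 (db5) basis
splits the 0-25 Hz band (at fs = 50 Hz) into dyadic sub-bands: detail
level j covers (fs/2^(j+1), fs/2^j) and the level-5 approximation covers
0-0.78 Hz.  The respiration wave lives in the approximation, the
ballistocardiogram in details 1-3; reconstructing each group separately
(after soft-thresholding the noisiest detail) yields the two aligned
channels.  For sampling rates other than 50 Hz the band plan is
recomputed so respiration keeps 0-0.8 Hz and the BCG keeps roughly
3-15 Hz of coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.fft import rfft, rfftfreq

from .synth import RawRecord

__all__ = [
    "WaveletDecomposition",
    "SeparatedSignals",
    "band_edges",
    "decompose",
    "reconstruct_band",
    "soft_threshold",
    "estimate_lambda",
    "separate",
    "spectrum",
    "dominant_frequency",
]

_MODE = "symmetric"  # boundary extension; keeps perfect reconstruction


def band_edges(fs: float, level: int, kind: str = "detail") -> tuple[float, float]:
    """Nominal frequency band of one decomposition level.

    Detail level j spans (fs/2^(j+1), fs/2^j); the approximation at level j
    spans (0, fs/2^(j+1)).
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    if not 1 <= level <= 10:
        raise ValueError(f"level must lie in [1, 10], got {level}")
    hi = fs / 2.0**level
    lo = fs / 2.0 ** (level + 1)
    if kind == "detail":
        return (lo, hi)
    if kind == "approx":
        return (0.0, lo)
    raise ValueError(f"kind must be 'detail' or 'approx', got {kind!r}")


@dataclass
class WaveletDecomposition:
    """Multilevel DWT coefficients of one record.

    ``details[j-1]`` holds the level-j detail coefficients, ``approx`` the
    deepest approximation; the inverse of the untouched coefficients
    reproduces the input to floating precision.
    """

    wavelet_name: str
    levels: int
    details: list[np.ndarray]
    approx: np.ndarray
    original_length: int
    fs: float

    def coeff_list(self) -> list[np.ndarray]:
        """Coefficients in pywt.waverec order: [approx, D_levels, ..., D1]."""
        return [self.approx] + self.details[::-1]

    def inverse(self) -> np.ndarray:
        out = pywt.waverec(self.coeff_list(), self.wavelet_name, mode=_MODE)
        return out[: self.original_length]


@dataclass
class SeparatedSignals:
    """Respiration and BCG channels reconstructed from wavelet bands."""

    respiration: np.ndarray
    bcg: np.ndarray
    fs: float
    band_plan: dict = field(default_factory=dict)
    threshold_used: dict = field(default_factory=dict)


def decompose(record: RawRecord, wavelet: str = "db5", levels: int = 5) -> WaveletDecomposition:
    """Multilevel discrete wavelet transform of one pressure record."""
    x = np.asarray(record.samples, dtype=float)
    if x.size < 2**levels:
        raise ValueError(f"signal too short for {levels} levels: {x.size} < {2**levels}")
    try:
        pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet!r}") from exc
    coeffs = pywt.wavedec(x, wavelet, mode=_MODE, level=levels)
    return WaveletDecomposition(
        wavelet_name=wavelet,
        levels=levels,
        details=coeffs[1:][::-1],  # store as [D1, D2, ..., D_levels]
        approx=coeffs[0],
        original_length=x.size,
        fs=record.fs,
    )


def reconstruct_band(decomp: WaveletDecomposition, level: int, kind: str = "detail") -> np.ndarray:
    """Time-domain reconstruction keeping a single band, zeroing all others."""
    coeffs = [np.zeros_like(c) for c in decomp.coeff_list()]
    if kind == "approx":
        coeffs[0] = decomp.approx
    elif kind == "detail":
        if not 1 <= level <= decomp.levels:
            raise ValueError(f"detail level {level} outside 1..{decomp.levels}")
        # coeff_list order is [A, D_levels, ..., D1]
        coeffs[decomp.levels - level + 1] = decomp.details[level - 1]
    else:
        raise ValueError(f"kind must be 'detail' or 'approx', got {kind!r}")
    out = pywt.waverec(coeffs, decomp.wavelet_name, mode=_MODE)
    return out[: decomp.original_length]


def soft_threshold(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Soft shrinkage sign(c) * max(|c| - lam, 0)."""
    if lam < 0:
        raise ValueError(f"threshold must be non-negative, got {lam}")
    c = np.asarray(coeffs, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)


def estimate_lambda(decomp: WaveletDecomposition, level: int = 1) -> float:
    """Universal threshold lambda = sigma * sqrt(2 ln N).

    The noise scale sigma is the median absolute deviation of the level-1
    detail coefficients divided by 0.6745 (its value under a Gaussian),
    and N is the original signal length.
    """
    d1 = decomp.details[level - 1]
    if d1.size == 0:
        raise ValueError("empty detail band")
    sigma = float(np.median(np.abs(d1))) / 0.6745
    return sigma * np.sqrt(2.0 * np.log(decomp.original_length))


def _default_band_plan(fs: float, levels: int) -> dict:
    """Which levels feed each output channel, from the band edges.

    Respiration keeps the deepest approximation (0 to fs/2^(levels+1));
    BCG keeps every detail level whose band overlaps 3-15 Hz.
    """
    bcg_levels = [
        j for j in range(1, levels + 1)
        if band_edges(fs, j, "detail")[1] > 3.0 and band_edges(fs, j, "detail")[0] < 15.0
    ]
    return {"respiration": {"approx": levels, "details": []}, "bcg": {"details": bcg_levels}}


def separate(
    record: RawRecord,
    wavelet: str = "db5",
    levels: int = 5,
    include_d5_respiration: bool = False,
    threshold_levels: tuple[int, ...] = (1,),
    detrend: str = "mean",
) -> SeparatedSignals:
    """Split one pressure record into respiration and BCG channels.

    The respiration channel is the inverse transform keeping only the
    deepest approximation (optionally plus the deepest detail), with the
    DC baseline removed by mean subtraction (or linear detrend).  The BCG
    channel keeps the detail levels covering roughly 3-15 Hz, with the
    level-1 band soft-thresholded at the universal threshold to suppress
    broadband noise.
    """
    decomp = decompose(record, wavelet, levels)
    plan = _default_band_plan(record.fs, levels)
    if include_d5_respiration:
        plan["respiration"]["details"] = [levels]

    thresholds = {j: estimate_lambda(decomp) for j in threshold_levels}

    resp = reconstruct_band(decomp, levels, "approx")
    for j in plan["respiration"]["details"]:
        resp = resp + reconstruct_band(decomp, j, "detail")
    if detrend == "linear":
        t = np.arange(resp.size)
        a, b = np.polyfit(t, resp, 1)
        resp = resp - (a * t + b)
    else:
        resp = resp - resp.mean()

    denoised = WaveletDecomposition(
        wavelet_name=decomp.wavelet_name,
        levels=decomp.levels,
        details=[
            soft_threshold(d, thresholds[j]) if j in thresholds else d
            for j, d in enumerate(decomp.details, start=1)
        ],
        approx=decomp.approx,
        original_length=decomp.original_length,
        fs=decomp.fs,
    )
    bcg = np.zeros(decomp.original_length)
    for j in plan["bcg"]["details"]:
        bcg = bcg + reconstruct_band(denoised, j, "detail")

    return SeparatedSignals(
        respiration=resp,
        bcg=bcg,
        fs=record.fs,
        band_plan=plan,
        threshold_used=thresholds,
    )


def spectrum(channel: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum (|rfft|) and its frequency axis."""
    x = np.asarray(channel, dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 samples, got {x.size}")
    mags = np.abs(rfft(x))
    freqs = rfftfreq(x.size, d=1.0 / fs)
    return freqs, mags


def dominant_frequency(channel: np.ndarray, fs: float, fmin: float = 0.0) -> float:
    """Frequency of the magnitude-spectrum maximum at frequencies >= fmin."""
    if not fmin < fs / 2:
        raise ValueError("fmin must be below the Nyquist frequency")
    freqs, mags = spectrum(channel, fs)
    mask = freqs >= fmin
    if not np.any(mask):
        raise ValueError("empty frequency band")
    return float(freqs[mask][np.argmax(mags[mask])])
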