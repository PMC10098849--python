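"""Per-breath feature extraction: HRV indices and waveform similarity.

The respiration channel is segmented into breath frames (trough to
trough, one respiratory cycle each).  Within each frame, the J-peaks of
the ballistocardiogram give the beat-to-beat (NN) intervals from which
the classical heart-rate-variability indices AVNN (mean NN interval),
SDNN (their standard deviation) and CV (their ratio) are computed; the
breath period Ti is the frame length over the sampling rate and the beat
count N is the number of J-peaks inside.

The sixth feature is the waveform-similarity statistic xi: the maximum
cross-correlation between the frame's respiration wave and a standard
single-breath template, normalized by the template's maximum
autocorrelation and expressed in percent.  Both waveforms are reduced to
zero mean and unit energy first, so xi is amplitude-invariant, bounded
by 100 (Cauchy-Schwarz), and collapses during apnea when the frame
holds no breath-shaped energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BreathFrame",
    "StandardTemplate",
    "FeatureVector",
    "FEATURE_NAMES",
    "segment_breath_frames",
    "avnn",
    "sdnn",
    "cv",
    "breath_period",
    "cross_correlation",
    "similarity",
    "extract_features",
    "default_template",
]

#: frame-duration bounds in seconds (~4-60 breaths/min)
MIN_FRAME_S = 1.0
MAX_FRAME_S = 15.0
FALLBACK_FRAME_S = 5.0

FEATURE_NAMES = ("avnn_s", "sdnn_s", "cv", "ti_s", "n_beats", "similarity_pct")


@dataclass
class BreathFrame:
    """One respiratory cycle: a half-open [start, end) slice of the record."""

    start_sample: int
    end_sample: int
    respiration: np.ndarray
    fs: float
    peaks_in_frame: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("frame end must exceed start")
        self.respiration = np.asarray(self.respiration, dtype=float)
        self.peaks_in_frame = np.asarray(self.peaks_in_frame, dtype=int)
        if self.peaks_in_frame.size and (
            self.peaks_in_frame.min() < self.start_sample
            or self.peaks_in_frame.max() >= self.end_sample
        ):
            raise ValueError("peaks_in_frame must lie inside [start, end)")

    @property
    def n_beats(self) -> int:
        return int(self.peaks_in_frame.size)


@dataclass
class StandardTemplate:
    """One normalized normal-breath cycle used as the similarity reference."""

    waveform: np.ndarray
    origin: str = "builtin"

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        w = w - w.mean()
        energy = float(np.sum(w**2))
        if energy <= 0:
            raise ValueError("template must have nonzero energy")
        self.waveform = w / math.sqrt(energy)

    @classmethod
    def from_file(cls, path: str | Path) -> "StandardTemplate":
        w = np.loadtxt(path, delimiter=",", ndmin=1)
        return cls(waveform=w, origin=str(path))


def default_template(n: int = 100, exhale_end_frac: float = 0.4) -> StandardTemplate:
    """Built-in standard breath: one asymmetric raised-cosine cycle."""
    from .synth import make_breath_cycle

    return StandardTemplate(waveform=make_breath_cycle(n, exhale_end_frac))


@dataclass
class FeatureVector:
    """The six per-frame features; NaN marks an undefined entry."""

    avnn_s: float
    sdnn_s: float
    cv: float
    ti_s: float
    n_beats: int
    similarity_pct: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.avnn_s, self.sdnn_s, self.cv, self.ti_s, self.n_beats, self.similarity_pct],
            dtype=float,
        )

    @property
    def fully_defined(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


# ---------------------------------------------------------------------------
# segmentation


def segment_breath_frames(
    respiration: np.ndarray,
    fs: float,
    peaks: np.ndarray | None = None,
) -> list[BreathFrame]:
    """Slice the respiration channel into trough-to-trough breath frames.

    Troughs are minima with prominence above an adaptive threshold (a
    fraction of the channel's robust amplitude), at least the minimum
    frame length apart.  Frames longer than the maximum are split into
    equal sub-frames; if no troughs are found at all (sustained apnea or
    a flat channel) fixed-length fallback frames are emitted and flagged.
    """
    x = np.asarray(respiration, dtype=float)
    peaks = np.asarray(peaks if peaks is not None else [], dtype=int)
    amp = float(np.percentile(x, 98) - np.percentile(x, 2)) / 2.0 if x.size else 0.0
    troughs = np.array([], dtype=int)
    if amp > 0:
        troughs, _ = find_peaks(-x, prominence=0.35 * amp, distance=max(int(MIN_FRAME_S * fs), 1))

    frames: list[BreathFrame] = []
    if troughs.size < 2:
        # degenerate channel: tile with fixed 5 s frames, flagged
        step = int(FALLBACK_FRAME_S * fs)
        for a in range(0, x.size - step + 1, step):
            frames.append(_make_frame(x, fs, a, a + step, peaks, fallback=True))
        return frames

    for a, b in zip(troughs, troughs[1:]):
        n_sub = max(1, math.ceil((b - a) / (MAX_FRAME_S * fs)))
        edges = np.linspace(a, b, n_sub + 1).round().astype(int)
        for i0, i1 in zip(edges, edges[1:]):
            if i1 - i0 >= int(MIN_FRAME_S * fs):
                frames.append(_make_frame(x, fs, int(i0), int(i1), peaks, fallback=n_sub > 1))
    return frames


def _make_frame(
    x: np.ndarray, fs: float, a: int, b: int, peaks: np.ndarray, fallback: bool
) -> BreathFrame:
    inside = peaks[(peaks >= a) & (peaks < b)]
    return BreathFrame(
        start_sample=a,
        end_sample=b,
        respiration=x[a:b],
        fs=fs,
        peaks_in_frame=inside,
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# HRV features


def _nn_intervals_s(frame: BreathFrame) -> np.ndarray:
    return np.diff(frame.peaks_in_frame) / frame.fs


def avnn(frame: BreathFrame) -> float:
    """Mean NN (J-to-J) interval in seconds; NaN when fewer than 2 beats."""
    if frame.n_beats < 2:
        return float("nan")
    return float(np.mean(_nn_intervals_s(frame)))


def sdnn(frame: BreathFrame) -> float:
    """Sample SD of the NN intervals in seconds (0 for a single interval)."""
    if frame.n_beats < 2:
        return float("nan")
    nn = _nn_intervals_s(frame)
    if nn.size == 1:
        return 0.0
    return float(np.std(nn, ddof=1))


def cv(avnn_s: float, sdnn_s: float, printed_form: bool = False) -> float:
    """Coefficient of variation of the NN intervals.

    Default is SDNN/AVNN (the conventional dimensionless CV);
    ``printed_form=True`` returns the reciprocal AVNN/SDNN instead.
    """
    if printed_form:
        return float("nan") if not sdnn_s or not np.isfinite(sdnn_s) else avnn_s / sdnn_s
    if not avnn_s or not np.isfinite(avnn_s):
        return float("nan")
    return sdnn_s / avnn_s


def breath_period(frame: BreathFrame) -> float:
    """Frame length over the sampling rate: Ti = Ci / Fn, in seconds."""
    return (frame.end_sample - frame.start_sample) / frame.fs


# ---------------------------------------------------------------------------
# waveform similarity


def cross_correlation(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Full cross-correlation R_{f,g}(n) = sum_k f[k] g[k+n] over all lags.

    Lags run from -(len(g)-1) to len(f)-1, zero-padded outside support,
    so every relative alignment of the two sequences is scored.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.size == 0 or g.size == 0:
        raise ValueError("cross_correlation needs nonempty inputs")
    # np.correlate(f, g, "full")[j] = sum_k f[k] g[k - (j - (len(g)-1))]
    # i.e. R_{f,g}(-m) at m = j - (len(g)-1); reverse to get R over n.
    return np.correlate(f, g, mode="full")[::-1]


def similarity(frame: BreathFrame, template: StandardTemplate | None = None) -> float:
    """Waveform-similarity statistic xi in percent.

    The standard template is resampled to the frame length; frame and
    template are reduced to zero mean and unit energy, and
    xi = max_n R_{f,g}(n) / max_n R_{f,f}(n) * 100, clamped below at 0.
    A degenerate (zero-energy) frame scores 0.
    """
    if frame.respiration.size < 4:
        raise ValueError("frame too short for similarity")
    template = template or default_template()
    g = frame.respiration - frame.respiration.mean()
    energy = float(np.sum(g**2))
    if energy <= 0:
        return 0.0
    g = g / math.sqrt(energy)
    # linear resampling of the template onto the frame length
    m, n = template.waveform.size, g.size
    f = np.interp(np.linspace(0, m - 1, n), np.arange(m), template.waveform)
    f = f - f.mean()
    fe = float(np.sum(f**2))
    if fe <= 0:
        return 0.0
    f = f / math.sqrt(fe)
    xi = 100.0 * float(np.max(cross_correlation(f, g))) / float(np.max(cross_correlation(f, f)))
    return max(xi, 0.0)


def extract_features(frame: BreathFrame, template: StandardTemplate | None = None) -> FeatureVector:
    """All six per-frame features; undefined entries are NaN."""
    a = avnn(frame)
    s = sdnn(frame)
    return FeatureVector(
        avnn_s=a,
        sdnn_s=s,
        cv=cv(a, s),
        ti_s=breath_period(frame),
        n_beats=frame.n_beats,
        similarity_pct=similarity(frame, template),
    )
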