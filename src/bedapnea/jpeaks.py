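"""J-peak detection in the separated ballistocardiogram channel.

The J-peak is the dominant positive deflection of each cardiac cycle and
serves as the per-beat fiducial (the BCG analog of the ECG R-peak).
Detection is amplitude thresholding of local maxima on the unit-peak
normalized channel, with a cardiac refractory window, followed by the
physiological correction pass: adjacent peaks closer than 0.4 of the mean
inter-peak interval are false detections (the smaller one is dropped),
gaps wider than 1.66 of the mean interval indicate a missed beat and are
re-searched at a relaxed threshold, and gaps that still yield nothing are
flagged as arrhythmia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = ["DetectorParams", "JPeakResult", "detect_candidates", "correct_peaks", "detect_jpeaks"]


@dataclass(frozen=True)
class DetectorParams:
    """Thresholds of the J-peak detector.

    ``ush_base`` is the peak-amplitude threshold USH on the unit-maximum
    normalized channel, ``bias`` an adaptive offset added to it; ``dsh``
    the minimum peak-to-peak interval in seconds and ``refractory_ms`` the
    ignore window after each accepted peak (both default to 220 ms, hence
    redundant at 50 Hz and enforced jointly).  ``low_factor`` and
    ``high_factor`` multiply the mean inter-peak interval to flag false
    and missed detections; ``threshold_relax`` scales USH when a gap is
    re-searched.
    """

    ush_base: float = 0.02
    bias: float = 0.0
    adaptive_bias: bool = True
    dsh: float = 0.22
    refractory_ms: float = 220.0
    low_factor: float = 0.4
    high_factor: float = 1.66
    threshold_relax: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.low_factor < 1 < self.high_factor:
            raise ValueError("need 0 < low_factor < 1 < high_factor")
        if self.dsh <= 0 or self.refractory_ms <= 0:
            raise ValueError("dsh and refractory_ms must be positive")

    @property
    def ush(self) -> float:
        return self.ush_base + self.bias

    def min_gap_samples(self, fs: float) -> int:
        return max(int(round(self.refractory_ms / 1000.0 * fs)), int(round(self.dsh * fs)), 1)


@dataclass
class JPeakResult:
    """Accepted J-peak indices plus the correction audit trail."""

    peaks: np.ndarray
    mean_jj: float
    removed: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    recovered: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    arrhythmia_gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=int)
        self.removed = np.asarray(self.removed, dtype=int)
        self.recovered = np.asarray(self.recovered, dtype=int)
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("peaks must be strictly increasing")


def _normalize(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x)) if x.size else 0.0
    return x / peak if peak > 0 else x


def effective_threshold(x_norm: np.ndarray, params: DetectorParams) -> float:
    """USH plus the adaptive bias on an already-normalized channel.

    The adaptive offset is derived from a two-means split of the local
    maximum heights above the base threshold: J-peaks form the tall
    cluster, the secondary H/L/N lobes of the cardiac cycle and residual
    noise form the short one, and the threshold lands in the valley
    between them.  The split is only applied when the clusters are well
    separated relative to their internal spreads; for a unimodal height
    distribution (e.g. an isolated clean pulse train with no secondary
    lobes above USH) the bias stays zero.
    """
    if not params.adaptive_bias:
        return params.ush
    locs, _ = find_peaks(x_norm, height=params.ush)
    if locs.size < 3:
        return params.ush
    h = np.sort(x_norm[locs])
    # 1-D two-means on the heights
    c1, c2 = float(h[0]), float(h[-1])
    for _ in range(100):
        mid = 0.5 * (c1 + c2)
        lo, hi = h[h <= mid], h[h > mid]
        if lo.size == 0 or hi.size == 0:
            return params.ush
        n1, n2 = float(lo.mean()), float(hi.mean())
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    separation = c2 - c1
    if hi.size < 3 or separation <= 2.0 * (float(lo.std()) + float(hi.std())):
        return params.ush
    return max(params.ush, 0.5 * float(lo.max() + hi.min()))


def detect_candidates(
    bcg: np.ndarray,
    fs: float,
    params: DetectorParams | None = None,
    *,
    threshold: float | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Local maxima above USH on the unit-normalized channel.

    Candidates are accepted greedily in descending amplitude order; any
    local maximum within the refractory window of an already accepted
    peak is ignored.  A flat channel yields an empty result.
    ``normalize=False`` skips the unit-maximum scaling (used when the
    caller already normalized a larger window, e.g. gap re-search).
    """
    params = params or DetectorParams()
    x = np.asarray(bcg, dtype=float)
    if normalize:
        x = _normalize(x)
    ush = effective_threshold(x, params) if threshold is None else threshold
    locs, _ = find_peaks(x, height=ush)
    if locs.size == 0:
        return np.array([], dtype=int)
    min_gap = params.min_gap_samples(fs)
    # greedy: tallest first, earlier wins ties
    order = np.lexsort((locs, -x[locs]))
    accepted: list[int] = []
    for i in order:
        p = int(locs[i])
        if all(abs(p - q) >= min_gap for q in accepted):
            accepted.append(p)
    return np.asarray(sorted(accepted), dtype=int)


def correct_peaks(
    candidates: np.ndarray,
    bcg: np.ndarray,
    fs: float,
    params: DetectorParams | None = None,
) -> JPeakResult:
    """Apply the false-detection and missed-beat correction rules.

    With ``mean_jj`` the mean inter-peak interval of the current window:
    adjacent peaks closer than ``low_factor * mean_jj`` lose the
    smaller-amplitude member; gaps wider than ``high_factor * mean_jj``
    are re-searched once at ``threshold_relax * USH``; unresolved gaps
    are recorded as arrhythmia.
    """
    params = params or DetectorParams()
    x = _normalize(np.asarray(bcg, dtype=float))
    peaks = sorted(int(p) for p in np.asarray(candidates, dtype=int))
    if len(peaks) < 2:
        return JPeakResult(peaks=np.asarray(peaks, dtype=int), mean_jj=float("nan"))

    removed: list[int] = []
    mean_jj = float(np.mean(np.diff(peaks)))

    # (b) close-pair removal: drop the smaller-amplitude peak
    changed = True
    while changed and len(peaks) >= 2:
        changed = False
        for i in range(len(peaks) - 1):
            if peaks[i + 1] - peaks[i] < params.low_factor * mean_jj:
                # ties keep the earlier peak
                drop = i if x[peaks[i]] < x[peaks[i + 1]] else i + 1
                removed.append(peaks.pop(drop))
                changed = True
                break

    # (c) missed-beat re-search at a relaxed threshold
    recovered: list[int] = []
    arrhythmia: list[tuple[int, int]] = []
    if len(peaks) >= 2:
        mean_jj = float(np.mean(np.diff(peaks)))
        min_gap = params.min_gap_samples(fs)
        relaxed = effective_threshold(x, params) * params.threshold_relax
        out = [peaks[0]]
        for nxt in peaks[1:]:
            prev = out[-1]
            if nxt - prev > params.high_factor * mean_jj:
                lo, hi = prev + min_gap, nxt - min_gap
                found = []
                if hi > lo:
                    inner = detect_candidates(
                        x[lo:hi], fs, params, threshold=relaxed, normalize=False
                    )
                    found = [int(lo + p) for p in inner]
                if found:
                    recovered.extend(found)
                    out.extend(found)
                else:
                    arrhythmia.append((prev, nxt))
            out.append(nxt)
        peaks = out

    mean_jj = float(np.mean(np.diff(peaks))) if len(peaks) >= 2 else float("nan")
    return JPeakResult(
        peaks=np.asarray(peaks, dtype=int),
        mean_jj=mean_jj,
        removed=np.asarray(sorted(removed), dtype=int),
        recovered=np.asarray(sorted(recovered), dtype=int),
        arrhythmia_gaps=arrhythmia,
    )


def detect_jpeaks(bcg: np.ndarray, fs: float, params: DetectorParams | None = None) -> JPeakResult:
    """Full detection: candidate search followed by the correction pass."""
    params = params or DetectorParams()
    return correct_peaks(detect_candidates(bcg, fs, params), bcg, fs, params)
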