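"""Synthetic bed-pressure signal generator with ground truth.

Emulates the additive signal model of a piezoelectric mattress sensor:
the recorded channel f(t) is the sum of a clean physiological signal
x(t) — a quasi-periodic respiration wave plus a ballistocardiogram (BCG)
pulse train — and broadband interference n(t), on top of a DC baseline.
Apnea episodes are injected by holding the respiration wave at its
end-inhalation (trough) or end-exhalation (peak) level while the cardiac
pulse train continues, which is the signature an apnea screen must detect.

Every record comes with a :class:`GroundTruth` carrying the true J-peak
positions, breath-cycle boundaries, per-frame labels and the noise-free
component channels, so downstream stages can be validated without any
recorded data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "RawRecord",
    "make_bcg_template",
    "make_breath_cycle",
    "synthesize",
    "noise_sd_for_snr",
    "write_annotations",
    "read_annotations",
]

APNEA_TYPES = ("post_inhalation", "post_exhalation")

#: fraction of a frame that must lie inside apnea events for the frame
#: to carry the "apnea" ground-truth label
APNEA_FRAME_FRACTION = 0.30


@dataclass(frozen=True)
class RawRecord:
    """One pressure channel: samples in arbitrary units plus sampling rate."""

    samples: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("record needs at least 2 samples in one channel")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Amplitudes are relative (arbitrary sensor units); the respiration wave
    dominates the raw mattress signal, the BCG rides on top of it.  Apnea
    events are (start_s, duration_s, type) with type ``post_inhalation``
    (breath held at the trough, i.e. end of inspiration) or
    ``post_exhalation`` (held at the peak).
    """

    fs: float = 50.0
    duration: float = 60.0
    hr_bpm: float = 70.0
    hr_jitter: float = 0.0
    breath_rate_hz: float = 0.3
    breath_amp: float = 1.0
    bcg_amp: float = 0.3
    noise_sd: float = 0.0
    motion_events: tuple = ()
    apnea_events: tuple = ()
    dc_offset: float = 0.0
    exhale_end_frac: float = 0.4
    apnea_attenuation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "motion_events", tuple(tuple(e) for e in self.motion_events))
        object.__setattr__(self, "apnea_events", tuple(tuple(e) for e in self.apnea_events))
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 0 < self.breath_rate_hz < self.fs / 2:
            raise ValueError("breath_rate_hz must lie in (0, fs/2)")
        if not 0 < self.exhale_end_frac < 1:
            raise ValueError("exhale_end_frac must lie in (0, 1)")
        if not 0 <= self.apnea_attenuation < 1:
            raise ValueError("apnea_attenuation must lie in [0, 1)")
        events = sorted(self.apnea_events, key=lambda e: e[0])
        for ev in events:
            start, dur, kind = ev
            if kind not in APNEA_TYPES:
                raise ValueError(f"unknown apnea type {kind!r}")
            if start < 0 or dur <= 0 or start + dur > self.duration:
                raise ValueError(f"apnea event {ev} outside [0, duration]")
        for a, b in zip(events, events[1:]):
            if a[0] + a[1] > b[0]:
                raise ValueError(f"apnea events overlap: {a} and {b}")


@dataclass
class GroundTruth:
    """Noise-free truth accompanying a synthetic record.

    ``frames`` are half-open [start, end) sample intervals spanning one
    breath cycle each (trough to trough); ``frame_labels`` holds one
    ``normal``/``apnea`` label per frame.
    """

    j_peak_samples: np.ndarray
    breath_trough_samples: np.ndarray
    frames: list[tuple[int, int]]
    frame_labels: list[str]
    apnea_spans: list[tuple[int, int, str]]
    clean_respiration: np.ndarray | None = None
    clean_bcg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.j_peak_samples = np.asarray(self.j_peak_samples, dtype=int)
        self.breath_trough_samples = np.asarray(self.breath_trough_samples, dtype=int)
        if np.any(np.diff(self.j_peak_samples) <= 0):
            raise ValueError("j_peak_samples must be strictly increasing")
        if len(self.frames) != len(self.frame_labels):
            raise ValueError("one label per frame required")


# ---------------------------------------------------------------------------
# component waveforms

# H..N lobe placement as fractions of the beat, signed amplitudes relative to
# J; systolic complex (H, I, J, K) followed by the smaller diastolic tail
# (L, M, N), J the global maximum.
_BCG_LOBES = (
    ("H", 0.16, 0.35),
    ("I", 0.25, -0.55),
    ("J", 0.34, 1.00),
    ("K", 0.43, -0.65),
    ("L", 0.54, 0.38),
    ("M", 0.66, -0.24),
    ("N", 0.78, 0.14),
)
_BCG_SIGMA_FRAC = 0.030  # Gaussian lobe width as a fraction of the beat


def make_bcg_template(fs: float, beat_duration: float) -> np.ndarray:
    """One cardiac cycle of a ballistocardiogram, peak-normalized to 1.

    The waveform is a sum of Gaussian-windowed lobes at fixed phase
    offsets producing the H, I, J, K, L, M, N extrema sequence with J the
    dominant positive peak; its energy sits in the 0.5-20 Hz band
    (truncated at Nyquist for low sampling rates).

    Parameters
    ----------
    fs : sampling rate in Hz, must be >= 25
    beat_duration : cardiac cycle length in seconds, in [0.3, 1.2]
    """
    if fs < 25:
        raise ValueError(f"fs must be >= 25 Hz, got {fs}")
    if not 0.3 <= beat_duration <= 1.2:
        raise ValueError(f"beat_duration must lie in [0.3, 1.2] s, got {beat_duration}")
    n = int(round(beat_duration * fs))
    t = np.arange(n) / fs
    sigma = _BCG_SIGMA_FRAC * beat_duration
    w = np.zeros(n)
    for _, frac, amp in _BCG_LOBES:
        w += amp * np.exp(-0.5 * ((t - frac * beat_duration) / sigma) ** 2)
    return w / np.max(w)


def bcg_j_offset(fs: float, beat_duration: float) -> int:
    """Sample offset of the J-peak inside the template."""
    return int(np.argmax(make_bcg_template(fs, beat_duration)))


def make_breath_cycle(n: int, exhale_end_frac: float = 0.4) -> np.ndarray:
    """One respiration cycle over ``n`` samples as an asymmetric raised cosine.

    Phase 0 is the trough (end of inspiration); the wave rises to the peak
    (end of exhalation) at phase ``exhale_end_frac`` and falls back to the
    trough, matching the pressure-sensor convention that exhalation ends at
    the peak of the breath wave.  Range is [-1, 1].
    """
    phase = np.arange(n) / n
    return _breath_value(phase, exhale_end_frac)


def _breath_value(phase: np.ndarray, f: float) -> np.ndarray:
    phase = np.asarray(phase, dtype=float) % 1.0
    rising = phase < f
    out = np.empty_like(phase)
    out[rising] = -np.cos(np.pi * phase[rising] / f)
    out[~rising] = np.cos(np.pi * (phase[~rising] - f) / (1.0 - f))
    return out


def noise_sd_for_snr(config: SynthConfig, snr_db: float, reference: str = "mixture") -> float:
    """Noise SD giving the requested SNR against a clean signal component.

    Synthesizes the noise-free record once, measures the mean power of the
    chosen reference — the full respiration+BCG mixture (default), or the
    single component named ``"respiration"`` or ``"bcg"`` — and returns
    the Gaussian noise SD whose power is ``snr_db`` decibels below it.
    The components differ by an order of magnitude in power, so noise
    levels for experiments that stress one component are quoted against
    that component.
    """
    clean_cfg = replace(config, noise_sd=0.0)
    _, gt = synthesize(clean_cfg)
    if reference == "mixture":
        clean = gt.clean_respiration + gt.clean_bcg
    elif reference == "respiration":
        clean = gt.clean_respiration
    elif reference == "bcg":
        clean = gt.clean_bcg
    else:
        raise ValueError(f"unknown SNR reference {reference!r}")
    power = float(np.mean(clean**2))
    return float(np.sqrt(power / 10.0 ** (snr_db / 10.0)))


# ---------------------------------------------------------------------------
# synthesis


def synthesize(config: SynthConfig) -> tuple[RawRecord, GroundTruth]:
    """Generate one pressure recording plus its ground truth.

    The emitted signal is ``dc_offset + respiration + bcg + motion + noise``
    exactly; during each apnea event the respiration component is held at
    the event-type level (trough for post-inhalation, peak for
    post-exhalation) with its oscillation attenuated to
    ``apnea_attenuation`` of normal, while the BCG train continues.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    # -- respiration with apnea holds
    phase = (config.breath_rate_hz * t) % 1.0
    resp_norm = _breath_value(phase, config.exhale_end_frac)
    in_apnea = np.zeros(n, dtype=bool)
    apnea_spans: list[tuple[int, int, str]] = []
    for start_s, dur_s, kind in sorted(config.apnea_events, key=lambda e: e[0]):
        i0 = int(round(start_s * fs))
        i1 = min(int(round((start_s + dur_s) * fs)), n)
        hold = -1.0 if kind == "post_inhalation" else 1.0
        resp_norm[i0:i1] = hold + config.apnea_attenuation * (resp_norm[i0:i1] - hold)
        in_apnea[i0:i1] = True
        apnea_spans.append((i0, i1, kind))
    clean_resp = config.breath_amp * resp_norm

    # breath-cycle boundaries: phase wraps outside apnea events
    wraps = np.flatnonzero(np.diff(phase) < 0) + 1
    troughs = np.concatenate(([0], wraps)) if phase[0] < 1e-12 else wraps
    troughs = troughs[~in_apnea[troughs]]

    # -- BCG pulse train
    mean_rr = 60.0 / config.hr_bpm
    beat_dur = float(np.clip(mean_rr * 0.92, 0.3, 1.2))
    template = config.bcg_amp * make_bcg_template(fs, beat_dur)
    j_off = int(np.argmax(template))
    clean_bcg = np.zeros(n)
    j_peaks: list[int] = []
    t_beat = 0.0
    while t_beat < config.duration:
        i0 = int(round(t_beat * fs))
        seg = template[: max(0, n - i0)]
        clean_bcg[i0 : i0 + seg.size] += seg
        if i0 + j_off < n:
            j_peaks.append(i0 + j_off)
        rr = mean_rr + (rng.normal(0.0, config.hr_jitter) if config.hr_jitter > 0 else 0.0)
        t_beat += max(rr, 0.3)

    # -- motion artifacts: exponentially decaying random transients
    motion = np.zeros(n)
    for start_s, dur_s, amp in config.motion_events:
        i0 = int(round(start_s * fs))
        i1 = min(int(round((start_s + dur_s) * fs)), n)
        if i1 <= i0:
            continue
        tt = np.arange(i1 - i0) / fs
        envelope = np.exp(-3.0 * tt / dur_s)
        motion[i0:i1] += amp * envelope * rng.standard_normal(i1 - i0)

    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    signal = config.dc_offset + clean_resp + clean_bcg + motion + noise

    frames = [(int(a), int(b)) for a, b in zip(troughs, troughs[1:])]
    labels = [
        "apnea" if np.mean(in_apnea[a:b]) >= APNEA_FRAME_FRACTION else "normal"
        for a, b in frames
    ]

    record = RawRecord(
        samples=signal,
        fs=fs,
        meta={"source": "bedapnea.synth", "seed": config.seed, "duration_s": config.duration},
    )
    gt = GroundTruth(
        j_peak_samples=np.asarray(j_peaks, dtype=int),
        breath_trough_samples=troughs.astype(int),
        frames=frames,
        frame_labels=labels,
        apnea_spans=apnea_spans,
        clean_respiration=clean_resp,
        clean_bcg=clean_bcg,
    )
    return record, gt


# ---------------------------------------------------------------------------
# annotation I/O

_ANNOT_HEADER = ["kind", "start_sample", "end_sample", "label"]


def write_annotations(gt: GroundTruth, path: str | Path) -> None:
    """Write ground-truth annotations to CSV (kind,start_sample,end_sample,label)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOT_HEADER)
        for i0, i1, kind in gt.apnea_spans:
            writer.writerow(["apnea", i0, i1, kind])
        for idx in gt.j_peak_samples:
            writer.writerow(["jpeak", idx, idx + 1, ""])
        for idx in gt.breath_trough_samples:
            writer.writerow(["trough", idx, idx + 1, ""])
        for (a, b), lab in zip(gt.frames, gt.frame_labels):
            writer.writerow(["frame", a, b, lab])


def read_annotations(path: str | Path) -> GroundTruth:
    """Read an annotation CSV back into a GroundTruth (clean channels absent)."""
    apnea, jpeaks, troughs, frames, labels = [], [], [], [], []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _ANNOT_HEADER:
            raise ValueError(f"unexpected annotation header {header!r}")
        for kind, a, b, lab in reader:
            a, b = int(a), int(b)
            if kind == "apnea":
                apnea.append((a, b, lab))
            elif kind == "jpeak":
                jpeaks.append(a)
            elif kind == "trough":
                troughs.append(a)
            elif kind == "frame":
                frames.append((a, b))
                labels.append(lab)
            else:
                raise ValueError(f"unknown annotation kind {kind!r}")
    return GroundTruth(
        j_peak_samples=np.asarray(jpeaks, dtype=int),
        breath_trough_samples=np.asarray(troughs, dtype=int),
        frames=frames,
        frame_labels=labels,
        apnea_spans=apnea,
    )
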