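"""Canned study-condition experiments on synthetic recordings.

These protocols fix the conditions under which the pipeline's headline
behaviors are measured: breathing rates drawn uniformly from the normal
0.2-0.4 Hz range, additive Gaussian noise 10 dB below the clean mixture
(or below the BCG component for beat-detection stress tests), apnea
episodes injected as post-inhalation/post-exhalation holds.  They are
used by the acceptance checks and the example scripts alike.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .features import FEATURE_NAMES, default_template, segment_breath_frames, similarity
from .io import features_table, run_pipeline
from .jpeaks import detect_jpeaks
from .synth import SynthConfig, synthesize, noise_sd_for_snr
from .wavelets import dominant_frequency, separate

__all__ = [
    "mean_similarity",
    "separation_dominant_frequencies",
    "jpeak_scores",
    "labeled_feature_set",
    "subject_config",
]


def _mix_seed(seed: int, offset: int) -> int:
    return int((seed * 1009 + offset) % (2**31 - 1))


def subject_config(seed: int, with_apnea: bool, duration: float = 60.0) -> SynthConfig:
    """One synthetic 'subject': random breath rate and heart rate per seed.

    Apnea subjects get one post-inhalation and one post-exhalation hold
    of 14 s each; noise is set to 10 dB below the clean mixture.
    """
    rng = np.random.default_rng(seed)
    events = ()
    if with_apnea:
        events = ((0.2 * duration, 14.0, "post_inhalation"),
                  (0.63 * duration, 14.0, "post_exhalation"))
    cfg = SynthConfig(
        duration=duration,
        breath_rate_hz=float(rng.uniform(0.2, 0.4)),
        hr_bpm=float(rng.uniform(60, 90)),
        hr_jitter=0.02,
        seed=seed,
        apnea_events=events,
    )
    return replace(cfg, noise_sd=noise_sd_for_snr(cfg, 10.0))


def apnea_cover_fraction(frame_start: int, frame_end: int, spans) -> float:
    covered = sum(
        max(0, min(b, frame_end) - max(a, frame_start)) for a, b, _ in spans
    )
    return covered / (frame_end - frame_start)


def mean_similarity(n_frames: int, apnea: bool, seed: int) -> tuple[float, int]:
    """Mean waveform-similarity xi (percent) over synthetic breath frames.

    Generates subjects until ``n_frames`` eligible frames are collected:
    normal frames must not touch an apnea episode, apnea frames must lie
    at least 90% inside one.  Returns (mean xi, frames used).
    """
    template = default_template()
    xis: list[float] = []
    k = 0
    while len(xis) < n_frames and k < 200:
        cfg = subject_config(_mix_seed(seed, k), with_apnea=apnea)
        record, gt = synthesize(cfg)
        sep = separate(record)
        for fr in segment_breath_frames(sep.respiration, record.fs):
            frac = apnea_cover_fraction(fr.start_sample, fr.end_sample, gt.apnea_spans)
            eligible = frac >= 0.9 if apnea else frac == 0.0
            if eligible:
                xis.append(similarity(fr, template))
        k += 1
    xis = xis[:n_frames]
    return float(np.mean(xis)), len(xis)


def separation_dominant_frequencies(seed: int = 7) -> tuple[float, float]:
    """Dominant frequencies (Hz) of the separated respiration and BCG channels.

    Fixed recording: 60 s at 50 Hz, 0.3 Hz breathing, 70 bpm, noise 10 dB
    below the clean mixture.  The DC bin is excluded on the respiration
    side.
    """
    cfg = SynthConfig(duration=60.0, breath_rate_hz=0.3, hr_bpm=70.0, seed=seed)
    cfg = replace(cfg, noise_sd=noise_sd_for_snr(cfg, 10.0))
    record, _ = synthesize(cfg)
    sep = separate(record)
    f_resp = dominant_frequency(sep.respiration, record.fs, fmin=0.05)
    f_bcg = dominant_frequency(sep.bcg, record.fs)
    return f_resp, f_bcg


def jpeak_scores(seed: int, snr_db: float | None = None, tol: int = 2) -> tuple[float, float]:
    """Sensitivity and PPV of J-peak detection on one synthetic subject.

    ``snr_db=None`` means a noise-free recording; otherwise Gaussian noise
    is added at the given SNR relative to the BCG component (the channel
    the detector works on).
    """
    cfg = SynthConfig(duration=60.0, hr_bpm=72, hr_jitter=0.02, seed=seed)
    if snr_db is not None:
        cfg = replace(cfg, noise_sd=noise_sd_for_snr(cfg, snr_db, reference="bcg"))
    record, gt = synthesize(cfg)
    res = detect_jpeaks(separate(record).bcg, record.fs)
    truth = gt.j_peak_samples
    if truth.size == 0 or res.peaks.size == 0:
        return 0.0, 0.0
    sens = float(np.mean([np.any(np.abs(res.peaks - t) <= tol) for t in truth]))
    ppv = float(np.mean([np.any(np.abs(truth - p) <= tol) for p in res.peaks]))
    return sens, ppv


def labeled_feature_set(seeds, with_apnea: bool = True, label_fraction: float = 0.3):
    """Per-frame feature matrix X, labels y and subject ids for a seed list.

    Runs the full pipeline on each subject and labels a frame apnea when
    at least ``label_fraction`` of it lies inside an injected episode.
    """
    X, y, groups = [], [], []
    for seed in seeds:
        cfg = subject_config(seed, with_apnea=with_apnea)
        record, gt = synthesize(cfg)
        out = run_pipeline(record)
        for _, row in out["features"].iterrows():
            frac = apnea_cover_fraction(int(row.frame_start), int(row.frame_end), gt.apnea_spans)
            X.append([row[name] for name in FEATURE_NAMES])
            y.append(1 if frac >= label_fraction else 0)
            groups.append(seed)
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int), np.asarray(groups)
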