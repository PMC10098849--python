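from dataclasses import replace

import numpy as np
import pytest

import bedapnea as ba

FEATURES = ("avnn_s", "sdnn_s", "cv", "ti_s", "n_beats", "similarity_pct")


@pytest.fixture(scope="session")
def clean_record():
    """60 s clean recording: 0.3 Hz breathing, 72 bpm, no noise."""
    cfg = ba.SynthConfig(duration=60.0, breath_rate_hz=0.3, hr_bpm=72, seed=1)
    record, gt = ba.synthesize(cfg)
    return cfg, record, gt


@pytest.fixture(scope="session")
def clean_separated(clean_record):
    _, record, _ = clean_record
    return ba.separate(record)


@pytest.fixture(scope="session")
def noisy_record():
    """Same recording at 10 dB mixture SNR, seed 7."""
    cfg = ba.SynthConfig(duration=60.0, breath_rate_hz=0.3, hr_bpm=70, seed=7)
    cfg = replace(cfg, noise_sd=ba.noise_sd_for_snr(cfg, 10.0))
    record, gt = ba.synthesize(cfg)
    return cfg, record, gt


def detection_scores(detected, truth, tol=2):
    """Sensitivity and PPV of detected indices against truth, +/- tol samples."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if truth.size == 0 or detected.size == 0:
        return 0.0, 0.0
    sens = np.mean([np.any(np.abs(detected - t) <= tol) for t in truth])
    ppv = np.mean([np.any(np.abs(truth - d) <= tol) for d in detected])
    return float(sens), float(ppv)


def apnea_overlap_fraction(frame_start, frame_end, apnea_spans):
    """Fraction of [frame_start, frame_end) covered by apnea spans."""
    length = frame_end - frame_start
    covered = 0
    for a, b, _ in apnea_spans:
        covered += max(0, min(b, frame_end) - max(a, frame_start))
    return covered / length
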