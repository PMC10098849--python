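"""Synthesize a bed-pressure recording with two apnea episodes.

Builds one minute of signal at 50 Hz — 0.3 Hz breathing, 70 bpm cardiac
pulse train, noise 10 dB below the clean mixture — and prints what the
ground truth contains.
"""

from dataclasses import replace

from bedapnea import SynthConfig, noise_sd_for_snr, synthesize

cfg = SynthConfig(
    duration=60.0,
    breath_rate_hz=0.3,
    hr_bpm=70.0,
    seed=42,
    apnea_events=((12.0, 14.0, "post_inhalation"), (38.0, 14.0, "post_exhalation")),
)
cfg = replace(cfg, noise_sd=noise_sd_for_snr(cfg, 10.0))
record, gt = synthesize(cfg)

print(f"samples            : {record.samples.size} at {record.fs:g} Hz")
print(f"true J-peaks       : {gt.j_peak_samples.size} (heart beats)")
print(f"true breath troughs: {gt.breath_trough_samples.size}")
print(f"breath frames      : {len(gt.frames)}, labels "
      f"{dict((l, gt.frame_labels.count(l)) for l in set(gt.frame_labels))}")
# The two holds silence respiration while the cardiac train keeps going;
# frames overlapping them carry the 'apnea' label.
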