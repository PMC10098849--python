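# Methods

`bedapnea` implements an unobtrusive sleep-apnea screening pipeline for a
single bed-pressure channel sampled at 50 Hz, of the kind produced by a
piezoelectric (PVDF) film under a mattress. This note records the models,
the parameters that matter, and the design choices made where the
procedure left room.

## Signal model and the synthetic generator

The recorded channel is modeled additively,

    f(t) = DC + r(t) + c(t) + m(t) + n(t),

with `r` the respiration wave, `c` the ballistocardiogram (BCG) pulse
train, `m` optional motion transients and `n` white Gaussian noise. The
generator (`bedapnea.synth`) emits this sum exactly together with the
noise-free components and event annotations, so every later stage can be
validated without recorded data.

**Respiration** is an asymmetric raised cosine at a configurable rate
(default 0.3 Hz; the normal range is 0.2–0.4 Hz). Phase 0 is the trough
(end of inspiration); the wave reaches the peak (end of exhalation) at a
configurable fraction of the cycle (default 0.4). The asymmetry makes
"peak" and "trough" semantically unambiguous, at the cost of harmonics
above the fundamental.

**BCG** is a sum of seven Gaussian-windowed lobes per beat producing the
H, I, J, K, L, M, N extrema sequence with J the dominant positive peak
(signed amplitudes 0.35, −0.55, 1, −0.65, 0.38, −0.24, 0.14 of J; lobe
width 3% of the beat). The template is peak-normalized and its energy
sits in roughly 4–16 Hz at typical beat lengths, inside the 0.5–20 Hz
band expected of a BCG. Beat-to-beat intervals are 60/HR plus optional
Gaussian jitter, floored at 0.3 s. Default amplitudes are respiration
1.0, BCG 0.3 — the breath dominates a raw mattress signal by roughly
this ratio.

**Apnea episodes** hold the respiration wave at the trough
(post-inhalation hold) or peak (post-exhalation hold) level while the
cardiac train continues. The residual oscillation is attenuated to 5%
of normal (not 0) so the channel stays continuous for segmentation; the
factor is configurable. A ground-truth frame is labeled "apnea" when at
least 30% of its samples lie inside an episode — enough to mark the
long straddling frames without polluting neighbors that merely touch an
event boundary.

**Noise levels** are specified as SNR relative to a named reference via
`noise_sd_for_snr(config, snr_db, reference)`. The clean mixture is the
default reference; because respiration carries an order of magnitude
more power than the BCG, experiments that stress the beat detector
quote SNR against the BCG component instead. A single mixture-referenced
figure would say nothing about the weaker component: at 10 dB below the
mixture the J-peak sits at about 1.4× the in-band noise SD, below what
any amplitude-threshold detector can work with.

**What the generator does not emulate:** baseline wander and sensor
drift, position-dependent waveform changes (turning over), obstructive
apnea with continued thoracic effort, snoring oscillations, and the
coupling between breathing and beat amplitude. Passing tests therefore
demonstrate the pipeline's correctness under the stated signal model,
not clinical performance on recorded subjects.

## Wavelet separation

The channel is decomposed with a 5-level Daubechies-5 (db5) DWT with
symmetric boundary extension (minimal edge artifacts; perfect
reconstruction holds to machine precision). At 50 Hz the dyadic bands
are D1 12.5–25, D2 6.25–12.5, D3 3.125–6.25, D4 1.5625–3.125, D5
0.7813–1.5625, A5 0–0.7813 Hz. Respiration is reconstructed from A5
alone by default (D5 optionally included — it carries part of the breath
wave but also body movement), then the DC baseline is removed by mean
subtraction (linear detrend available). The BCG is reconstructed from
D1–D3 after soft-thresholding D1 with the universal threshold
λ = σ̂·√(2 ln N), σ̂ = median(|D1|)/0.6745; D2–D3 thresholding is
configurable but off by default, since the universal threshold is
larger than the BCG's own coefficients at realistic amplitudes and
would shrink the signal along with the noise. For sampling rates other
than 50 Hz the band plan is recomputed so respiration keeps 0–0.8 Hz
and the BCG keeps the detail levels overlapping 3–15 Hz.

## J-peak detection

The BCG channel is normalized to unit maximum per processing window, so
the base amplitude threshold USH = 0.02 is a fraction of the peak.
Candidates are local maxima above USH + bias, accepted greedily in
descending height with a 220 ms refractory window (equivalently the
0.22 s minimum-interval rule; both are 11 samples at 50 Hz and both are
enforced). Ties keep the earlier peak.

The **adaptive bias** is derived from a two-means split of the candidate
heights: the secondary H/L/N lobes of a realistic BCG cycle stand well
above 2% of the J-peak, so a fixed USH accepts several maxima per beat.
The tall cluster (J-peaks) and the short cluster (secondary lobes,
noise) are separated by 1-D two-means; the threshold is placed in the
valley only when the cluster separation exceeds twice the sum of the
within-cluster SDs (a d′-style guard), otherwise the bias stays 0 so a
unimodal height distribution — e.g. an isolated clean pulse train — is
untouched. `adaptive_bias=False` restores the fixed threshold.

The correction pass computes the mean inter-peak interval of the window
(`mean_jj`): adjacent peaks closer than 0.4·mean_jj lose the
smaller-amplitude member; gaps wider than 1.66·mean_jj are re-searched
once at half the effective threshold (relaxation factor 0.5,
configurable); gaps that still yield nothing are recorded as arrhythmia.
The refractory window is applied from each accepted peak (greedy), and
the pass is a fixed point on already-valid trains.

## Breath frames and features

Troughs of the respiration channel are minima with prominence above
0.35 of the robust half-amplitude (2nd–98th percentile range / 2), at
least 1 s apart. Frames are trough-to-trough slices clipped to 1–15 s
(~4–60 breaths/min); longer stretches — sustained apnea — are split
into equal sub-frames and flagged, and a channel with no troughs at all
falls back to fixed 5 s flagged frames. Because the respiration channel
keeps only 0–0.78 Hz, the minimum of the asymmetric breath wave shifts
by a few samples (~0.1 s at 50 Hz); the offset is systematic and cancels
in trough-to-trough durations.

Per frame, with B_n the J-peak samples inside and F_n the sampling
rate: AVNN = mean((B_{n+1}−B_n)/F_n), SDNN their sample SD (n−1
denominator; 0 for a single interval), CV = SDNN/AVNN (the conventional
dimensionless form; the reciprocal is available behind a switch),
Ti = frame length/F_n, and the beat count N. AVNN/SDNN/CV are undefined
(NaN) below two beats; such frames are excluded from classifier training
and median-imputed at prediction.

**Waveform similarity ξ.** The standard template is one raised-cosine
breath cycle (user-replaceable), linearly resampled to the frame length.
Frame and template are reduced to zero mean and unit energy — the
package's reading of "normalizing" the waveform so that breath intensity
differences between people drop out — and

    ξ = max_n R_{f,g}(n) / max_n R_{f,f}(n) × 100,

with R the full cross-correlation over all lags. With unit-energy
normalization the denominator is 1 and Cauchy–Schwarz bounds ξ at 100;
negative maxima clamp to 0. A normal frame scores near 100; a frame
inside an apnea hold retains only the 5% residual plus low-passed noise
and scores well below 40. ξ degrades roughly linearly with frame
rotation (about 1 point per 2% shift) because the lag search is linear,
not circular.

## Classifier

Binomial logistic regression on the six features, fit by maximizing the
exact Bernoulli log-likelihood with Newton's method (default) or
gradient ascent; both use step halving, so the likelihood trace is
non-decreasing, and a 1e-8 ridge on the Hessian keeps near-separable
problems finite (ξ alone nearly separates the synthetic classes).
Features are centered/scaled internally for conditioning; weights are
reported on both scales and predictions are scale-equivariant.
Convergence: max |Δw| < 1e-8 or 100 iterations. The decision threshold
is v = 0.5 with ties going to apnea. The training protocol mirrors a
subject-wise split: synthetic "subjects" are distinct seeds, and no
frame from a test subject enters training.

## Agreement evaluation

Pearson correlation and Bland–Altman limits of agreement d̄ ± 1.96·SD
(n−1 SD). The difference direction is fixed as estimate − reference;
points exactly on a limit count as within.

## Problem sizes

The bundled experiments use 60–120 s records at 50 Hz (3000–6000
samples), 16 training + 4 test synthetic subjects (~200 frames), 50
frames per similarity condition, and 20 seeds for Monte-Carlo checks —
sizes at which every behavior of interest is already stable and the full
suite runs in seconds.

## Known limitations

- At 10 dB below the full mixture the beat-interval features (AVNN,
  SDNN, CV, N) are unreliable; classification then rests on ξ and Ti.
  This mirrors the physical situation: the cardiac signal is the faint
  component of a mattress recording.
- The adaptive bias assumes J-peaks form the tallest height cluster; a
  recording dominated by motion spikes would need artifact rejection
  first (motion transients are off by default in the generator).
- EDF input is not supported; CSV is the only interchange format.
- `mean_jj` is computed over the processing window, not per breath
  frame, when detection is run outside frame context.
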