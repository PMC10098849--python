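# File formats

All interchange files are plain CSV/JSON/YAML. Sample indices are
0-based, event intervals are half-open `[start, end)`, times are in
seconds.

## Signal CSV
`time_s,value` — one row per sample. Read back with the sampling rate
inferred from the timestamps; jitter above 0.1/fs is refused. A
single-column `value` file is accepted when the sampling rate is
declared by the caller (`read_signal(path, fs=...)`).

## Annotation CSV
`kind,start_sample,end_sample,label` with `kind` one of:
- `apnea` — an injected episode; `label` is `post_inhalation` or
  `post_exhalation`.
- `jpeak` / `trough` — single-sample events (`end = start + 1`).
- `frame` — one breath frame; `label` is `normal` or `apnea`.

## Peaks CSV
`sample_index,time_s,amplitude,flag` with `flag` ∈ {accepted, recovered}.

## Features CSV
`frame_start,frame_end,avnn_s,sdnn_s,cv,ti_s,n_beats,similarity_pct,fallback`.
NaN marks an undefined feature (fewer than two beats in the frame).

## Calls CSV
`frame_start,frame_end,p_apnea,label` (label 1 = apnea).

## Model JSON
`feature_names`, `weights` (scaled space, intercept last),
`raw_weights`, `threshold`, `center`, `scale`, `impute`.

## Pipeline config YAML
Keys mirror `bedapnea.PipelineConfig`; unknown keys are rejected.
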