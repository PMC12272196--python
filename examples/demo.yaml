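# Demo study: 3 subjects, 10-minute stimulation-night excerpts.
seed: 7
n_subjects: 3
raw_sampling_rate: 500
recording_duration_s: 600
stage_schedule:
  arousal_rate_per_hour: 4.0
cue_model:
  target_total_tones: 240
spindle_model:
  amplitude_ratio: 8.0
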