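# Parameter-recovery validation: high-SNR, fixed-duration bursts in stable N2,
# flat learning curves so the random-block penalty is identifiable.
seed: 31
n_subjects: 2
raw_sampling_rate: 500
recording_duration_s: 900
stage_schedule:
  cycle: [["N2", 40]]
  arousal_rate_per_hour: 0.0
spindle_model:
  density_per_min: {"N2/cue": 3.0, "N2/nocue": 3.0, "N2/other": 3.0}
  duration_range_s: [0.8, 0.8]
  amplitude_ratio: 10.0
behaviour_model:
  learning_curve:
    S1: [0.0, 0.06]
    S2: [0.0, 0.06]
    S3: [0.0, 0.06]
    S4: [0.0, 0.06]
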