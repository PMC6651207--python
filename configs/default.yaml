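# Study-scale run: 24 subjects, 12,000 images, 20/2/2 subject split.
n_subjects: 24
fs: 128.0
cohort_seed: 7
preprocess:
  highpass_cutoff: 1.0
  lowpass_cutoff: 50.0
  filter_order: 5
max_lag: 0
analysis_subtasks: [KATA-III, Plan]
soft_sensor:
  conv_blocks: [[32, [3, 3], [2, 2]], [64, [3, 3], [2, 2]]]
  dense_units: 128
  learning_rate: 0.001
  epochs: 10
  batch_size: 32
  seed: 0
output_dir: leansense_run
write_recordings: false
write_images: false
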