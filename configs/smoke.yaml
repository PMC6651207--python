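# Quick end-to-end check: 4 subjects, 2 epochs, ~1 minute on one CPU.
n_subjects: 4
fs: 128.0
cohort_seed: 11
soft_sensor:
  epochs: 2
  seed: 11
output_dir: leansense_smoke
write_recordings: false
write_images: false
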