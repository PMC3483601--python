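# Shared configuration for the numbered analysis drivers.
# One synthetic profiling study: 2 genotypes x (induced, uninduced) x 3
# replicates of head libraries, one planted 5-fold induction effect on the
# mir-1 5p arm, and 6 CAG-repeat reads spiked into the first sample.
output_dir: scratch/pipeline
seed: 42
replicates: 3
dispersion: 0.05
error_rate: 0.0
effect_map:
  mir-1_5p:
    induced: 5.0
spike_n: 6
spike_edit_profile: {0: 2, 1: 3, 2: 1}
reference:
  n_stemloops: 8
  mean_expression_range: [40.0, 400.0]
  transgene_repeat_units: 80
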