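# One moderate-effect one-way DMI on the two-autosome reference genome,
# mapped from 10 replicate populations sampled at generations 10 and 50.
genome:
  chrom_length: 20800000
  markers_per_chromosome: 500
  arm_rate: 1.0e-7      # 10 cM/Mb chromosome arms
  center_rate: 1.0e-9   # 0.1 cM/Mb central domain
dmis:
  mode: two_locus
  s: 0.2
  interaction: one_way
  dominance_a: dominant
  dominance_b: dominant
fitness:
  composition: multiplicative
experiment:
  n_individuals: 1000
  n_replicate_pops: 10
  sample_generations: [10, 50]
  n_replicate_sets: 10
  n_neutral_sims: 150
  rng_seed: 7
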