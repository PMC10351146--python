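# Desk-scale configuration: minutes on one CPU, preserves the full design's
# regime (kinship-rate target attainable, OCS constraint active, per-phase
# historical drift matched). Counts are chosen directly rather than through
# the uniform `scale` factor so that the number of OCS sires stays large
# enough for the 0.005 kinship-rate target to be reachable.
master_seed: 1
genome:
  n_chromosomes: 5
  loci_per_chromosome: 300
  historical_trajectory:
    - {size: 150, generations: 300}
    - {size: 30, generations: 30}
    - {size: 80, generations: 30}
  n_qtl: 150
  n_neutral: 300
  base_males: 240
  base_females: 240
program:
  n_sires_pblup: 48
  n_sires_ocs: 32
evaluation:
  window_generations: 4
  n_genotyped_males: 160
  always_gblup: true
metrics:
  n_kinship_pairs: 600
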