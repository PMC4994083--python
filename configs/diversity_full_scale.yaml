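# Full-scale parameterisation of the diversity measurements: N = 2000
# individuals on 7 resources (5 consumed per species), R_Max = 300,
# equilibrated for 1e8 generations and averaged over the following 1e6.
# This is NOT a desk-scale run (days of CPU); it is provided as the
# reference configuration the headline diversity curves correspond to.
# Sweep the mutation rate and selection intensity around it, e.g.:
#   resgame sweep --axis mutation_rate --config configs/diversity_full_scale.yaml \
#       --values 1e-7,1e-6,1e-5 --w-values 0.001,1,10
community_size: 2000
num_resources: 7
num_consumed: 5
r_max: 300.0
selection_intensity: 10.0
mutation_prob: 1.0e-6
generations: 101000000
burn_in: 100000000
sampling_interval: 100
init_mode: single
master_seed: 1
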