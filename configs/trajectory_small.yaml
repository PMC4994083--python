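# Desk-scale recorded-trajectory run: a community of 100 individuals on
# 3 resources under strong selection and rare speciation.  Runs in a few
# seconds and typically shows a handful of speciation events, some of
# which coexist with the resident species for long stretches.
community_size: 100
num_resources: 3
num_consumed: 2
r_max: 30.0
selection_intensity: 10.0
mutation_prob: 5.0e-5
generations: 100000
burn_in: 0
sampling_interval: 100
init_mode: single
master_seed: 7
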