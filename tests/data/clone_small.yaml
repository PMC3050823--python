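alpha_preset: neutral-hi
experiment: clone
params:
  mutations_per_generation: 0
replicates: 3
schema_version: 1
seed: 20260920
seeding:
  P0: 0.0
stop:
  size_cap: 200
  t_max: 60
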