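# Desk-scale demo pipeline: 1 synthetic archetype, 3 grid values per trait,
# one N level, 1 scored year.  Runs in about a minute.
out_dir: demo_out
n_species: 1
n_levels: [360]
steps: 2
fraction: 0.3
years: 1
spin_max_cycles: 6
seed: 5
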