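# Facultative-apomict screen: 22 simulated seeds, 20 sexual + 2 pseudogamous 2/6
rng_seed: 5
output_dir: seedscreen_out
tolerance: 0.08
simulate_species:
  - species: festuca_like
    n_seeds: 22
    scenario_mix:
      "2/3": 0.90909090909
      "2/6": 0.09090909091
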