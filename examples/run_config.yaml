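# Example run configuration for the phyloroot CLI:
#   phyloroot all --config examples/run_config.yaml --outdir run/
# Every block maps onto a dataclass (WorldConfig, FilterCriteria, RunConfig);
# omitted keys keep their defaults.
world:
  n_classes_per_kingdom: 3
  n_species_per_class: 3
  n_outgroup_phyla: 24
  species_per_outgroup_phylum: 1
  stem_length: 0.5
  fast_clades: []          # e.g. [["A1", 8.0]] for a DPANN-like clade
criteria:
  e_value_max: 1.0e-5
  min_archaeal_members: 4
  partial_fraction: 0.5
  min_outgroup_phyla: 24
n_families: 50
event_rates: [0.2, 0.1, 0.1]   # p_hgt, p_paralog, p_partial
n_sites_range: [300, 600]
correction: ml-poisson
gamma_alpha: 1.0
bootstrap: 100
seed: 1
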