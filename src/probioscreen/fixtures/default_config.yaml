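# Default run configuration: the screen's own thresholds and quotas,
# executed on the packaged reference fixtures.
seed: 42
inputs:
  mode: fixtures
rapd:
  tolerance: 0.05
  cutoff: 85
selection:
  biomass_min_g_per_L: 1.0
  enzyme_min_count: 8
  biofilm_od_min: 0.8
  hydrophobicity_min_pct: 20
  autoaggregation_min_pct: 20
  autoaggregation_time_h: 1
  halo_min_mm: 1
  rare_species_biomass_floor: 0.7
  species_quota:
    Candida haemuloni: 2
    Candida parapsilosis: 3
    Debaryomyces hansenii: 2
# Patterns where the screen's documented representative differs from the
# highest-biomass member (see docs/methods.md).
representative_override:
  B: C01
  L: C17
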