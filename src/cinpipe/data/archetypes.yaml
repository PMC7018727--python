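# Bundled scenario: the four recurrent karyotype archetypes of the ex vivo
# ovarian cancer cultures, simulated on the 500 Mb toy genome and pushed
# through read-count emission, state calling and karyotype scoring.
seed: 1
simulate:
  genome: toy
  presets: [whole_chromosome, rearranged, monosomy, tetrasomy]
  n_cells: 30
  reads_per_copy: 100
  dispersion: 0.0
call:
  default_ploidy: 2
  smoothing_window: 3
score:
  euploid_ploidy: 2
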