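# One configuration for the whole analysis sequence.
# alpha_gwas is the generator-calibrated marker-selection threshold for the
# synthetic study conditions (see docs/methods.md); the flanking thresholds
# are the standard defaults of the association chain.
seed: 0
simulate: {}
thresholds:
  alpha_gwas: 1.0e-20
consensus:
  k_max: 4
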