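# Default bindings and tunable thresholds.  Values here are configuration,
# not code: users may point the engine at an edited copy.

# Maximum duplex length (paired columns) for which the nearest-neighbor
# approach is used; longer duplexes fall back to an approximative formula.
nn_length_threshold: 60

# Cmax/Cmin ratio from which one strand counts as "in excess" (F = 1).
strand_excess_ratio: 10.0

# Minimum length of a terminal all-adenine overhang treated as a
# long poly-A queue.
polya_min_length: 2

# Owczarzy 2008 competition bounds on R = sqrt(Mg_free)/monovalent:
# below the low bound monovalent ions dominate (sodium correction),
# above the high bound magnesium dominates (magnesium correction),
# in between the mixed monovalent/bivalent correction applies.
owczarzy_ratio_low: 0.22
owczarzy_ratio_high: 6.0

# Default nearest-neighbor parameter set per hybridization type.  No
# dataset ships for dnarna/rnadna/mrnarna duplexes; supply one with
# --data / --nn to compute those.
default_parameter_sets:
  dnadna: san04
  rnarna: xia98

# Default ion corrections.
default_sodium_correction:
  dnadna: owc2204
  rnarna: wet91rna
  dnarna: wet91dnarna
  rnadna: wet91dnarna
  mrnarna: wet91rna
default_magnesium_correction: owcmg08
default_mixed_correction: owcmg08

# Default sodium-equivalence method.
default_naeq: ahs01

# Default approximative formula per hybridization type.
default_approx:
  dnadna: wetdna91
  rnarna: wetrna91
  dnarna: wetdnarna91
  rnadna: wetdnarna91
  mrnarna: wetrna91

# Default denaturing-agent corrections.
default_dmso_correction: ahs01dmso
default_formamide_correction: bla96
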