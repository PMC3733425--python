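<?xml version="1.0"?>
<!-- DNA/DNA Watson-Crick nearest-neighbor parameters (Breslauer et al.
     1986), 1 M NaCl reference.  Two-class initiation: one entry when both
     terminal base pairs are A/T, another when at least one is G/C.
     Sequence notation: top 5'->3' over bottom 3'->5'; cal/mol units. -->
<data type="dnadna" id="bre86" initiation-rule="two_class"
      reference-sodium="1.0" citation="Breslauer et al. 1986">
  <neighbor sequence="AA/TT"><enthalpy>-9100</enthalpy><entropy>-24.0</entropy></neighbor>
  <neighbor sequence="AT/TA"><enthalpy>-8600</enthalpy><entropy>-23.9</entropy></neighbor>
  <neighbor sequence="TA/AT"><enthalpy>-6000</enthalpy><entropy>-16.9</entropy></neighbor>
  <neighbor sequence="CA/GT"><enthalpy>-5800</enthalpy><entropy>-12.9</entropy></neighbor>
  <neighbor sequence="GT/CA"><enthalpy>-6500</enthalpy><entropy>-17.3</entropy></neighbor>
  <neighbor sequence="CT/GA"><enthalpy>-7800</enthalpy><entropy>-20.8</entropy></neighbor>
  <neighbor sequence="GA/CT"><enthalpy>-5600</enthalpy><entropy>-13.5</entropy></neighbor>
  <neighbor sequence="CG/GC"><enthalpy>-11900</enthalpy><entropy>-27.8</entropy></neighbor>
  <neighbor sequence="GC/CG"><enthalpy>-11100</enthalpy><entropy>-26.7</entropy></neighbor>
  <neighbor sequence="GG/CC"><enthalpy>-11000</enthalpy><entropy>-26.6</entropy></neighbor>
  <initiation type="two_AT"><enthalpy>0</enthalpy><entropy>-20.1</entropy></initiation>
  <initiation type="at_least_one_GC"><enthalpy>0</enthalpy><entropy>-16.8</entropy></initiation>
  <symmetry><enthalpy>0</enthalpy><entropy>-1.4</entropy></symmetry>
</data>
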