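<?xml version="1.0"?>
<!-- RNA/RNA Watson-Crick nearest-neighbor parameters (Xia et al. 1998),
     1 M NaCl reference.  Initiation: one base entry plus a penalty per
     terminal A.U base pair.  Sequence notation: top 5'->3' over bottom
     3'->5'; cal/mol units. -->
<data type="rnarna" id="xia98" initiation-rule="base_plus_terminal_AU"
      reference-sodium="1.0" citation="Xia et al. 1998">
  <neighbor sequence="AA/UU"><enthalpy>-6820</enthalpy><entropy>-19.0</entropy></neighbor>
  <neighbor sequence="AU/UA"><enthalpy>-9380</enthalpy><entropy>-26.7</entropy></neighbor>
  <neighbor sequence="UA/AU"><enthalpy>-7690</enthalpy><entropy>-20.5</entropy></neighbor>
  <neighbor sequence="CU/GA"><enthalpy>-10480</enthalpy><entropy>-27.1</entropy></neighbor>
  <neighbor sequence="CA/GU"><enthalpy>-10440</enthalpy><entropy>-26.9</entropy></neighbor>
  <neighbor sequence="GU/CA"><enthalpy>-11400</enthalpy><entropy>-29.5</entropy></neighbor>
  <neighbor sequence="GA/CU"><enthalpy>-12440</enthalpy><entropy>-32.5</entropy></neighbor>
  <neighbor sequence="CG/GC"><enthalpy>-10640</enthalpy><entropy>-26.7</entropy></neighbor>
  <neighbor sequence="GC/CG"><enthalpy>-14880</enthalpy><entropy>-36.9</entropy></neighbor>
  <neighbor sequence="GG/CC"><enthalpy>-13390</enthalpy><entropy>-32.7</entropy></neighbor>
  <initiation type="base"><enthalpy>3610</enthalpy><entropy>-1.5</entropy></initiation>
  <initiation type="per_AU"><enthalpy>3720</enthalpy><entropy>10.5</entropy></initiation>
  <symmetry><enthalpy>0</enthalpy><entropy>-1.4</entropy></symmetry>
</data>
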