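<?xml version="1.0"?>
<!-- Unified DNA/DNA Watson-Crick nearest-neighbor parameters
     (SantaLucia & Hicks 2004), 1 M NaCl reference.
     Sequence notation: top strand 5'->3' over bottom strand 3'->5'.
     Only one orientation per stack is stored; the loader resolves the
     reverse orientation.  Units: cal/mol and cal/(mol.K). -->
<data type="dnadna" id="san04" initiation-rule="per_terminal"
      reference-sodium="1.0" citation="SantaLucia and Hicks 2004">
  <neighbor sequence="AA/TT"><enthalpy>-7900</enthalpy><entropy>-22.2</entropy></neighbor>
  <neighbor sequence="AT/TA"><enthalpy>-7200</enthalpy><entropy>-20.4</entropy></neighbor>
  <neighbor sequence="TA/AT"><enthalpy>-7200</enthalpy><entropy>-21.3</entropy></neighbor>
  <neighbor sequence="CA/GT"><enthalpy>-8500</enthalpy><entropy>-22.7</entropy></neighbor>
  <neighbor sequence="GT/CA"><enthalpy>-8400</enthalpy><entropy>-22.4</entropy></neighbor>
  <neighbor sequence="CT/GA"><enthalpy>-7800</enthalpy><entropy>-21.0</entropy></neighbor>
  <neighbor sequence="GA/CT"><enthalpy>-8200</enthalpy><entropy>-22.2</entropy></neighbor>
  <neighbor sequence="CG/GC"><enthalpy>-10600</enthalpy><entropy>-27.2</entropy></neighbor>
  <neighbor sequence="GC/CG"><enthalpy>-9800</enthalpy><entropy>-24.4</entropy></neighbor>
  <neighbor sequence="GG/CC"><enthalpy>-8000</enthalpy><entropy>-19.9</entropy></neighbor>
  <initiation type="per_GC"><enthalpy>100</enthalpy><entropy>-2.8</entropy></initiation>
  <initiation type="per_AT"><enthalpy>2300</enthalpy><entropy>4.1</entropy></initiation>
  <symmetry><enthalpy>0</enthalpy><entropy>-1.4</entropy></symmetry>
</data>
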