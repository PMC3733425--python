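# nnmelt

Melting-temperature prediction for nucleic-acid duplexes, for anyone who
designs oligonucleotides — PCR primers, hybridization probes, antisense or
siRNA work — and needs ΔH, ΔS and Tm under realistic buffer conditions.

`nnmelt` takes one or two strands as plain text (gaps written as `-`),
decomposes the aligned duplex into mutually exclusive patterns — perfectly
matching runs, single and tandem mismatches, internal loops, bulge loops,
dangling ends, poly-A tails, modified residues (inosine, locked nucleic
acids, 2-hydroxyadenosine, azobenzene), CNG triplet repeats — prices every
pattern from pluggable XML thermodynamic parameter sets, corrects for the
ionic environment (Na⁺, K⁺, Tris, Mg²⁺, dNTP) and denaturing agents (DMSO,
formamide), and returns the melting temperature.

## The model

Duplex stability is computed with the nearest-neighbor model: enthalpy and
entropy are sums over stacked base-pair doublets plus initiation terms,

    ΔH = δh_init + Σ δh_pattern,   ΔS = δs_init + Σ δs_pattern,

and the melting temperature of a two-state duplex is

    Tm(°C) = ΔH / (ΔS + R ln(C_T / F)) − 273.15,

with R = 1.9872 cal mol⁻¹ K⁻¹, C_T the total oligomer concentration, and
F = 1 for self-complementary duplexes (detected automatically, with an
entropic symmetry correction), F = 4 for equimolar non-self-complementary
strands, F = 1 again when one strand is in large excess.  When the two
strand concentrations are known the concentration term becomes
ln(C_max − C_min/2).  Self-complementary duplexes made purely of 5–7 CNG
triplet repeats melt through a hairpin and use Tm = ΔH/ΔS − 273.15.

Parameter sets are referenced to 1 M Na⁺; other buffers are handled by a
registry of published ion corrections (entropy-type corrections shift the
salt-dependent entropy; temperature-type corrections transform Tm), chosen
by the monovalent/bivalent competition ratio √[Mg²⁺]/[mon⁺], with mixed
buffers mapped to an equivalent sodium concentration, e.g.

    [Na⁺]eq = [Na⁺] + [K⁺] + [Tris]/2 + 3.79 √([Mg²⁺] − [dNTP]).

Long duplexes (default > 60 paired positions) fall back to
composition-based approximations (Wetmur-style %GC / length / salt
formulas), which embed their own sodium dependence.

## Worked example

```sh
$ nnmelt -S AGCGTCATGC -H dnadna -P 0.0002 -E Na=1 -v
# 5'->3' AGCGTCATGC
# 3'->5' TCGCAGTACG
# pattern perfect [0,10)
# energy perfect dh=-78800.0 ds=-207.400
# na_eq 1
# f_factor 4
tm	65.23
enthalpy	-76400.0
entropy	-206.100
method	nn
formula	san04
corrections	owc2204
```

Reading the report: the 10-mer and its generated complement form a single
perfectly matching pattern whose nine stacks sum to −78.8 kcal/mol and
−207.4 cal/(mol·K); adding the two terminal initiation terms gives the
duplex totals ΔH = −76.4 kcal/mol and ΔS = −206.1 cal/(mol·K).  At 0.2 mM
total strands, F = 4, and 1 M Na⁺ (where the selected sodium correction is
an exact no-op), the two-state formula puts the melting temperature at
65.23 °C.

The same computation from Python:

```python
from nnmelt import Environment, build_duplex, compute

duplex = build_duplex("AGCGTCATGC", None, "dnadna")
env = Environment(hybridization="dnadna", Na=1.0, CT=2e-4)
result = compute(duplex, env)
print(round(result.tm, 2))   # 65.23
```

Mismatches, loops, bulges and dangling ends are declared by aligning the
two strands yourself (`-S AAC--TT -C TTATCAA` is a 1×3 internal loop); the
shipped datasets (`san04`, `all97`, `bre86` for DNA/DNA, `xia98` for
RNA/RNA) cover perfectly matching duplexes, and any pattern can be priced
by pointing `--data`/`--nn` at your own XML parameter files — the schema
and the generators in `nnmelt.fixtures` are documented in
`docs/methods.md`.  A benchmark harness (`nnmelt.benchmark`) evaluates
predictions against tab-separated tables of experimental Tm values.

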