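# Methods

## Scope and model

`nnmelt` predicts the melting temperature of a *given* duplex alignment; it
does not search for an alignment, fold sequences, or model secondary
structure.  The user expresses dangling ends, bulges and asymmetric loops
by placing `-` gaps; the two strands are aligned column by column (top
5'→3', bottom 3'→5'), and no column may hold gaps on both strands.

The thermodynamic model is the two-state nearest-neighbor model: the
duplex free energy is a sum over stacked base-pair doublets plus
initiation terms, and

    Tm(°C) = ΔH / (ΔS + R ln x) − 273.15,  R = 1.9872 cal mol⁻¹ K⁻¹,

where x = C_T/F by default.  All energies are in cal/mol and cal/(mol·K),
following the conventions of the nearest-neighbor literature; sums are
accumulated in input (left-to-right) order in double precision for
bit-reproducibility.

### The concentration factor

F is 1 for self-complementary duplexes, 4 for equimolar
non-self-complementary strands, 1 when one strand is in excess
(C_max/C_min ≥ 10 by default, or an explicit flag).  When both strand
concentrations are supplied and the duplex is not self-complementary, the
concentration argument is x = C_max − C_min/2 — i.e. C_max minus *half*
C_min, not half the difference.  This reading is forced by its two limits:
for C_max ≫ C_min it tends to C_T (the excess-strand regime, F = 1), and
for C_max ≈ C_min (so C_T = C_max + C_min) it tends to C_T/4, recovering
F = 4.  The alternative reading (C_max − C_min)/2 collapses to 0 at
equimolarity and satisfies neither limit.

## Sequence model

Tokens: `A T C G U`, inosine `I`, 2-hydroxyadenosine `A*`, locked
nucleotides `Al Cl Gl Tl`, azobenzene `X_C`/`X_T`, gap `-`.  Parsing is
greedy longest-match (`A*` beats `A`), case-insensitive for canonical
letters; the LNA marker must be a lowercase `l` so that it can never be
confused with a base.  Tokenization round-trips to the input text exactly.

Design choices where the conventions were genuinely open:

* **Azobenzene** is an inserted photo-switch, not a base: it is expected
  opposite a gap, and duplexes containing it are priced only under
  DNA/DNA hybridization (as are all modified residues except inosine,
  which is supported for DNA/DNA and RNA/RNA).
* **Coordinates** are 0-based alignment columns; pattern segments are
  half-open `[start, end)`.
* A strand consisting only of gaps is rejected.

Self-complementarity is detected on the paired core (terminal gap columns
ignored) of perfectly matching same-type duplexes: the core must equal its
own reverse complement.  Structures with mismatches or modified residues
cannot be auto-detected; the `--self` flag then declares
self-complementarity, and the single input strand is paired against its
own reverse (which is what a self-complementary strand physically does —
its mismatched columns fall out naturally, as in CNG repeats).

## Pattern decomposition

Maximal runs of canonical Watson-Crick pairs are located first; every
remaining maximal run of non-perfect columns is one pattern, typed by its
topology:

* any modified residue in the run ⇒ `modified` (so an inosine adjacent to
  a mismatch is one merged two-pair pattern; two modified columns
  separated by perfect pairs stay separate);
* both strands contribute ≥ 1 unpaired nucleotide ⇒ internal loop with
  per-strand sizes (L1, L2); without gaps this specializes to a single
  mismatch (1 column), tandem mismatch (2) or symmetric loop (≥ 3).  The
  bulge/loop distinction is by nucleotide counts, not raw gap placement: a
  1×3 loop has gaps on one strand only yet is a loop because both strands
  contribute nucleotides;
* one strand contributes nothing ⇒ bulge loop when interior, dangling end
  at a duplex terminus (single for 1 nucleotide, "second dangling" for a
  2-stack overhang), or a long poly-A queue when the overhang is all
  adenines of length ≥ 2 (threshold configurable);
* a duplex that is exactly 2–7 identical `CNG` triplets (C first, G last)
  of a self-complementary duplex is one `cng_repeat` pattern.

G·U wobble pairs under RNA/RNA count as perfect stacks only when the
active parameter set prices them (it contains a neighbor entry with a G·U
column); otherwise they classify as mismatches.  A defect run mixing
mismatches and gaps is treated as one internal loop; no attempt is made to
split interleaved bulges out of such runs.

## Pattern energies

Every pattern kind maps to a registered formula with an applicability
scope (kind, hybridization, predicate); the first applicable registration
wins, and a failing runtime applicability check falls back to the next
candidate.  The member formulas are keyed lookups against the parameter
store, with flanking pairs consulted where the thermodynamics require
context:

* **perfect** — sum of the L−1 `neighbor` doublets (key `"XY/ZW"`, top
  5'→3' over bottom 3'→5'; the store resolves the reverse orientation
  `"WZ/YX"` automatically);
* **single mismatch** — the two `mismatch` doublets spanning the
  mismatched column and its flanking pairs; **tandem mismatch** — one
  `mismatch` entry for the 4-column window.  Mismatches and loops must be
  internal: a terminal mismatch raises an explicit error;
* **internal loop (generic)** — size-keyed loop initiation
  (`mismatch type="initiation" size="L1+L2"`), a per-unit `asymmetry`
  penalty on |L1−L2|, `closure` penalties per A·U/G·U closing pair, and
  optional sequence-specific first-mismatch bonuses;
* **internal loop, RNA/RNA 1×(n−1), n > 2** — an enthalpy-only rule:
  loop-size initiation + one penalty per adjacent A·U/G·U closing pair +
  first-mismatch bonuses + a *signed* (L1−L2) asymmetry term; its entropy
  is exactly zero.  It applies only to RNA/RNA duplexes and only to that
  loop shape; otherwise the generic rule is used;
* **bulges** — a size-keyed `bulge` entry; single bulges additionally keep
  the `neighbor` stack of their flanking pairs across the bulged residue;
* **dangling ends** — one sense-keyed `dangling` lookup per overhang
  position over the doublet toward the duplex core (`sens` is `5` or `3`
  on the overhanging strand); **poly-A queues** — a per-adenine
  `penalty type="long_polyA"` entry;
* **modified residues** — `modified` doublets over the run extended to its
  flanking pairs (a lone inosine pair is its two stacks; terminal modified
  pairs are allowed and use the single available stack), plus an optional
  `terminal type="IU"` penalty for a terminal inosine·U pair in RNA/RNA;
* **CNG repeats** — a single `CNG` entry keyed by the triplet and the
  repeat count; initiation is already contained in these parameters, so
  the duplex initiation term is zero for CNG duplexes.

### Initiation and symmetry

Parameter sets declare their initiation rule:

* `two_class` — one entry when both terminal pairs are A/T, another when
  at least one is G/C (the convention of the 1986-era DNA tables);
* `per_terminal` — a per-A/T and a per-G/C entry summed over the two
  terminal pairs (the unified DNA tables);
* `base_plus_terminal_AU` — a base entry plus a penalty per terminal A·U
  pair (the RNA tables).

Terminal pairs are the outermost *paired* columns, so dangling ends do not
shift them; a terminal pair is G/C-class iff both bases are in {G, C}
(wobble or inosine terminals count as A/T-class).  Self-complementary
duplexes additionally add the set's `symmetry` entry (conventionally
entropy-only, −1.4 cal/(mol·K)), whether self-complementarity was detected
or declared.

### The entropy split

Terminal mismatches of internal loops are assumed to share the salt
dependence of paired bases, while the interior of large loops is salt
independent: for n1×n2 loops with n1 > 2 *and* n2 > 2, the loop-length and
loop-asymmetry entropy terms are accumulated separately as
`ds_salt_independent`, ion corrections touch only the salt-dependent
remainder, and the final ΔS is the sum of the corrected dependent part and
the untouched independent part.

## Parameter store

Datasets are XML files: a `data` root (`type` = hybridization scope, plus
bookkeeping attributes `id`, `initiation-rule`, `reference-sodium`,
`citation`) whose children each hold numeric `enthalpy` and `entropy`
children in cal/mol units.  The permitted child elements and attributes
are fixed (`neighbor`, `initiation`, `terminal`, `symmetry`, `mismatch`,
`asymmetry`, `penalty`, `parameters`, `bulge`, `closure`, `modified`,
`CNG`, `dangling`); unknown elements, unknown attributes and missing
energy children are load errors naming the offender.  `write ∘ load` and
`load ∘ write` are identities (energies serialized at full precision).

Shipped payload: the perfectly-matching DNA/DNA tables `san04`, `all97`
(per-terminal initiation) and `bre86` (two-class initiation), and the
RNA/RNA table `xia98` (base + per-terminal-A·U initiation), transcribed
from their original publications.  Mismatch, dangling-end, inosine and CNG
literature tables are not shipped; those patterns compute as soon as a
user supplies a dataset covering them (`--data`/`--nn`).  No default
dataset exists for DNA/RNA or 2'-O-methyl hybridizations; the engine says
so explicitly rather than guessing.  Parameter sets referenced to a
sodium concentration other than 1 M declare it via `reference-sodium`,
and every entry's entropy is shifted by −0.368·ln([Na⁺]_ref) per stack
before use (the standard per-phosphate salt entropy), bringing the set to
the common 1 M reference; enthalpies are untouched and the shift is
exactly invertible.

## Ion and denaturant corrections

Sodium equivalence methods (all reduce to [Na⁺] when the other cations are
zero):

| id | formula (mol/L) |
|----|----------------|
| `ahs01` | Na + K + Tris/2 + 3.79·√(max(Mg − dNTP, 0)) |
| `mit96` | Na + K + Tris/2 + 3.79·√Mg |
| `pey00` | Na + K + Tris/2 + 3.3·√(max(Mg − dNTP, 0)) |

The √ term carries the 3.79 mol⁻¹ᐟ² coefficient (the 120·√mM rule in molar
units); dNTPs chelate magnesium, so the excess is clamped at zero.  The
`mit96` variant omits the chelation term; the `pey00` magnesium weighting
is a best-effort transcription of the cited secondary constant.

The correction class is selected by the cation-competition algorithm:
with R = √[Mg²⁺]_free/[mon⁺] (mon⁺ = Na + K + Tris/2), sodium corrections
apply for R < 0.22, the magnesium correction for R ≥ 6 or mon⁺ = 0, and
the mixed monovalent/bivalent correction in between (both bounds are
configuration values).  A user-forced correction bypasses the selector but
is still scope-checked against the hybridization.

Registered corrections (f_GC = GC fraction, N = paired columns, T in K
where reciprocal):

| id | kind | formula |
|----|------|---------|
| `schlif`, `marschdot`, `ahs01` | temperature | Tm + 16.6·log₁₀[Na⁺] |
| `wet91` (+`wet91rna`, `wet91dnarna`) | temperature | Tm + 16.6·log₁₀(1.7[Na⁺]/(1+0.7[Na⁺])) |
| `san96` | temperature | Tm + 12.5·log₁₀[Na⁺] |
| `kam71` | temperature | Tm + (7.95 − 3.06·f_GC)·ln[Na⁺] |
| `san04` | entropy | ΔS + 0.368·(N−1)·ln[Na⁺] |
| `owc2104` | temperature | 1/Tm + (4.29·f_GC − 3.95)·10⁻⁵·ln[Na⁺] |
| `owc2204` | temperature | owc2104 + 9.40·10⁻⁶·ln²[Na⁺] |
| `owcmg08` | temperature | 1/Tm + a + b·lnMg + f_GC(c + d·lnMg) + (e + f·lnMg + g·ln²Mg)/(2(N−1)) |

`owcmg08` uses a = 3.92·10⁻⁵, b = −9.11·10⁻⁶, c = 6.26·10⁻⁵,
d = 1.42·10⁻⁵, e = −4.82·10⁻⁴, f = 5.25·10⁻⁴, g = 8.31·10⁻⁵; in the mixed
regime a, d and g become the published functions of the monovalent
concentration.  Only corrections whose source equations could be verified
are registered; the registry is a plain mapping and accepts additions.
Every sodium-referenced correction is an exact no-op at its 1 M reference
(asserted by test); magnesium corrections have no sodium fixed point by
construction, so the corresponding check is monotone stabilization over
the 0.0005–0.02 M Mg range instead.

Entropy-type corrections are applied to the salt-dependent entropy before
the Tm formula; temperature-type corrections transform the Tm computed at
the 1 M reference.  Denaturant corrections follow the ion step and are
independent of it (no published interaction model exists): DMSO rules are
linear in volume percent (−0.75, −0.675, −0.6 or −0.5 °C/% for `ahs01dmso`,
`esc80`, `mus81`, `cul76`); formamide uses the GC-dependent molar rule
(0.453·f_GC − 2.88)·[formamide] by default (`bla96`) or the linear
−0.62 °C/% rule (`lincorr`) — the formamide value is interpreted in the
unit of the chosen rule.  All default bindings live in
`src/nnmelt/data/defaults.yaml`, not in code.

## Approximative path

Duplexes longer than the threshold (default 60 paired columns,
configurable, bypassable with `--force`) use composition formulas; the
DNA/DNA default is

    Tm = 81.5 + 16.6·log₁₀([Na⁺]/(1 + 0.7[Na⁺])) + 0.41·%GC − 500/size − %mismatching,

with the RNA/RNA and DNA/RNA variants differing in intercept (78, 67) and
GC slope (0.7, 0.8).  %GC and %mismatching are computed over paired
(non-gap) columns and size is the paired-column count.  Because these
formulas embed their own salt dependence, the engine computes the sodium
equivalent of mixed buffers first and never stacks an ion correction on
top; ΔH/ΔS are not reported on this path.

## Synthetic data

`nnmelt.fixtures` generates seeded, bit-reproducible test data: duplex
plans (`FixtureSpec`) realized as duplexes with known ground-truth
segmentation (defect blocks separated by perfect runs, so the layout *is*
the oracle), and matching parameter sets obtained by replaying the
engine's own key builders against a recording store plus a generic base
(all neighbor doublets, all initiation styles, mismatch/inosine doublets,
loop and bulge size tables, CNG entries).  Values are uniform
(−8000, −22) — so totals have closed forms — or seeded-random with both
orientations of a stack forced equal.  The generator emulates pattern
*topology*, not thermodynamic realism: passing tests demonstrate correct
decomposition, dispatch, arithmetic and corrections, not predictive
accuracy on real measurements, which requires the literature parameter
tables and experimental Tm datasets (the `nnmelt.benchmark` harness exists
for exactly that comparison).

## Problem sizes and numerics

The test suite uses 500 seeded random duplex plans plus an exhaustive
sweep of all ≤ 8-column two-letter duplexes with ≤ 2 defects (~35k
duplexes) for the segmentation oracle; 1000 random (ΔH, ΔS) pairs for the
concentration monotonicity property; 100 randomized parameter sets for XML
round-trips.  Degenerate inputs (C_T ≤ 0, zero denominator, zero
experimental Tm) raise validation errors rather than returning NaN; Tm
values are exact function evaluations with no iteration, so the only
tolerance in the package is the 10⁻⁹ used by tests on algebraic
identities.

## Known limitations

* Terminal mismatches are rejected — all mismatches and loops must be
  flanked by paired bases.
* No hairpin/secondary-structure competition except the dedicated CNG
  hairpin rule; long-sequence accuracy is bounded by the approximative
  formulas.
* Shipped datasets cover perfect-match DNA/DNA and RNA/RNA only; all
  other patterns and hybridizations need user-supplied parameter files.
* Loop-size entries are looked up exactly (no log-extrapolation to unseen
  sizes); a missing size is a missing-parameter error.
* Ion and denaturant corrections are independent by construction.
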