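"""Enthalpy/entropy computation per pattern and duplex assembly.

Each pattern kind is priced by a registered formula: a keyed lookup (plus
flanking-pair context where the thermodynamics require it) against a
:class:`~nnmelt.paramstore.ParameterSet`.  The duplex totals are

    dH = dh_initiation + sum(dh_pattern)        (+ symmetry term)
    dS = ds_initiation + sum(ds_pattern)        (+ symmetry term)

with the entropy additionally split into a sodium-dependent and a
sodium-independent part: for n1 x n2 internal loops with n1 > 2 and
n2 > 2, the loop-length and loop-asymmetry entropy terms are salt
independent and ion corrections must not touch them.

Key conventions (fixed by this package, standard NN notation):

* stacks — ``neighbor sequence="XY/ZW"`` with top 5'->3' over bottom 3'->5';
* single mismatch — the two ``mismatch`` doublets spanning the mismatched
  column and its flanking pairs;
* tandem mismatch — one ``mismatch`` entry for the 4-column window
  (closing pair, both mismatches, closing pair);
* internal loop — ``mismatch type="initiation" size="n1+n2"`` plus the
  ``asymmetry`` entry per unpaired-count difference plus ``closure``
  penalties for A.U / G.U closing pairs (sequence-specific first-mismatch
  bonuses are consulted as optional ``mismatch loop="first"`` entries);
* bulge — ``bulge size="L"``; a single bulge keeps the stack of its
  flanking pairs (``neighbor`` across the bulge);
* dangling / poly-A — ``dangling sequence=... sens="5"|"3"`` per overhang
  position, or a per-adenine ``penalty type="long_polyA"``;
* modified residues — ``modified`` doublets over the run extended to its
  flanking pairs, plus an optional ``terminal type="IU"`` penalty for a
  terminal inosine.U pair in RNA/RNA duplexes;
* CNG repeats — one ``CNG sequence=<triplet> repeats="r"`` entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (MissingParameterError, NoFormulaError,
                     NotApplicableError, TerminalMismatchError)
from .paramstore import (ParameterSet, ThermoResult, ZERO, key)
from .segmentation import PatternSegment, segment as segment_duplex
from .sequences import Duplex, FIVE_TO_THREE, STRAND_TYPES

SODIUM_ENTROPY_PER_STACK = 0.368  # cal/(mol.K) per phosphate pair, x ln[Na+]


@dataclass(frozen=True)
class SegmentEnergy:
    """Energy of one pattern plus its salt-independent entropy share."""

    thermo: ThermoResult
    ds_salt_independent: float = 0.0


@dataclass
class EnergyBreakdown:
    """Assembled duplex energetics."""

    per_segment: list[tuple[PatternSegment, ThermoResult]]
    initiation: ThermoResult
    symmetry: ThermoResult
    ds_salt_independent: float

    @property
    def total(self) -> ThermoResult:
        t = self.initiation + self.symmetry
        for _, thermo in self.per_segment:
            t = t + thermo
        return t

    @property
    def ds_salt_dependent(self) -> float:
        return self.total.ds - self.ds_salt_independent


# ---------------------------------------------------------------------------
# helpers

def _sym(duplex: Duplex, i: int, strand: str) -> str:
    s = duplex.top if strand == "top" else duplex.bottom
    return s.tokens[i].symbol


def doublet(duplex: Duplex, i: int, j: int | None = None) -> str:
    """Sequence descriptor of columns i and j (default i+1): ``XY/ZW``."""
    j = i + 1 if j is None else j
    return (f"{_sym(duplex, i, 'top')}{_sym(duplex, j, 'top')}/"
            f"{_sym(duplex, i, 'bottom')}{_sym(duplex, j, 'bottom')}")


def window(duplex: Duplex, start: int, end: int) -> str:
    top = "".join(_sym(duplex, i, "top") for i in range(start, end))
    bottom = "".join(_sym(duplex, i, "bottom") for i in range(start, end))
    return f"{top}/{bottom}"


def _pair_symbols(duplex: Duplex, i: int) -> frozenset[str]:
    return frozenset(duplex.column(i))


def _is_au_or_gu(duplex: Duplex, i: int) -> bool:
    pair = _pair_symbols(duplex, i)
    return pair == frozenset({"A", "U"}) or pair == frozenset({"G", "U"})


def _require_internal(segment: PatternSegment, duplex: Duplex) -> None:
    if segment.start == 0 or segment.end == len(duplex):
        raise TerminalMismatchError(
            "terminal mismatches cannot be computed: all mismatches and "
            "internal loops must be flanked by paired bases")


def set_supports_wobble(pset: ParameterSet) -> bool:
    """True iff the set prices G.U wobble stacks (has a neighbor entry
    with a G.U column)."""
    for k in pset.entries:
        if k.element_kind != "neighbor":
            continue
        seq = k.get("sequence") or ""
        top, _, bottom = seq.partition("/")
        for t, b in zip(top, bottom):
            if {t, b} == {"G", "U"}:
                return True
    return False


# ---------------------------------------------------------------------------
# pattern formulas

def perfect_energy(segment: PatternSegment, duplex: Duplex,
                   pset: ParameterSet) -> SegmentEnergy:
    """Sum of nearest-neighbor stack terms inside a perfect run:
    L base pairs contribute L-1 doublets."""
    total = ZERO
    for i in range(segment.start, segment.end - 1):
        total = total + pset.lookup(key("neighbor", sequence=doublet(duplex, i)))
    return SegmentEnergy(total)


def single_mismatch_energy(segment: PatternSegment, duplex: Duplex,
                           pset: ParameterSet) -> SegmentEnergy:
    """An internal single mismatch is priced by its two flanking doublets
    from the mismatch table."""
    _require_internal(segment, duplex)
    i = segment.start
    total = (pset.lookup(key("mismatch", sequence=doublet(duplex, i - 1)))
             + pset.lookup(key("mismatch", sequence=doublet(duplex, i))))
    return SegmentEnergy(total)


def tandem_mismatch_energy(segment: PatternSegment, duplex: Duplex,
                           pset: ParameterSet) -> SegmentEnergy:
    _require_internal(segment, duplex)
    seq = window(duplex, segment.start - 1, segment.end + 1)
    return SegmentEnergy(pset.lookup(key("mismatch", sequence=seq)))


def _loop_closures(segment: PatternSegment, duplex: Duplex,
                   pset: ParameterSet, *, per_pair_key: str) -> ThermoResult:
    total = ZERO
    for i in (segment.start - 1, segment.end):
        if _is_au_or_gu(duplex, i):
            total = total + pset.lookup(key("closure", type=per_pair_key))
    return total


def _first_noncanonical_bonus(segment: PatternSegment, duplex: Duplex,
                              pset: ParameterSet) -> ThermoResult:
    # Sequence-specific bonus for the first non-canonical pair at each end
    # of a loop; consulted as optional entries.
    total = ZERO
    for i in (segment.start, segment.end - 1):
        t, b = duplex.column(i)
        if t == "-" or b == "-":
            continue
        hit = pset.lookup_optional(
            key("mismatch", sequence=f"{t}/{b}", loop="first"))
        if hit is not None:
            total = total + hit
    return total


def internal_loop_energy(segment: PatternSegment, duplex: Duplex,
                         pset: ParameterSet) -> SegmentEnergy:
    """Generic internal-loop rule: size-keyed loop initiation, a per-unit
    asymmetry penalty and A.U/G.U closure penalties.

    For n1 x n2 loops with both sides > 2 the loop-length and asymmetry
    entropy terms are reported as salt independent.
    """
    _require_internal(segment, duplex)
    l1, l2 = segment.loop_sizes
    init = pset.lookup(key("mismatch", type="initiation", size=str(l1 + l2)))
    total = init
    asym_total = ZERO
    if l1 != l2:
        asym = pset.lookup(key("asymmetry"))
        asym_total = asym.scaled(abs(l1 - l2))
        total = total + asym_total
    total = total + _loop_closures(segment, duplex, pset, per_pair_key="per_AU_GU")
    total = total + _first_noncanonical_bonus(segment, duplex, pset)
    ds_indep = init.ds + asym_total.ds if (l1 > 2 and l2 > 2) else 0.0
    return SegmentEnergy(total, ds_salt_independent=ds_indep)


def internal_loop_energy_lu(segment: PatternSegment, duplex: Duplex,
                            pset: ParameterSet) -> SegmentEnergy:
    """RNA/RNA 1 x (n-1) internal-loop rule (n > 2): enthalpy only.

    dh = loop-size initiation + one penalty per adjacent A.U or G.U
    closing pair + sequence-specific first-mismatch bonuses + signed
    (L1 - L2) asymmetry term; the entropy is exactly zero.
    """
    if duplex.hybridization != "rnarna":
        raise NotApplicableError("the 1 x (n-1) RNA loop rule applies only "
                                 "to RNA/RNA duplexes")
    l1, l2 = segment.loop_sizes
    if min(l1, l2) != 1 or max(l1, l2) <= 2:
        raise NotApplicableError("the RNA loop rule applies only to "
                                 "1 x (n-1) internal loops with n > 2")
    _require_internal(segment, duplex)
    dh = pset.lookup(key("mismatch", type="initiation", size=str(l1 + l2))).dh
    for i in (segment.start - 1, segment.end):
        if _is_au_or_gu(duplex, i):
            dh += pset.lookup(key("closure", type="per_AU_GU")).dh
    dh += _first_noncanonical_bonus(segment, duplex, pset).dh
    if l1 != l2:
        dh += (l1 - l2) * pset.lookup(key("asymmetry")).dh
    return SegmentEnergy(ThermoResult(dh, 0.0))


def single_bulge_energy(segment: PatternSegment, duplex: Duplex,
                        pset: ParameterSet) -> SegmentEnergy:
    """A single bulge: size-1 bulge penalty; the flanking pairs keep
    stacking across the bulged-out residue."""
    i = segment.start
    total = (pset.lookup(key("bulge", size="1"))
             + pset.lookup(key("neighbor",
                               sequence=doublet(duplex, i - 1, segment.end))))
    return SegmentEnergy(total)


def long_bulge_energy(segment: PatternSegment, duplex: Duplex,
                      pset: ParameterSet) -> SegmentEnergy:
    total = pset.lookup(key("bulge", size=str(segment.length)))
    total = total + _loop_closures(segment, duplex, pset, per_pair_key="per_AU_GU")
    return SegmentEnergy(total)


def _dangling_positions(segment: PatternSegment, duplex: Duplex):
    """Overhang columns ordered from the paired edge outward, with the
    overhanging strand and its 5'/3' sense."""
    at_left = segment.start == 0
    cols = list(range(segment.start, segment.end))
    if at_left:
        cols.reverse()
    strand = ("top" if all(duplex.bottom.tokens[i].is_gap
                           for i in range(segment.start, segment.end))
              else "bottom")
    # The left duplex end is the top strand's 5' end and the bottom
    # strand's 3' end.
    if strand == "top":
        sens = "5" if at_left else "3"
    else:
        sens = "3" if at_left else "5"
    return cols, sens, at_left


def dangling_energy(segment: PatternSegment, duplex: Duplex,
                    pset: ParameterSet) -> SegmentEnergy:
    """Single and second dangling ends: one sense-keyed lookup per
    overhang position, each over the doublet toward the duplex core."""
    cols, sens, at_left = _dangling_positions(segment, duplex)
    total = ZERO
    for c in cols:
        i, j = (c, c + 1) if at_left else (c - 1, c)
        total = total + pset.lookup(
            key("dangling", sequence=doublet(duplex, i, j), sens=sens))
    return SegmentEnergy(total)


def polya_energy(segment: PatternSegment, duplex: Duplex,
                 pset: ParameterSet) -> SegmentEnergy:
    """Long poly-A queue: one per-adenine penalty entry."""
    per_a = pset.lookup(key("penalty", type="long_polyA"))
    return SegmentEnergy(per_a.scaled(segment.length))


def modified_energy(segment: PatternSegment, duplex: Duplex,
                    pset: ParameterSet) -> SegmentEnergy:
    """Patterns holding modified residues: ``modified`` doublets over the
    run extended to its flanking pairs (so a lone inosine pair is priced by
    its two stacks), plus the terminal inosine.U penalty hook for RNA/RNA."""
    lo = max(segment.start - 1, 0)
    hi = min(segment.end + 1, len(duplex))
    total = ZERO
    for i in range(lo, hi - 1):
        total = total + pset.lookup(key("modified", sequence=doublet(duplex, i)))
    if duplex.hybridization == "rnarna":
        for i in (0, len(duplex) - 1):
            if segment.start <= i < segment.end and \
                    _pair_symbols(duplex, i) == frozenset({"I", "U"}):
                hit = pset.lookup_optional(key("terminal", type="IU"))
                if hit is not None:
                    total = total + hit
    return SegmentEnergy(total)


def cng_energy(segment: PatternSegment, duplex: Duplex,
               pset: ParameterSet) -> SegmentEnergy:
    unit = "".join(duplex.top.symbols()[:3])
    return SegmentEnergy(pset.lookup(
        key("CNG", sequence=unit, repeats=str(segment.repeats))))


# ---------------------------------------------------------------------------
# initiation and symmetry

def _terminal_paired_columns(duplex: Duplex) -> list[int]:
    paired = duplex.paired_columns()
    if not paired:
        return []
    ends = [paired[0]]
    if paired[-1] != paired[0]:
        ends.append(paired[-1])
    return ends


def _terminal_class(duplex: Duplex, i: int) -> str:
    pair = set(duplex.column(i))
    return "GC" if pair <= {"G", "C"} else "AT"


def initiation_energy(duplex: Duplex, pset: ParameterSet,
                      is_cng: bool = False) -> ThermoResult:
    """Duplex initiation under the rule the parameter set declares.

    * ``two_class`` — one entry keyed by whether both terminal pairs are
      A/T (``two_AT``) or at least one is G/C (``at_least_one_GC``);
    * ``per_terminal`` — the sum of per-terminal A/T and G/C entries over
      the terminal base-pair counts;
    * ``base_plus_terminal_AU`` — a base entry plus a penalty per terminal
      A.U pair (RNA sets).

    CNG-repeat duplexes already embed initiation in their parameters and
    return zero.
    """
    if is_cng:
        return ZERO
    ends = _terminal_paired_columns(duplex)
    rule = pset.initiation_rule
    if rule == "two_class":
        classes = {_terminal_class(duplex, i) for i in ends}
        which = "two_AT" if classes == {"AT"} else "at_least_one_GC"
        return pset.lookup(key("initiation", type=which))
    if rule == "per_terminal":
        total = ZERO
        for i in ends:
            which = "per_AT" if _terminal_class(duplex, i) == "AT" else "per_GC"
            total = total + pset.lookup(key("initiation", type=which))
        return total
    if rule == "base_plus_terminal_AU":
        total = pset.lookup(key("initiation", type="base"))
        for i in ends:
            if set(duplex.column(i)) <= {"A", "U", "T"}:
                total = total + pset.lookup(key("initiation", type="per_AU"))
        return total
    raise NotApplicableError(f"unknown initiation rule {rule!r} declared by "
                             f"parameter set {pset.id!r}")


def symmetry_energy(duplex: Duplex, pset: ParameterSet) -> ThermoResult:
    """The set's symmetry correction for self-complementary duplexes
    (typically entropy-only); zero otherwise."""
    if not duplex.self_complementary:
        return ZERO
    return pset.lookup(key("symmetry"))


# ---------------------------------------------------------------------------
# formula registry and assembly

@dataclass(frozen=True)
class FormulaSpec:
    """A registered pattern formula with its applicability scope."""

    name: str
    kind: str
    compute: callable
    hybridizations: tuple[str, ...] | None = None  # None = any
    applicable: callable = None                    # extra predicate
    priority: int = 10

    def applies(self, segment: PatternSegment, duplex: Duplex) -> bool:
        if self.kind != segment.kind:
            return False
        if (self.hybridizations is not None
                and duplex.hybridization not in self.hybridizations):
            return False
        if self.applicable is not None and not self.applicable(segment, duplex):
            return False
        return True


def _lu_applicable(segment: PatternSegment, duplex: Duplex) -> bool:
    l1, l2 = segment.loop_sizes
    return min(l1, l2) == 1 and max(l1, l2) > 2


def _modified_applicable(segment: PatternSegment, duplex: Duplex) -> bool:
    # Inosine parameters exist for DNA/DNA and RNA/RNA; every other
    # modified entity is implemented for DNA/DNA duplexes only.
    if duplex.hybridization == "dnadna":
        return True
    if duplex.hybridization != "rnarna":
        return False
    mods = {t.symbol for s in (duplex.top, duplex.bottom)
            for t in s.tokens[segment.start:segment.end] if t.is_modified}
    return mods <= {"I"}


DEFAULT_FORMULAS: tuple[FormulaSpec, ...] = (
    FormulaSpec("perfect_nn", "perfect", perfect_energy, priority=0),
    FormulaSpec("single_mismatch_nn", "single_mismatch", single_mismatch_energy),
    FormulaSpec("tandem_mismatch_nn", "tandem_mismatch", tandem_mismatch_energy),
    FormulaSpec("internal_loop_lu", "internal_loop", internal_loop_energy_lu,
                hybridizations=("rnarna",), applicable=_lu_applicable,
                priority=0),
    FormulaSpec("internal_loop_generic", "internal_loop", internal_loop_energy),
    FormulaSpec("single_bulge_nn", "single_bulge", single_bulge_energy),
    FormulaSpec("long_bulge_nn", "long_bulge", long_bulge_energy),
    FormulaSpec("single_dangling_nn", "single_dangling", dangling_energy),
    FormulaSpec("second_dangling_nn", "second_dangling", dangling_energy),
    FormulaSpec("long_polyA_penalty", "long_polyA", polya_energy),
    FormulaSpec("modified_nn", "modified", modified_energy,
                applicable=_modified_applicable),
    FormulaSpec("cng_repeats", "cng_repeat", cng_energy),
)


class EnergyModel:
    """Formula registry bound to parameter sets.

    ``default_set`` prices every pattern unless ``per_kind_sets`` overrides
    the dataset for a given pattern kind (the per-pattern ``--nn`` option).
    User-supplied formulas can replace registry entries by name.
    """

    def __init__(self, default_set: ParameterSet,
                 per_kind_sets: dict[str, ParameterSet] | None = None,
                 formulas: tuple[FormulaSpec, ...] = DEFAULT_FORMULAS):
        self.default_set = default_set
        self.per_kind_sets = dict(per_kind_sets or {})
        self.formulas = tuple(sorted(formulas, key=lambda f: f.priority))

    def pset_for(self, kind: str) -> ParameterSet:
        return self.per_kind_sets.get(kind, self.default_set)

    def formula_for(self, segment: PatternSegment, duplex: Duplex) -> FormulaSpec:
        for spec in self.formulas:
            if spec.applies(segment, duplex):
                return spec
        raise NoFormulaError(
            f"no thermodynamic formula applies to a {segment.kind!r} pattern "
            f"under {duplex.hybridization!r} hybridization")

    def segment_energy(self, segment: PatternSegment,
                       duplex: Duplex) -> tuple[FormulaSpec, SegmentEnergy]:
        spec = self.formula_for(segment, duplex)
        pset = self.pset_for(segment.kind)
        try:
            return spec, spec.compute(segment, duplex, pset)
        except NotApplicableError:
            # A higher-priority formula whose runtime applicability check
            # failed: fall through to the next registered candidate.
            for other in self.formulas:
                if other is not spec and other.applies(segment, duplex):
                    return other, other.compute(segment, duplex, pset)
            raise

    def wobble_pairs(self, duplex: Duplex) -> frozenset:
        if duplex.hybridization == "rnarna" and \
                set_supports_wobble(self.pset_for("perfect")):
            return frozenset({("G", "U"), ("U", "G")})
        return frozenset()


def pattern_energy(segment: PatternSegment, duplex: Duplex,
                   model: EnergyModel) -> ThermoResult:
    """Dispatch one pattern to its registered formula."""
    _, energy = model.segment_energy(segment, duplex)
    return energy.thermo


def assemble(duplex: Duplex,
             segments: list[PatternSegment],
             model: EnergyModel,
             environment=None) -> EnergyBreakdown:
    """Price every segment and assemble totals, initiation, symmetry and
    the sodium-dependent/independent entropy split."""
    per_segment: list[tuple[PatternSegment, ThermoResult]] = []
    ds_indep = 0.0
    is_cng = any(s.kind == "cng_repeat" for s in segments)
    for seg in segments:
        _, energy = model.segment_energy(seg, duplex)
        per_segment.append((seg, energy.thermo))
        ds_indep += energy.ds_salt_independent
    initiation = initiation_energy(duplex, model.default_set, is_cng=is_cng)
    symmetry = symmetry_energy(duplex, model.default_set)
    return EnergyBreakdown(per_segment=per_segment, initiation=initiation,
                           symmetry=symmetry, ds_salt_independent=ds_indep)


def compute_breakdown(duplex: Duplex, model: EnergyModel,
                      polya_min: int | None = None) -> tuple[list[PatternSegment],
                                                             EnergyBreakdown]:
    """Segment (with wobble support decided by the active set) and price."""
    kwargs = {} if polya_min is None else {"polya_min": polya_min}
    segments = segment_duplex(duplex, wobble=model.wobble_pairs(duplex), **kwargs)
    return segments, assemble(duplex, segments, model)


# ---------------------------------------------------------------------------
# 0.1 M sodium pre-correction

def pre_correct_0p1M_set(pset: ParameterSet) -> ParameterSet:
    """Bring a set determined at a non-1 M sodium reference to the 1 M
    reference by removing the per-stack sodium entropy term
    0.368 * ln([Na+]_ref) from every entry; enthalpies are untouched.

    Sets already referenced to 1 M are returned unchanged.
    """
    import math

    ref = pset.reference_sodium
    if ref == 1.0:
        return pset
    shift = SODIUM_ENTROPY_PER_STACK * math.log(ref)
    corrected = {k: ThermoResult(v.dh, v.ds - shift)
                 for k, v in pset.entries.items()}
    metadata = dict(pset.metadata)
    metadata["reference-sodium"] = 1.0
    return ParameterSet(id=pset.id, hybridization_scope=pset.hybridization_scope,
                        entries=corrected, metadata=metadata)
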