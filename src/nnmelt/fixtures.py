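"""Synthetic test data: parameter sets and duplexes with known structure.

These generators make the whole engine testable without any transcribed
literature data.  A :class:`FixtureSpec` is a seeded plan of defects;
:func:`make_duplex` builds a duplex realizing the plan together with its
ground-truth segmentation, and :func:`make_fixture_set` emits a parameter
set guaranteed to price every pattern the plan produces (it runs the
energetics key builders against a recording store, so coverage follows the
engine's own key conventions).

Fixture energies make no claim of thermodynamic realism; the ``uniform``
value scheme exists so totals are computable in closed form.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .energetics import EnergyModel, assemble
from .paramstore import (DescriptorKey, ParameterSet, ThermoResult, key)
from .segmentation import PatternSegment, segment as segment_duplex
from .sequences import (COMPLEMENT, Duplex, STRAND_TYPES, Strand,
                        THREE_TO_FIVE, tokenize)

_DEFECT_KINDS = ("single_mismatch", "tandem_mismatch", "internal_loop",
                 "single_bulge", "long_bulge", "modified", "modified_mismatch")


@dataclass(frozen=True)
class FixtureSpec:
    """A seeded plan: which defects a duplex carries and how the matching
    parameter set values its entries."""

    hybridization: str = "dnadna"
    block_length: int = 4                 # perfect run length between defects
    defects: tuple[str, ...] = ()         # drawn from _DEFECT_KINDS
    loop_sizes: tuple[int, int] = (1, 3)  # used by internal_loop defects
    long_bulge_length: int = 3
    dangling: str | None = None           # None | "left" | "right" | "polyA"
    dangling_length: int = 1
    scheme: str = "uniform"               # "uniform" | "random"
    dh: float = -8000.0
    ds: float = -22.0
    seed: int = 0

    @staticmethod
    def random_plan(seed: int) -> "FixtureSpec":
        """A randomized but reproducible defect plan."""
        rng = random.Random(seed)
        defects = tuple(rng.choice(_DEFECT_KINDS)
                        for _ in range(rng.randint(0, 3)))
        dangling = rng.choice([None, None, "left", "right", "polyA"])
        l1 = rng.randint(1, 4)
        l2 = rng.randint(1, 4)
        if l1 == l2 and l1 < 3:
            l2 = l1 + 2  # keep loop plans distinguishable from mismatch runs
        return FixtureSpec(
            block_length=rng.randint(2, 5),
            defects=defects,
            loop_sizes=(l1, l2),
            long_bulge_length=rng.randint(2, 4),
            dangling=dangling,
            dangling_length=rng.randint(1, 3),
            seed=seed,
        )


_DNA = "ACGT"
_RNA = "ACGU"


def _alphabet(hybridization: str) -> tuple[str, str]:
    top_type, bottom_type = STRAND_TYPES[hybridization]
    return (_DNA if top_type == "dna" else _RNA,
            _DNA if bottom_type == "dna" else _RNA)


def make_duplex(spec: FixtureSpec) -> tuple[Duplex, list[PatternSegment]]:
    """Build the planned duplex and its ground-truth segmentation.

    Defect blocks are separated (and flanked) by perfect runs so each is
    one pattern; the known block layout *is* the oracle segmentation.
    """
    rng = random.Random(spec.seed)
    top_alpha, _ = _alphabet(spec.hybridization)
    bottom_type = STRAND_TYPES[spec.hybridization][1]
    comp = COMPLEMENT[bottom_type]

    top: list[str] = []
    bottom: list[str] = []
    truth: list[tuple[str, int, int, tuple[int, int] | None]] = []

    def perfect_block(n: int) -> None:
        for _ in range(n):
            b = rng.choice(top_alpha)
            top.append(b)
            bottom.append(comp[b])

    def mismatch_col() -> None:
        b = rng.choice(top_alpha)
        wrong = rng.choice([x for x in _alphabet(spec.hybridization)[1]
                            if x != comp[b]])
        top.append(b)
        bottom.append(wrong)

    def mark(kind: str, ncols: int, loop_sizes=None) -> None:
        truth.append((kind, len(top) - ncols, len(top), loop_sizes))

    if spec.dangling in ("left", "polyA"):
        n = spec.dangling_length
        sym = "A" if spec.dangling == "polyA" else "C"
        if spec.dangling == "polyA":
            n = max(n, 2)
        top.extend([sym] * n)
        bottom.extend(["-"] * n)
        if spec.dangling == "polyA":
            mark("long_polyA", n)
        else:
            mark("single_dangling" if n == 1 else "second_dangling", n)

    perfect_block(spec.block_length)
    for defect in spec.defects:
        before = len(top)
        if defect == "single_mismatch":
            mismatch_col()
            mark("single_mismatch", 1)
        elif defect == "tandem_mismatch":
            mismatch_col()
            mismatch_col()
            mark("tandem_mismatch", 2)
        elif defect == "internal_loop":
            l1, l2 = spec.loop_sizes
            for i in range(max(l1, l2)):
                if i < min(l1, l2):
                    mismatch_col()
                elif l1 > l2:
                    top.append(rng.choice(top_alpha))
                    bottom.append("-")
                else:
                    top.append("-")
                    bottom.append(rng.choice(_alphabet(spec.hybridization)[1]))
            if l1 == l2 == 1:
                mark("single_mismatch", 1)
            elif l1 == l2 == 2:
                mark("tandem_mismatch", 2)
            else:
                mark("internal_loop", len(top) - before, (l1, l2))
        elif defect == "single_bulge":
            top.append(rng.choice(top_alpha))
            bottom.append("-")
            mark("single_bulge", 1)
        elif defect == "long_bulge":
            for _ in range(spec.long_bulge_length):
                top.append("-")
                bottom.append(rng.choice(_alphabet(spec.hybridization)[1]))
            mark("long_bulge", spec.long_bulge_length)
        elif defect == "modified":
            top.append("I")
            bottom.append(rng.choice(_alphabet(spec.hybridization)[1]))
            mark("modified", 1)
        elif defect == "modified_mismatch":
            # inosine adjacent to a mismatch merges into one pattern
            top.append("I")
            bottom.append(rng.choice(_alphabet(spec.hybridization)[1]))
            mismatch_col()
            mark("modified", 2)
        else:
            raise ValueError(f"unknown defect kind {defect!r}")
        perfect_block(spec.block_length)

    if spec.dangling == "right":
        n = spec.dangling_length
        top.extend(["-"] * n)
        bottom.extend([rng.choice(["C", "G"])
                       for _ in range(n)])
        mark("single_dangling" if n == 1 else "second_dangling", n)

    duplex = Duplex(
        Strand(tuple(tokenize("".join(top)).tokens)),
        Strand(tuple(tokenize("".join(bottom)).tokens), THREE_TO_FIVE),
        spec.hybridization,
    )

    # Fill perfect gaps between marked defect blocks.
    segments: list[PatternSegment] = []
    cursor = 0
    for kind, start, end, loop_sizes in truth:
        if start > cursor:
            segments.append(PatternSegment("perfect", cursor, start))
        segments.append(PatternSegment(kind, start, end, loop_sizes=loop_sizes))
        cursor = end
    if cursor < len(duplex):
        segments.append(PatternSegment("perfect", cursor, len(duplex)))
    return duplex, segments


class _RecordingSet(ParameterSet):
    """Parameter store that answers every lookup and remembers the key."""

    def __init__(self, value: ThermoResult):
        super().__init__(id="recording", hybridization_scope="any")
        self.value = value
        self.seen: set[DescriptorKey] = set()

    def lookup(self, k: DescriptorKey) -> ThermoResult:
        self.seen.add(k)
        return self.value


def _base_entries(hybridization: str) -> set[DescriptorKey]:
    top_alpha, _ = _alphabet(hybridization)
    comp = COMPLEMENT[STRAND_TYPES[hybridization][1]]
    keys: set[DescriptorKey] = set()
    for a in top_alpha:
        for b in top_alpha:
            keys.add(key("neighbor", sequence=f"{a}{b}/{comp[a]}{comp[b]}"))
    for which in ("two_AT", "at_least_one_GC", "per_AT", "per_GC",
                  "base", "per_AU"):
        keys.add(key("initiation", type=which))
    keys.add(key("symmetry"))
    keys.add(key("asymmetry"))
    keys.add(key("closure", type="per_AU_GU"))
    keys.add(key("penalty", type="long_polyA"))
    keys.add(key("terminal", type="IU"))
    for size in range(2, 41):
        keys.add(key("mismatch", type="initiation", size=str(size)))
    for size in range(1, 31):
        keys.add(key("bulge", size=str(size)))
    n_alpha = top_alpha
    for n in n_alpha:
        for r in range(2, 8):
            keys.add(key("CNG", sequence=f"C{n}G", repeats=str(r)))
    # generic single-mismatch doublets: one paired column flanking one
    # mismatched column, in both orders
    bottom_alpha = _alphabet(hybridization)[1]
    for a in top_alpha:
        for c in top_alpha:
            for d in bottom_alpha:
                if d == comp[c]:
                    continue
                keys.add(key("mismatch", sequence=f"{a}{c}/{comp[a]}{d}"))
                keys.add(key("mismatch", sequence=f"{c}{a}/{d}{comp[a]}"))
    # inosine doublets against any partner, next to any paired column
    for a in top_alpha:
        for x in bottom_alpha:
            keys.add(key("modified", sequence=f"I{a}/{x}{comp[a]}"))
            keys.add(key("modified", sequence=f"{a}I/{comp[a]}{x}"))
    return keys


def make_fixture_set(spec: FixtureSpec,
                     duplexes: list[Duplex] | None = None) -> ParameterSet:
    """A parameter set covering the plan's patterns (plus generic entries).

    Coverage is obtained by pricing the planned duplex against a recording
    store, so the emitted keys follow exactly the engine's conventions.
    Deterministic for a given spec: the ``random`` scheme iterates entries
    in sorted order under the plan's seed.
    """
    recorder = _RecordingSet(ThermoResult(spec.dh, spec.ds))
    targets = list(duplexes) if duplexes is not None else []
    if duplexes is None:
        duplex, _ = make_duplex(spec)
        targets.append(duplex)
    for duplex in targets:
        model = EnergyModel(recorder)
        segments = segment_duplex(duplex)
        assemble(duplex, segments, model)

    keys = _base_entries(spec.hybridization) | recorder.seen
    pset = ParameterSet(
        id=f"fixture-{spec.scheme}-{spec.seed}",
        hybridization_scope=spec.hybridization,
        metadata={"initiation-rule": "per_terminal", "reference-sodium": 1.0,
                  "citation": "synthetic fixture"},
    )
    if spec.scheme == "uniform":
        for k in sorted(keys, key=str):
            pset.entries[k] = ThermoResult(spec.dh, spec.ds)
    elif spec.scheme == "random":
        from .paramstore import reversed_key
        rng = random.Random(spec.seed)
        for k in sorted(keys, key=str):
            rk = reversed_key(k)
            if rk is not None and rk in pset.entries:
                # both orientations of a stack carry the same energy
                pset.entries[k] = pset.entries[rk]
                continue
            pset.entries[k] = ThermoResult(round(rng.uniform(-12000, -4000), 2),
                                           round(rng.uniform(-34, -12), 2))
    else:
        raise ValueError(f"unknown value scheme {spec.scheme!r}")
    # The symmetry correction is conventionally entropy-only.
    pset.entries[key("symmetry")] = ThermoResult(0.0, -1.4)
    return pset
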