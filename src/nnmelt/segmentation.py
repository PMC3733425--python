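"""Decompose an aligned duplex into mutually exclusive, typed patterns.

Maximal runs of perfectly matching Watson-Crick pairs are located first;
every remaining maximal run of consecutive non-perfect columns (possibly
containing gaps) becomes one pattern, typed by its gap topology:

* no unpaired-strand asymmetry and no gaps — single mismatch (1 column),
  tandem mismatch (2) or symmetric internal loop (>= 3);
* both strands contribute unpaired nucleotides — internal loop (L1 x L2);
* one strand contributes nothing — bulge loop (interior) or dangling
  end / long poly-A queue (at a duplex terminus);
* any column holding a modified residue folds the whole run into a single
  ``modified`` pattern, so an inosine adjacent to a mismatch is priced as
  one two-base-pair pattern.

Sequences that are entirely 2-7 CNG triplet repeats of a self-complementary
duplex are one dedicated ``cng_repeat`` pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import Duplex

PATTERN_KINDS = (
    "perfect", "single_mismatch", "tandem_mismatch", "internal_loop",
    "single_bulge", "long_bulge", "single_dangling", "second_dangling",
    "long_polyA", "modified", "cng_repeat",
)

#: Minimum length of a terminal all-adenine overhang priced as a poly-A
#: queue rather than a dangling end.  Configurable at segmentation time.
DEFAULT_POLYA_MIN = 2


@dataclass(frozen=True)
class PatternSegment:
    """A located, typed region of the duplex alignment.

    ``start`` is the first column (0-based), ``end`` is exclusive, so
    ``end - start`` is the column length L.  ``loop_sizes`` is the
    (L1, L2) nucleotide count per strand, present only for internal loops.
    ``repeats`` is set only for CNG patterns.
    """

    kind: str
    start: int
    end: int
    loop_sizes: tuple[int, int] | None = None
    repeats: int | None = None

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("empty pattern segment")
        if (self.loop_sizes is not None) != (self.kind == "internal_loop"):
            raise ValueError("loop_sizes present iff kind is internal_loop")

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_cng(duplex: Duplex) -> int | None:
    """Repeat count r in [2, 7] iff the top strand is exactly r identical
    CNG triplets of a self-complementary duplex, else None.

    The triplet must start with C (pairing G) and end with G (pairing C);
    self-complementarity is taken from the duplex flag or from the bottom
    strand being the top strand paired against itself (its reverse).
    """
    n = len(duplex)
    if n % 3 != 0 or not (2 <= n // 3 <= 7):
        return None
    top = duplex.top.symbols()
    bottom = duplex.bottom.symbols()
    if "-" in top or "-" in bottom:
        return None
    unit = top[:3]
    if unit[0] != "C" or unit[2] != "G" or any(t.is_modified for t in duplex.top):
        return None
    r = n // 3
    if any(top[3 * i: 3 * i + 3] != unit for i in range(r)):
        return None
    if not (duplex.self_complementary or bottom == tuple(reversed(top))):
        return None
    return r


def classify(run: tuple[int, int], duplex: Duplex,
             polya_min: int = DEFAULT_POLYA_MIN) -> tuple[str, tuple[int, int] | None]:
    """Type one maximal non-perfect column run ``[start, end)``.

    Returns ``(kind, loop_sizes)`` with ``loop_sizes`` set only for
    internal loops.
    """
    start, end = run
    n = len(duplex)
    cols = range(start, end)
    if any(duplex.top.tokens[i].is_modified or duplex.bottom.tokens[i].is_modified
           for i in cols):
        return "modified", None
    top_nts = sum(1 for i in cols if not duplex.top.tokens[i].is_gap)
    bottom_nts = sum(1 for i in cols if not duplex.bottom.tokens[i].is_gap)
    length = end - start
    terminal = start == 0 or end == n

    if top_nts == 0 or bottom_nts == 0:
        # Unpaired nucleotides on one strand only.
        overhang = duplex.top if bottom_nts == 0 else duplex.bottom
        count = max(top_nts, bottom_nts)
        if terminal:
            if (count >= polya_min
                    and all(overhang.tokens[i].symbol == "A" for i in cols)):
                return "long_polyA", None
            if count == 1:
                return "single_dangling", None
            return "second_dangling", None
        return ("single_bulge" if count == 1 else "long_bulge"), None

    # Both strands contribute nucleotides.
    if top_nts == bottom_nts == length:
        if length == 1:
            return "single_mismatch", None
        if length == 2:
            return "tandem_mismatch", None
        return "internal_loop", (length, length)
    return "internal_loop", (top_nts, bottom_nts)


def segment(duplex: Duplex,
            wobble: frozenset = frozenset(),
            polya_min: int = DEFAULT_POLYA_MIN) -> list[PatternSegment]:
    """Ordered, exclusive, covering decomposition of the duplex.

    ``wobble`` whitelists extra (top, bottom) symbol pairs counted as
    perfect stacks (G.U under RNA/RNA when the parameter set prices them).
    """
    r = detect_cng(duplex)
    if r is not None:
        return [PatternSegment("cng_repeat", 0, len(duplex), repeats=r)]

    n = len(duplex)
    perfect = [duplex.is_wc_pair(i, wobble) for i in range(n)]
    segments: list[PatternSegment] = []
    i = 0
    while i < n:
        j = i
        while j < n and perfect[j] == perfect[i]:
            j += 1
        if perfect[i]:
            segments.append(PatternSegment("perfect", i, j))
        else:
            kind, loop_sizes = classify((i, j), duplex, polya_min)
            segments.append(PatternSegment(kind, i, j, loop_sizes=loop_sizes))
        i = j
    return segments
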