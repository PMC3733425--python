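"""Strand tokenization, duplex construction and self-complementarity.

A strand is entered as linear text over an extended nucleotide alphabet:
the canonical bases ``A T C G U``, inosine ``I``, 2-hydroxyadenosine ``A*``,
the locked nucleic acids ``Al Cl Gl Tl`` and the azobenzene photo-switch
``X_C`` (cis) / ``X_T`` (trans).  Gaps in the alignment are written as
``-``.  Tokenization is greedy longest-match, so ``A*`` always wins over
``A`` followed by a stray ``*``.

A :class:`Duplex` is a positional alignment of a 5'->3' top strand over a
3'->5' bottom strand; the user expresses dangling ends, bulges and
asymmetric loops by placing dashes.  No alignment search is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlignmentError, SequenceParseError

GAP = "-"

#: Symbols of chemically modified residues (everything but A/T/C/G/U and gap).
MODIFIED_SYMBOLS = frozenset({"I", "A*", "Al", "Cl", "Gl", "Tl", "X_C", "X_T"})

CANONICAL_SYMBOLS = frozenset({"A", "T", "C", "G", "U"})

#: Canonical base each modified residue derives from (None for azobenzene).
BASE_CLASS = {
    "A": "A", "T": "T", "C": "C", "G": "G", "U": "U",
    "I": "A",  # behaves as a modified adenine with universal pairing
    "A*": "A", "Al": "A", "Cl": "C", "Gl": "G", "Tl": "T",
    "X_C": None, "X_T": None, GAP: None,
}

#: Token inventory ordered longest-first for the greedy scanner.
_TOKEN_INVENTORY = ("X_C", "X_T", "A*", "Al", "Cl", "Gl", "Tl",
                    "A", "T", "C", "G", "U", "I", GAP)

HYBRIDIZATIONS = ("dnadna", "rnarna", "dnarna", "rnadna", "mrnarna")

#: Nucleic-acid type of (top, bottom) strand per hybridization id.
STRAND_TYPES = {
    "dnadna": ("dna", "dna"),
    "rnarna": ("rna", "rna"),
    "dnarna": ("dna", "rna"),
    "rnadna": ("rna", "dna"),
    "mrnarna": ("rna", "rna"),  # 2'-O-methyl RNA against RNA
}

#: Watson-Crick complement of a canonical base, keyed by the *partner*
#: strand's nucleic-acid type.
COMPLEMENT = {
    "dna": {"A": "T", "T": "A", "U": "A", "C": "G", "G": "C", GAP: GAP},
    "rna": {"A": "U", "T": "A", "U": "A", "C": "G", "G": "C", GAP: GAP},
}

FIVE_TO_THREE = "5'->3'"
THREE_TO_FIVE = "3'->5'"


@dataclass(frozen=True)
class NucleotideToken:
    """One residue (or gap) of a strand."""

    symbol: str

    def __post_init__(self):
        if self.symbol not in _TOKEN_INVENTORY:
            raise SequenceParseError(f"unknown nucleotide symbol {self.symbol!r}")

    @property
    def is_gap(self) -> bool:
        return self.symbol == GAP

    @property
    def is_modified(self) -> bool:
        return self.symbol in MODIFIED_SYMBOLS

    @property
    def base_class(self) -> str | None:
        return BASE_CLASS[self.symbol]

    def __str__(self) -> str:
        return self.symbol


@dataclass(frozen=True)
class Strand:
    """An ordered, oriented run of tokens; round-trips to its source text."""

    tokens: tuple[NucleotideToken, ...]
    orientation: str = FIVE_TO_THREE

    def __post_init__(self):
        if not self.tokens:
            raise SequenceParseError("a strand must contain at least one token")
        if all(t.is_gap for t in self.tokens):
            raise SequenceParseError("a strand consisting only of gaps is invalid")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def text(self) -> str:
        return "".join(t.symbol for t in self.tokens)

    def symbols(self) -> tuple[str, ...]:
        return tuple(t.symbol for t in self.tokens)

    def reversed(self, orientation: str | None = None) -> "Strand":
        return Strand(tuple(reversed(self.tokens)),
                      orientation or self.orientation)


def _normalize(text: str) -> str:
    # Canonical letters are case-insensitive; the locked-nucleic-acid marker
    # must stay lowercase 'l' to avoid ambiguity, so it is kept verbatim.
    out = []
    for ch in text:
        if ch.upper() in "ATCGUIX":
            out.append(ch.upper())
        else:
            out.append(ch)
    return "".join(out)


def tokenize(text: str, orientation: str = FIVE_TO_THREE) -> Strand:
    """Greedy longest-match tokenization of strand text.

    Modifier characters (``*``, ``l``, ``_C``, ``_T``) bind to the preceding
    base character to form a single token; ``-`` becomes a gap token.

    Raises
    ------
    SequenceParseError
        On an unknown character or dangling modifier, naming the 0-based
        offset of the failure.
    """
    if not text:
        raise SequenceParseError("empty strand text", offset=0)
    text = _normalize(text)
    tokens: list[NucleotideToken] = []
    i = 0
    while i < len(text):
        for sym in _TOKEN_INVENTORY:
            if text.startswith(sym, i):
                tokens.append(NucleotideToken(sym))
                i += len(sym)
                break
        else:
            raise SequenceParseError(
                f"cannot parse strand text at offset {i}: {text[i:i + 3]!r}",
                offset=i,
            )
    return Strand(tuple(tokens), orientation)


def complement(strand: Strand, hybridization: str) -> Strand:
    """Position-wise Watson-Crick complement forming the partner strand.

    The partner's nucleic-acid type (hence A<->T vs A<->U) follows from the
    hybridization id; gaps map to gaps and the orientation flag is flipped.
    Modified residues have no defined complement: the caller must then
    supply the second strand explicitly.
    """
    if hybridization not in STRAND_TYPES:
        raise AlignmentError(f"unknown hybridization type {hybridization!r}")
    partner_type = (STRAND_TYPES[hybridization][1]
                    if strand.orientation == FIVE_TO_THREE
                    else STRAND_TYPES[hybridization][0])
    table = COMPLEMENT[partner_type]
    out = []
    for pos, tok in enumerate(strand.tokens):
        if tok.is_modified:
            raise SequenceParseError(
                f"cannot complement modified nucleotide {tok.symbol!r} at "
                f"position {pos}; supply the second strand explicitly",
                offset=pos,
            )
        out.append(NucleotideToken(table[tok.symbol]))
    flipped = THREE_TO_FIVE if strand.orientation == FIVE_TO_THREE else FIVE_TO_THREE
    return Strand(tuple(out), flipped)


def reverse_complement_text(text: str, nucleic_type: str = "dna") -> str:
    """Reverse complement of canonical strand text (helper for detection)."""
    table = COMPLEMENT[nucleic_type]
    return "".join(table[c] for c in reversed(text))


@dataclass(frozen=True)
class Duplex:
    """Two positionally aligned strands plus the hybridization type."""

    top: Strand          # 5'->3'
    bottom: Strand       # 3'->5', same column order as top
    hybridization: str
    self_complementary: bool = False

    def __post_init__(self):
        if self.hybridization not in STRAND_TYPES:
            raise AlignmentError(
                f"unknown hybridization type {self.hybridization!r}; "
                f"expected one of {', '.join(HYBRIDIZATIONS)}")
        if len(self.top) != len(self.bottom):
            raise AlignmentError(
                f"strands have different token counts "
                f"({len(self.top)} vs {len(self.bottom)}); align them with dashes")
        for i, (t, b) in enumerate(zip(self.top, self.bottom)):
            if t.is_gap and b.is_gap:
                raise AlignmentError(f"both strands have a gap at column {i}")

    def __len__(self) -> int:
        return len(self.top)

    def column(self, i: int) -> tuple[str, str]:
        return self.top.tokens[i].symbol, self.bottom.tokens[i].symbol

    def is_wc_pair(self, i: int, wobble: frozenset = frozenset()) -> bool:
        """True iff column i is a canonical Watson-Crick pair.

        ``wobble`` may whitelist extra (top, bottom) pairs, e.g. G.U stacks
        under RNA/RNA when the active parameter set prices them.
        """
        t, b = self.top.tokens[i], self.bottom.tokens[i]
        if t.is_gap or b.is_gap or t.is_modified or b.is_modified:
            return False
        bottom_type = STRAND_TYPES[self.hybridization][1]
        if COMPLEMENT[bottom_type][t.symbol] == b.symbol:
            return True
        return (t.symbol, b.symbol) in wobble

    def paired_columns(self) -> list[int]:
        return [i for i in range(len(self))
                if not (self.top.tokens[i].is_gap or self.bottom.tokens[i].is_gap)]


def is_self_complementary(duplex: Duplex) -> bool:
    """Detect whether the paired core of the top strand is its own
    reverse complement.

    Detection applies to perfectly matching duplexes, with or without
    dangling ends; any other structure (mismatches, modified residues,
    heteroduplex types) returns False and an explicit user flag then
    governs.
    """
    top_type, bottom_type = STRAND_TYPES[duplex.hybridization]
    if top_type != bottom_type:
        return False
    core = duplex.paired_columns()
    if not core:
        return False
    for i in core:
        if not duplex.is_wc_pair(i):
            return False
    text = "".join(duplex.top.tokens[i].symbol for i in core)
    return text == reverse_complement_text(text, top_type)


def build_duplex(seq1: str,
                 seq2: str | None = None,
                 hybridization: str = "dnadna",
                 self_flag: bool = False) -> Duplex:
    """Build an aligned duplex from one or two strand texts.

    With ``seq2`` absent the bottom strand is generated: by Watson-Crick
    complementation normally, or — when ``self_flag`` is set — by pairing
    the strand against its own reverse, which is how a self-complementary
    sequence containing mismatches or modified residues duplexes with
    itself.
    """
    top = tokenize(seq1, FIVE_TO_THREE)
    if seq2 is not None:
        bottom = tokenize(seq2, THREE_TO_FIVE)
    elif self_flag:
        bottom = top.reversed(THREE_TO_FIVE)
    else:
        bottom = complement(top, hybridization)
    duplex = Duplex(top, bottom, hybridization, self_complementary=self_flag)
    if not self_flag and is_self_complementary(duplex):
        duplex = Duplex(top, bottom, hybridization, self_complementary=True)
    return duplex
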