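"""Independent brute-force oracles.

These are deliberately written from first principles (exhaustive search,
naive scans) and share no code with the package implementation they check.
"""

from __future__ import annotations

VOCAB = ("X_C", "X_T", "A*", "Al", "Cl", "Gl", "Tl",
         "A", "T", "C", "G", "U", "I", "-")


def all_tokenizations(text: str) -> list[tuple[str, ...]]:
    """Every way of splitting ``text`` into vocabulary tokens."""
    if not text:
        return [()]
    out = []
    for tok in VOCAB:
        if text.startswith(tok):
            for rest in all_tokenizations(text[len(tok):]):
                out.append((tok,) + rest)
    return out


def greedy_tokenization(text: str) -> tuple[str, ...] | None:
    """The unique longest-match tokenization, found by exhaustive search:
    among all tokenizations, the one whose token-length sequence is
    lexicographically maximal (the greedy scanner always prefers the
    longest prefix)."""
    candidates = all_tokenizations(text)
    if not candidates:
        return None
    return max(candidates, key=lambda toks: [len(t) for t in toks])


_COMP_DNA = {"A": "T", "T": "A", "U": "A", "C": "G", "G": "C"}
_COMP_RNA = {"A": "U", "T": "A", "U": "A", "C": "G", "G": "C"}


def naive_reverse_complement(text: str, nucleic: str = "dna") -> str:
    table = _COMP_DNA if nucleic == "dna" else _COMP_RNA
    return "".join(table[c] for c in text[::-1])


def naive_self_complementary(text: str, nucleic: str = "dna") -> bool:
    return text == naive_reverse_complement(text, nucleic)


_MODIFIED = {"I", "A*", "Al", "Cl", "Gl", "Tl", "X_C", "X_T"}


def _column_state(t: str, b: str, hybridization: str) -> str:
    if t in _MODIFIED or b in _MODIFIED:
        return "modified"
    if t == "-":
        return "gap_top"
    if b == "-":
        return "gap_bottom"
    comp = _COMP_RNA if hybridization in ("rnarna", "dnarna", "mrnarna") else _COMP_DNA
    return "perfect" if comp.get(t) == b else "mismatch"


def naive_segments(top: list[str], bottom: list[str], hybridization: str,
                   polya_min: int = 2) -> list[tuple]:
    """Independent re-derivation of the pattern decomposition.

    Returns tuples (kind, start, end, loop_sizes-or-None).
    """
    n = len(top)
    states = [_column_state(top[i], bottom[i], hybridization) for i in range(n)]
    out = []
    i = 0
    while i < n:
        j = i
        while j < n and (states[j] == "perfect") == (states[i] == "perfect"):
            j += 1
        if states[i] == "perfect":
            out.append(("perfect", i, j, None))
        else:
            out.append(_classify_run(top, bottom, states, i, j, n, polya_min))
        i = j
    return out


def _classify_run(top, bottom, states, i, j, n, polya_min):
    run_states = states[i:j]
    if "modified" in run_states:
        return ("modified", i, j, None)
    n_top = sum(1 for k in range(i, j) if top[k] != "-")
    n_bot = sum(1 for k in range(i, j) if bottom[k] != "-")
    touches_end = i == 0 or j == n
    if n_top == 0 or n_bot == 0:
        count = max(n_top, n_bot)
        letters = [top[k] if top[k] != "-" else bottom[k] for k in range(i, j)]
        if touches_end:
            if count >= polya_min and set(letters) == {"A"}:
                return ("long_polyA", i, j, None)
            if count == 1:
                return ("single_dangling", i, j, None)
            return ("second_dangling", i, j, None)
        return (("single_bulge" if count == 1 else "long_bulge"), i, j, None)
    if n_top == n_bot == j - i:
        if j - i == 1:
            return ("single_mismatch", i, j, None)
        if j - i == 2:
            return ("tandem_mismatch", i, j, None)
        return ("internal_loop", i, j, (j - i, j - i))
    return ("internal_loop", i, j, (n_top, n_bot))
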