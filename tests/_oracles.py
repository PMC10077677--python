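"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths they check: the motif oracle
expands an IUPAC code into its full concrete word set and string-searches
each word; the alignment oracle is a direct memoized recursion over edit
operations with affine gap state.
"""

from functools import lru_cache
from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def expand_words(code: str) -> list[str]:
    """All concrete words an IUPAC code stands for (N stays literal N: a
    sequence N only satisfies a pattern N)."""
    return ["".join(p) for p in product(*(IUPAC[c] for c in code))]


def find_all(seq: str, word: str) -> list[int]:
    out = []
    i = seq.find(word)
    while i != -1:
        out.append(i)
        i = seq.find(word, i + 1)
    return out


def oracle_match_positions(seq: str, code: str, both_strands: bool = False) -> set[int]:
    """Forward-coordinate window offsets matching the code; with
    ``both_strands`` the reverse-complemented concrete words are also
    searched on the forward sequence."""
    words = set(expand_words(code))
    if both_strands:
        words |= {"".join(_COMP[c] for c in reversed(w)) for w in expand_words(code)}
    hits: set[int] = set()
    for w in words:
        hits.update(find_all(seq, w))
    return hits


def oracle_align_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> float:
    """Optimal affine-gap global alignment score by memoized recursion over
    (position in a, position in b, previous operation); end gaps penalized."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")
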