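"""IUPAC nucleotide alphabet utilities shared by the motif stages.

A degenerate consensus is a string over the 15-letter IUPAC alphabet.  Two
codes are *compatible* when their base sets intersect; scanning a promoter for
a consensus requires compatibility at every aligned position (no mismatches).
An ``N`` in a *sequence* is treated like any other degenerate code, i.e. it is
compatible with everything.
"""

from __future__ import annotations

import numpy as np

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_SET_TO_CODE = {frozenset(bases): code for code, bases in IUPAC.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_CODES = list(IUPAC)
_CODE_INDEX = {code: i for i, code in enumerate(_CODES)}

# _COMPAT[i, j] is True when codes i and j share at least one base.
_COMPAT = np.array(
    [[bool(set(IUPAC[a]) & set(IUPAC[b])) for b in _CODES] for a in _CODES],
    dtype=bool,
)


def code_for(bases) -> str:
    """Minimal IUPAC code covering a nonempty collection of A/C/G/T bases."""
    key = frozenset(bases)
    if not key or not key <= set("ACGT"):
        raise ValueError(f"not a set of concrete bases: {sorted(bases)!r}")
    return _SET_TO_CODE[key]


def bases_of(code: str) -> frozenset:
    try:
        return frozenset(IUPAC[code.upper()])
    except KeyError:
        raise ValueError(f"not an IUPAC code: {code!r}") from None


def is_valid(consensus: str) -> bool:
    return len(consensus) > 0 and all(ch.upper() in IUPAC for ch in consensus)


def revcomp(s: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    try:
        return "".join(COMPLEMENT[ch] for ch in reversed(s.upper()))
    except KeyError as exc:
        raise ValueError(f"not an IUPAC string: {s!r}") from exc


def compatible(a: str, b: str) -> bool:
    """True when two single IUPAC codes share at least one concrete base."""
    return bool(bases_of(a) & bases_of(b))


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer code indices (raises on non-IUPAC letters)."""
    try:
        return np.fromiter(
            (_CODE_INDEX[ch] for ch in seq.upper()), dtype=np.int8, count=len(seq)
        )
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in sequence: {exc}") from None


def scan(seq: str, pattern: str, both_strands: bool = True) -> list[tuple[int, str]]:
    """All exact (0-mismatch) occurrences of an IUPAC pattern in a sequence.

    Returns ``(offset, strand)`` pairs where ``offset`` is the 0-based start of
    the matched window on the forward sequence for both strands.  A window
    matches when every position's base set intersects the pattern's.
    """
    if not is_valid(pattern):
        raise ValueError(f"invalid IUPAC pattern: {pattern!r}")
    w, L = len(pattern), len(seq)
    if w > L:
        return []
    enc = encode(seq)
    n_win = L - w + 1
    hits: list[tuple[int, str]] = []
    strands = (("+", pattern), ("-", revcomp(pattern))) if both_strands else (("+", pattern),)
    for strand, pat in strands:
        ok = np.ones(n_win, dtype=bool)
        for j, ch in enumerate(pat.upper()):
            ok &= _COMPAT[_CODE_INDEX[ch]][enc[j : j + n_win]]
        hits.extend((int(i), strand) for i in np.nonzero(ok)[0])
    hits.sort()
    return hits
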