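"""IUPAC nucleotide alphabet utilities.

Every sequence handled by this package is a string over the one-letter
IUPAC nucleotide codes (A, C, G, T plus the ambiguity codes R, Y, S, W,
K, M, B, D, H, V, N).  Ambiguity codes denote *sets* of bases; most
operations here reduce to set arithmetic on 4-bit masks (A=1, C=2, G=4,
T=8).
"""

from __future__ import annotations

# 4-bit base masks: A=1, C=2, G=4, T=8
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

#: code -> frozenset of concrete bases
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(CODE_TO_BASES)

#: code -> 4-bit mask over {A,C,G,T}
CODE_TO_MASK: dict[str, int] = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in CODE_TO_BASES.items()
}

#: 4-bit mask -> minimal covering IUPAC code
MASK_TO_CODE: dict[int, str] = {mask: code for code, mask in CODE_TO_MASK.items()}

_COMP_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: code -> complement code (complement of the base set)
COMPLEMENT: dict[str, str] = {
    code: MASK_TO_CODE[sum(_BASE_BITS[_COMP_BASE[b]] for b in bases)]
    for code, bases in CODE_TO_BASES.items()
}

_COMP_TABLE = str.maketrans(COMPLEMENT)


def is_valid(seq: str) -> bool:
    """True when every character of *seq* is an IUPAC nucleotide code."""
    return all(c in IUPAC_CODES for c in seq)


def first_invalid(seq: str) -> int | None:
    """0-based index of the first non-IUPAC character, or None if valid."""
    for i, c in enumerate(seq):
        if c not in IUPAC_CODES:
            return i
    return None


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Ambiguity codes are complemented as base sets (Y<->R, K<->M, W, S
    and N map to themselves), so e.g. ``revcomp("CACTTCCYY") ==
    "RRGGAAGTG"`` and ``revcomp`` is an involution on the full alphabet.
    """
    bad = first_invalid(seq)
    if bad is not None:
        raise ValueError(
            f"invalid IUPAC nucleotide code {seq[bad]!r} at position {bad + 1}"
        )
    return seq.translate(_COMP_TABLE)[::-1]


def codes_intersect(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC codes share at least one base.

    This is the matching rule used for consensus sequences, where an
    ambiguity code should match any base it covers.
    """
    return bool(CODE_TO_MASK[a] & CODE_TO_MASK[b])


def minimal_code(bases: set[str] | frozenset[str]) -> str:
    """Minimal IUPAC code covering a non-empty set of concrete bases."""
    if not bases:
        raise ValueError("cannot encode an empty base set")
    mask = 0
    for b in bases:
        for base in CODE_TO_BASES[b]:
            mask |= _BASE_BITS[base]
    return MASK_TO_CODE[mask]
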