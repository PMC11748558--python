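"""IUPAC degenerate-nucleotide algebra.

A degenerate sequence is a plain string over the 15-letter IUPAC nucleotide
alphabet (``A C G T R Y S W K M B D H V N``), where each ambiguity code
stands for a set of concrete bases (``Y`` = C or T, ``N`` = any, ...).  A
degenerate primer therefore encodes a pool of concrete primers; its
*degeneracy* is the size of that pool — the product over positions of the
number of bases each symbol encodes.

Everything downstream (window consensus, in-silico PCR site finding) reduces
to two primitives defined here: per-symbol base sets and degenerate-aware
compatibility (two symbols are compatible iff their base sets intersect).
Base sets are also exposed as 4-bit masks so that template scanning can run
vectorised over numpy arrays.
"""

from __future__ import annotations

from itertools import product as _product

import numpy as np

__all__ = [
    "IUPAC_BASES",
    "BASES_TO_SYMBOL",
    "normalize",
    "bases",
    "symbol_for_bases",
    "degeneracy",
    "expand",
    "complement",
    "revcomp",
    "matches",
    "encode_mask",
]

#: IUPAC nucleotide code -> set of concrete bases.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse table: frozenset of bases -> the minimal IUPAC code covering it.
BASES_TO_SYMBOL: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# 4-bit mask per symbol: bit0=A, bit1=C, bit2=G, bit3=T.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_SYMBOL_MASK = {
    sym: np.uint8(sum(_BASE_BIT[b] for b in bs)) for sym, bs in IUPAC_BASES.items()
}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _m in _SYMBOL_MASK.items():
    _MASK_LUT[ord(_sym)] = _m


class InvalidSymbolError(ValueError):
    """A character outside the IUPAC nucleotide alphabet (position reported)."""


def normalize(seq: str) -> str:
    """Validate and canonicalise a nucleotide string.

    Upper-cases, maps U to T, and rejects anything outside the IUPAC
    alphabet — including gap characters, which must be stripped upstream.
    """
    if not seq:
        raise ValueError("empty sequence")
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in IUPAC_BASES:
            raise InvalidSymbolError(
                f"invalid IUPAC symbol {ch!r} at position {i} (0-based)"
            )
    return out


def bases(symbol: str) -> frozenset[str]:
    """Concrete bases encoded by one IUPAC symbol."""
    try:
        return IUPAC_BASES[symbol.upper()]
    except KeyError:
        raise InvalidSymbolError(f"invalid IUPAC symbol {symbol!r}") from None


def symbol_for_bases(base_set: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC code covering a nonempty set of concrete bases."""
    key = frozenset(base_set)
    try:
        return BASES_TO_SYMBOL[key]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(base_set)!r}") from None


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate sequence encodes.

    Product over positions of the per-symbol base-set size; 1 for a fully
    concrete sequence.
    """
    seq = normalize(seq)
    d = 1
    for ch in seq:
        d *= len(IUPAC_BASES[ch])
    return d


def expand(seq: str, limit: int = 4096) -> set[str]:
    """All concrete A/C/G/T strings compatible with ``seq``.

    Refuses to expand beyond ``limit`` concrete sequences so a stray
    poly-N string cannot blow up memory.
    """
    seq = normalize(seq)
    d = degeneracy(seq)
    if d > limit:
        raise ValueError(f"degeneracy {d} exceeds expansion limit {limit}")
    return {"".join(p) for p in _product(*(sorted(IUPAC_BASES[ch]) for ch in seq))}


def complement(seq: str) -> str:
    """IUPAC-aware complement (R<->Y, K<->M, B<->V, D<->H; S, W, N fixed)."""
    return normalize(seq).translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement; an involution."""
    return complement(seq)[::-1]


def encode_mask(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of 4-bit base masks.

    Two positions are compatible iff the bitwise AND of their masks is
    nonzero — the vectorised form of base-set intersection.
    """
    seq = normalize(seq)
    return _MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def matches(primer: str, window: str, max_mismatch: int = 0) -> tuple[bool, int]:
    """Degenerate-aware comparison of two equal-length sequences.

    A position is compatible iff the two symbols' base sets intersect, so a
    template ``N`` never counts as a mismatch.  Returns ``(matched,
    mismatches)`` with ``matched`` true iff the number of incompatible
    positions is at most ``max_mismatch``.
    """
    p = normalize(primer)
    w = normalize(window)
    if len(p) != len(w):
        raise ValueError(f"length mismatch: {len(p)} vs {len(w)}")
    mm = int(np.count_nonzero((encode_mask(p) & encode_mask(w)) == 0))
    return mm <= max_mismatch, mm
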