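"""Nucleotide and IUPAC ambiguity-code utilities.

Sequences are manipulated either as Python strings or as numpy uint8 arrays
holding a 4-bit allele mask per position (A=1, C=2, G=4, T=8).  Ambiguity
codes are the bitwise OR of their alleles; N carries all four bits.  The mask
representation makes allele-set intersection a vectorized ``&``.
"""

from __future__ import annotations

import numpy as np

DNA = "ACGT"

# 4-bit allele masks
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

IUPAC_TO_SET: dict[str, frozenset[str]] = {
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

SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_SET.items()}

CODE_TO_MASK: dict[str, int] = {
    code: sum(_BITS[b] for b in alleles) for code, alleles in IUPAC_TO_SET.items()
}
MASK_TO_CODE: dict[int, str] = {m: c for c, m in CODE_TO_MASK.items()}

N_MASK = 15

# string -> mask lookup table indexed by ASCII byte (0 = invalid)
_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _LUT[ord(_c)] = _m
    _LUT[ord(_c.lower())] = _m

_INV_LUT = np.full(256, ord("?"), dtype=np.uint8)
for _m, _c in MASK_TO_CODE.items():
    _INV_LUT[_m] = ord(_c)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into a uint8 allele-mask array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _LUT[raw]
    if (masks == 0).any():
        bad = seq[int(np.argmax(masks == 0))]
        raise ValueError(f"invalid nucleotide code {bad!r}")
    return masks


def decode(masks: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _INV_LUT[masks].tobytes().decode("ascii")


def is_ambiguous(code: str) -> bool:
    """True for two-to-four-allele IUPAC codes other than N."""
    return code != "N" and len(IUPAC_TO_SET[code]) > 1


def het_code(a: str, b: str) -> str:
    """IUPAC code for an unordered pair of distinct bases, e.g. A,G -> R."""
    return SET_TO_IUPAC[frozenset((a, b))]


def identity(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Fraction of matching positions between two equal-length sequences.

    Positions with N in either sequence are excluded from numerator and
    denominator; IUPAC codes match when their allele sets intersect.  Returns
    0.0 when no position is comparable.
    """
    am = encode(a) if isinstance(a, str) else a
    bm = encode(b) if isinstance(b, str) else b
    if am.shape != bm.shape:
        raise ValueError(f"length mismatch: {am.size} vs {bm.size}")
    comparable = (am != N_MASK) & (bm != N_MASK)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return 0.0
    matches = int(((am & bm) > 0)[comparable].sum())
    return matches / n_comp
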