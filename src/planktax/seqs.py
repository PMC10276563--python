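"""Nucleotide sequence helpers: IUPAC degeneracy, complementing, encoding.

Sequences are plain upper-case strings over the IUPAC nucleotide alphabet.
For degenerate matching every base is represented as a 4-bit mask over
{A, C, G, T}; two bases are compatible iff their masks intersect.
"""

from __future__ import annotations

import numpy as np

# 4-bit presence masks: A=1, C=2, G=4, T=8
IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    code: frozenset(b for b in "ACGT" if IUPAC_MASK[code] & IUPAC_MASK[b])
    for code in IUPAC_MASK
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)

# byte -> mask lookup tables for fast numpy encoding
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_TABLE[ord(_c)] = _m
    _MASK_TABLE[ord(_c.lower())] = _m

# variant where N (and other codes containing N-like full ambiguity) in a
# *template* matches nothing -- used by the primer-site scanner
_MASK_TABLE_STRICT_N = _MASK_TABLE.copy()
_MASK_TABLE_STRICT_N[ord("N")] = 0
_MASK_TABLE_STRICT_N[ord("n")] = 0


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_masks(seq: str, template_n_matches_nothing: bool = False) -> np.ndarray:
    """Encode a sequence as an array of 4-bit IUPAC masks.

    With ``template_n_matches_nothing`` an ``N`` encodes to the empty mask,
    so it can never satisfy a primer base; unknown characters always encode
    to the empty mask.
    """
    table = _MASK_TABLE_STRICT_N if template_n_matches_nothing else _MASK_TABLE
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[raw]


def encode_acgt(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 (anything else gets a unique sentinel >3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        out[raw == ord(b)] = i
        out[raw == ord(b.lower())] = i
    return out


def realize_degenerate(seq: str) -> str:
    """One concrete A/C/G/T realization of a degenerate sequence.

    Deterministic: the alphabetically first base of each expansion is taken.
    """
    return "".join(min(IUPAC_EXPANSION[c]) for c in seq)
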