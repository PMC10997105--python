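"""IUPAC nucleotide alphabet: base sets, bitmasks and reverse complement.

A primer position *matches* a template position when the two characters'
nucleotide sets intersect; degeneracy is therefore symmetric between primer
and template. Bitmask encoding (A=1, C=2, G=4, T=8) makes the intersection
test a bitwise AND, which the scanning engine vectorises with numpy.
"""

from __future__ import annotations

import numpy as np

# Base sets for every IUPAC nucleotide code (T and U are synonymous; U is
# normalised to T on input).
IUPAC_SETS: dict[str, frozenset[str]] = {
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

VALID_CODES = frozenset(IUPAC_SETS)

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASKS: dict[str, int] = {
    code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

# Complement permutes the underlying base sets: A<->T, C<->G, and every
# ambiguity code maps to the code of the complemented set.
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

# Minimal IUPAC code for each non-empty subset of {A,C,G,T}.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

# Lookup table mapping ASCII byte -> bitmask (0 for invalid characters).
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _mask in IUPAC_MASKS.items():
    _MASK_TABLE[ord(_code)] = _mask


def is_iupac(sequence: str) -> bool:
    """True if every character of ``sequence`` is a valid IUPAC code."""
    return bool(sequence) and set(sequence) <= VALID_CODES


def reverse_complement(sequence: str) -> str:
    """Reverse complement, preserving ambiguity codes."""
    bad = set(sequence) - VALID_CODES
    if bad:
        raise ValueError(f"invalid character {sorted(bad)[0]!r} in sequence")
    return sequence.translate(_COMPLEMENT_TABLE)[::-1]


def encode_masks(sequence: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of IUPAC bitmasks.

    Raises ValueError on the first invalid character.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    masks = _MASK_TABLE[arr]
    if not masks.all():
        pos = int(np.argmin(masks != 0))
        raise ValueError(
            f"invalid character {sequence[pos]!r} at position {pos}"
        )
    return masks
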