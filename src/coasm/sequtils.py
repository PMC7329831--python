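"""Small shared DNA sequence helpers (complement tables, revcomp)."""

from __future__ import annotations

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMP_BYTES = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

BASES = "ACGT"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# complement by index: A<->T, C<->G
COMP_INDEX = (3, 2, 1, 0)
BASES_B = b"ACGT"
BASE_INDEX_B = {65: 0, 67: 1, 71: 2, 84: 3}  # ord map for bytes iteration


def revcomp(seq):
    """Reverse complement of a DNA ``str`` or ``bytes`` (N-safe)."""
    if isinstance(seq, bytes):
        return seq.translate(_COMP_BYTES)[::-1]
    return seq.translate(_COMP_STR)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMP_STR)
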