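"""Small shared helpers: sequence orientation and coordinate conversion.

All genomic coordinates in this package are 0-based half-open. Conversion to
and from 1-based inclusive display coordinates happens only here.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRANDS = ("+", "-")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_one_based(pos0: int) -> int:
    """0-based position -> 1-based display coordinate."""
    return pos0 + 1


def from_one_based(pos1: int) -> int:
    """1-based display coordinate -> 0-based position."""
    return pos1 - 1
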