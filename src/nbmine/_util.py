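"""Small shared helpers: sequence encoding, complementing, rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNWSMKRYacgtnwsmkry", b"TGCANWSKMYRtgcanwskmyr")

# IUPAC nucleotide degeneracy. N in a *read* is deliberately absent from every
# value set: an uncalled base never counts as a primer match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """View a sequence string as a uint8 byte array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def phred_from_string(qual: str, offset: int = 33) -> np.ndarray:
    """Decode an offset-encoded quality string to integer Phred scores."""
    q = encode(qual).astype(np.int16) - offset
    if q.size and q.min() < 0:
        raise ValueError("quality string below Phred offset")
    return q


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report-style), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage with half-up rounding; 0 when the denominator is 0."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
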