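"""Small shared DNA utilities: encoding, complementation, IUPAC handling."""

from __future__ import annotations

import numpy as np

DNA = "ACGTN"
# A=0 C=1 G=2 T=3 N=4; complement indices
_COMP_IDX = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(DNA):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC degenerate codes and their complements (W, S, N are self-complementary)
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMNacgtryswkmn", "TGCAYRSWMKNtgcayrswmkn")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0..T=3, anything else N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(DNA[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; non-ACGT become their IUPAC complement."""
    return seq.translate(_COMP_TABLE)[::-1]


def iupac_revcomp(seq: str) -> str:
    """Reverse complement over the degenerate IUPAC alphabet."""
    return seq.translate(_IUPAC_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_IDX[codes][::-1]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    acgt = codes < 4
    if not acgt.any():
        return 0.0
    return float(np.isin(codes[acgt], (1, 2)).mean())
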