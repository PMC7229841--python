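"""Small nucleotide-sequence utilities shared across the package.

Sequences are plain uppercase strings over the DNA alphabet. Only A, C, G,
T and N are accepted in references; other IUPAC ambiguity codes are
rejected up front so that downstream mismatch counting has unambiguous
semantics (N never matches a concrete guide base, but satisfies an N in a
PAM pattern).
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC code -> set of concrete bases it stands for (PAM patterns only).
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# minimal standard-code translation used for codon re-translation
_CODON_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_CODON_BASES)
    for j, b in enumerate(_CODON_BASES)
    for k, c in enumerate(_CODON_BASES)
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def validate_reference(seq: str, name: str = "reference") -> str:
    """Uppercase *seq* and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(
            f"{name} contains unsupported characters {sorted(bad)}; "
            "only A/C/G/T/N are accepted"
        )
    return seq


def matches_iupac(base: str, code: str) -> bool:
    """True if reference *base* satisfies IUPAC *code*.

    A reference N is treated as an unknown base: it satisfies only a
    pattern N (which accepts anything), never a more specific code.
    """
    allowed = IUPAC[code]
    if base == "N":
        return len(allowed) == 4
    return base in allowed


def matches_pattern(seq: str, pattern: str) -> bool:
    """Match *seq* against an IUPAC *pattern* of the same length."""
    if len(seq) != len(pattern):
        return False
    return all(matches_iupac(b, c) for b, c in zip(seq, pattern))


def translate(cds: str) -> str:
    """Translate an in-frame CDS with the standard code ('*' = stop)."""
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
# code 4 = N / anything else: never equal to a concrete base code


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
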