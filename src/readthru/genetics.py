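"""Genetic-code constants and amino-acid property tables.

Everything here operates on RNA-alphabet strings (A/C/G/U, 5'->3').
DNA input is normalised at the catalog boundary, not here.
"""

from __future__ import annotations

NUCLEOTIDES = ("A", "C", "G", "U")
STOP_CODONS = ("UAA", "UAG", "UGA")

#: Standard genetic code, RNA codons -> one-letter amino acid ('*' for stop).
CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    # Compact encoding of the standard code, ordered U, C, A, G per position.
    bases = "UCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()

SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))
ALL_CODONS = tuple(sorted(CODON_TABLE))
AMINO_ACIDS = tuple(sorted(set(CODON_TABLE.values()) - {"*"}))

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

POSITIVE_AA = frozenset("KRH")
NEGATIVE_AA = frozenset("DE")
AROMATIC_AA = frozenset("FWY")
# Polar uncharged side chains.
POLAR_AA = frozenset("STNQCY")
# Small residues (Taylor classification "small" set).
SMALL_AA = frozenset("ACDGNPSTV")


def translate(rna: str) -> str:
    """Translate an in-frame RNA string; stops render as '*'."""
    if len(rna) % 3 != 0:
        raise ValueError(f"length {len(rna)} is not a multiple of 3")
    return "".join(CODON_TABLE[rna[i:i + 3]] for i in range(0, len(rna), 3))


def charge_class(aa: str) -> str:
    if aa in POSITIVE_AA:
        return "positive"
    if aa in NEGATIVE_AA:
        return "negative"
    return "neutral"


def normalize_rna(seq: str) -> str:
    """Uppercase and transcribe T->U. Validation happens in the catalog."""
    return seq.upper().replace("T", "U")
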