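"""Shared genetic-code helpers (standard nuclear code, DNA alphabet)."""

from __future__ import annotations

import itertools

NUCLEOTIDES = "ACGT"

# IUPAC nucleotide ambiguity codes -> concrete base sets.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASES = ["T", "C", "A", "G"]
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

#: codon (upper-case DNA) -> one-letter amino acid, '*' for stop.
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AMINO[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def translate(cds: str) -> str:
    """Translate an in-frame DNA sequence; raises on partial codons."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"sequence length {len(cds)} not divisible by 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def has_internal_stop(cds: str) -> bool:
    """True if any codon before the last encodes a stop."""
    protein = translate(cds)
    return "*" in protein[:-1]


def split_codons(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"sequence length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def expand_ambiguities(seq: str, max_ambiguous: int = 8):
    """Yield every concrete sequence encoded by IUPAC ambiguity codes.

    Raises ValueError if more than ``max_ambiguous`` positions are ambiguous
    (combinatorial guard) or an unknown character is present.
    """
    seq = seq.upper()
    choices = []
    n_ambiguous = 0
    for ch in seq:
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"unknown nucleotide code {ch!r}") from None
        if len(opts) > 1:
            n_ambiguous += 1
        choices.append(opts)
    if n_ambiguous > max_ambiguous:
        raise ValueError(
            f"{n_ambiguous} ambiguous positions exceed the limit of "
            f"{max_ambiguous}"
        )
    for combo in itertools.product(*choices):
        yield "".join(combo)
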