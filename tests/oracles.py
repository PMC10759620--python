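"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities from first principles (explicit
enumeration, textbook formulas) without importing the implementations
they check.
"""

from __future__ import annotations

import itertools
from math import comb

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
SENSE = sorted(c for c in GENETIC_CODE if c not in STOPS)


def ng_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites of a sense codon: per position,
    synonymous fraction among single-nt changes that avoid stops."""
    syn_total = 0.0
    for pos in range(3):
        outcomes = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOPS:
                continue
            outcomes.append(GENETIC_CODE[alt] == GENETIC_CODE[codon])
        if outcomes:
            syn_total += sum(outcomes) / len(outcomes)
    return syn_total, 3.0 - syn_total


def ng_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) by enumerating every ordering of single-nt steps,
    excluding pathways through stop codons (fallback: all pathways,
    stop steps counted nonsynonymous)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, hit_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                hit_stop = True
                nd += 1
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hit_stop else clean).append((sd, nd))
    use = clean if clean else dirty
    return (
        sum(x[0] for x in use) / len(use),
        sum(x[1] for x in use) / len(use),
    )


def hypergeom_fisher_less(table) -> float:
    """One-sided (alternative: first cell small) Fisher p by direct
    hypergeometric tail summation."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)
    lo = max(0, row1 - (n - col1))
    return sum(
        comb(col1, k) * comb(n - col1, row1 - k) / denom
        for k in range(lo, a + 1)
    )


def pearson_chi2(table) -> float:
    """Textbook sum of (O-E)^2/E over a 2-D count table."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    chi2 = 0.0
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            e = r * c / total
            chi2 += (table[i][j] - e) ** 2 / e
    return chi2
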