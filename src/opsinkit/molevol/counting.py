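"""Nei-Gojobori (1986) style codon counting and the per-branch Fisher test.

Site counting: at each codon position the synonymous fraction is the
number of synonymous single-nucleotide changes divided by the number of
changes that do not create a stop codon; the nonsynonymous fraction is
its complement, so every codon contributes exactly 3 sites
(N_sites + S_sites = 3 x codon count).

Difference counting: for a codon pair differing at k positions, all k!
orderings of single-nucleotide steps are enumerated; pathways passing
through a stop codon are excluded and the synonymous/nonsynonymous step
counts are averaged over the remaining pathways. If every pathway is
blocked by stops, all pathways are used with steps into or out of a stop
counted as nonsynonymous (degenerate fallback, flagged in the result of
the pairwise helper).

The branch test places rounded counts in the 2x2 table
[[Nd, N_sites - Nd], [Sd, S_sites - Sd]] and applies a one-sided
Fisher's exact test (default side: purifying, pN < pS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from math import floor

from scipy.stats import fisher_exact

from opsinkit._codon import (
    CODON_TABLE,
    NUCLEOTIDES,
    STOP_CODONS,
    split_codons,
)


@dataclass(frozen=True)
class BranchSubstCounts:
    """Site and difference counts for one branch, with the test result."""

    branch: tuple[str, str]  # (parent node id, child node id)
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    fisher_p: float | None = None
    side: str | None = None
    identical: bool = False

    @property
    def pN(self) -> float:
        return self.Nd / self.N_sites

    @property
    def pS(self) -> float:
        return self.Sd / self.S_sites

    @property
    def omega(self) -> float | None:
        """pN/pS proportion ratio; None when undefined (pS == 0)."""
        if self.Sd == 0:
            return None
        return self.pN / self.pS

    def to_dict(self) -> dict:
        return {
            "branch": f"{self.branch[0]}->{self.branch[1]}",
            "N_sites": self.N_sites,
            "S_sites": self.S_sites,
            "Nd": self.Nd,
            "Sd": self.Sd,
            "pN": self.pN,
            "pS": self.pS,
            "omega": self.omega,
            "fisher_p": self.fisher_p,
            "side": self.side,
            "flag": "identical" if self.identical else "",
        }


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TABLE[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        s_total += syn / valid if valid else 0.0
    return s_total, 3.0 - s_total


def sequence_site_counts(cds: str) -> tuple[float, float]:
    """(S_sites, N_sites) summed over all codons of a sequence."""
    s = n = 0.0
    for codon in split_codons(cds):
        cs, cn = codon_site_counts(codon)
        s += cs
        n += cn
    return s, n


def _pathway_steps(c1: str, c2: str, positions: tuple[int, ...]):
    """Walk c1->c2 changing `positions` in order; yield (from, to) codons."""
    cur = c1
    for pos in positions:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        yield cur, nxt
        cur = nxt


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) fractional difference counts between two sense codons."""
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} in difference counting")
    diff = tuple(i for i in range(3) if c1[i] != c2[i])
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in itertools.permutations(diff):
        sd = nd = 0
        through_stop = False
        for a, b in _pathway_steps(c1, c2, order):
            if b in STOP_CODONS:
                through_stop = True
                nd += 1  # only used by the all-blocked fallback
            elif CODON_TABLE[a] == CODON_TABLE[b]:
                sd += 1
            else:
                nd += 1
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid or blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def count_branch_substitutions(
    parent_seq: str,
    child_seq: str,
    branch: tuple[str, str] = ("parent", "child"),
) -> BranchSubstCounts:
    """NG86 sites (averaged over the two sequences) and differences."""
    parent_seq, child_seq = parent_seq.upper(), child_seq.upper()
    if len(parent_seq) != len(child_seq):
        raise ValueError("parent and child sequences differ in length")
    sp, np_ = sequence_site_counts(parent_seq)
    sc, nc = sequence_site_counts(child_seq)
    s_sites = (sp + sc) / 2.0
    n_sites = (np_ + nc) / 2.0
    sd = nd = 0.0
    for cp, cc in zip(split_codons(parent_seq), split_codons(child_seq)):
        d_s, d_n = codon_pair_differences(cp, cc)
        sd += d_s
        nd += d_n
    return BranchSubstCounts(
        branch=branch,
        N_sites=n_sites,
        S_sites=s_sites,
        Nd=nd,
        Sd=sd,
        identical=(sd == 0.0 and nd == 0.0),
    )


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def branch_omega_test(
    counts: BranchSubstCounts, side: str = "purifying"
) -> BranchSubstCounts:
    """Fill fisher_p with a one-sided Fisher's exact test.

    side="purifying" asks whether pN < pS; side="positive" whether
    pN > pS. Fractional counts are rounded half-up for the 2x2 table
    only; the stored counts stay fractional.
    """
    if side not in ("purifying", "positive"):
        raise ValueError(f"unknown side {side!r}")
    if counts.N_sites <= 0 or counts.S_sites <= 0:
        raise ValueError("site counts must be positive")
    nd, n = _round_half_up(counts.Nd), _round_half_up(counts.N_sites)
    sd, s = _round_half_up(counts.Sd), _round_half_up(counts.S_sites)
    table = [[nd, n - nd], [sd, s - sd]]
    if min(min(row) for row in table) < 0:
        raise RuntimeError(f"negative cell in Fisher table {table}")
    alternative = "less" if side == "purifying" else "greater"
    _, p = fisher_exact(table, alternative=alternative)
    return replace(counts, fisher_p=float(p), side=side)
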