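"""Accept/reject codon-evolution simulator on a fixed rooted topology.

Substitutions arise from a Gillespie process over single-nucleotide
changes. The relative rate of a change is kappa/(kappa+2) for a
transition and 1/(kappa+2) for a transversion (so each nucleotide site
has unit total rate under neutrality), multiplied by omega when the
change is nonsynonymous; changes creating a stop codon have rate zero.
Branch lengths are therefore expected substitutions per nucleotide site
on the neutral mutation scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from opsinkit._codon import (
    CODON_TABLE,
    NUCLEOTIDES,
    STOP_CODONS,
    has_internal_stop,
    is_transition,
)
from opsinkit.molevol.ancestral import label_internal_nodes, node_id
from opsinkit.molevol.pipeline import CodonAlignment

_CODONS = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}


@dataclass
class CodonSimParams:
    """Parameters of the codon substitution simulation."""

    ancestral_cds: str
    branch_lengths: float | dict[str, float] = 0.1
    omega: float = 0.2
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        cds = self.ancestral_cds.upper()
        if len(cds) % 3:
            raise ValueError("ancestral_cds length must be divisible by 3")
        if has_internal_stop(cds):
            raise ValueError("ancestral_cds contains an internal stop codon")
        if set(cds) - set(NUCLEOTIDES):
            raise ValueError("ancestral_cds must be unambiguous DNA")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if isinstance(self.branch_lengths, dict):
            if any(v < 0 for v in self.branch_lengths.values()):
                raise ValueError("branch lengths must be >= 0")
        elif self.branch_lengths < 0:
            raise ValueError("branch lengths must be >= 0")
        self.ancestral_cds = cds


@dataclass
class CodonSimResult:
    """Tip alignment plus the true internal-node sequences."""

    alignment: CodonAlignment
    ancestral_sequences: dict[str, str] = field(default_factory=dict)


def _rate_tables(omega: float, kappa: float):
    """Arrays [codon, position, target-nt] of change rates and next codons."""
    n = len(_CODONS)
    rates = np.zeros((n, 3, 4))
    nxt = np.zeros((n, 3, 4), dtype=np.int16)
    base_w = 1.0 / (kappa + 2.0)
    for ci, codon in enumerate(_CODONS):
        if codon in STOP_CODONS:
            continue
        aa = CODON_TABLE[codon]
        for pos in range(3):
            for ti, nt in enumerate(NUCLEOTIDES):
                alt = codon[:pos] + nt + codon[pos + 1 :]
                nxt[ci, pos, ti] = _CODON_INDEX[alt]
                if nt == codon[pos] or alt in STOP_CODONS:
                    continue
                w = base_w * (kappa if is_transition(codon[pos], nt) else 1.0)
                if CODON_TABLE[alt] != aa:
                    w *= omega
                rates[ci, pos, ti] = w
    return rates, nxt


def _evolve_branch(codons, length, rates, nxt, rng):
    """Gillespie simulation of one branch; returns the child codon array."""
    codons = codons.copy()
    if length == 0:
        return codons
    site_rates = rates[codons]  # (L, 3, 4)
    t = 0.0
    while True:
        total = site_rates.sum()
        if total <= 0:
            return codons
        t += rng.exponential(1.0 / total)
        if t > length:
            return codons
        flat = site_rates.reshape(codons.size, -1)
        site_tot = flat.sum(axis=1)
        site = rng.choice(codons.size, p=site_tot / total)
        within = rng.choice(12, p=flat[site] / site_tot[site])
        pos, target = divmod(within, 4)
        codons[site] = nxt[codons[site], pos, target]
        site_rates[site] = rates[codons[site]]


def _branch_length(params: CodonSimParams, child_name: str) -> float:
    if isinstance(params.branch_lengths, dict):
        try:
            return float(params.branch_lengths[child_name])
        except KeyError:
            raise ValueError(f"no branch length for node {child_name!r}") from None
    return float(params.branch_lengths)


DEFAULT_TOPOLOGY = "((A,B)AB,C)root;"


def simulate_codon_evolution(
    params: CodonSimParams,
    topology: str | dendropy.Tree = DEFAULT_TOPOLOGY,
) -> CodonSimResult:
    """Simulate codon evolution down a rooted tree.

    topology : Newick string or dendropy tree with named tips; internal
        nodes are auto-labeled in preorder when unnamed. branch_lengths
        may be a scalar (all branches) or a dict keyed by child node id.
    Returns tip sequences as a CodonAlignment plus the true sequences of
    the root and every internal node. Bit-reproducible for a fixed seed.
    """
    if isinstance(topology, str):
        tree = dendropy.Tree.get(
            file=io.StringIO(topology), schema="newick", rooting="force-rooted"
        )
    else:
        tree = topology
    label_internal_nodes(tree)
    rng = np.random.default_rng(params.seed)
    rates, nxt = _rate_tables(params.omega, params.kappa)

    root_codons = np.array(
        [
            _CODON_INDEX[params.ancestral_cds[i : i + 3]]
            for i in range(0, len(params.ancestral_cds), 3)
        ],
        dtype=np.int16,
    )
    states = {id(tree.seed_node): root_codons}
    tip_seqs: dict[str, str] = {}
    internal_seqs: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            internal_seqs[node_id(node)] = _decode(root_codons)
            continue
        parent_codons = states[id(node.parent_node)]
        length = _branch_length(params, node_id(node))
        child_codons = _evolve_branch(parent_codons, length, rates, nxt, rng)
        states[id(node)] = child_codons
        if node.is_leaf():
            tip_seqs[node_id(node)] = _decode(child_codons)
        else:
            internal_seqs[node_id(node)] = _decode(child_codons)

    alignment = CodonAlignment(list(tip_seqs), tip_seqs, tree)
    return CodonSimResult(alignment, internal_seqs)


def _decode(codons: np.ndarray) -> str:
    return "".join(_CODONS[i] for i in codons)


def random_sense_cds(n_codons: int, seed: int = 0) -> str:
    """Uniform-random in-frame sequence of sense codons (no stops)."""
    rng = np.random.default_rng(seed)
    sense = [c for c in _CODONS if c not in STOP_CODONS]
    return "".join(rng.choice(sense) for _ in range(n_codons))
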