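"""Codon alignment container and the composed per-branch selection test."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

from opsinkit._codon import has_internal_stop
from opsinkit.molevol.ancestral import (
    infer_ancestral_codons,
    label_internal_nodes,
    node_id,
)
from opsinkit.molevol.counting import (
    BranchSubstCounts,
    branch_omega_test,
    count_branch_substitutions,
)


@dataclass
class CodonAlignment:
    """Gap-free in-frame codon alignment plus a rooted Newick topology."""

    taxa: list[str]
    sequences: dict[str, str]
    tree: dendropy.Tree

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not divisible by 3")
        for name, seq in self.sequences.items():
            if "-" in seq:
                raise ValueError(f"{name}: gaps are not supported")
            if has_internal_stop(seq):
                raise ValueError(f"{name}: internal stop codon")
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        if not tips <= set(self.sequences):
            missing = tips - set(self.sequences)
            raise ValueError(f"tree tips missing from alignment: {missing}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    @classmethod
    def from_files(cls, fasta_path, newick_path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        sequences = {r.id: str(r.seq).upper() for r in records}
        tree = dendropy.Tree.get(
            path=str(newick_path), schema="newick", rooting="force-rooted"
        )
        return cls(list(sequences), sequences, tree)

    @classmethod
    def from_strings(cls, sequences: dict[str, str], newick: str) -> "CodonAlignment":
        tree = dendropy.Tree.get(
            file=io.StringIO(newick), schema="newick", rooting="force-rooted"
        )
        return cls(list(sequences), {k: v.upper() for k, v in sequences.items()}, tree)


def pipeline_branch_test(
    alignment: CodonAlignment,
    outgroup: str | None = None,
    side: str = "purifying",
) -> list[BranchSubstCounts]:
    """Ancestral inference + NG86 counting + Fisher test per ingroup branch.

    Returns one BranchSubstCounts per ancestor->tip branch of the
    non-outgroup tips. Branches with zero substitutions are flagged
    identical, with fisher_p = 1 and omega undefined.
    """
    ancestors = infer_ancestral_codons(alignment, outgroup=outgroup)
    results = []
    for leaf in alignment.tree.leaf_node_iter():
        tip = node_id(leaf)
        if outgroup is not None and tip == outgroup:
            continue
        parent = leaf.parent_node
        parent_name = node_id(parent)
        counts = count_branch_substitutions(
            ancestors[parent_name],
            alignment.sequences[tip],
            branch=(parent_name, tip),
        )
        results.append(branch_omega_test(counts, side=side))
    return results


def branch_table(results: list[BranchSubstCounts]) -> pd.DataFrame:
    """Tabulate branch test results (one row per branch)."""
    return pd.DataFrame([r.to_dict() for r in results])


def annotated_newick(alignment: CodonAlignment, results: list[BranchSubstCounts]) -> str:
    """Newick string with 'omega=..;p=..' comments on tested tip branches."""
    by_tip = {r.branch[1]: r for r in results}
    tree = alignment.tree
    label_internal_nodes(tree)
    for leaf in tree.leaf_node_iter():
        r = by_tip.get(leaf.taxon.label)
        if r is None:
            continue
        omega = "NA" if r.omega is None else f"{r.omega:.4g}"
        leaf.annotations.add_new("branch_test", f"omega={omega};p={r.fisher_p:.3g}")
    return tree.as_string(schema="newick", suppress_annotations=False).strip()
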