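"""Fitch parsimony ancestral reconstruction on nucleotide columns.

A deliberate simplification of likelihood-based ancestral inference:
with a shallow ingroup pair plus outgroup on highly conserved coding
genes the two coincide except at saturated sites. Ties are resolved
deterministically: prefer the outgroup's observed state, then the
alphabetically first nucleotide. Reconstructions creating a stop codon
are repaired to the next-best states available in the Fitch sets.
"""

from __future__ import annotations

import itertools

import numpy as np

from opsinkit._codon import STOP_CODONS

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_NT = {1: "A", 2: "C", 4: "G", 8: "T"}


def node_id(node) -> str:
    """Stable identifier for a dendropy node (taxon label or node label)."""
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    raise ValueError("internal node lacks a label; call label_internal_nodes")


def label_internal_nodes(tree) -> None:
    """Assign 'nodeK' labels (preorder) to unlabeled internal nodes."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"node{k}"
            k += 1


def _encode(seq: str) -> np.ndarray:
    return np.array([_BIT[c] for c in seq.upper()], dtype=np.uint8)


def _decode(bits: np.ndarray) -> str:
    return "".join(_NT[int(b)] for b in bits)


def _lowest_bit(mask: np.ndarray) -> np.ndarray:
    return mask & (-mask.astype(np.int16)).astype(np.uint8)


def infer_ancestral_codons(alignment, outgroup: str | None = None) -> dict[str, str]:
    """Per internal node, the parsimony nucleotide sequence.

    alignment : CodonAlignment with a rooted topology.
    outgroup : tip used for tie-breaking (default: last child of the root
        if it is a leaf, else the alphabetically first tip).
    Returns a map from internal-node id to sequence.
    """
    tree = alignment.tree
    root = tree.seed_node
    if len(root.child_nodes()) != 2:
        raise ValueError("topology must be rooted (bifurcation at the root)")
    label_internal_nodes(tree)

    tips = {node_id(n) for n in tree.leaf_node_iter()}
    if outgroup is None:
        last = root.child_nodes()[-1]
        outgroup = node_id(last) if last.is_leaf() else sorted(tips)[0]
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} is not a tip of the tree")

    out_states = _encode(alignment.sequences[outgroup])

    # bottom-up Fitch sets
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = _encode(alignment.sequences[node_id(node)])
        else:
            children = [masks[id(c)] for c in node.child_nodes()]
            inter = children[0].copy()
            union = children[0].copy()
            for m in children[1:]:
                inter &= m
                union |= m
            masks[id(node)] = np.where(inter > 0, inter, union)

    # top-down assignment with deterministic tie-breaking
    chosen: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            chosen[id(node)] = masks[id(node)]
            continue
        m = masks[id(node)]
        if node is root:
            pick = np.where(out_states & m, out_states, _lowest_bit(m))
        else:
            parent_state = chosen[id(node.parent_node)]
            pick = np.where(
                parent_state & m,
                parent_state,
                np.where(out_states & m, out_states, _lowest_bit(m)),
            )
        chosen[id(node)] = pick.astype(np.uint8)

    result: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        seq = _decode(chosen[id(node)])
        seq = _repair_stops(seq, masks[id(node)])
        result[node_id(node)] = seq
    return result


def _repair_stops(seq: str, mask: np.ndarray) -> str:
    """Replace stop codons with the next-best states from the Fitch sets."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for ci, codon in enumerate(codons):
        if codon not in STOP_CODONS:
            continue
        options = []
        for p in range(3):
            m = int(mask[3 * ci + p])
            options.append([nt for bit, nt in sorted(_NT.items()) if m & bit])
        candidates = sorted(
            ("".join(c) for c in itertools.product(*options)),
            key=lambda c: (sum(a != b for a, b in zip(c, codon)), c),
        )
        for cand in candidates:
            if cand not in STOP_CODONS:
                codons[ci] = cand
                break
        # if every combination is a stop, the original choice stands
    return "".join(codons)
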