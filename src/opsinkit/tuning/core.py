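"""Tuning-site genotypes and the additive five-site lambda-max rule.

LWS lambda-max is predicted by the additive five-site rule: a base
genotype (S180, H197, Y277, T285, A308) anchors 560 nm and each
deviating residue contributes a tabulated shift. SWS2 carries seven key
sites (91, 94, 116, 122, 261, 292, 295, fish numbering) that are only
compared across genotypes, never fed into an additive rule.

Site numbering is defined by packaged numbering-reference proteins; a
query haplotype is globally aligned to the reference and residues are
read off at the reference-numbered positions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from opsinkit._codon import expand_ambiguities, translate

TUNING_SITES: dict[str, tuple[int, ...]] = {
    "LWS": (180, 197, 277, 285, 308),
    "SWS2": (91, 94, 116, 122, 261, 292, 295),
}

_REFERENCE_FILES = {
    "LWS": "lws_reference.fasta",
    "SWS2": "sws2_reference.fasta",
}


def _data_text(name: str) -> str:
    return (resources.files("opsinkit.data") / name).read_text()


def load_reference(gene: str) -> tuple[str, str]:
    """(id, protein sequence) of the packaged numbering reference."""
    try:
        text = _data_text(_REFERENCE_FILES[gene])
    except KeyError:
        raise ValueError(f"no numbering reference for gene {gene!r}") from None
    lines = text.strip().splitlines()
    name = lines[0][1:].split()[0]
    return name, "".join(lines[1:])


@dataclass
class OpsinHaplotype:
    """An in-frame opsin CDS; IUPAC ambiguity codes mark unphased SNVs."""

    id: str
    gene: str
    cds: str
    protein: str = ""

    def __post_init__(self) -> None:
        self.cds = self.cds.upper().replace("U", "T")
        if len(self.cds) % 3:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        if not self.protein:
            # translate through the first concrete expansion; ambiguous
            # codons become their first realization for alignment purposes
            concrete = next(expand_ambiguities(self.cds, max_ambiguous=64))
            self.protein = translate(concrete)
        if "*" in self.protein[:-1]:
            raise ValueError(f"{self.id}: internal stop codon")
        self.protein = self.protein.rstrip("*")


@dataclass
class TuningGenotype:
    """Residues at the reference-numbered tuning sites of one gene."""

    gene: str
    site_residues: dict[int, str | None]
    numbering_reference: str

    def __post_init__(self) -> None:
        expected = TUNING_SITES.get(self.gene)
        if expected is not None and set(self.site_residues) != set(expected):
            raise ValueError(
                f"{self.gene} genotype must cover sites {expected}, "
                f"got {sorted(self.site_residues)}"
            )

    def residue_string(self) -> str:
        return "".join(
            f"{self.site_residues[s] or '-'}{s}"
            for s in sorted(self.site_residues)
        )

    def __hash__(self) -> int:
        return hash((self.gene, tuple(sorted(self.site_residues.items(),
                                             key=lambda kv: kv[0]))))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TuningGenotype)
            and self.gene == other.gene
            and self.site_residues == other.site_residues
        )


@dataclass
class ShiftTable:
    """Base lambda-max plus additive per-substitution shifts (LWS)."""

    gene: str
    base_genotype: dict[int, str]
    base_lambda_max: float
    shifts: dict[tuple[int, str, str], float]
    numbering_reference: str = ""

    def __post_init__(self) -> None:
        if self.gene != "LWS":
            raise ValueError("shift tables are defined for LWS only")

    @classmethod
    def load_default(cls) -> "ShiftTable":
        raw = json.loads(_data_text("lws_shift_table.json"))
        shifts = {}
        for key, delta in raw["shifts"].items():
            site, change = key.split(":")
            frm, to = change.split(">")
            shifts[(int(site), frm, to)] = float(delta)
        return cls(
            gene=raw["gene"],
            base_genotype={int(k): v for k, v in raw["base_genotype"].items()},
            base_lambda_max=float(raw["base_lambda_max"]),
            shifts=shifts,
            numbering_reference=raw.get("numbering_reference", ""),
        )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _map_reference_sites(
    reference_protein: str, query_protein: str, sites
) -> dict[int, str | None]:
    """Residue of the query at each 1-based reference position."""
    alignment = _aligner().align(reference_protein, query_protein)[0]
    # column index of the query for each reference position; -1 in gaps
    ref_to_query = {}
    for (r0, r1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(r1 - r0):
            ref_to_query[r0 + offset] = q0 + offset
    identical = sum(
        1
        for rpos, qpos in ref_to_query.items()
        if reference_protein[rpos] == query_protein[qpos]
    )
    if not ref_to_query or identical / len(reference_protein) < 0.2:
        raise ValueError("query protein is not alignable to the reference")
    result: dict[int, str | None] = {}
    for site in sites:
        if site < 1 or site > len(reference_protein):
            raise ValueError(f"site {site} outside the reference")
        qpos = ref_to_query.get(site - 1)
        if qpos is None:
            warnings.warn(
                f"site {site} falls in an alignment gap; reported missing",
                stacklevel=3,
            )
            result[site] = None
        else:
            result[site] = query_protein[qpos]
    return result


def extract_tuning_sites(
    haplotype: OpsinHaplotype,
    reference: tuple[str, str] | None = None,
    sites: tuple[int, ...] | None = None,
) -> TuningGenotype:
    """Align a haplotype to the numbering reference and read off residues.

    reference : (name, protein) pair; default is the packaged reference
        for the haplotype's gene. sites defaults to the gene's tuning
        sites. A site falling in an alignment gap is reported as None
        with a warning.
    """
    if reference is None:
        reference = load_reference(haplotype.gene)
    ref_name, ref_protein = reference
    if sites is None:
        sites = TUNING_SITES[haplotype.gene]
    residues = _map_reference_sites(ref_protein, haplotype.protein, sites)
    return TuningGenotype(haplotype.gene, residues, ref_name)


def predict_lws_lambda_max(
    genotype: TuningGenotype, table: ShiftTable | None = None
) -> float:
    """Additive five-site-rule lambda-max prediction in nm."""
    if genotype.gene != "LWS":
        raise ValueError("lambda-max prediction applies to LWS genotypes only")
    if table is None:
        table = ShiftTable.load_default()
    value = table.base_lambda_max
    for site, base_res in table.base_genotype.items():
        residue = genotype.site_residues.get(site)
        if residue is None:
            raise ValueError(f"site {site} missing from the genotype")
        if residue == base_res:
            continue
        key = (site, base_res, residue)
        if key not in table.shifts:
            raise ValueError(
                f"no shift entry for substitution {base_res}{site}{residue}"
            )
        value += table.shifts[key]
    return value


def compare_key_sites(genotypes: list[TuningGenotype]) -> dict:
    """Per-site residue multisets across genotypes with differs flags."""
    if not genotypes:
        raise ValueError("no genotypes to compare")
    genes = {g.gene for g in genotypes}
    if len(genes) != 1:
        raise ValueError(f"cannot compare mixed genes {sorted(genes)}")
    sites = sorted(genotypes[0].site_residues)
    per_site = {}
    for site in sites:
        residues = [g.site_residues.get(site) for g in genotypes]
        per_site[site] = {
            "residues": residues,
            "differs": len({r for r in residues if r is not None}) > 1,
        }
    return {
        "gene": genotypes[0].gene,
        "sites": per_site,
        "any_difference": any(v["differs"] for v in per_site.values()),
    }


def enumerate_haplotype_genotypes(
    haplotype: OpsinHaplotype,
    reference: tuple[str, str] | None = None,
    sites: tuple[int, ...] | None = None,
    max_ambiguous: int = 8,
) -> list[TuningGenotype]:
    """Expand IUPAC ambiguities and return the deduplicated genotype set.

    Raises if more than ``max_ambiguous`` positions are ambiguous.
    """
    seen: list[TuningGenotype] = []
    for concrete in expand_ambiguities(haplotype.cds, max_ambiguous):
        hap = OpsinHaplotype(
            id=haplotype.id, gene=haplotype.gene, cds=concrete
        )
        genotype = extract_tuning_sites(hap, reference=reference, sites=sites)
        if genotype not in seen:
            seen.append(genotype)
    return seen


_PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(protein: str) -> str:
    """Deterministic one-codon-per-residue reverse translation (for
    constructing synthetic haplotypes from a numbering reference)."""
    return "".join(_PREFERRED_CODON[aa] for aa in protein)
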