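"""Synonymous codon usage: RSCU, relative adaptiveness, and CAI.

The codon adaptation index (CAI) of a gene is the geometric mean of the
relative-adaptiveness weights w of its codons, where w_c = RSCU_c / max RSCU
over c's synonym family and RSCU is the observed codon count divided by the
mean count in the family.  The weights derive from a reference set of highly
expressed genes (ribosomal proteins and translation elongation factors by
default); a gene written purely in the reference set's preferred codons has
CAI = 1.  Following the canonical construction, the start codon, the stop
codon and the single-codon families (Met, Trp) are excluded from the mean.

The bacterial genetic code (NCBI table 11) defines the synonym families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .genome import Replicon

_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYM_FAMILIES.setdefault(_aa, ())
    SYNONYM_FAMILIES[_aa] += (_codon,)
SINGLE_CODON_AAS = frozenset(
    aa for aa, fam in SYNONYM_FAMILIES.items() if len(fam) == 1
)  # M and W under table 11

DEFAULT_REFERENCE_KEYWORDS = ("ribosomal protein", "elongation factor")


class CodonValidationError(ValueError):
    pass


class UndefinedCAIError(ValueError):
    pass


def _codons(cds: str, gene_id: str = "<cds>") -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise CodonValidationError(
            f"{gene_id}: CDS length {len(cds)} not divisible by 3"
        )
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise CodonValidationError(
                f"{gene_id}: internal stop codon {c} at codon {i + 1}"
            )
    return codons


def rscu(cds_set: Sequence[str] | Mapping[str, str]) -> dict[str, float]:
    """Relative synonymous codon usage over a set of coding sequences.

    RSCU_c = count_c / mean(count over c's synonym family).  Codons of
    families with zero total observations get ``float('nan')`` (undefined,
    flagged by NaN).  Stop codons are not counted.
    """
    items = (
        cds_set.items() if isinstance(cds_set, Mapping)
        else ((f"cds_{i}", s) for i, s in enumerate(cds_set))
    )
    counts = {c: 0 for c in CODON_TO_AA}
    for gene_id, cds in items:
        for codon in _codons(cds, gene_id):
            if codon in counts:
                counts[codon] += 1
    out: dict[str, float] = {}
    for aa, family in SYNONYM_FAMILIES.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            for c in family:
                out[c] = float("nan")
        else:
            mean = total / len(family)
            for c in family:
                out[c] = counts[c] / mean
    return out


@dataclass
class WTable:
    """Relative-adaptiveness weights w in (0, 1], max w = 1 per family."""

    w: dict[str, float]
    reference_gene_ids: list[str] = field(default_factory=list)
    genetic_code: int = 11
    floored_codons: frozenset[str] = frozenset()
    floor: float = 0.01

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tamino_acid\tw\tfloored\n")
            for codon in sorted(self.w):
                fh.write(
                    f"{codon}\t{CODON_TO_AA[codon]}\t{self.w[codon]:.6f}\t"
                    f"{'yes' if codon in self.floored_codons else 'no'}\n"
                )


def relative_adaptiveness(
    rscu_map: Mapping[str, float],
    floor: float = 0.01,
    reference_gene_ids: Iterable[str] = (),
) -> WTable:
    """w_c = RSCU_c / max synonymous RSCU; unobserved codons floored."""
    w: dict[str, float] = {}
    floored: set[str] = set()
    for aa, family in SYNONYM_FAMILIES.items():
        vals = [rscu_map.get(c, float("nan")) for c in family]
        finite = [v for v in vals if not math.isnan(v)]
        vmax = max(finite) if finite else 0.0
        for c, v in zip(family, vals):
            if math.isnan(v) or v == 0.0 or vmax == 0.0:
                w[c] = floor
                floored.add(c)
            else:
                w[c] = v / vmax
    return WTable(w=w, reference_gene_ids=list(reference_gene_ids),
                  floored_codons=frozenset(floored), floor=floor)


def cai(cds: str, wtable: WTable, gene_id: str = "<cds>") -> float:
    """Geometric mean of w over the gene's eligible codons.

    The start codon, a terminal stop codon, and codons of the single-codon
    families (Met, Trp) are excluded from the mean.
    """
    codons = _codons(cds, gene_id)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    eligible = [
        c for c in codons[1:]
        if c in CODON_TO_AA and CODON_TO_AA[c] not in SINGLE_CODON_AAS
    ]
    if not eligible:
        raise UndefinedCAIError(f"{gene_id}: no eligible codons for CAI")
    log_sum = sum(math.log(wtable.w[c]) for c in eligible)
    return math.exp(log_sum / len(eligible))


def select_reference_genes(
    replicons: Sequence[Replicon],
    keywords: Sequence[str] = DEFAULT_REFERENCE_KEYWORDS,
) -> dict[str, str]:
    """Pick highly-expressed reference CDS by product-text keyword.

    Case-insensitive substring match against each gene's product annotation;
    returns ``{locus_tag: cds_nt}`` so the selection is auditable.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    selected: dict[str, str] = {}
    for rep in replicons:
        for gene in rep.genes:
            product = gene.product.lower()
            if any(k in product for k in lowered):
                selected[gene.locus_tag] = rep.cds_nt(gene.locus_tag)
    if not selected:
        raise ValueError(
            f"no reference genes matched keywords {list(keywords)!r}"
        )
    return selected
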