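"""Operon pairing of toxin/antitoxin candidates by intergenic distance.

Two adjacent candidates of opposite role, co-oriented and separated by a
signed intergenic distance inside a small window (default -20..30 bp, bounds
inclusive; negative = overlap) are called one type II toxin-antitoxin locus.
Each candidate joins at most one locus; conflicts are resolved
deterministically by smallest absolute distance, then lowest combined
e-value, then leftmost position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome import (
    ContainmentError,
    GeneRecord,
    Replicon,
    intergenic_distance,
)
from .profiles import ProfileSet, TACandidate

DEFAULT_WINDOW = (-20, 30)


@dataclass(frozen=True)
class TALocus:
    replicon_id: str
    antitoxin: TACandidate
    toxin: TACandidate
    intergenic_bp: int
    strand: str
    family: str
    gene_order: str  # 'antitoxin_first' | 'toxin_first'


def _genes_between(replicon: Replicon, a: GeneRecord, b: GeneRecord) -> bool:
    """True if any annotated gene lies entirely within the a..b gap."""
    return any(
        g.locus_tag not in (a.locus_tag, b.locus_tag)
        and a.end <= g.start
        and g.end <= b.start
        for g in replicon.genes
    )


def find_loci(
    candidates: Sequence[TACandidate],
    replicon: Replicon,
    profiles: ProfileSet | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    require_same_strand: bool = True,
    require_opposite_roles: bool = True,
    allow_intervening_genes: bool = False,
    include_ambiguous: bool = False,
) -> list[TALocus]:
    """Pair flanking candidates into TA locus calls.

    Candidates are scanned in genomic order; only directly adjacent candidate
    pairs (no candidate in between) are considered.  A pair qualifies when its
    signed intergenic distance lies within ``window`` (inclusive), the strand
    and role rules hold, and (by default) no non-candidate gene sits in the
    intergenic gap.  The returned assignment is a matching: no candidate
    appears in two loci.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window min {lo} > max {hi}")
    tags = {g.locus_tag for g in replicon.genes}
    for c in candidates:
        if c.gene.locus_tag not in tags:
            raise KeyError(
                f"candidate {c.gene.locus_tag} does not belong to replicon "
                f"{replicon.id}"
            )
    pool = [c for c in candidates if include_ambiguous or c.role != "ambiguous"]
    pool = sorted(pool, key=lambda c: (c.gene.start, c.gene.end))

    scored = []
    for a, b in zip(pool, pool[1:]):
        try:
            d = intergenic_distance(a.gene, b.gene)
        except ContainmentError:
            continue  # nested genes are excluded from pairing
        if not (lo <= d <= hi):
            continue
        if require_same_strand and a.gene.strand != b.gene.strand:
            continue
        if require_opposite_roles:
            if {a.role, b.role} != {"toxin", "antitoxin"}:
                continue
        if not allow_intervening_genes and d > 0 and _genes_between(replicon, a.gene, b.gene):
            continue
        scored.append((abs(d), a.best_hit.evalue + b.best_hit.evalue,
                       a.gene.start, a, b, d))

    loci: list[TALocus] = []
    used: set[str] = set()
    for _absd, _ev, _pos, a, b, d in sorted(scored, key=lambda t: t[:3]):
        if a.gene.locus_tag in used or b.gene.locus_tag in used:
            continue
        used.update((a.gene.locus_tag, b.gene.locus_tag))
        anti, tox = (a, b) if a.role == "antitoxin" else (b, a)
        strand = a.gene.strand
        # 5' gene in transcription direction: left on '+', right on '-'
        upstream = a if strand == "+" else b
        order = "antitoxin_first" if upstream.role == "antitoxin" else "toxin_first"
        family = (
            profiles.family_of(tox.best_hit.profile_id) if profiles is not None else ""
        )
        loci.append(
            TALocus(
                replicon_id=replicon.id,
                antitoxin=anti,
                toxin=tox,
                intergenic_bp=d,
                strand=strand,
                family=family,
                gene_order=order,
            )
        )
    loci.sort(key=lambda l: min(l.antitoxin.gene.start, l.toxin.gene.start))
    return loci


def run_pipeline(
    genome_files: Sequence[str],
    hit_table: str,
    profile_map: str | ProfileSet,
    evalue_cutoff: float = 0.01,
    min_aa: int = 30,
    max_aa: int = 500,
    window: tuple[int, int] = DEFAULT_WINDOW,
    require_same_strand: bool = True,
) -> tuple[list[TALocus], pd.DataFrame, list[str]]:
    """End-to-end locus prediction: parse -> classify -> pair -> summarize.

    ``genome_files`` are GenBank paths (one or many replicons each);
    ``hit_table`` is a HMMER3 domtblout; ``profile_map`` a role TSV or a
    :class:`ProfileSet`.  Returns the loci, the per-replicon/family summary
    and a line-oriented run log whose header records every parameter.
    """
    from .genome import read_genbank
    from .profiles import classify_candidates, parse_domtblout

    log = [
        "# tamine run_pipeline",
        f"# evalue_cutoff={evalue_cutoff} min_aa={min_aa} max_aa={max_aa} "
        f"window=[{window[0]},{window[1]}] same_strand={require_same_strand}",
    ]
    profiles = (
        profile_map
        if isinstance(profile_map, ProfileSet)
        else ProfileSet.from_tsv(profile_map)
    )
    replicons: list[Replicon] = []
    for path in genome_files:
        try:
            replicons.extend(read_genbank(path))
        except Exception as exc:
            raise RuntimeError(f"[genome_io] {path}: {exc}") from exc
    log.append(f"# replicons={','.join(r.id for r in replicons)}")
    try:
        hits = parse_domtblout(hit_table, evalue_cutoff=evalue_cutoff)
    except Exception as exc:
        raise RuntimeError(f"[profile_search] {hit_table}: {exc}") from exc
    log.append(f"# hits_retained={len(hits)}")
    all_tags = {g.locus_tag for r in replicons for g in r.genes}
    unknown = sorted({h.protein_id for h in hits} - all_tags)
    if unknown:
        raise RuntimeError(
            f"[profile_search] hits reference unknown proteins: {unknown[:5]}"
        )

    all_loci: list[TALocus] = []
    for rep in replicons:
        tags = {g.locus_tag for g in rep.genes}
        rep_hits = [h for h in hits if h.protein_id in tags]
        try:
            cands = classify_candidates(
                rep.genes, rep_hits, profiles, min_aa=min_aa, max_aa=max_aa
            )
            loci = find_loci(
                cands, rep, profiles=profiles, window=window,
                require_same_strand=require_same_strand,
            )
        except Exception as exc:
            raise RuntimeError(f"[ta_pairing] {rep.id}: {exc}") from exc
        log.append(f"{rep.id}\tcandidates={len(cands)}\tloci={len(loci)}")
        all_loci.extend(loci)
    return all_loci, summarize_loci(all_loci), log


def summarize_loci(loci: Sequence[TALocus]) -> pd.DataFrame:
    """Locus counts per (replicon, family), lexicographically ordered."""
    if not loci:
        return pd.DataFrame(columns=["replicon", "family", "n_loci"])
    df = pd.DataFrame(
        {"replicon": [l.replicon_id for l in loci],
         "family": [l.family for l in loci]}
    )
    out = (
        df.groupby(["replicon", "family"], as_index=False)
        .size()
        .rename(columns={"size": "n_loci"})
        .sort_values(["replicon", "family"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
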