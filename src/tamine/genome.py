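"""Annotated-genome I/O and coordinate arithmetic.

A genome is a set of replicons (chromosome and/or plasmids), each carrying an
ordered list of CDS gene records.  Internally every interval is 0-based
half-open; GenBank and GFF3, both 1-based inclusive dialects, are converted on
the way in and out so that round trips are lossless.

The signed intergenic distance between two position-ordered genes is the
quantity the operon-pairing rule operates on: positive for a gap, negative for
an overlap, zero for abutting genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class GenomeFormatError(ValueError):
    """Input file is not readable in the declared format."""


class GenomeValidationError(ValueError):
    """A record violates the data model (coordinates, identifiers...)."""


class ContainmentError(ValueError):
    """Intergenic distance is undefined for nested genes."""


@dataclass(frozen=True)
class GeneRecord:
    """One CDS: 0-based half-open interval, strand, product text, protein."""

    locus_tag: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    protein: str = ""
    partial: bool = False
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise GenomeValidationError(f"{self.locus_tag}: strand must be + or -")
        bad = set(self.protein) - _VALID_AA
        if bad:
            raise GenomeValidationError(
                f"{self.locus_tag}: non-standard residues {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class Replicon:
    """One annotated DNA molecule with genes sorted by start coordinate."""

    id: str
    length: int
    topology: str = "linear"
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeValidationError("replicon id must be non-empty")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        tags = [g.locus_tag for g in self.genes]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise GenomeValidationError(f"{self.id}: duplicate locus_tag {dup}")
        for g in self.genes:
            if g.end > self.length:
                raise GenomeValidationError(
                    f"{self.id}: gene {g.locus_tag} interval [{g.start}, {g.end}) "
                    f"outside sequence of length {self.length}"
                )

    def gene(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    def cds_nt(self, locus_tag: str) -> str:
        """Nucleotide CDS in transcription direction (requires sequence)."""
        g = self.gene(locus_tag)
        if not self.sequence:
            raise GenomeValidationError(f"{self.id}: no sequence loaded")
        nt = self.sequence[g.start : g.end]
        if g.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        return nt


def _translate_cds(nt: str, partial: bool) -> str:
    """Bacterial-code translation; alternative start codons rendered as M."""
    seq = Seq(nt)
    if not partial and len(nt) % 3 == 0:
        try:
            return str(seq.translate(table=11, cds=True))
        except Exception:
            pass  # fall through: e.g. no stop codon in a synthetic fixture
    prot = str(seq.translate(table=11))
    return prot.rstrip("*")


def read_genbank(path: str | Path) -> list[Replicon]:
    """Parse a GenBank flat file into one Replicon per record.

    CDS features lacking a ``translation`` qualifier are translated from the
    spliced nucleotide sequence with the bacterial genetic code (table 11);
    partial features are retained but flagged.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise GenomeFormatError(f"{path}: not readable as GenBank: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    replicons = []
    for rec in records:
        seq = str(rec.seq)
        genes = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            tag = feat.qualifiers.get("locus_tag", [None])[0]
            if tag is None:
                tag = feat.qualifiers.get("gene", [f"CDS_{len(genes)}"])[0]
            start, end = int(feat.location.start), int(feat.location.end)
            if start < 0 or end > len(seq):
                raise GenomeValidationError(
                    f"{rec.id}: CDS {tag} coordinates [{start}, {end}) outside "
                    f"sequence of length {len(seq)}"
                )
            partial = "<" in str(feat.location) or ">" in str(feat.location)
            pseudo = "pseudo" in feat.qualifiers
            protein = feat.qualifiers.get("translation", [None])[0]
            if protein is None and not pseudo:
                nt = str(feat.extract(rec.seq))
                protein = _translate_cds(nt, partial)
            genes.append(
                GeneRecord(
                    locus_tag=tag,
                    start=start,
                    end=end,
                    strand="+" if feat.location.strand != -1 else "-",
                    product=feat.qualifiers.get("product", [""])[0],
                    protein=protein or "",
                    partial=partial,
                    pseudo=pseudo,
                )
            )
        topology = rec.annotations.get("topology", "linear")
        replicons.append(
            Replicon(id=rec.id, length=len(seq), topology=topology, genes=genes,
                     sequence=seq)
        )
    return replicons


def _parse_gff3_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff3_fasta(gff: str | Path, fasta: str | Path) -> list[Replicon]:
    """Load the same data model as :func:`read_genbank` from a GFF3+FASTA pair.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    gff, fasta = Path(gff), Path(fasta)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    if not seqs:
        raise GenomeFormatError(f"{fasta}: no FASTA records found")
    per_replicon: dict[str, list[GeneRecord]] = {sid: [] for sid in seqs}
    with open(gff) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(
                    f"{gff}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _src, ftype, start1, end1, _score, strand, _phase, col9 = cols
            if ftype != "CDS":
                continue
            if seqid not in seqs:
                raise GenomeValidationError(
                    f"{gff}:{lineno}: seqid {seqid!r} absent from FASTA"
                )
            attrs = _parse_gff3_attributes(col9)
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if not tag:
                raise GenomeValidationError(
                    f"{gff}:{lineno}: CDS without locus_tag/ID attribute"
                )
            start, end = int(start1) - 1, int(end1)  # to 0-based half-open
            partial = attrs.get("partial", "false").lower() == "true"
            nt = seqs[seqid][start:end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            per_replicon[seqid].append(
                GeneRecord(
                    locus_tag=tag,
                    start=start,
                    end=end,
                    strand=strand,
                    product=attrs.get("product", ""),
                    protein=_translate_cds(nt, partial),
                    partial=partial,
                )
            )
    return [
        Replicon(id=sid, length=len(seq), genes=per_replicon[sid], sequence=seq)
        for sid, seq in seqs.items()
    ]


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Signed distance ``b.start - a.end`` for position-ordered genes.

    Positive: gap length in bp.  Negative: number of overlapping nucleotides,
    negated.  Zero: abutting.  Undefined (raises) when one gene contains the
    other.
    """
    if a.start > b.start:
        raise ValueError("genes must be ordered by start coordinate (a before b)")
    if a is b or (a.start == b.start and a.end == b.end):
        raise ValueError("distance requires two distinct genes")
    if b.end <= a.end or (a.start == b.start):
        raise ContainmentError(
            f"gene {b.locus_tag} nested within {a.locus_tag}: distance undefined"
        )
    return b.start - a.end


def write_locus_report(loci: Iterable, out: str | Path | TextIO, fmt: str = "tsv") -> None:
    """Write TA locus calls as TSV or GFF3 (1-based inclusive on output)."""
    if fmt not in ("tsv", "gff3"):
        raise ValueError(f"unknown report format {fmt!r} (use 'tsv' or 'gff3')")
    own = isinstance(out, (str, Path))
    fh: TextIO = open(out, "w") if own else out  # type: ignore[arg-type]
    try:
        if fmt == "tsv":
            fh.write(
                "replicon\tantitoxin_locus_tag\ttoxin_locus_tag\tfamily\tstrand\t"
                "intergenic_bp\tantitoxin_evalue\ttoxin_evalue\n"
            )
            for loc in loci:
                fh.write(
                    f"{loc.replicon_id}\t{loc.antitoxin.gene.locus_tag}\t"
                    f"{loc.toxin.gene.locus_tag}\t{loc.family}\t{loc.strand}\t"
                    f"{loc.intergenic_bp}\t{loc.antitoxin.best_hit.evalue:g}\t"
                    f"{loc.toxin.best_hit.evalue:g}\n"
                )
        else:
            fh.write("##gff-version 3\n")
            for i, loc in enumerate(loci, 1):
                genes = [loc.antitoxin.gene, loc.toxin.gene]
                start = min(g.start for g in genes) + 1  # to 1-based inclusive
                end = max(g.end for g in genes)
                fh.write(
                    f"{loc.replicon_id}\ttamine\tta_locus\t{start}\t{end}\t.\t"
                    f"{loc.strand}\t.\tID=ta_locus_{i};family={loc.family};"
                    f"antitoxin={loc.antitoxin.gene.locus_tag};"
                    f"toxin={loc.toxin.gene.locus_tag};"
                    f"intergenic_bp={loc.intergenic_bp}\n"
                )
    finally:
        if own:
            fh.close()
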