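"""Hermetic synthetic fixtures: genomes with planted TA operons, hit tables
and Ct tables, each paired with a ground-truth table.

The generator emulates the two-replicon architecture of a *Streptomyces*-like
genome (one chromosome-scale and one plasmid-scale replicon): antitoxin-toxin
gene pairs are planted with exact signed intergenic distances drawn from the
operon window (-20..30 bp, overlaps included), surrounded by non-TA decoy
genes and size-outlier proteins.  Planted proteins embed fixed role
signatures (synthetic peptide blocks, not real RelBE sequences) from which
matching seed alignments and a HMMER3-style domain hit table can be derived,
so the whole pipeline is testable without any external search.

Overlap feasibility: a same-strand overlap always contains the upstream
gene's stop codon, so overlap lengths k with k >= 3 and k % 3 == 0 (stop
in-frame inside the downstream CDS) and k in {2, 3, 5} (no stop codon is
compatible with the shared bases) cannot occur in real co-oriented gene
pairs; the generator draws from the feasible set {1, 4} U {k >= 6, k % 3 != 0}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon import SYNONYM_FAMILIES
from .profiles import Profile, ProfileSet

# Role signatures planted into synthetic proteins.  The antitoxin block
# carries a ZXnnZnnRZ-compatible window (VVAAVAARL) mirroring the RelB
# consensus; the toxin block is an arbitrary distinct peptide.
ANTITOXIN_SIGNATURE = "DQWHEVVAAVAARLKHWQD"
TOXIN_SIGNATURE = "KWYRGHNPRYEKWGH"

ANTITOXIN_PROFILE = "relB_like"
TOXIN_PROFILE = "relE_like"

DEFAULT_PROFILE_SET = ProfileSet(
    [
        Profile(ANTITOXIN_PROFILE, "antitoxin", "relBE"),
        Profile(TOXIN_PROFILE, "toxin", "relBE"),
    ],
    version="synthetic-1",
)

FEASIBLE_OVERLAPS = tuple(
    k for k in range(1, 21) if k in (1, 4) or (k >= 6 and k % 3 != 0)
)
STOP = "TAA"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

REFERENCE_PRODUCTS = (
    "30S ribosomal protein S1",
    "50S ribosomal protein L2",
    "elongation factor Tu",
    "30S ribosomal protein S4",
    "elongation factor G",
)


class SpecError(ValueError):
    pass


@dataclass
class GenomeSpec:
    """Study-condition defaults: two replicons, five planted pairs, decoys."""

    n_replicons: int = 2
    replicon_lengths: tuple[int, ...] = (60_000, 25_000)
    n_ta_pairs: int = 5
    n_decoys: int = 50
    n_adjacent_decoy_pairs: int = 0  # co-oriented decoy pairs inside the window
    n_reference_genes: int = 5
    size_outlier_fraction: float = 0.1
    minus_strand_fraction: float = 0.4
    fixed_distances: tuple[int, ...] | None = None  # else drawn from window
    n_out_of_window_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicons < 1 or len(self.replicon_lengths) < self.n_replicons:
            raise SpecError("need a length for every replicon")
        if min(self.n_ta_pairs, self.n_decoys, self.n_reference_genes,
               self.n_out_of_window_pairs) < 0:
            raise SpecError("counts must be >= 0")


@dataclass
class PlantedLocus:
    replicon_id: str
    antitoxin_tag: str
    toxin_tag: str
    intergenic_bp: int
    strand: str
    in_window: bool


@dataclass
class TruthTable:
    planted: list[PlantedLocus] = field(default_factory=list)
    decoy_tags: list[str] = field(default_factory=list)
    outlier_tags: list[str] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)

    @property
    def planted_in_window(self) -> list[PlantedLocus]:
        return [p for p in self.planted if p.in_window]


def _random_protein(rng: np.random.Generator, length: int,
                    signature: str | None = None) -> str:
    body = "".join(rng.choice(list(_AA20), size=length - 1))
    if signature:
        # keep the signature clear of the C-terminal bases an overlap may rewrite
        lo, hi = 2, max(3, length - 1 - len(signature) - 12)
        pos = int(rng.integers(lo, max(lo + 1, hi)))
        body = body[:pos] + signature + body[pos + len(signature):]
        body = body[: length - 1]
    return "M" + body


def _encode(rng: np.random.Generator, protein: str) -> str:
    """Back-translate with uniformly drawn synonymous codons; ATG start."""
    codons = []
    for i, aa in enumerate(protein):
        fam = SYNONYM_FAMILIES[aa]
        codons.append("ATG" if i == 0 and aa == "M" else str(rng.choice(fam)))
    return "".join(codons) + STOP


def _bridge(k: int) -> str:
    """Shared nucleotides of a k-nt overlap (upstream stop + downstream ATG)."""
    if k == 1:
        return "A"
    if k == 4:
        return "ATGA"
    if k >= 6 and k % 3 != 0:
        return "ATG" + "C" * (k - 6) + STOP
    raise SpecError(f"overlap of {k} nt is not feasible for co-oriented CDS")


def _valid_cds(nt: str) -> bool:
    if len(nt) % 3 or not nt.startswith("ATG"):
        return False
    prot = str(Seq(nt).translate(table=11))
    return prot.endswith("*") and prot.count("*") == 1


def _pair_cassette(
    rng: np.random.Generator, d: int, len_a: int, len_b: int
) -> tuple[str, str, str, int, int, int, int]:
    """Nucleotides of an antitoxin(A)-toxin(B) pair at exact distance d.

    Returns (cassette_nt, nt_a, nt_b, a_start, a_end, b_start, b_end) with
    coordinates relative to the cassette.  Overlaps rewrite the junction
    codons of both genes; assignments are retried until both CDS stay valid.
    """
    for _ in range(200):
        prot_a = _random_protein(rng, len_a, ANTITOXIN_SIGNATURE)
        prot_b = _random_protein(rng, len_b, TOXIN_SIGNATURE)
        nt_a, nt_b = _encode(rng, prot_a), _encode(rng, prot_b)
        if d >= 0:
            spacer = "".join(rng.choice(list("ACGT"), size=d))
            cass = nt_a + spacer + nt_b
            a, b = (0, len(nt_a)), (len(nt_a) + d, len(nt_a) + d + len(nt_b))
            return cass, nt_a, nt_b, *a, *b
        k = -d
        s = _bridge(k)
        nt_a2 = nt_a[: len(nt_a) - k] + s
        nt_b2 = s + nt_b[k:]
        if _valid_cds(nt_a2) and _valid_cds(nt_b2):
            cass = nt_a2 + nt_b2[k:]
            a = (0, len(nt_a2))
            b = (len(nt_a2) - k, len(nt_a2) - k + len(nt_b2))
            return cass, nt_a2, nt_b2, *a, *b
    raise SpecError(f"could not realize overlap {d} after 200 attempts")


def _draw_distance(rng: np.random.Generator, out_of_window: bool) -> int:
    if out_of_window:
        return int(rng.integers(40, 120))
    if rng.random() < 0.5:
        return int(rng.integers(0, 31))
    return -int(rng.choice(FEASIBLE_OVERLAPS))


@dataclass
class _Gene:
    tag: str
    start: int
    end: int
    strand: str
    product: str
    nt: str  # transcription direction


def make_genome(
    spec: GenomeSpec, out_dir: str | Path
) -> tuple[dict[str, Path], TruthTable]:
    """Emit a synthetic annotated genome (GenBank and GFF3+FASTA dialects).

    Returns the written file paths and the ground truth.  Fixed seed gives
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()

    counter = 0

    def next_tag() -> str:
        nonlocal counter
        counter += 10
        return f"SYN_{counter:05d}"

    # distribute features round-robin over replicons
    rep_ids = [f"SYNREP{i + 1:02d}" for i in range(spec.n_replicons)]
    items: list[tuple[str, object]] = []
    distances = list(spec.fixed_distances or [])
    for i in range(spec.n_ta_pairs):
        d = distances[i] if i < len(distances) else _draw_distance(rng, False)
        items.append(("pair", d))
    for _ in range(spec.n_out_of_window_pairs):
        items.append(("pair_out", _draw_distance(rng, True)))
    n_outliers = int(round(spec.n_decoys * spec.size_outlier_fraction))
    for _ in range(spec.n_decoys - n_outliers):
        items.append(("decoy", None))
    for _ in range(spec.n_adjacent_decoy_pairs):
        items.append(("decoy_pair", int(rng.integers(0, 31))))
    for _ in range(n_outliers):
        items.append(("outlier", None))
    for i in range(spec.n_reference_genes):
        items.append(("reference", REFERENCE_PRODUCTS[i % len(REFERENCE_PRODUCTS)]))

    per_rep: dict[str, list[_Gene]] = {rid: [] for rid in rep_ids}
    per_seq: dict[str, list[str]] = {rid: [] for rid in rep_ids}
    cursor = {rid: 0 for rid in rep_ids}

    def emit(rid: str, cassette: str, genes: list[_Gene]) -> None:
        gap = int(rng.integers(60, 300))
        filler = "".join(rng.choice(list("ACGT"), size=gap))
        base = cursor[rid] + gap
        per_seq[rid].extend([filler, cassette])
        for g in genes:
            per_rep[rid].append(
                _Gene(g.tag, base + g.start, base + g.end, g.strand, g.product, g.nt)
            )
        cursor[rid] = base + len(cassette)

    for idx, (kind, payload) in enumerate(items):
        rid = rep_ids[idx % len(rep_ids)]
        if kind in ("pair", "pair_out"):
            d = int(payload)  # type: ignore[arg-type]
            len_a = int(rng.integers(70, 100))
            len_b = int(rng.integers(80, 110))
            cass, nt_a, nt_b, a0, a1, b0, b1 = _pair_cassette(rng, d, len_a, len_b)
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            tag_a, tag_b = next_tag(), next_tag()
            if strand == "+":
                genes = [
                    _Gene(tag_a, a0, a1, "+", "hypothetical protein", nt_a),
                    _Gene(tag_b, b0, b1, "+", "hypothetical protein", nt_b),
                ]
            else:
                cass = str(Seq(cass).reverse_complement())
                L = len(cass)
                genes = [
                    _Gene(tag_b, L - b1, L - b0, "-", "hypothetical protein", nt_b),
                    _Gene(tag_a, L - a1, L - a0, "-", "hypothetical protein", nt_a),
                ]
            emit(rid, cass, genes)
            prot_a = str(Seq(nt_a).translate(table=11)).rstrip("*")
            prot_b = str(Seq(nt_b).translate(table=11)).rstrip("*")
            truth.proteins[tag_a] = prot_a
            truth.proteins[tag_b] = prot_b
            truth.planted.append(
                PlantedLocus(
                    replicon_id=rid,
                    antitoxin_tag=tag_a,
                    toxin_tag=tag_b,
                    intergenic_bp=d,
                    strand=strand,
                    in_window=(kind == "pair" and -20 <= d <= 30),
                )
            )
        elif kind == "decoy_pair":
            d = int(payload)  # type: ignore[arg-type]
            genes_pair: list[_Gene] = []
            nts = []
            for _ in range(2):
                prot = _random_protein(rng, int(rng.integers(80, 200)))
                nts.append(_encode(rng, prot))
            spacer = "".join(rng.choice(list("ACGT"), size=d))
            cass = nts[0] + spacer + nts[1]
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            coords = [(0, len(nts[0])),
                      (len(nts[0]) + d, len(nts[0]) + d + len(nts[1]))]
            tags = [next_tag(), next_tag()]
            if strand == "-":
                cass = str(Seq(cass).reverse_complement())
                L = len(cass)
                coords = [(L - e, L - s) for s, e in coords]
            for tag, (s, e), nt in zip(tags, coords, nts):
                genes_pair.append(_Gene(tag, s, e, strand,
                                        "hypothetical protein", nt))
                truth.proteins[tag] = str(Seq(nt).translate(table=11)).rstrip("*")
                truth.decoy_tags.append(tag)
            emit(rid, cass, genes_pair)
        else:
            if kind == "outlier":
                length = (int(rng.integers(10, 29)) if rng.random() < 0.5
                          else int(rng.integers(501, 560)))
            else:
                length = int(rng.integers(80, 300))
            prot = _random_protein(rng, length)
            nt = _encode(rng, prot)
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            cass = nt if strand == "+" else str(Seq(nt).reverse_complement())
            tag = next_tag()
            product = (payload if kind == "reference"
                       else "hypothetical protein")  # type: ignore[assignment]
            emit(rid, cass, [_Gene(tag, 0, len(nt), strand, str(product), nt)])
            truth.proteins[tag] = str(Seq(nt).translate(table=11)).rstrip("*")
            if kind == "outlier":
                truth.outlier_tags.append(tag)
            elif kind == "decoy":
                truth.decoy_tags.append(tag)

    # pad and check capacity
    records = []
    gff_lines = ["##gff-version 3"]
    for rid, length in zip(rep_ids, spec.replicon_lengths):
        tail = length - cursor[rid]
        if tail < 0:
            raise SpecError(
                f"{rid}: planted features need {cursor[rid]} bp but replicon "
                f"length is {length}"
            )
        per_seq[rid].append("".join(rng.choice(list("ACGT"), size=tail)))
        seq = "".join(per_seq[rid])
        assert len(seq) == length
        rec = SeqRecord(Seq(seq), id=rid, name=rid,
                        description="tamine synthetic replicon")
        rec.annotations.update(
            molecule_type="DNA", topology="linear", date="01-JAN-2016",
            data_file_division="BCT",
        )
        for g in sorted(per_rep[rid], key=lambda g: g.start):
            prot = str(Seq(g.nt).translate(table=11)).rstrip("*")
            feat = SeqFeature(
                FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [g.tag],
                    "product": [g.product],
                    "transl_table": ["11"],
                    "translation": [prot],
                },
            )
            rec.features.append(feat)
            gff_lines.append(
                "\t".join(
                    [rid, "tamine_synth", "CDS", str(g.start + 1), str(g.end),
                     ".", g.strand, "0",
                     f"ID={g.tag};locus_tag={g.tag};product={g.product}"]
                )
            )
        records.append(rec)

    paths = {
        "genbank": out_dir / "genome.gbk",
        "gff3": out_dir / "genome.gff3",
        "fasta": out_dir / "genome.fasta",
    }
    SeqIO.write(records, str(paths["genbank"]), "genbank")
    with open(paths["gff3"], "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    with open(paths["fasta"], "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")
    return paths, truth


def make_hit_table(
    truth: TruthTable,
    path: str | Path,
    noise: float = 0.0,
    seed: int = 0,
    inject_malformed_row: bool = False,
) -> Path:
    """Write a HMMER3-style domtblout for the planted genes.

    Planted antitoxins/toxins (and size outliers, which exercise the size
    filter) get hits with e-values drawn log-uniformly in [1e-8, 1e-3], well
    below the 0.01 cutoff; with probability ``noise`` each decoy gets a
    spurious below-cutoff hit with a random role.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]

    def row(tag: str, profile: str, evalue: float) -> str:
        tlen = len(truth.proteins[tag])
        qlen = (len(ANTITOXIN_SIGNATURE) if profile == ANTITOXIN_PROFILE
                else len(TOXIN_SIGNATURE))
        score = max(5.0, -10.0 * np.log10(evalue))
        return (
            f"{tag:<21}-          {tlen:5d} {profile:<20} -          {qlen:5d} "
            f"{evalue:9.2g} {score:6.1f}   0.0   1   1 {evalue:9.2g} {evalue:9.2g} "
            f"{score:6.1f}   0.0     1 {qlen:5d}     1 {tlen:5d}     1 {tlen:5d} "
            f"0.99 synthetic hit"
        )

    def draw_e() -> float:
        return float(10 ** rng.uniform(-8, -3))

    for locus in truth.planted:
        lines.append(row(locus.antitoxin_tag, ANTITOXIN_PROFILE, draw_e()))
        lines.append(row(locus.toxin_tag, TOXIN_PROFILE, draw_e()))
    for tag in truth.outlier_tags:
        profile = ANTITOXIN_PROFILE if rng.random() < 0.5 else TOXIN_PROFILE
        lines.append(row(tag, profile, draw_e()))
    for tag in truth.decoy_tags:
        if rng.random() < noise:
            profile = ANTITOXIN_PROFILE if rng.random() < 0.5 else TOXIN_PROFILE
            lines.append(row(tag, profile, draw_e()))
    if inject_malformed_row:
        lines.append("BROKEN_ROW only three columns")
    lines.append("#")
    lines.append("# Program:         tamine-synth")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_seed_alignment(
    role: str, n_seqs: int = 6, mutation_rate: float = 0.1, seed: int = 0
) -> list[str]:
    """Aligned variants of a role signature, for the built-in PSSM scorer."""
    if role not in ("antitoxin", "toxin"):
        raise ValueError("role must be antitoxin or toxin")
    base = ANTITOXIN_SIGNATURE if role == "antitoxin" else TOXIN_SIGNATURE
    rng = np.random.default_rng(seed)
    seqs = [base]
    for _ in range(n_seqs - 1):
        chars = list(base)
        for i in range(len(chars)):
            if rng.random() < mutation_rate:
                chars[i] = str(rng.choice(list(_AA20)))
        seqs.append("".join(chars))
    return seqs


def make_ct_table(
    true_folds: dict[str, float],
    n_replicates: int = 3,
    sd: float = 0.3,
    seed: int = 0,
    reference: str = "16S",
    target_base_ct: float = 22.0,
    reference_ct: float = 12.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with known induction folds.

    Control-condition targets sit at ``target_base_ct`` cycles; treated
    targets are shifted by -log2(fold) so the expected ddCt recovers the
    fold exactly; Gaussian noise of ``sd`` cycles is added per replicate.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in ("control", "treated"):
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_{rep}"
            rows.append(
                {"sample_id": sample, "condition": cond, "gene": reference,
                 "replicate": rep,
                 "ct": reference_ct + rng.normal(0, sd)}
            )
            for gene, fold in true_folds.items():
                ct = target_base_ct + rng.normal(0, sd)
                if cond == "treated":
                    ct -= np.log2(fold)
                rows.append(
                    {"sample_id": sample, "condition": cond, "gene": gene,
                     "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene",
                                       "replicate", "ct"])


# Osmotic-stress induction folds used as the generator's default condition:
# antitoxin gene ~3x, ClpP protease genes 2x/4x/3x/6x.
DEFAULT_TRUE_FOLDS = {
    "relB2": 3.0,
    "clpP1": 2.0,
    "clpP2": 4.0,
    "clpP4": 3.0,
    "clpP6": 6.0,
}
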