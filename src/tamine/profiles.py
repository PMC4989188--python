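"""Homolog identification from role-labeled profile hits.

Two interchangeable homology backends feed the pairing stage:

* an external HMMER3 run, supplied as per-domain tabular output (domtblout),
  filtered on the per-domain independent e-value at an inclusive cutoff; or
* a built-in position-specific scoring matrix (PSSM) derived from a seed
  alignment, scored by best ungapped window with a shuffle-based empirical
  p-value.

Proteins with surviving hits are classified as toxin or antitoxin by the role
of their lowest-e-value profile and then filtered to the 30-500 aa size band
characteristic of type II toxin-antitoxin proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GeneRecord

DEFAULT_EVALUE_CUTOFF = 0.01
DEFAULT_MIN_AA = 30
DEFAULT_MAX_AA = 500

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class DomtbloutParseError(ValueError):
    pass


class CrossReferenceError(KeyError):
    pass


@dataclass(frozen=True)
class Profile:
    profile_id: str
    role: str  # 'toxin' | 'antitoxin'
    family: str = ""
    source: str = "external_table"


@dataclass
class ProfileSet:
    profiles: list[Profile]
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [p.profile_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate profile_id in ProfileSet")
        for p in self.profiles:
            if p.role not in ("toxin", "antitoxin"):
                raise ValueError(f"{p.profile_id}: role must be toxin or antitoxin")

    def role_of(self, profile_id: str) -> str:
        return self._by_id()[profile_id].role

    def family_of(self, profile_id: str) -> str:
        return self._by_id()[profile_id].family

    def _by_id(self) -> dict[str, Profile]:
        return {p.profile_id: p for p in self.profiles}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileSet":
        """Two/three-column TSV: profile_id, role[, family]."""
        profiles = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                family = cols[2] if len(cols) > 2 else ""
                profiles.append(Profile(cols[0], cols[1], family))
        return cls(profiles)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    profile_id: str
    evalue: float
    bit_score: float
    ali_from: int  # 1-based on the protein
    ali_to: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError("alignment coordinates must satisfy 1 <= from <= to")


@dataclass(frozen=True)
class TACandidate:
    gene: GeneRecord
    role: str  # 'toxin' | 'antitoxin' | 'ambiguous'
    best_hit: DomainHit
    length_aa: int


def parse_domtblout(
    path: str | Path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    Orientation is that of ``hmmsearch`` (target = protein, query = profile).
    Rows whose per-domain *independent* e-value exceeds the cutoff are
    discarded; the comparison is inclusive (``<=``).
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split(None, 22)
            if len(cols) < 22:
                raise DomtbloutParseError(
                    f"{path}:{lineno}: expected >=22 whitespace-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                evalue = float(cols[12])  # per-domain independent e-value
                hit = DomainHit(
                    protein_id=cols[0],
                    profile_id=cols[3],
                    evalue=evalue,
                    bit_score=float(cols[13]),
                    ali_from=int(cols[17]),
                    ali_to=int(cols[18]),
                )
            except ValueError as exc:
                raise DomtbloutParseError(f"{path}:{lineno}: {exc}") from exc
            if evalue <= evalue_cutoff:
                hits.append(hit)
    return hits


@dataclass
class Pssm:
    """Ungapped log-odds matrix over the 20 standard amino acids.

    ``scores[j, i]`` is ln of the pseudocounted column frequency of residue
    ``AA_ALPHABET[i]`` at position ``j`` over its background frequency.
    """

    scores: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    pseudocount: float

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (length, 20)")
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM length must be >= 1")
        if np.any(self.background <= 0) or not math.isclose(
            float(self.background.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background must be positive and sum to 1")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.scores.argmax(axis=1))


def build_pssm(
    seed_msa: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> Pssm:
    """Build a PSSM from an aligned set of protein sequences.

    Columns with more than ``max_gap_fraction`` gaps are dropped.  Scores are
    ``ln(((count + kappa/20) / (n + kappa)) / background)`` with ``kappa`` the
    pseudocount and ``n`` the number of sequences; deterministic for a fixed
    input.
    """
    if len(seed_msa) < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    width = len(seed_msa[0])
    if any(len(s) != width for s in seed_msa):
        raise ValueError("ragged alignment: sequences differ in length")
    if background is None:
        background = np.full(20, 1 / 20)
    n = len(seed_msa)
    columns = []
    for j in range(width):
        col = [s[j].upper() for s in seed_msa]
        gaps = sum(c in "-." for c in col)
        if gaps / n > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in col:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        freqs = (counts + pseudocount / 20) / (n + pseudocount)
        columns.append(np.log(freqs / background))
    if not columns:
        raise ValueError("all alignment columns were gap-dominated")
    return Pssm(scores=np.asarray(columns), background=np.asarray(background),
                pseudocount=pseudocount)


def load_seed_alignment(path: str | Path, fmt: str = "fasta") -> list[str]:
    """Read a seed alignment (aligned FASTA or Stockholm) for build_pssm."""
    from Bio import AlignIO

    if fmt not in ("fasta", "stockholm"):
        raise ValueError("alignment format must be 'fasta' or 'stockholm'")
    alignment = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in alignment]


class NoScan(Exception):
    """Protein shorter than the profile: no window can be scored."""


def pssm_scan(
    protein: str, pssm: Pssm, n_shuffles: int = 99, seed: int = 0
) -> tuple[float, float, tuple[int, int]]:
    """Best ungapped window score plus a shuffle-based empirical p-value.

    Returns ``(best_score, empirical_p, (start, end))`` with the window as
    1-based inclusive residue positions.  ``empirical_p`` uses the add-one
    correction ``(1 + #shuffles >= observed) / (n_shuffles + 1)``.
    """
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be >= 99")
    L, m = len(protein), pssm.length
    if L < m:
        raise NoScan(f"protein length {L} < profile length {m}")

    def best(seq: str) -> tuple[float, int]:
        idx = np.array([_AA_INDEX.get(c, -1) for c in seq])
        scores = np.empty(len(seq) - m + 1)
        for off in range(len(scores)):
            window = idx[off : off + m]
            # unknown residues contribute the column mean (neutral)
            s = 0.0
            for j, i in enumerate(window):
                s += pssm.scores[j, i] if i >= 0 else float(pssm.scores[j].mean())
            scores[off] = s
        k = int(scores.argmax())
        return float(scores[k]), k

    observed, off = best(protein)
    rng = np.random.default_rng(seed)
    letters = list(protein)
    exceed = 0
    for _ in range(n_shuffles):
        rng.shuffle(letters)
        if best("".join(letters))[0] >= observed:
            exceed += 1
    empirical_p = (1 + exceed) / (n_shuffles + 1)
    return observed, empirical_p, (off + 1, off + m)


def classify_candidates(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    profiles: ProfileSet,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
) -> list[TACandidate]:
    """Assign toxin/antitoxin roles and apply the inclusive size filter.

    Each gene with at least one hit takes the role of its lowest-e-value hit;
    a gene whose best toxin and best antitoxin e-values are exactly tied is
    marked ``ambiguous``.  Genes outside ``[min_aa, max_aa]`` residues
    (bounds inclusive) are dropped.
    """
    by_tag = {g.locus_tag: g for g in genes}
    per_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.protein_id not in by_tag:
            raise CrossReferenceError(
                f"hit references unknown protein_id {h.protein_id!r}"
            )
        per_gene.setdefault(h.protein_id, []).append(h)

    candidates = []
    for tag in sorted(per_gene):
        gene = by_tag[tag]
        if not (min_aa <= gene.length_aa <= max_aa):
            continue
        gene_hits = sorted(per_gene[tag], key=lambda h: (h.evalue, -h.bit_score))
        best = gene_hits[0]
        role = profiles.role_of(best.profile_id)
        best_other = next(
            (h for h in gene_hits if profiles.role_of(h.profile_id) != role), None
        )
        if best_other is not None and best_other.evalue == best.evalue:
            role = "ambiguous"
        candidates.append(
            TACandidate(gene=gene, role=role, best_hit=best,
                        length_aa=gene.length_aa)
        )
    return candidates
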