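"""RelB/RelE protein sequence analyses.

RelB-family antitoxins carry a short C-terminal consensus, ZXnnZnnRZ, that
mediates the hydrophobic contacts with the RelE toxin: Z is a hydrophobic
residue with a small side chain (Val/Ile/Leu/Ala), X any hydrophobic residue,
n any residue, and position 8 is an invariant arginine.  This module scans
proteins for windows compatible with that consensus, maps catalytic residues
between toxin homologs by global alignment (the RelE catalytic tyrosine,
e.g. Tyr87 in the E. coli toxin), applies point mutations given in the
compact N61V-style notation, and computes pairwise identity and molecular
mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import molecular_weight

MOTIF_LENGTH = 9
# 1-based offsets of the constrained positions within the 9-residue motif
_Z_OFFSETS = (1, 5, 9)
_X_OFFSET = 2
_R_OFFSET = 8

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ResidueClasses:
    """Residue classes for the consensus positions; configurable."""

    Z_set: frozenset[str] = frozenset("VILA")
    X_set: frozenset[str] = frozenset("AVILMFWC")

    def __post_init__(self) -> None:
        if not self.Z_set or not self.X_set:
            raise ValueError("residue classes must be non-empty")
        if any(len(a) != 1 for a in self.Z_set | self.X_set):
            raise ValueError("residue classes use single-letter codes")
        if not self.Z_set <= (self.X_set | {"A"}):
            raise ValueError("Z_set must be a subset of X_set plus Ala")


@dataclass(frozen=True)
class PositionVerdict:
    position: int  # 1-based within the protein
    residue: str
    class_required: str  # 'Z' | 'X' | 'n' | 'R'
    ok: bool


@dataclass(frozen=True)
class MotifMatch:
    start: int  # 1-based residue index of motif position 1
    assignments: tuple[PositionVerdict, ...]
    overall_pass: bool


def _verdicts(window: str, start: int, classes: ResidueClasses) -> MotifMatch:
    out = []
    for off in range(1, MOTIF_LENGTH + 1):
        res = window[off - 1]
        if off in _Z_OFFSETS:
            req, ok = "Z", res in classes.Z_set
        elif off == _X_OFFSET:
            req, ok = "X", res in classes.X_set
        elif off == _R_OFFSET:
            req, ok = "R", res == "R"
        else:
            req, ok = "n", True
        out.append(PositionVerdict(start + off - 1, res, req, ok))
    return MotifMatch(
        start=start,
        assignments=tuple(out),
        overall_pass=all(v.ok for v in out if v.class_required != "n"),
    )


def scan_consensus_motif(
    protein: str,
    classes: ResidueClasses = ResidueClasses(),
    c_terminal_fraction: float | None = None,
    include_near_misses: bool = False,
) -> list[MotifMatch]:
    """Scan every 9-residue window for ZXnnZnnRZ compatibility.

    By default the whole sequence is scanned; ``c_terminal_fraction`` (e.g.
    0.4) restricts matches to windows starting in the final fraction of the
    protein, a heuristic proxy for the C-terminal location of the motif in
    RelB antitoxins.  Windows containing non-standard letters are skipped.
    Returns passing matches, or all evaluated windows when
    ``include_near_misses`` is set.
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    protein = protein.upper()
    first_start = 1
    if c_terminal_fraction is not None:
        if not (0 < c_terminal_fraction <= 1):
            raise ValueError("c_terminal_fraction must be in (0, 1]")
        first_start = max(1, len(protein)
                          - int(len(protein) * c_terminal_fraction) + 1)
    matches = []
    for start in range(first_start, len(protein) - MOTIF_LENGTH + 2):
        window = protein[start - 1 : start + MOTIF_LENGTH - 1]
        if set(window) - _STANDARD_AA:
            continue
        m = _verdicts(window, start, classes)
        if m.overall_pass or include_near_misses:
            matches.append(m)
    return matches


def motif_anchor_positions(match_start: int) -> tuple[int, int]:
    """(X position, last-Z position) for a motif starting at ``match_start``.

    The X residue is motif position 2 and the last Z is position 9, so an X
    anchored at residue 61 places the last Z at residue 68.
    """
    if match_start < 1:
        raise ValueError("match_start is 1-based and must be >= 1")
    return match_start + _X_OFFSET - 1, match_start + MOTIF_LENGTH - 1


@dataclass(frozen=True)
class MutationSpec:
    ref_residue: str
    position: int  # 1-based
    alt_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("mutation position is 1-based and must be >= 1")
        for r in (self.ref_residue, self.alt_residue):
            if r not in _STANDARD_AA:
                raise ValueError(f"non-standard residue {r!r} in mutation spec")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse mutation {text!r} (expected e.g. N61V)")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    @classmethod
    def parse_list(cls, text: str) -> list["MutationSpec"]:
        """Parse the compact comma/ampersand form, e.g. ``"N61V,M68L"``."""
        parts = re.split(r"[,&]", text)
        return [cls.parse(p) for p in parts if p.strip()]


class ReferenceMismatchError(ValueError):
    pass


def apply_mutations(protein: str, specs: list[MutationSpec]) -> str:
    """Apply point mutations left-to-right; length is unchanged.

    Each spec's reference residue must match the sequence at its position
    (guards against off-by-one numbering); duplicate positions conflict.
    """
    seen: dict[int, MutationSpec] = {}
    residues = list(protein)
    for spec in specs:
        if spec.position > len(residues):
            raise ValueError(
                f"position {spec.position} beyond sequence length {len(residues)}"
            )
        if spec.position in seen:
            raise ValueError(f"duplicate mutation at position {spec.position}")
        actual = residues[spec.position - 1]
        if actual != spec.ref_residue:
            raise ReferenceMismatchError(
                f"expected {spec.ref_residue} at position {spec.position}, "
                f"found {actual}"
            )
        residues[spec.position - 1] = spec.alt_residue
        seen[spec.position] = spec
    return "".join(residues)


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_catalytic_residue(
    query: str, reference: str, ref_catalytic_pos: int
) -> tuple[int | None, str | None]:
    """Find the query residue aligned to a reference catalytic position.

    A BLOSUM62 global alignment (gap open 11, extend 1) is computed and the
    query column opposite ``ref_catalytic_pos`` (1-based) is returned as
    ``(query_position, query_residue)``; ``(None, None)`` signals that the
    catalytic column is deleted in the query.  The first optimal alignment of
    Biopython's deterministic traceback is used.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    if not (1 <= ref_catalytic_pos <= len(reference)):
        raise ValueError("ref_catalytic_pos outside reference sequence")
    aln = _aligner("global").align(reference, query)[0]
    ref_idx = ref_catalytic_pos - 1
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        if r0 <= ref_idx < r1:
            qpos = int(q0) + (ref_idx - int(r0))
            return qpos + 1, query[qpos]
    return None, None


def pairwise_identity(a: str, b: str, mode: str = "global") -> float:
    """Percent identity from a pairwise alignment, to 0.1%.

    Identity = identical aligned columns / total alignment columns, gap
    columns included in the denominator (the common BLAST convention for the
    aligned region); ``mode`` selects global or local alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    aln = _aligner(mode).align(a, b)[0]
    counts = aln.counts()  # gaps, identities, mismatches
    columns = counts.gaps + counts.identities + counts.mismatches
    if mode == "global":
        # count terminal overhangs too: full alignment length
        columns = aln.length
    return round(100.0 * counts.identities / columns, 1)


def molecular_mass(protein: str) -> float:
    """Average-isotopic protein mass in kDa (residue masses + one water)."""
    if not protein:
        raise ValueError("protein sequence is empty")
    bad = set(protein) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    return molecular_weight(protein, seq_type="protein") / 1000.0
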