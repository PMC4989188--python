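"""Antitoxin consensus-motif scan and toxin catalytic-residue mapping.

Scans every mined antitoxin for ZXnnZnnRZ-compatible windows, reports the
X / last-Z anchor positions, demonstrates the hydrophobic double mutation
that restores motif compatibility when the X position holds a hydrophilic
residue, and maps the catalytic-position correspondence between two toxins
by global alignment.
"""

from _common import RESULTS, fixture_paths
from tamine.pairing import run_pipeline
from tamine.seqanalysis import (
    MutationSpec,
    apply_mutations,
    map_catalytic_residue,
    motif_anchor_positions,
    pairwise_identity,
    scan_consensus_motif,
)
from tamine.synth import DEFAULT_PROFILE_SET


def main() -> None:
    paths, truth, hit_table = fixture_paths()
    loci, _, _ = run_pipeline([str(paths["genbank"])], str(hit_table),
                              DEFAULT_PROFILE_SET)
    rows = []
    for locus in loci:
        protein = locus.antitoxin.gene.protein
        for m in scan_consensus_motif(protein):
            x_pos, last_z = motif_anchor_positions(m.start)
            rows.append((locus.antitoxin.gene.locus_tag, m.start, x_pos,
                         last_z, "".join(v.residue for v in m.assignments)))
    with open(RESULTS / "03_motif_report.tsv", "w") as fh:
        fh.write("antitoxin\tmotif_start\tX_pos\tlast_Z_pos\twindow\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    print(f"{len(rows)} motif matches across {len(loci)} mined antitoxins")

    # A hydrophilic residue at the X position breaks the consensus; the
    # double substitution to small hydrophobics restores it.
    broken = "G" * 59 + "VNAAVAARM" + "G" * 10  # N at X (61), M at last Z (68)
    assert scan_consensus_motif(broken) == []
    repaired = apply_mutations(broken, MutationSpec.parse_list("N61V,M68L"))
    (m,) = scan_consensus_motif(repaired)
    print(f"N61V,M68L repairs the motif: match at {m.start}, "
          f"anchors {motif_anchor_positions(m.start)}")

    # catalytic mapping between the two mined toxins
    if len(loci) >= 2:
        tox_a = loci[0].toxin.gene.protein
        tox_b = loci[1].toxin.gene.protein
        ref_pos = tox_a.index("Y") + 1  # first tyrosine of the reference toxin
        pos, res = map_catalytic_residue(tox_b, tox_a, ref_pos)
        ident = pairwise_identity(tox_a, tox_b)
        print(f"toxin identity {ident}%; reference Tyr{ref_pos} maps to "
              f"query position {pos} ({res})")


if __name__ == "__main__":
    main()
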