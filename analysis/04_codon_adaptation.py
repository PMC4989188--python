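"""Codon adaptation of the mined TA genes against highly expressed genes.

Builds the relative-adaptiveness table from the genome's ribosomal-protein
and elongation-factor CDS and computes the CAI of every mined toxin and
antitoxin gene; writes the w table and the per-gene CAI values.
"""

from _common import RESULTS, fixture_paths
from tamine.codon import cai, relative_adaptiveness, rscu, select_reference_genes
from tamine.genome import read_genbank
from tamine.pairing import run_pipeline
from tamine.synth import DEFAULT_PROFILE_SET


def main() -> None:
    paths, truth, hit_table = fixture_paths()
    replicons = read_genbank(paths["genbank"])
    reference = select_reference_genes(replicons)
    print(f"reference set ({len(reference)} genes): {', '.join(reference)}")
    wtable = relative_adaptiveness(rscu(reference),
                                   reference_gene_ids=list(reference))
    wtable.to_tsv(str(RESULTS / "04_w_table.tsv"))

    loci, _, _ = run_pipeline([str(paths["genbank"])], str(hit_table),
                              DEFAULT_PROFILE_SET)
    by_id = {r.id: r for r in replicons}
    with open(RESULTS / "04_cai.tsv", "w") as fh:
        fh.write("locus_tag\trole\tcai\n")
        for locus in loci:
            for cand in (locus.antitoxin, locus.toxin):
                nt = by_id[locus.replicon_id].cds_nt(cand.gene.locus_tag)
                value = cai(nt, wtable, gene_id=cand.gene.locus_tag)
                fh.write(f"{cand.gene.locus_tag}\t{cand.role}\t{value:.2f}\n")
                print(f"{cand.gene.locus_tag} ({cand.role}): CAI {value:.2f}")
    print(f"w table -> {RESULTS / '04_w_table.tsv'}")


if __name__ == "__main__":
    main()
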