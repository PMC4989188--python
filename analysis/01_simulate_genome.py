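"""Generate the synthetic two-replicon genome with planted TA operons.

Emits the genome (GenBank + GFF3/FASTA) and a matching profile hit table
under scratch/, and records the ground truth of every planted locus in
results/01_truth_table.tsv.  Planted intergenic distances include the 8-nt
antitoxin-toxin overlap geometry and window-edge cases (0, -1, 10, 30 bp).
"""

from _common import RESULTS, SEED, fixture_paths


def main() -> None:
    paths, truth, hit_table = fixture_paths()
    out = RESULTS / "01_truth_table.tsv"
    with open(out, "w") as fh:
        fh.write("replicon\tantitoxin_tag\ttoxin_tag\tintergenic_bp\tstrand\t"
                 "in_window\n")
        for p in truth.planted:
            fh.write(f"{p.replicon_id}\t{p.antitoxin_tag}\t{p.toxin_tag}\t"
                     f"{p.intergenic_bp}\t{p.strand}\t{p.in_window}\n")
    print(f"seed {SEED}: wrote {paths['genbank']} and {hit_table}")
    print(f"planted {len(truth.planted)} TA pairs "
          f"({len(truth.planted_in_window)} inside the -20..30 bp window), "
          f"{len(truth.decoy_tags)} decoys, "
          f"{len(truth.outlier_tags)} size outliers")
    print(f"truth table -> {out}")


if __name__ == "__main__":
    main()
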