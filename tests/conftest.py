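import pathlib

import pytest

from tamine.profiles import parse_domtblout
from tamine.synth import (
    DEFAULT_PROFILE_SET,
    GenomeSpec,
    make_genome,
    make_hit_table,
)

# Hand-written two-gene GenBank fixture: the plus-strand CDS (1..30) and the
# minus-strand CDS (complement(31..60)) encode the same 30-nt reading frame
# ATG GCT GAT AAA GGC TTT CCG TGG CAT TAA, whose hand translation under the
# bacterial code is MADKGFPWH.
TWO_GENE_GENBANK = """\
LOCUS       TESTREP01                 60 bp    DNA     linear   BCT 01-JAN-2016
DEFINITION  two-gene fixture.
ACCESSION   TESTREP01
VERSION     TESTREP01
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     CDS             1..30
                     /locus_tag="T_0001"
                     /product="demo plus"
     CDS             complement(31..60)
                     /locus_tag="T_0002"
                     /product="demo minus"
ORIGIN
        1 atggctgata aaggctttcc gtggcattaa ttaatgccac ggaaagcctt tatcagccat
//
"""
HAND_TRANSLATION = "MADKGFPWH"

TWO_GENE_GFF3 = """\
##gff-version 3
TESTREP01\ttest\tCDS\t1\t30\t.\t+\t0\tID=T_0001;locus_tag=T_0001;product=demo plus
TESTREP01\ttest\tCDS\t31\t60\t.\t-\t0\tID=T_0002;locus_tag=T_0002;product=demo minus
"""
TWO_GENE_FASTA = """\
>TESTREP01
atggctgataaaggctttccgtggcattaattaatgccacggaaagcctttatcagccat
"""


@pytest.fixture(scope="session")
def two_gene_gbk(tmp_path_factory) -> pathlib.Path:
    path = tmp_path_factory.mktemp("gbk") / "two_gene.gbk"
    path.write_text(TWO_GENE_GENBANK)
    return path


@pytest.fixture(scope="session")
def two_gene_gff_fasta(tmp_path_factory) -> tuple[pathlib.Path, pathlib.Path]:
    d = tmp_path_factory.mktemp("gff")
    gff = d / "two_gene.gff3"
    fasta = d / "two_gene.fasta"
    gff.write_text(TWO_GENE_GFF3)
    fasta.write_text(TWO_GENE_FASTA)
    return gff, fasta


# Planted intergenic distances: the study geometries (8-nt overlap of the
# relBE2-like pair), an abutting pair, and window-edge cases.
PLANTED_DISTANCES = (-8, 0, 10, -1, 30)


@pytest.fixture(scope="session")
def synth_spec() -> GenomeSpec:
    return GenomeSpec(seed=42, fixed_distances=PLANTED_DISTANCES)


@pytest.fixture(scope="session")
def synth_genome(tmp_path_factory, synth_spec):
    """(paths, truth, hit_table_path) for one fixed-seed synthetic genome."""
    out = tmp_path_factory.mktemp("synth")
    paths, truth = make_genome(synth_spec, out)
    hit_table = make_hit_table(truth, out / "hits.domtblout", seed=42)
    return paths, truth, hit_table


@pytest.fixture(scope="session")
def synth_hits(synth_genome):
    _, _, hit_table = synth_genome
    return parse_domtblout(hit_table)


@pytest.fixture(scope="session")
def profile_set():
    return DEFAULT_PROFILE_SET
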