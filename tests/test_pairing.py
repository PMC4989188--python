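"""Operon pairing: window semantics, tie-breaking, and the full pipeline."""

import itertools

import pytest

from tamine.genome import GeneRecord, Replicon, intergenic_distance
from tamine.pairing import find_loci, run_pipeline, summarize_loci
from tamine.profiles import DomainHit, Profile, ProfileSet, TACandidate
from tamine.synth import DEFAULT_PROFILE_SET, GenomeSpec, make_genome, make_hit_table

PROFILES = ProfileSet(
    [Profile("tox_prof", "toxin", "relBE"), Profile("anti_prof", "antitoxin", "relBE")]
)


def _cand(tag, start, end, role, strand="+", evalue=1e-6):
    gene = GeneRecord(locus_tag=tag, start=start, end=end, strand=strand,
                      protein="M" + "A" * 49)
    profile = "anti_prof" if role == "antitoxin" else "tox_prof"
    hit = DomainHit(protein_id=tag, profile_id=profile, evalue=evalue,
                    bit_score=40.0, ali_from=1, ali_to=10)
    return TACandidate(gene=gene, role=role, best_hit=hit, length_aa=50)


def _rep(cands, length=5000):
    return Replicon(id="R", length=length, genes=[c.gene for c in cands])


class TestFindLoci:
    def test_overlapping_pair_found_with_brute_force_agreement(self):
        """One antitoxin-toxin pair at -8 bp: the scan must agree with a
        brute-force evaluation of every candidate pair."""
        cands = [_cand("a", 100, 400, "antitoxin"), _cand("t", 392, 700, "toxin")]
        loci = find_loci(cands, _rep(cands), profiles=PROFILES)
        brute = [
            (x, y)
            for x, y in itertools.permutations(cands, 2)
            if x.gene.start <= y.gene.start
            and x.role == "antitoxin" and y.role == "toxin"
            and -20 <= intergenic_distance(x.gene, y.gene) <= 30
        ]
        assert len(loci) == len(brute) == 1
        (locus,) = loci
        assert locus.intergenic_bp == -8
        assert locus.gene_order == "antitoxin_first"
        assert locus.family == "relBE"

    @pytest.mark.parametrize("d,found", [(-21, False), (-20, True), (30, True),
                                         (31, False)])
    def test_window_bounds_inclusive(self, d, found):
        cands = [_cand("a", 100, 400, "antitoxin"),
                 _cand("t", 400 + d, 700 + max(d, 0), "toxin")]
        loci = find_loci(cands, _rep(cands), profiles=PROFILES)
        assert bool(loci) is found

    def test_same_role_neighbors_do_not_pair(self):
        cands = [_cand("t1", 100, 400, "toxin"), _cand("t2", 410, 700, "toxin")]
        assert find_loci(cands, _rep(cands)) == []

    def test_opposite_strands_do_not_pair_by_default(self):
        cands = [_cand("a", 100, 400, "antitoxin", "+"),
                 _cand("t", 410, 700, "toxin", "-")]
        assert find_loci(cands, _rep(cands)) == []
        assert len(find_loci(cands, _rep(cands), require_same_strand=False)) == 1

    def test_minus_strand_gene_order(self):
        # transcription right-to-left: the downstream-positioned gene is 5'
        cands = [_cand("t", 100, 400, "toxin", "-"),
                 _cand("a", 410, 700, "antitoxin", "-")]
        (locus,) = find_loci(cands, _rep(cands))
        assert locus.gene_order == "antitoxin_first"

    def test_ambiguous_candidates_excluded_by_default(self):
        cands = [_cand("a", 100, 400, "antitoxin"), _cand("t", 410, 700, "toxin")]
        amb = TACandidate(gene=cands[1].gene, role="ambiguous",
                          best_hit=cands[1].best_hit, length_aa=50)
        assert find_loci([cands[0], amb], _rep(cands)) == []

    def test_candidate_joins_at_most_one_locus(self):
        # antitoxin flanked by two toxins: nearer |distance| wins
        cands = [
            _cand("t1", 100, 395, "toxin"),
            _cand("a", 400, 700, "antitoxin"),
            _cand("t2", 702, 1000, "toxin"),
        ]
        loci = find_loci(cands, _rep(cands), profiles=PROFILES)
        assert len(loci) == 1
        assert loci[0].toxin.gene.locus_tag == "t2"  # |2| < |5|
        used = [loci[0].antitoxin.gene.locus_tag, loci[0].toxin.gene.locus_tag]
        assert len(set(used)) == 2

    def test_intervening_gene_blocks_pairing(self):
        cands = [_cand("a", 100, 400, "antitoxin"), _cand("t", 430, 700, "toxin")]
        middle = GeneRecord(locus_tag="mid", start=405, end=425, strand="+",
                            protein="MAAAAA")
        rep = Replicon(id="R", length=5000,
                       genes=[c.gene for c in cands] + [middle])
        assert find_loci(cands, rep) == []
        assert len(find_loci(cands, rep, allow_intervening_genes=True)) == 1

    def test_foreign_candidate_is_cross_reference_error(self):
        cands = [_cand("a", 100, 400, "antitoxin"), _cand("t", 410, 700, "toxin")]
        other = Replicon(id="other", length=5000, genes=[])
        with pytest.raises(KeyError):
            find_loci(cands, other)

    def test_widening_window_is_monotone(self):
        cands = [
            _cand("a1", 100, 400, "antitoxin"), _cand("t1", 410, 700, "toxin"),
            _cand("a2", 1000, 1300, "antitoxin"), _cand("t2", 1345, 1650, "toxin"),
        ]
        rep = _rep(cands)
        small = find_loci(cands, rep, window=(0, 20))
        large = find_loci(cands, rep, window=(-20, 60))
        keys = lambda loci: {(l.antitoxin.gene.locus_tag, l.toxin.gene.locus_tag)
                             for l in loci}
        assert keys(small) <= keys(large)
        assert len(large) == 2 and len(small) == 1


class TestSummarize:
    def test_counts_per_replicon_and_family(self, synth_genome, profile_set):
        paths, truth, hit_table = synth_genome
        loci, summary, _ = run_pipeline([paths["genbank"]], str(hit_table),
                                        profile_set)
        assert summary["n_loci"].sum() == len(loci)
        assert list(summary.columns) == ["replicon", "family", "n_loci"]
        reps = sorted({p.replicon_id for p in truth.planted_in_window})
        assert sorted(summary["replicon"].unique()) == reps

    def test_empty_input_gives_empty_table(self):
        assert summarize_loci([]).empty


class TestRunPipeline:
    def test_recovers_exactly_the_planted_loci(self, synth_genome, profile_set):
        paths, truth, hit_table = synth_genome
        loci, _, log = run_pipeline([paths["genbank"]], str(hit_table), profile_set)
        found = {(l.antitoxin.gene.locus_tag, l.toxin.gene.locus_tag,
                  l.intergenic_bp) for l in loci}
        expected = {(p.antitoxin_tag, p.toxin_tag, p.intergenic_bp)
                    for p in truth.planted_in_window}
        assert found == expected  # precision = recall = 1
        assert any("evalue_cutoff" in line for line in log)

    def test_narrowed_window_recovers_subset(self, synth_genome, profile_set):
        paths, truth, hit_table = synth_genome
        loci, _, _ = run_pipeline([paths["genbank"]], str(hit_table), profile_set,
                                  window=(0, 0))
        expected = {(p.antitoxin_tag, p.toxin_tag)
                    for p in truth.planted_in_window if p.intergenic_bp == 0}
        assert {(l.antitoxin.gene.locus_tag, l.toxin.gene.locus_tag)
                for l in loci} == expected

    def test_zero_candidates_is_not_an_error(self, tmp_path, synth_spec,
                                             profile_set):
        spec = GenomeSpec(n_ta_pairs=0, n_decoys=5, seed=9,
                          replicon_lengths=(8000, 8000))
        paths, truth = make_genome(spec, tmp_path)
        hit_table = make_hit_table(truth, tmp_path / "h.domtblout", seed=9)
        loci, summary, _ = run_pipeline([paths["genbank"]], str(hit_table),
                                        profile_set)
        assert loci == [] and summary.empty

    def test_strand_flip_symmetry(self, synth_genome, profile_set):
        """Reverse-complementing a replicon (mirroring coordinates) must give
        the same loci with the same intergenic distances."""
        from tamine.genome import read_genbank
        from tamine.profiles import classify_candidates, parse_domtblout

        paths, _, hit_table = synth_genome
        hits = parse_domtblout(hit_table)
        for rep in read_genbank(paths["genbank"]):
            tags = {g.locus_tag for g in rep.genes}
            rep_hits = [h for h in hits if h.protein_id in tags]
            cands = classify_candidates(rep.genes, rep_hits, profile_set)
            loci = find_loci(cands, rep, profiles=profile_set)

            L = rep.length
            flip = {"+": "-", "-": "+"}
            mirrored_genes = [
                GeneRecord(locus_tag=g.locus_tag, start=L - g.end, end=L - g.start,
                           strand=flip[g.strand], product=g.product,
                           protein=g.protein)
                for g in rep.genes
            ]
            mirrored = Replicon(id=rep.id, length=L, genes=mirrored_genes)
            mcands = classify_candidates(mirrored.genes, rep_hits, profile_set)
            mloci = find_loci(mcands, mirrored, profiles=profile_set)

            key = lambda ls: {
                (l.antitoxin.gene.locus_tag, l.toxin.gene.locus_tag,
                 l.intergenic_bp, l.gene_order) for l in ls
            }
            assert key(loci) == key(mloci)
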