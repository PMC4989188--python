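"""Profile-hit parsing, the PSSM fallback scorer, and candidate filters."""

import math

import numpy as np
import pytest

from tamine.genome import GeneRecord
from tamine.profiles import (
    AA_ALPHABET,
    CrossReferenceError,
    DomtbloutParseError,
    NoScan,
    Profile,
    ProfileSet,
    build_pssm,
    classify_candidates,
    parse_domtblout,
    pssm_scan,
)
from tamine.synth import make_hit_table, make_seed_alignment

TOY_PROFILES = ProfileSet(
    [Profile("tox_prof", "toxin", "fam"), Profile("anti_prof", "antitoxin", "fam")]
)


def _row(target, query, ievalue, tlen=100, qlen=20, score=40.0):
    return (
        f"{target} - {tlen} {query} - {qlen} {ievalue} {score} 0.0 1 1 "
        f"{ievalue} {ievalue} {score} 0.0 1 {qlen} 1 {tlen} 1 {tlen} 0.99 desc"
    )


class TestParseDomtblout:
    def test_inclusive_evalue_cutoff(self, tmp_path):
        path = tmp_path / "t.domtblout"
        path.write_text(
            "# comment\n"
            + _row("p1", "tox_prof", "2e-3") + "\n"
            + _row("p2", "tox_prof", "1.1e-2") + "\n"
            + _row("p3", "tox_prof", "0.01") + "\n"
        )
        hits = parse_domtblout(path, evalue_cutoff=0.01)
        assert [h.protein_id for h in hits] == ["p1", "p3"]

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "c.domtblout"
        path.write_text("# one\n# two\n")
        assert parse_domtblout(path) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text(_row("p1", "tox_prof", "1e-5") + "\nonly three cols\n")
        with pytest.raises(DomtbloutParseError, match=":2:"):
            parse_domtblout(path)

    def test_agrees_with_biopython_searchio(self, synth_genome):
        """Cross-check the parser against Bio.SearchIO on the same table."""
        from Bio import SearchIO

        _, _, hit_table = synth_genome
        ours = {
            (h.protein_id, h.profile_id): (h.evalue, h.bit_score)
            for h in parse_domtblout(hit_table, evalue_cutoff=math.inf)
        }
        theirs = {}
        for qres in SearchIO.parse(str(hit_table), "hmmsearch3-domtab"):
            for hit in qres:
                for hsp in hit:
                    theirs[(hit.id, qres.id)] = (hsp.evalue, hsp.bitscore)
        assert ours == theirs

    def test_retained_fields_round_trip(self, synth_genome):
        _, truth, hit_table = synth_genome
        hits = parse_domtblout(hit_table)
        planted = {p.antitoxin_tag for p in truth.planted}
        planted |= {p.toxin_tag for p in truth.planted}
        assert planted <= {h.protein_id for h in hits}
        for h in hits:
            assert 1 <= h.ali_from <= h.ali_to <= len(truth.proteins[h.protein_id])


class TestBuildPssm:
    def test_identical_sequences_maximize_consensus(self):
        pssm = build_pssm(["MKV", "MKV"])
        assert pssm.consensus() == "MKV"
        for j, aa in enumerate("MKV"):
            assert pssm.scores[j].argmax() == AA_ALPHABET.index(aa)

    def test_uniform_composition_gives_zero_scores(self):
        # each column holds every residue once against a uniform background
        msa = ["".join(AA_ALPHABET[(i + j) % 20] for j in range(5))
               for i in range(20)]
        pssm = build_pssm(msa, pseudocount=1.0)
        assert np.allclose(pssm.scores, 0.0, atol=1e-12)

    def test_three_sequence_scores_match_hand_formula(self):
        pssm = build_pssm(["AC", "AC", "AD"], pseudocount=1.0)
        bg, kappa, n = 1 / 20, 1.0, 3

        def expected(count):
            return math.log(((count + kappa / 20) / (n + kappa)) / bg)

        assert pssm.scores[0, AA_ALPHABET.index("A")] == pytest.approx(expected(3))
        assert pssm.scores[1, AA_ALPHABET.index("C")] == pytest.approx(expected(2))
        assert pssm.scores[1, AA_ALPHABET.index("D")] == pytest.approx(expected(1))
        assert pssm.scores[1, AA_ALPHABET.index("W")] == pytest.approx(expected(0))

    def test_gap_dominated_columns_dropped(self):
        pssm = build_pssm(["A-C", "A-C", "AEC", "A-C"])
        assert pssm.length == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_pssm(["AC", "ACD"])

    def test_seed_alignment_loads_from_fasta_and_stockholm(self, tmp_path):
        from tamine.profiles import load_seed_alignment

        seqs = make_seed_alignment("antitoxin", seed=4)
        fasta = tmp_path / "seed.afa"
        fasta.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        sto = tmp_path / "seed.sto"
        sto.write_text("# STOCKHOLM 1.0\n"
                       + "".join(f"s{i}  {s}\n" for i, s in enumerate(seqs))
                       + "//\n")
        assert load_seed_alignment(fasta) == seqs
        assert load_seed_alignment(sto, fmt="stockholm") == seqs


class TestPssmScan:
    def test_single_window_equals_column_sum(self):
        msa = make_seed_alignment("toxin", seed=3)
        pssm = build_pssm(msa)
        protein = msa[0]
        best, _, window = pssm_scan(protein, pssm, n_shuffles=99, seed=0)
        direct = sum(
            pssm.scores[j, AA_ALPHABET.index(c)] for j, c in enumerate(protein)
        )
        assert best == pytest.approx(direct)
        assert window == (1, len(protein))

    def test_best_score_matches_brute_force_all_offsets(self):
        rng = np.random.default_rng(7)
        pssm = build_pssm(make_seed_alignment("antitoxin", seed=1))
        for _ in range(10):
            protein = "".join(rng.choice(list(AA_ALPHABET), size=50))
            best, _, (w0, w1) = pssm_scan(protein, pssm, n_shuffles=99, seed=0)
            scores = [
                sum(pssm.scores[j, AA_ALPHABET.index(c)]
                    for j, c in enumerate(protein[off : off + pssm.length]))
                for off in range(len(protein) - pssm.length + 1)
            ]
            assert best == pytest.approx(max(scores))
            assert protein[w0 - 1 : w1] == protein[
                int(np.argmax(scores)) : int(np.argmax(scores)) + pssm.length
            ]

    def test_consensus_hits_minimal_pvalue(self):
        pssm = build_pssm(make_seed_alignment("antitoxin", seed=5))
        consensus = pssm.consensus()
        best, p, _ = pssm_scan(consensus, pssm, n_shuffles=199, seed=11)
        assert best == pytest.approx(float(pssm.scores.max(axis=1).sum()))
        assert p == pytest.approx(1 / 200)

    def test_null_pvalues_spread_over_unit_interval(self):
        """For a random protein scored against its own shuffles the
        empirical p should be roughly uniform, not piled at either end."""
        rng = np.random.default_rng(13)
        pssm = build_pssm(make_seed_alignment("toxin", seed=2))
        ps = []
        for i in range(30):
            protein = "".join(rng.choice(list(AA_ALPHABET), size=60))
            _, p, _ = pssm_scan(protein, pssm, n_shuffles=99, seed=i)
            ps.append(p)
        assert 0.25 < float(np.mean(ps)) < 0.75
        assert len(set(ps)) > 10

    def test_short_protein_is_no_scan_not_zero(self):
        pssm = build_pssm(make_seed_alignment("toxin", seed=0))
        with pytest.raises(NoScan):
            pssm_scan("MKV", pssm, n_shuffles=99, seed=0)


def _gene(tag, n_aa):
    return GeneRecord(locus_tag=tag, start=0, end=3 * (n_aa + 1), strand="+",
                      protein="M" + "A" * (n_aa - 1))


def _hit(tag, profile, evalue):
    from tamine.profiles import DomainHit

    return DomainHit(protein_id=tag, profile_id=profile, evalue=evalue,
                     bit_score=40.0, ali_from=1, ali_to=10)


class TestClassifyCandidates:
    @pytest.mark.parametrize(
        "n_aa,kept", [(29, False), (30, True), (500, True), (501, False)]
    )
    def test_size_bounds_inclusive(self, n_aa, kept):
        genes = [_gene("g", n_aa)]
        hits = [_hit("g", "tox_prof", 1e-8)]
        cands = classify_candidates(genes, hits, TOY_PROFILES)
        assert bool(cands) is kept

    def test_lowest_evalue_wins_role(self):
        genes = [_gene("g", 100)]
        hits = [_hit("g", "tox_prof", 1e-8), _hit("g", "anti_prof", 1e-3)]
        (cand,) = classify_candidates(genes, hits, TOY_PROFILES)
        assert cand.role == "toxin" and cand.best_hit.evalue == 1e-8

    def test_exact_role_tie_is_ambiguous(self):
        genes = [_gene("g", 100)]
        hits = [_hit("g", "tox_prof", 1e-5), _hit("g", "anti_prof", 1e-5)]
        (cand,) = classify_candidates(genes, hits, TOY_PROFILES)
        assert cand.role == "ambiguous"

    def test_unknown_protein_is_cross_reference_error(self):
        with pytest.raises(CrossReferenceError):
            classify_candidates([_gene("g", 100)], [_hit("other", "tox_prof", 1e-5)],
                                TOY_PROFILES)

    def test_filters_are_monotone(self, synth_genome, profile_set):
        """Raising the e-value cutoff or widening the size band never
        removes a previously retained candidate."""
        paths, truth, hit_table = synth_genome
        from tamine.genome import read_genbank

        reps = read_genbank(paths["genbank"])
        genes = [g for r in reps for g in r.genes]
        base_hits = parse_domtblout(hit_table, evalue_cutoff=1e-4)
        wide_hits = parse_domtblout(hit_table, evalue_cutoff=1e-2)
        assert {(h.protein_id, h.profile_id) for h in base_hits} <= {
            (h.protein_id, h.profile_id) for h in wide_hits
        }
        narrow = {c.gene.locus_tag
                  for c in classify_candidates(genes, wide_hits, profile_set,
                                               min_aa=40, max_aa=200)}
        wide = {c.gene.locus_tag
                for c in classify_candidates(genes, wide_hits, profile_set,
                                             min_aa=30, max_aa=500)}
        assert narrow <= wide
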