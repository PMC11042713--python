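"""Identity filtering, p-distances, barcode-gap analysis and rank fallback."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jaydiet import taxonomy as tx
from jaydiet._seq import encode
from jaydiet._align import smith_waterman
from jaydiet.read_qc import UniqueSequence
from oracles import gap_stats, pdist_naive, random_library, sw_align


def T(sp="sp0", g="g0", f="f0"):
    return tx.Taxon(species=sp, genus=g, family=f)


def hit(ident, length, sp="sp0", bits=0.0, qid="q1"):
    return tx.Hit(query_id=qid, taxon=T(sp=sp), percent_identity=ident,
                  alignment_length=length, bitscore=bits)


def ref(seq, rid="r0", sp="sp0", g="g0", f="f0", marker="COI-5P"):
    return tx.ReferenceRecord(record_id=rid, marker=marker,
                              taxon=T(sp, g, f), aligned_sequence=seq)


class TestFilterHits:
    def test_boundaries(self):
        kept, _ = tx.filter_hits([hit(94.9, 120), hit(95.0, 100),
                                  hit(96.0, 99)])
        assert [(h.percent_identity, h.alignment_length) for h in kept] == \
            [(95.0, 100)]

    @given(st.lists(st.tuples(st.floats(80, 100), st.integers(50, 200)),
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_random_table_equals_brute_force(self, rows):
        hits = [hit(i, l, qid=f"q{k}") for k, (i, l) in enumerate(rows)]
        kept, log = tx.filter_hits(hits)
        assert kept == [h for h in hits
                        if h.percent_identity >= 95 and
                        h.alignment_length >= 100]
        assert log.n_in == log.n_out + log.n_dropped


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("AC-GT", "ACAGA", 0.25),  # gap column excluded: 1 of 4 comparable
        ("NNNN", "ACGT", math.nan),
    ])
    def test_examples(self, a, b, expected):
        d = tx.p_distance(a, b)
        if math.isnan(expected):
            assert math.isnan(d)
        else:
            assert d == pytest.approx(expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            tx.p_distance("ACGT", "ACG")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 80))
        a = "".join(rng.choice(list("ACGTN-"), n))
        b = "".join(rng.choice(list("ACGTN-"), n))
        d = tx.p_distance(a, b)
        d2 = tx.p_distance(b, a)
        ora = pdist_naive(a, b)
        if math.isnan(ora):
            assert math.isnan(d) and math.isnan(d2)
        else:
            assert d == d2 == ora


def test_distance_matrix_symmetric_zero_diagonal(clean_gap_library):
    dm = tx.distance_matrix(clean_gap_library)
    assert np.allclose(dm.values, dm.values.T, atol=1e-12)
    assert (np.diag(dm.values) == 0).all()


class TestReferenceQC:
    def test_ambiguity_threshold(self):
        bad = ref("N" * 3 + "A" * 97, rid="bad")    # 3% N -> removed
        ok = ref("N" * 2 + "A" * 98, rid="ok")      # 2% N -> retained
        kept, log = tx.reference_qc([bad, ok])
        assert [r.record_id for r in kept] == ["ok"]
        assert log.reasons["ambiguous_bases"] == 1

    def test_terminal_gap_threshold(self):
        bad = ref("-" * 13 + "A" * 87, rid="bad13")
        ok = ref("-" * 12 + "N" + "A" * 87, rid="ok12")  # 12 gaps + ~1% N
        kept, log = tx.reference_qc([bad, ok])
        assert [r.record_id for r in kept] == ["ok12"]
        assert log.reasons["terminal_gaps"] == 1

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            tx.reference_qc([ref("ACGT"), ref("ACG", rid="r1")])


class TestNaiveSearch:
    def test_identical_query_scores_full_identity(self):
        r = ref("ACGTACGTACGTACGTACGT")
        hits = tx.naive_search("ACGTACGTACGTACGTACGT", [r])
        assert hits[0].percent_identity == 100.0
        assert hits[0].alignment_length == 20

    def test_five_substitutions_in_hundred_gives_95(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        q = list(base)
        for pos in (10, 30, 50, 70, 90):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        hits = tx.naive_search("".join(q), [ref(base)])
        assert hits[0].percent_identity == pytest.approx(95.0)
        assert hits[0].alignment_length == 100

    def test_marker_mismatch_rejected(self):
        q = UniqueSequence("ACGT", 1, "S01", "rbcLa")
        with pytest.raises(ValueError, match="marker"):
            tx.naive_search(q, [ref("ACGTACGT")])

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tx.naive_search("ACGT", [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_exhaustive_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 80))))
        refs = [ref("".join(rng.choice(list("ACGT"), 120)), rid=f"r{i}",
                    sp=f"sp{i}") for i in range(10)]
        hits = tx.naive_search(q, refs)
        oracle = []
        for r in refs:
            score, matches, cols = sw_align(q, r.aligned_sequence)
            oracle.append((r.taxon.species, score, matches, cols))
        best = max(oracle, key=lambda t: t[1])
        by_taxon = {h.taxon.species: h for h in hits}
        impl = by_taxon[best[0]]
        assert impl.bitscore == best[1]
        assert impl.alignment_length == best[3]
        assert impl.percent_identity == pytest.approx(100 * best[2] / best[3])


class TestCandidateSelection:
    def test_empty_hits_give_none(self):
        assert tx.candidate_species("q1", []) is None

    def test_single_hit_wins(self):
        c = tx.candidate_species("q1", [hit(99.0, 150, sp="spA")])
        assert c.rank == "species" and c.taxon.species == "spA"

    def test_lexicographic_top_hit(self):
        hits = [hit(99.0, 150, sp="spA"), hit(99.0, 160, sp="spB"),
                hit(98.0, 200, sp="spC")]
        c = tx.candidate_species("q1", hits)
        assert c.taxon.species == "spB"  # longer alignment breaks the tie

    def test_exact_species_tie_promotes_to_genus(self):
        a = tx.Hit("q1", tx.Taxon("spA", "gX", "fX"), 99.0, 150, 10.0)
        b = tx.Hit("q1", tx.Taxon("spB", "gX", "fX"), 99.0, 150, 10.0)
        c = tx.candidate_species("q1", [a, b])
        assert c.rank == "genus" and c.taxon.genus == "gX"

    def test_cross_genus_tie_promotes_to_family(self):
        a = tx.Hit("q1", tx.Taxon("spA", "gX", "fX"), 99.0, 150, 10.0)
        b = tx.Hit("q1", tx.Taxon("spB", "gY", "fX"), 99.0, 150, 10.0)
        c = tx.candidate_species("q1", [a, b])
        assert c.rank == "family"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_tie_rule_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        hits = []
        for i in range(int(rng.integers(1, 12))):
            sp = f"sp{rng.integers(0, 4)}"
            g = "g" + sp[-1] if rng.random() < 0.7 else "gZ"
            hits.append(tx.Hit("q1", tx.Taxon(sp, g, "f0"),
                               float(rng.choice([97.0, 99.0])),
                               int(rng.choice([120, 150])), 0.0))
        c = tx.candidate_species("q1", hits)
        key = max((h.percent_identity, h.alignment_length, h.bitscore)
                  for h in hits)
        tied = {h.taxon for h in hits
                if (h.percent_identity, h.alignment_length,
                    h.bitscore) == key}
        if len({t.species for t in tied}) == 1:
            assert c.rank == "species"
        elif len({t.genus for t in tied}) == 1:
            assert c.rank == "genus"
        else:
            assert c.rank == "family"  # all share family f0 here


class TestGapAnalysis:
    def test_clean_gap_detected(self):
        # two taxa of two sequences; intra distances 0.01-level, inter 0.05
        refs = [ref("A" * 99 + "C", rid="a1", sp="sp1"),
                ref("A" * 100, rid="a2", sp="sp1"),
                ref("G" * 5 + "A" * 95, rid="b1", sp="sp2", g="g0"),
                ref("G" * 5 + "A" * 94 + "C", rid="b2", sp="sp2", g="g0")]
        g = tx.gap_analysis(refs, "sp1", "species")
        mx, mn, verdict = gap_stats(
            [(r.taxon.species, r.taxon.genus, r.taxon.family,
              r.aligned_sequence) for r in refs], "sp1", "species")
        assert (g.max_intra, g.min_inter, g.has_gap) == (mx, mn, True)

    def test_overlapping_clusters_have_no_gap(self):
        refs = [ref("C" * 6 + "A" * 94, rid="a1", sp="sp1"),
                ref("G" * 6 + "A" * 94, rid="a2", sp="sp1"),  # intra 0.06
                ref("C" * 4 + "A" * 96, rid="b1", sp="sp2", g="g0")]
        g = tx.gap_analysis(refs, "sp1", "species")
        # min_inter (a1 vs b1: 0.02) < max_intra (0.06): clusters overlap
        assert (g.max_intra, g.min_inter) == (0.06, 0.02)
        assert g.has_gap is False

    def test_equality_means_no_gap(self):
        refs = [ref("C" * 5 + "A" * 95, rid="a1", sp="sp1"),
                ref("G" * 5 + "A" * 95, rid="a2", sp="sp1"),
                ref("T" * 5 + "A" * 95 , rid="b1", sp="sp2", g="g0")]
        g = tx.gap_analysis(refs, "sp1", "species")
        assert g.max_intra == g.min_inter == 0.05
        assert g.has_gap is False

    def test_singleton_focal_group_is_undetermined(self):
        refs = [ref("A" * 100, rid="a1", sp="sp1"),
                ref("G" * 100, rid="b1", sp="sp2", g="g0")]
        g = tx.gap_analysis(refs, "sp1", "species")
        assert g.n_intra_pairs == 0 and g.has_gap is None

    def test_absent_focal_taxon_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            tx.gap_analysis([ref("ACGT")], "nope", "species")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_equals_exhaustive_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = random_library(rng, max_seqs=20)
        refs = [ref(s, rid=f"r{i}", sp=sp, g=g, f=f)
                for i, (sp, g, f, s) in enumerate(records)]
        for sp in sorted({r[0] for r in records}):
            g = tx.gap_analysis(refs, sp, "species")
            mx, mn, verdict = gap_stats(records, sp, "species")
            assert g.has_gap == verdict
            if g.n_intra_pairs:
                assert g.max_intra == mx
            if g.n_inter_pairs:
                assert g.min_inter == mn


class TestRankFallback:
    def mk_gaps(self, species_gap, genus_gap):
        return {
            ("spA", "species"): tx.GapResult("spA", "species", 0.01, 0.05,
                                             species_gap, 3, 9),
            ("gX", "genus"): tx.GapResult("gX", "genus", 0.02, 0.06,
                                          genus_gap, 3, 9),
        }

    def cand(self, rank="species"):
        return tx.Candidate("q1", rank, tx.Taxon("spA", "gX", "fX"))

    def test_species_gap_keeps_species_rank(self):
        a = tx.apply_rank_fallback(self.cand(), self.mk_gaps(True, True),
                                   "COI-5P")
        assert (a.assigned_rank, a.assigned_taxon) == ("species", "spA")

    def test_coi_without_species_gap_pulls_back_to_genus(self):
        a = tx.apply_rank_fallback(self.cand(), self.mk_gaps(False, True),
                                   "COI-5P")
        assert (a.assigned_rank, a.assigned_taxon) == ("genus", "gX")
        assert "no species-level barcode gap" in a.fallback_reason

    def test_rbcla_without_any_gap_pulls_back_to_family(self):
        a = tx.apply_rank_fallback(self.cand(), self.mk_gaps(False, False),
                                   "rbcLa")
        assert (a.assigned_rank, a.assigned_taxon) == ("family", "fX")

    def test_rbcla_with_genus_gap_stops_at_genus(self):
        a = tx.apply_rank_fallback(self.cand(), self.mk_gaps(False, True),
                                   "rbcLa")
        assert (a.assigned_rank, a.assigned_taxon) == ("genus", "gX")

    def test_missing_gap_result_flags_unassigned(self):
        a = tx.apply_rank_fallback(self.cand(), {}, "COI-5P")
        assert a.assigned_rank == "unassigned"
        assert "missing" in a.fallback_reason

    def test_family_rank_only_for_plants(self):
        a = tx.apply_rank_fallback(self.cand("family"),
                                   self.mk_gaps(True, True), "COI-5P")
        assert a.assigned_rank == "unassigned"
        b = tx.apply_rank_fallback(self.cand("family"),
                                   self.mk_gaps(True, True), "rbcLa")
        assert b.assigned_rank == "family"

    @pytest.mark.parametrize("marker", ["COI-5P", "rbcLa", "ITS2"])
    @pytest.mark.parametrize("cand_rank", ["species", "genus", "family"])
    @pytest.mark.parametrize("sg", [True, False, None])
    @pytest.mark.parametrize("gg", [True, False, None])
    def test_rank_never_more_specific_than_candidate(self, marker, cand_rank,
                                                     sg, gg):
        order = {"species": 0, "genus": 1, "family": 2, "unassigned": 3}
        a = tx.apply_rank_fallback(self.cand(cand_rank), self.mk_gaps(sg, gg),
                                   marker)
        assert order[a.assigned_rank] >= order[cand_rank]


def test_reference_fasta_roundtrip(tmp_path, clean_gap_library):
    path = tmp_path / "refs.fasta"
    tx.write_reference_fasta(clean_gap_library, path)
    back = tx.read_reference_fasta(path, "COI-5P")
    assert back == clean_gap_library


def test_hits_tsv_roundtrip(tmp_path):
    hits = [hit(97.123, 140, sp="spA", bits=88.0), hit(95.0, 100, sp="spB")]
    path = tmp_path / "hits.tsv"
    tx.write_hits_tsv(hits, path)
    back = tx.read_hits_tsv(path)
    assert [(h.query_id, h.taxon, h.alignment_length) for h in back] == \
        [(h.query_id, h.taxon, h.alignment_length) for h in hits]
    assert back[0].percent_identity == pytest.approx(97.123, abs=1e-3)


def test_kernel_agrees_with_oracle_on_gapped_alignment():
    a, b = "ACGTACGTAC", "ACGTCGTAC"  # forces a gap column
    assert smith_waterman(encode(a), encode(b)) == sw_align(a, b)
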