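"""Hit filtering, fractional best-hit assignment and profile comparison."""

import random

import pytest

from primerforge.taxo_assign import (
    AlignmentHit,
    TaxonomicProfile,
    assign_pair,
    assign_read,
    build_profile,
    compare_profiles,
    filter_hits,
    rank_abundance,
    read_hits,
    read_subject_metadata,
    write_hits,
    write_subject_metadata,
    SubjectMeta,
)


def _hit(query="q", subject="s", identity=99.0, alnlen=350, evalue=1e-50,
         bitscore=200.0, strand="+", phylum="P", genus="G", gene_class="SSU_rRNA"):
    return AlignmentHit(query, subject, identity, alnlen, evalue, bitscore,
                        strand, phylum, genus, gene_class)


class TestFilterHits:
    def test_evalue_threshold_is_strict(self):
        hits = [_hit(evalue=1e-8), _hit(evalue=0.9e-8)]
        kept = filter_hits(hits, max_evalue=1e-8, min_alnlen=0)
        assert len(kept) == 1 and kept[0].evalue == 0.9e-8

    def test_alignment_length_threshold_is_inclusive(self):
        hits = [_hit(alnlen=300), _hit(alnlen=299)]
        kept = filter_hits(hits, max_evalue=1.0, min_alnlen=300)
        assert len(kept) == 1 and kept[0].alnlen == 300

    def test_empty_input(self):
        assert filter_hits([], 1e-8, 100) == []


class TestHitIO:
    def test_round_trip_with_strand_inference(self, tmp_path):
        meta = {
            "s1": SubjectMeta("P1", "G1"),
            "s2": SubjectMeta("P2", "G2", gene_class="other"),
        }
        hits = [
            _hit(subject="s1", strand="+", phylum="P1", genus="G1"),
            _hit(subject="s2", strand="-", phylum="P2", genus="G2", gene_class="other"),
        ]
        write_subject_metadata(meta, tmp_path / "subj.tsv")
        write_hits(hits, tmp_path / "hits.tsv")
        back_meta = read_subject_metadata(tmp_path / "subj.tsv")
        back, malformed = read_hits(tmp_path / "hits.tsv", back_meta)
        assert malformed == 0
        assert [h.strand for h in back] == ["+", "-"]
        assert back[1].gene_class == "other"
        assert back[0].genus == "G1"

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        lines = [
            "q\ts\t99.0\t350\t0\t0\t1\t350\t1\t350\t1e-50\t200.0",
            "q\ts\tnot_a_number\t350\t0\t0\t1\t350\t1\t350\t1e-50\t200.0",
            "too\tfew\tcolumns",
        ]
        (tmp_path / "hits.tsv").write_text("\n".join(lines) + "\n")
        hits, malformed = read_hits(tmp_path / "hits.tsv")
        assert len(hits) == 1 and malformed == 2


class TestAssignRead:
    def test_tied_best_hits_split_evenly(self):
        hits = [
            _hit(bitscore=100, genus="g1"),
            _hit(bitscore=100, genus="g2"),
            _hit(bitscore=90, genus="g3"),
        ]
        assignment = assign_read(hits)
        assert assignment.genus == {"g1": 0.5, "g2": 0.5}

    def test_single_hit_contributes_unit(self):
        assert assign_read([_hit(genus="g1")]).genus == {"g1": 1.0}

    def test_tied_hits_in_same_taxon_accumulate(self):
        hits = [_hit(bitscore=100, genus="g1", subject="a"),
                _hit(bitscore=100, genus="g1", subject="b")]
        assert assign_read(hits).genus == {"g1": 1.0}

    def test_identity_tiers_evaluated_independently(self):
        assignment = assign_read([_hit(identity=90.0, genus="g1", phylum="P1")])
        assert assignment.genus == {} and assignment.phylum == {"P1": 1.0}

    def test_no_qualifying_hits_unassigned(self):
        assignment = assign_read([_hit(identity=80.0)])
        assert assignment.genus == {} and assignment.phylum == {}

    def test_genus_assigned_implies_phylum_assigned(self):
        rng = random.Random(31)
        for _ in range(200):
            hits = [
                _hit(
                    identity=rng.uniform(80, 100),
                    bitscore=rng.choice([100.0, 150.0, 200.0]),
                    genus=f"g{rng.randrange(4)}",
                    phylum=f"P{rng.randrange(3)}",
                )
                for _ in range(rng.randint(1, 6))
            ]
            a = assign_read(hits)
            for fractions in (a.genus, a.phylum):
                assert sum(fractions.values()) in (0.0, pytest.approx(1.0))
            if a.genus:
                assert a.phylum  # identity >= 94 implies >= 85


class TestAssignPair:
    def test_same_taxon_opposite_strands_contributes_one_unit(self):
        h1 = [_hit(strand="+", genus="g1")]
        h2 = [_hit(strand="-", genus="g1")]
        assert assign_pair(h1, h2) == {"g1": 1.0}

    def test_different_taxa_discarded(self):
        assert assign_pair([_hit(genus="g1", strand="+")],
                           [_hit(genus="g2", strand="-")]) == {}

    def test_same_strand_discarded_by_default_but_configurable(self):
        h1 = [_hit(strand="+", genus="g1")]
        h2 = [_hit(strand="+", genus="g1")]
        assert assign_pair(h1, h2) == {}
        assert assign_pair(h1, h2, require_opposite_strands=False) == {"g1": 1.0}

    def test_non_ssu_best_hit_disqualifies(self):
        h1 = [_hit(strand="+", genus="g1", gene_class="other")]
        h2 = [_hit(strand="-", genus="g1")]
        assert assign_pair(h1, h2) == {}

    def test_ambiguous_mate_call_discards_pair(self):
        h1 = [_hit(strand="+", genus="g1", bitscore=100),
              _hit(strand="+", genus="g2", bitscore=100)]
        h2 = [_hit(strand="-", genus="g1")]
        assert assign_pair(h1, h2) == {}

    def test_phylum_rank_pairing(self):
        h1 = [_hit(strand="+", identity=88.0, phylum="P1")]
        h2 = [_hit(strand="-", identity=88.0, phylum="P1")]
        assert assign_pair(h1, h2, rank="phylum") == {"P1": 1.0}


class TestProfiles:
    def test_build_profile_sums_fractions(self):
        profile = build_profile([{"g1": 1.0}, {"g1": 1.0}], "genus")
        assert profile.abundances == {"g1": 2.0} and profile.assigned_total == 2.0

    def test_split_reads_additive(self):
        profile = build_profile([{"g1": 0.5, "g2": 0.5}, {"g1": 1.0}], "genus")
        assert profile.abundances == {"g1": 1.5, "g2": 0.5}

    def test_empty_assignments_give_empty_profile(self):
        profile = build_profile([{}, {}], "genus")
        assert profile.abundances == {} and profile.assigned_total == 0.0
        assert profile.input_read_count == 2

    def test_profile_additivity_under_union(self):
        rng = random.Random(19)
        batches = [
            [
                {f"g{rng.randrange(5)}": 0.5, f"h{rng.randrange(5)}": 0.5}
                for _ in range(30)
            ]
            for _ in range(2)
        ]
        separate = [build_profile(b, "genus") for b in batches]
        union = build_profile(batches[0] + batches[1], "genus")
        for taxon in union.abundances:
            assert union.abundances[taxon] == pytest.approx(
                sum(p.abundances.get(taxon, 0.0) for p in separate)
            )


class TestCompareProfiles:
    def _profile(self, values, rank="phylum"):
        return TaxonomicProfile(rank=rank, abundances=dict(values))

    def test_identical_profiles_give_one(self):
        p = self._profile({"a": 5.0, "b": 3.0, "c": 1.0})
        assert compare_profiles(p, p) == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        p1 = self._profile({t: float(i + 1) for i, t in enumerate("abcde")})
        p2 = self._profile({t: float(5 - i) for i, t in enumerate("abcde")})
        assert compare_profiles(p1, p2) == pytest.approx(-1.0)

    def test_single_swap_worked_example(self):
        # ranks (1,2,3,4) vs (2,1,3,4): rho = 1 - 6*2/(4*15) = 0.8
        p1 = self._profile({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        p2 = self._profile({"a": 2.0, "b": 1.0, "c": 3.0, "d": 4.0})
        assert compare_profiles(p1, p2) == pytest.approx(0.8)

    def test_symmetry_and_scale_invariance(self):
        p1 = self._profile({"a": 3.0, "b": 9.0, "c": 1.0, "d": 5.0})
        p2 = self._profile({"a": 2.0, "b": 4.0, "c": 8.0, "d": 1.0})
        scaled = self._profile({t: 7.5 * v for t, v in p2.abundances.items()})
        assert compare_profiles(p1, p2) == pytest.approx(compare_profiles(p2, p1))
        assert compare_profiles(p1, scaled) == pytest.approx(compare_profiles(p1, p2))

    def test_missing_taxa_count_as_zero(self):
        p1 = self._profile({"a": 3.0, "b": 2.0, "c": 1.0})
        p2 = self._profile({"a": 3.0, "b": 2.0})
        rho = compare_profiles(p1, p2)
        assert -1.0 <= rho <= 1.0

    def test_fewer_than_three_taxa_raises(self):
        p = self._profile({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            compare_profiles(p, p)

    def test_mismatched_ranks_raise(self):
        with pytest.raises(ValueError):
            compare_profiles(self._profile({}, "genus"), self._profile({}, "phylum"))


class TestRankAbundance:
    def _profile(self, values):
        return TaxonomicProfile(rank="phylum", abundances=dict(values))

    def test_simple_ordering(self):
        ranked = rank_abundance(self._profile({"a": 3.0, "b": 2.0, "c": 1.0}))
        assert [(t, r) for t, _, r in ranked] == [("a", 1), ("b", 2), ("c", 3)]

    def test_competition_ranking_skips_after_tie(self):
        ranked = rank_abundance(self._profile({"a": 2.0, "b": 2.0, "c": 1.0}))
        assert [(t, r) for t, _, r in ranked] == [("a", 1), ("b", 1), ("c", 3)]

    def test_top_n_truncation(self):
        ranked = rank_abundance(self._profile({"a": 3.0, "b": 2.0, "c": 1.0}), top_n=1)
        assert ranked == [("a", 3.0, 1)]

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            rank_abundance(self._profile({}))
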