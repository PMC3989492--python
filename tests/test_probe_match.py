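"""Mismatch-tolerant primer matching, coverage metrics and eukaryote exclusion."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from primerforge.probe_match import (
    coverage_matrix,
    eukaryote_exclusion_filter,
    filter_by_position,
    genus_coverage,
    min_mismatch,
    sequence_coverage,
)
from primerforge.primer_design import PrimerCandidate
from primerforge.seqio import reverse_complement

from conftest import make_record


def naive_min_mismatch(primer, template):
    """All-offsets brute force oracle."""
    k = len(primer)
    if k > len(template):
        return None
    return min(
        sum(1 for a, b in zip(primer, template[i : i + k]) if a != b)
        for i in range(len(template) - k + 1)
    )


class TestMinMismatch:
    def test_exact_site_is_zero(self):
        assert min_mismatch("ACGTACGT", "TTTACGTACGTTT") == 0

    def test_single_substitution_at_best_offset(self):
        primer = "ACGTACGTACGTACGT"
        template = "GG" + "ACGTACGTACGAACGT" + "GG"
        assert min_mismatch(primer, template) == 1

    def test_reverse_orientation_matches_reverse_complement_site(self):
        primer = "ACCGGTTACGTAC"
        template = "TTT" + reverse_complement(primer) + "AAA"
        assert min_mismatch(primer, template, "reverse") == 0
        assert min_mismatch(primer, template, "forward") > 0

    def test_primer_longer_than_template_is_no_site(self):
        assert min_mismatch("ACGTACGT", "ACG") is None

    def test_degenerate_primer_rejected(self):
        with pytest.raises(ValueError):
            min_mismatch("ACNT", "ACGTACGT")

    def test_matches_bruteforce_oracle_on_random_strings(self):
        rng = random.Random(99)
        for _ in range(400):
            k = rng.randint(3, 20)
            n = rng.randint(k, 200)
            primer = "".join(rng.choice("ACGT") for _ in range(k))
            template = "".join(rng.choice("ACGT") for _ in range(n))
            assert min_mismatch(primer, template) == naive_min_mismatch(primer, template)

    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=12),
        st.text(alphabet="ACGT", min_size=12, max_size=60),
    )
    @settings(max_examples=150, derandomize=True)
    def test_reverse_complement_with_swapped_orientation_is_identical(self, primer, template):
        assert min_mismatch(primer, template, "forward") == min_mismatch(
            reverse_complement(primer), template, "reverse"
        )


class TestSequenceCoverage:
    def _records(self):
        primer = "ACGTACGTACGT"
        seqs = [
            "TT" + primer + "TT",                     # 0 mm
            "TT" + "ACGTACGTACGA" + "TT",             # 1 mm
            "TT" + "ACGAACGTACGA" + "TT",             # 2 mm
            "TT" + "TCGAACGTACGA" + "TT",             # 3 mm
        ]
        return primer, [
            make_record(s, rec_id=f"r{i}", origin="eukaryote") for i, s in enumerate(seqs)
        ]

    def test_verbatim_everywhere_is_100(self):
        primer, records = self._records()
        table = sequence_coverage(primer, records[:1], max_mm=0)
        assert table.percent == {"eukaryote": 100.0}

    def test_three_of_four_within_two_mismatches(self):
        primer, records = self._records()
        table = sequence_coverage(primer, records, max_mm=2)
        assert table.percent["eukaryote"] == 75.0
        assert table.counts["eukaryote"] == (3, 4)

    def test_all_sites_three_or_more_mismatches_is_zero(self):
        primer, records = self._records()
        table = sequence_coverage(primer, records[3:], max_mm=2)
        assert table.percent["eukaryote"] == 0.0

    def test_monotonic_in_mismatch_allowance(self):
        primer, records = self._records()
        series = [
            sequence_coverage(primer, records, mm).percent["eukaryote"]
            for mm in (0, 1, 2, 3)
        ]
        assert series == sorted(series)


class TestGenusCoverage:
    def _records(self, primer):
        # phylum P: genus A has 2/3 matching members, genus B 1/2
        rows = [
            ("A", "TT" + primer),
            ("A", primer + "GG"),
            ("A", "TTTTTTTTTTTTTTTTTT"),
            ("B", primer),
            ("B", "GGGGGGGGGGGGGGGGGG"),
        ]
        return [
            make_record(seq, rec_id=f"r{i}", phylum="P", genus=genus)
            for i, (genus, seq) in enumerate(rows)
        ]

    def test_strict_majority_rule(self):
        primer = "ACGTACGTACGTACG"
        table = genus_coverage(primer, self._records(primer), max_mm=1)
        # genus A: 2/3 matched (majority); genus B: 1/2 (exactly half, not majority)
        assert table.percent == {"P": 50.0}

    def test_all_exact_matches_is_100_everywhere(self):
        primer = "ACGTACGTACGTACG"
        records = [
            make_record("T" + primer, rec_id=f"{p}{g}", phylum=p, genus=f"{p}{g}")
            for p in ("P1", "P2")
            for g in range(3)
        ]
        table = genus_coverage(primer, records)
        assert table.percent == {"P1": 100.0, "P2": 100.0}

    def test_no_matches_is_zero(self):
        records = [
            make_record("T" * 20, rec_id="x", phylum="P", genus="G"),
        ]
        assert genus_coverage("ACGTACGTACGTACG", records).percent == {"P": 0.0}

    def test_invariant_under_duplicating_matching_member(self):
        primer = "ACGTACGTACGTACG"
        records = self._records(primer)
        before = genus_coverage(primer, records).percent
        clone = make_record("TT" + primer, rec_id="dup", phylum="P", genus="A")
        after = genus_coverage(primer, records + [clone]).percent
        assert before == after

    def test_monotonic_in_mismatch_allowance(self):
        rng = random.Random(5)
        primer = "ACGTACGTACGTACG"
        records = [
            make_record(
                "".join(rng.choice("ACGT") for _ in range(60)),
                rec_id=f"r{i}",
                phylum=f"P{i % 3}",
                genus=f"G{i % 9}",
            )
            for i in range(27)
        ]
        for phylum in ("P0", "P1", "P2"):
            series = [
                genus_coverage(primer, records, mm).percent[phylum] for mm in (0, 2, 4, 6)
            ]
            assert series == sorted(series)


class TestExclusionFilter:
    def _candidate(self, seq="ACGTACGTACGTACG"):
        return PrimerCandidate(seq, ref_start=100, ref_end=99 + len(seq))

    def _group(self, primer, n_match, n_total, origin):
        records = []
        for i in range(n_total):
            seq = ("TT" + primer + "TT") if i < n_match else "T" * (len(primer) + 4)
            records.append(make_record(seq, rec_id=f"{origin}{i}", origin=origin))
        return records

    def test_over_half_eukaryote_coverage_excluded(self):
        cand = self._candidate()
        euk = self._group(cand.sequence, 3, 5, "eukaryote")  # 60%
        kept, excluded = eukaryote_exclusion_filter([cand], [], euk)
        assert kept == [] and len(excluded) == 1

    def test_zero_coverage_kept(self):
        cand = self._candidate()
        euk = self._group(cand.sequence, 0, 5, "eukaryote")
        mito = self._group(cand.sequence, 0, 5, "mitochondrion")
        kept, excluded = eukaryote_exclusion_filter([cand], mito, euk)
        assert kept == [cand] and excluded == []

    def test_exactly_half_is_kept(self):
        cand = self._candidate()
        euk = self._group(cand.sequence, 2, 4, "eukaryote")  # exactly 50%
        kept, _ = eukaryote_exclusion_filter([cand], [], euk)
        assert kept == [cand]

    def test_mitochondrial_coverage_alone_excludes(self):
        cand = self._candidate()
        mito = self._group(cand.sequence, 4, 5, "mitochondrion")
        kept, excluded = eukaryote_exclusion_filter([cand], mito, [])
        assert kept == [] and "mitochondrion" in excluded[0][1]


class TestCoverageMatrix:
    def test_planted_primer_row(self):
        primer = "ACGTTGCAACGTACG"
        prok = [
            make_record("AA" + primer + "AA", rec_id=f"p{i}", phylum=f"P{i % 2}", genus=f"G{i}")
            for i in range(4)
        ]
        euk = [make_record("T" * 40, rec_id=f"e{i}", origin="eukaryote") for i in range(3)]
        matrix = coverage_matrix(
            [("cand", primer, "forward")], prok, {"eukaryote": euk}
        )
        row = matrix.loc["cand"]
        assert row["P0"] == 100.0 and row["P1"] == 100.0 and row["eukaryote"] == 0.0

    def test_empty_primer_list_gives_empty_matrix(self):
        assert coverage_matrix([], [], {}).empty

    def test_invariant_under_record_shuffling(self):
        rng = random.Random(13)
        primer = "ACGTTGCAACGTACG"
        records = [
            make_record(
                "".join(rng.choice("ACGT") for _ in range(50)),
                rec_id=f"r{i}",
                phylum=f"P{i % 2}",
                genus=f"G{i % 4}",
            )
            for i in range(12)
        ]
        shuffled = records[:]
        rng.shuffle(shuffled)
        a = coverage_matrix([("c", primer, "forward")], records, {})
        b = coverage_matrix([("c", primer, "forward")], shuffled, {})
        assert a.equals(b)


def test_position_filter_keeps_interval_inclusive():
    candidates = [
        PrimerCandidate("ACGTACGTACGTACG", start, start + 14)
        for start in (29, 30, 600, 1200, 1201)
    ]
    kept = filter_by_position(candidates)
    assert [c.ref_start for c in kept] == [30, 600, 1200]
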