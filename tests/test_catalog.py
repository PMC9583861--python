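"""Catalog semantics: nomenclature, shift arithmetic, seeds, merged seeds."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirnet.catalog import (
    AdjacentPair,
    AnnotationError,
    IsomirNameError,
    build_isomir,
    compute_5p_shift,
    dedup_merged_seeds,
    derive_isomir_sequence,
    enumerate_adjacent_pairs,
    format_isomir_name,
    merge_seed_regions,
    merge_seeds,
    parse_isomir_name,
    seed6,
    uracil_start_test,
)

# published isomiR names with every shift rendering the nomenclature allows
PRINTED_NAMES = [
    ("hsa-miR-192-5p—+1", "hsa-miR-192-5p", 1),
    ("hsa-miR-203a-3p—0", "hsa-miR-203a-3p", 0),
    ("hsa-miR-514a-3p—-3", "hsa-miR-514a-3p", -3),
    ("hsa-miR-101-3p—-1", "hsa-miR-101-3p", -1),
    ("hsa-miR-9-5p—+2", "hsa-miR-9-5p", 2),
    ("hsa-miR-30e-5p—+1", "hsa-miR-30e-5p", 1),
    ("hsa-miR-142-3p—+1", "hsa-miR-142-3p", 1),
    ("hsa-miR-302a-5p—+3", "hsa-miR-302a-5p", 3),
    ("hsa-miR-519a-5p—-1", "hsa-miR-519a-5p", -1),
]


class TestNomenclature:
    @pytest.mark.parametrize("name,mature,shift", PRINTED_NAMES)
    def test_parse_printed_names(self, name, mature, shift):
        assert parse_isomir_name(name) == (mature, shift)

    @pytest.mark.parametrize("name,mature,shift", PRINTED_NAMES)
    def test_roundtrip(self, name, mature, shift):
        assert format_isomir_name(*parse_isomir_name(name)) == name
        assert parse_isomir_name(format_isomir_name(mature, shift)) == (mature, shift)

    def test_format_rules(self):
        assert format_isomir_name("hsa-miR-101-3p", -1) == "hsa-miR-101-3p—-1"
        assert format_isomir_name("x", 0) == "x—0"
        assert format_isomir_name("x", 2) == "x—+2"

    def test_ascii_fallback_accepted_emdash_emitted(self):
        assert parse_isomir_name("hsa-miR-192-5p--+1") == ("hsa-miR-192-5p", 1)
        assert parse_isomir_name("hsa-miR-514a-3p---3") == ("hsa-miR-514a-3p", -3)
        assert format_isomir_name("hsa-miR-192-5p", 1) == "hsa-miR-192-5p—+1"

    @pytest.mark.parametrize(
        "bad", ["hsa-miR-21-5p", "hsa—miR—21", "hsa-miR-21—x", "—1", ""]
    )
    def test_malformed_names_raise(self, bad):
        with pytest.raises(IsomirNameError):
            parse_isomir_name(bad)

    def test_empty_mature_id_rejected(self):
        with pytest.raises(IsomirNameError):
            format_isomir_name("", 0)

    @given(shift=st.integers(-9, 9))
    @settings(derandomize=True, max_examples=25)
    def test_roundtrip_property(self, shift):
        name = format_isomir_name("hsa-miR-9-5p", shift)
        assert parse_isomir_name(name) == ("hsa-miR-9-5p", shift)


class TestShiftArithmetic:
    def test_plus_strand_shifts(self):
        mature = ("chr1", 1005, 1026)
        assert compute_5p_shift(("chr1", 1005, 1026), mature, "+") == 0
        assert compute_5p_shift(("chr1", 1006, 1026), mature, "+") == 1
        assert compute_5p_shift(("chr1", 1004, 1026), mature, "+") == -1

    def test_minus_strand_plus_one_drops_first_nucleotide(self, minus_hairpin):
        """On the minus strand a +1 shift means the genomic *end* moves down
        by one, and the derived sequence loses its first 5' base."""
        hp, mature = minus_hairpin
        g_end_5p = hp.end - mature.start + 1  # genomic coordinate of the mature 5' end
        g_start_3p = hp.end - mature.end + 1
        shift = compute_5p_shift(
            (hp.chrom, g_start_3p, g_end_5p - 1), (hp.chrom, g_start_3p, g_end_5p), "-"
        )
        assert shift == 1
        canonical = derive_isomir_sequence(hp, mature, 0)
        shifted = derive_isomir_sequence(hp, mature, 1)
        assert shifted == canonical[1:]

    def test_chromosome_mismatch(self):
        with pytest.raises(AnnotationError):
            compute_5p_shift(("chr1", 5, 10), ("chr2", 5, 10), "+")


class TestDeriveSequence:
    def test_canonical_slice(self, plus_hairpin):
        hp, mature = plus_hairpin
        assert derive_isomir_sequence(hp, mature, 0) == hp.sequence[4:26]

    def test_plus_one_with_length(self, plus_hairpin):
        hp, mature = plus_hairpin
        assert derive_isomir_sequence(hp, mature, 1, length=21) == hp.sequence[5:26]

    def test_minus_one_gains_5p_nucleotide(self, plus_hairpin):
        hp, mature = plus_hairpin
        seq = derive_isomir_sequence(hp, mature, -1, length=23)
        assert seq == hp.sequence[3:26]
        assert seq[1:] == derive_isomir_sequence(hp, mature, 0)

    def test_consecutive_shifts_drop_one_base(self, plus_hairpin):
        hp, mature = plus_hairpin
        for k in (-1, 0, 1):
            longer = derive_isomir_sequence(hp, mature, k)
            shorter = derive_isomir_sequence(hp, mature, k + 1)
            assert longer[1:] == shorter

    def test_window_out_of_bounds(self, plus_hairpin):
        hp, mature = plus_hairpin
        with pytest.raises(AnnotationError):
            derive_isomir_sequence(hp, mature, -10)
        with pytest.raises(AnnotationError):
            derive_isomir_sequence(hp, mature, 0, length=100)


class TestSeeds:
    def test_positions_2_to_7(self):
        assert seed6("UAGCUUAUCAG") == "AGCUUA"

    def test_too_short(self):
        with pytest.raises(AnnotationError):
            seed6("ACGUAC")

    def test_adjacent_seed_offset(self, plus_hairpin):
        """seed6 of the +1 isomiR equals positions 3-8 of the canonical one."""
        hp, mature = plus_hairpin
        a = build_isomir(hp, mature, 0)
        b = build_isomir(hp, mature, 1)
        assert b.seed6 == a.sequence[2:8]


class TestAdjacentPairs:
    def test_run_of_three_shifts(self, toy_isomirs):
        pairs = enumerate_adjacent_pairs([toy_isomirs[s] for s in (-1, 0, 1)])
        assert [(p.isomir_a.shift5, p.isomir_b.shift5) for p in pairs] == [(-1, 0), (0, 1)]

    def test_gap_of_two(self, toy_isomirs):
        assert enumerate_adjacent_pairs([toy_isomirs[0], toy_isomirs[2]]) == []

    def test_pairs_never_cross_matures(self, toy_isomirs, minus_hairpin):
        hp, mature = minus_hairpin
        other = build_isomir(hp, mature, 1)
        pairs = enumerate_adjacent_pairs([toy_isomirs[0], other])
        assert pairs == []

    def test_merged_seed_prefix_and_length(self, toy_isomirs):
        for pair in enumerate_adjacent_pairs(list(toy_isomirs.values())):
            merged = merge_seed_regions(pair)
            assert len(merged) == 7
            assert merged.startswith(pair.isomir_a.seed6)


class TestMergedSeeds:
    def test_overlap_merge(self):
        assert merge_seeds("UCGAAC", "CGAACU") == "UCGAACU"

    def test_homopolymer(self):
        assert merge_seeds("AAAAAA", "AAAAAA") == "AAAAAAA"

    def test_inconsistent_overlap(self):
        with pytest.raises(AnnotationError):
            merge_seeds("UCGAAC", "GGGGGG")

    def _pair(self, hp, mature, lo):
        return AdjacentPair(build_isomir(hp, mature, lo), build_isomir(hp, mature, lo + 1))

    def test_dedup_keeps_highest_score(self, plus_hairpin):
        hp, mature = plus_hairpin
        p = self._pair(hp, mature, 0)
        kept = dedup_merged_seeds([(p, 0.1), (p, 0.3)])
        assert kept == [(p, 0.3)]

    def test_dedup_identity_on_distinct_seeds(self, plus_hairpin):
        hp, mature = plus_hairpin
        entries = [(self._pair(hp, mature, -1), 0.2), (self._pair(hp, mature, 0), 0.1)]
        assert dedup_merged_seeds(entries) == entries

    def test_paralog_style_duplicates_collapse(self, plus_hairpin, minus_hairpin):
        # two arms yielding the same merged 7-mer (as paralogous families do)
        hp, mature = plus_hairpin
        p1 = self._pair(hp, mature, 0)
        import dataclasses

        twin_a = dataclasses.replace(p1.isomir_a, mature_id="toy-miR-1b-5p")
        twin_b = dataclasses.replace(p1.isomir_b, mature_id="toy-miR-1b-5p")
        p2 = AdjacentPair(twin_a, twin_b)
        kept = dedup_merged_seeds([(p1, 0.5), (p2, 0.2)])
        assert kept == [(p1, 0.5)]


class TestUracilStartTest:
    def test_observed_equals_expected(self):
        stat, p = uracil_start_test(25, 100, 0.25)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_forty_nine_of_fifty(self):
        """Closed-form (O-E)^2/E over both cells: 36.5^2/12.5 + 36.5^2/37.5."""
        stat, p = uracil_start_test(49, 50, 0.25)
        assert stat == pytest.approx(142.11, abs=5e-3)
        from scipy.stats import chi2

        assert p == pytest.approx(float(chi2.sf(stat, df=1)), rel=1e-12)

    @pytest.mark.parametrize("n_u,n,f", [(10, 40, 0.25), (3, 17, 0.4), (0, 9, 0.1)])
    def test_cell_swap_invariance(self, n_u, n, f):
        stat_a, p_a = uracil_start_test(n_u, n, f)
        stat_b, p_b = uracil_start_test(n - n_u, n, 1.0 - f)
        assert stat_a == pytest.approx(stat_b, rel=1e-12)
        assert p_a == pytest.approx(p_b, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            uracil_start_test(0, 0, 0.25)
        with pytest.raises(ValueError):
            uracil_start_test(5, 4, 0.25)
        with pytest.raises(ValueError):
            uracil_start_test(1, 4, 1.0)
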