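"""Alignment, variant calling, tallying and the rarity screen."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mthia.census import (AlignedPair, AlignmentScoring, COMMON,
                          EXTREMELY_RARE, InputError, REVIEW, VariantCensus,
                          align_to_reference, call_variants, rarity_screen,
                          tally)
from mthia.nomenclature import format_variant, parse_variant

SCORING = AlignmentScoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)


def brute_force_score(a: str, b: str, scoring: AlignmentScoring = SCORING
                      ) -> float:
    """Best global-alignment score by exhaustive path enumeration (no DP).

    Recursion over (i, j, previous op) so affine gap costs apply: the first
    base of a gap run costs ``gap_open``, later bases ``gap_extend``.
    """
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            best = max(best, s + rec(i + 1, j + 1, "m"))
        if i < len(a):
            g = scoring.gap_extend if prev == "d" else scoring.gap_open
            best = max(best, g + rec(i + 1, j, "d"))
        if j < len(b):
            g = scoring.gap_extend if prev == "i" else scoring.gap_open
            best = max(best, g + rec(i, j + 1, "i"))
        return best

    return rec(0, 0, None)


class TestAlignment:
    def test_identity_alignment_has_no_gaps_or_mismatches(self):
        ref = "ACGTACGTAC"
        pair = align_to_reference(ref, ref)
        assert pair.reference_row == pair.sample_row == ref
        assert pair.score == len(ref)
        assert call_variants(pair) == []

    def test_single_substitution(self):
        # 3 matches + 1 mismatch beats any gapped alternative: score 2
        pair = align_to_reference("AGGT", "ACGT")
        assert pair.score == 2
        calls = call_variants(pair)
        assert [format_variant(c) for c in calls] == ["m.2C>G"]

    def test_single_deletion(self):
        pair = align_to_reference("ACT", "ACGT", length_tolerance=None)
        assert pair.score == 1  # 3 matches + one opened gap
        calls = call_variants(pair)
        assert len(calls) == 1 and calls[0].kind == "deletion"
        assert calls[0].position == 3

    def test_empty_and_invalid_sequences_rejected(self):
        with pytest.raises(InputError):
            align_to_reference("", "ACGT")
        with pytest.raises(InputError):
            align_to_reference("ACXT", "ACGT")

    def test_length_tolerance_enforced(self):
        with pytest.raises(InputError):
            align_to_reference("ACGT" * 3, "ACGT" * 4)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(a=st.text(alphabet="ACGT", min_size=1, max_size=6),
           b=st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_score_matches_brute_force_enumeration(self, a, b):
        pair = align_to_reference(b, a, length_tolerance=None)
        assert pair.score == brute_force_score(a, b)


class TestCalling:
    def test_substitution_at_known_site(self):
        # reference A at m.1553 replaced by G in the sample
        ref = "ACGT" * 500  # length 2000, the 12S window covered
        assert ref[1552] == "A"
        sample = ref[:1552] + "G" + ref[1553:]
        calls = call_variants(align_to_reference(sample, ref))
        assert [format_variant(c) for c in calls] == ["m.1553A>G"]

    def test_homopolymer_insertion_reported_with_run_length(self):
        pair = AlignedPair("ACGT-----ACGT", "ACGTCCCCCACGT")
        calls = call_variants(pair)
        assert [format_variant(c) for c in calls] == ["m.4InsC(5)"]

    def test_mixed_base_insertion_reported_base_by_base(self):
        pair = AlignedPair("ACGT---ACGT", "ACGTCACACGT")
        calls = call_variants(pair)
        assert [format_variant(c) for c in calls] == \
            ["m.4InsC", "m.4InsA", "m.4InsC"]

    def test_sample_n_never_yields_a_call(self):
        pair = AlignedPair("ACGTACGT", "ACNTACNT")
        assert call_variants(pair) == []

    def test_padding_shifts_but_preserves_calls(self):
        ref, smp = "ACGTACGTAC", "ACGTACATAC"
        base = call_variants(align_to_reference(smp, ref))
        pad = "GGGG"
        padded = call_variants(align_to_reference(pad + smp + pad,
                                                  pad + ref + pad))
        assert [(c.position - len(pad), c.ref_base, c.alt_base)
                for c in padded] == \
            [(c.position, c.ref_base, c.alt_base) for c in base]


class TestTally:
    def test_empty_collection(self):
        census = tally([])
        assert census.counts == {} and census.n_sequences == 0

    def test_counts_are_per_sample(self):
        v = parse_variant("m.1555A>G")
        calls = [[v]] * 3 + [[]] * 7
        census = tally(calls)
        assert census.count("m.1555A>G") == 3
        assert census.n_sequences == 10

    def test_mixed_coordinate_systems_rejected(self):
        with pytest.raises(InputError):
            tally([[parse_variant("m.1555A>G")], [parse_variant("908A>G")]])

    def test_site_totals_aggregate_variant_types(self):
        a = parse_variant("m.961T>A")
        d = parse_variant("m.961delT")
        census = tally([[a], [d], [a]])
        assert census.site_totals[961] == 3
        assert sum(census.site_totals.values()) == census.total_variations

    def test_census_conservation_invariant(self):
        # site total equals the sum over variants at that site, every site
        import numpy as np
        rng = np.random.default_rng(11)
        variants = [parse_variant(f"m.{p}A>G")
                    for p in rng.choice(range(700, 1600), 20, replace=False)]
        calls = [[v for v in variants if rng.random() < 0.3]
                 for _ in range(50)]
        census = tally(calls)
        per_site = {}
        for v, c in census.counts.items():
            per_site[v.position] = per_site.get(v.position, 0) + c
        assert per_site == census.site_totals


class TestRarityScreen:
    def make_census(self, counts):
        return VariantCensus(
            counts={parse_variant(k): v for k, v in counts.items()},
            n_sequences=1000)

    def test_labels_by_combined_count(self):
        primary = self.make_census({"m.1555A>G": 25, "m.1494C>T": 2})
        secondary = self.make_census({"m.1555A>G": 4, "m.1494C>T": 1})
        report = rarity_screen(primary, secondary,
                               variants=["m.1555A>G", "m.1494C>T", "m.902G>A"])
        assert report["m.1555A>G"] == COMMON        # 29 appearances
        assert report["m.1494C>T"] == REVIEW        # 3 appearances
        assert report["m.902G>A"] == EXTREMELY_RARE  # never seen

    def test_threshold_boundary_inclusive(self):
        census = self.make_census({"m.902G>A": 15, "m.879T>C": 16})
        report = rarity_screen(census)
        assert report["m.879T>C"] == COMMON
        assert report["m.902G>A"] == REVIEW
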