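"""C_v bin assignment and per-bin distribution statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from mthia.binning import (BIN_HIGH, BIN_LOW, BIN_MID, BIN_NEG,
                           BIN_NOT_ALIGNED, BIN_TOP, BinningError,
                           ConservationEntry, ConservationTable,
                           assign_bin, bin_statistics, derive_bin_statistics,
                           load_packaged_bin_counts, normalize_count,
                           raw_counts_from_census, round_half_up)
from mthia.census import VariantCensus
from mthia.nomenclature import parse_variant
from mthia.synthetic import generate_conservation


@pytest.mark.parametrize("cv,expected", [
    (2.0, BIN_TOP), (1.95, BIN_TOP), (1.9, BIN_TOP),   # lower bound inclusive
    (1.89, BIN_HIGH), (1.5, BIN_HIGH),
    (1.49, BIN_MID), (1.0, BIN_MID),
    (0.99, BIN_LOW), (0.0, BIN_LOW),
    (-0.01, BIN_NEG), (-1.0, BIN_NEG),
])
def test_bin_assignment_half_open_intervals(cv, expected):
    entry = ConservationEntry(position=1, cv=cv, crw_letter="o")
    assert assign_bin(entry) == expected


def test_not_aligned_entries_get_their_own_bin():
    entry = ConservationEntry(position=1, aligned=False)
    assert assign_bin(entry) == BIN_NOT_ALIGNED


@pytest.mark.parametrize("count,size,ref,expected", [
    (31, 150, 277, 57.25),
    (85, 161, 277, 146.24),
    (73, 277, 277, 73.00),
])
def test_normalize_count_published_values(count, size, ref, expected):
    assert normalize_count(count, size, ref) == expected


def test_normalization_identity_and_zero_size():
    for c in (0, 1, 7, 333):
        for b in (1, 13, 277):
            assert normalize_count(c, b, b) == float(c)
    with pytest.raises(BinningError):
        normalize_count(1, 0, 277)


@pytest.fixture(scope="module")
def stats():
    return derive_bin_statistics(load_packaged_bin_counts())


class TestPackagedCounts:
    """Derived statistics recomputed from the packaged raw bin counts."""

    def test_percent_variant_sites_most_conserved_bin(self, stats):
        assert stats[BIN_TOP].pct_sites_in_bin == 3.48  # 4 of 115 sites

    def test_variations_per_site_most_conserved_bins(self, stats):
        assert stats[BIN_TOP].variations_per_site == 2.90
        assert stats[BIN_HIGH].variations_per_site == 1.05

    def test_outlier_exclusion_rate(self, stats):
        # removing the 330 appearances at the hypervariable site leaves
        # 3 variations over 115 sites
        assert stats[BIN_TOP].variations_per_site_excl == 0.03
        assert stats[BIN_TOP].total_variations_excl == 3
        assert stats[BIN_TOP].sites_with_variations_excl == 3

    def test_not_aligned_bin_rate_and_normalization(self, stats):
        assert stats[BIN_NOT_ALIGNED].variations_per_site == 41.40
        assert stats[BIN_NOT_ALIGNED].normalized_sites == 146.24

    def test_high_bin_normalized_sites(self, stats):
        assert stats[BIN_HIGH].normalized_sites == 57.25

    def test_grand_totals(self, stats):
        assert stats.totals.total_variations == 14560
        assert stats.totals.sites_with_variations == 263
        assert stats.totals.size == 955

    def test_top_bin_normalization_uses_actual_size(self, stats):
        # with the actual 115-site bin size the normalized values are
        # 9.63 / 802.10 (a size of 114 would give 9.72 / 809.13 instead)
        assert stats[BIN_TOP].normalized_sites == 9.63
        assert stats[BIN_TOP].normalized_variations == 802.10


class TestCensusPath:
    def make_table(self, cvs):
        records = []
        for pos in range(1, len(cvs) + 1):
            cv = cvs[pos - 1]
            if cv is None:
                records.append(ConservationEntry(position=pos, aligned=False))
            else:
                records.append(ConservationEntry(position=pos, cv=cv,
                                                 crw_letter="o"))
        return ConservationTable.from_records(records, length=len(cvs))

    def test_counts_and_derived_columns(self):
        # 6 positions: two top-bin, two low-bin, one negative, one not aligned
        table = self.make_table([1.95, 1.92, 0.5, 0.2, -0.5, None])
        census = VariantCensus(counts={
            parse_variant("1A>G"): 5,
            parse_variant("3C>U"): 2,
            parse_variant("3C>A"): 1,
            parse_variant("6G>A"): 4,
        }, n_sequences=50)
        raw = raw_counts_from_census(census, table)
        assert raw[BIN_TOP].sites_with_variations == 1
        assert raw[BIN_TOP].total_variations == 5
        assert raw[BIN_LOW].sites_with_variations == 1
        assert raw[BIN_LOW].total_variations == 3
        assert raw[BIN_NOT_ALIGNED].total_variations == 4
        stats = derive_bin_statistics(raw, reference_bin=BIN_LOW)
        assert stats[BIN_TOP].pct_sites_in_bin == 50.0
        assert stats[BIN_TOP].normalized_variations == 5.0  # equal bin sizes

    def test_bin_count_conservation_on_synthetic_table(self):
        import numpy as np
        rng = np.random.default_rng(5)
        table = generate_conservation(length=954, seed=5)
        positions = rng.choice(range(1, 955), size=80, replace=False)
        census = VariantCensus(counts={
            parse_variant(f"{int(p)}A>G"): int(rng.integers(1, 20))
            for p in positions}, n_sequences=200)
        raw = raw_counts_from_census(census, table)
        assert sum(r.sites_with_variations for r in raw.values()) == 80
        assert sum(r.total_variations for r in raw.values()) == \
            census.total_variations
        assert sum(r.size for r in raw.values()) == 954

    def test_exclusion_validation(self):
        table = self.make_table([1.95, 0.5])
        census = VariantCensus(counts={parse_variant("1A>G"): 5},
                               n_sequences=10)
        with pytest.raises(BinningError):
            raw_counts_from_census(census, table, exclusions=[(1, 6)])
        with pytest.raises(BinningError):
            raw_counts_from_census(census, table, exclusions=[(2, 1)])

    def test_genomic_census_converted_to_gene_coordinates(self):
        table = self.make_table([1.95] * 954)
        census = VariantCensus(counts={parse_variant("m.1555A>G"): 3},
                               n_sequences=10)
        raw = raw_counts_from_census(census, table)
        assert raw[BIN_TOP].total_variations == 3


@settings(derandomize=True, max_examples=60)
@given(c=st.integers(0, 1000), b=st.integers(1, 954))
def test_normalization_scale_invariance(c, b):
    assert normalize_count(c, b, b) == float(c)


def test_half_up_rounding_convention():
    assert round_half_up(57.245) == 57.25
    assert round_half_up(0.025) == 0.03
    assert round_half_up(2.895) == 2.90
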