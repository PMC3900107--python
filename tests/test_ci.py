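"""The four conservation indexes and their composite identity."""

import pytest

from conftest import make_map
from mthia.ci import (CiError, CiScores, NO_INFORMATION, ci_1ry, ci_2ry,
                      ci_tot, ci_univ, score_position, score_variant)
from mthia.binning import ConservationEntry, ConservationTable
from mthia.nomenclature import parse_variant
from mthia.structure import EquivalenceTable
from mthia.synthetic import generate_structure_pair


@pytest.mark.parametrize("letter,value", [
    ("x", 0), ("w", 1), ("o", 2),
    ("a", 3), ("c", 3), ("g", 3), ("u", 3), ("n", 3),
    ("A", 4), ("C", 4), ("G", 4), ("U", 4), ("N", 4),
])
def test_ci_univ_letter_mapping(letter, value):
    assert ci_univ(letter) == value


def test_ci_univ_rejects_unknown_symbols():
    with pytest.raises(CiError):
        ci_univ("z")


def test_letter_map_satisfies_every_published_pair(variant_table):
    """The letter -> value map must satisfy all (letter, Ci_Univ) pairs of
    the packaged table simultaneously."""
    checked = 0
    for row in variant_table:
        if row["ci_univ"] == "NI":
            continue
        assert ci_univ(row["crw_letter"]) == int(row["ci_univ"]), row
        checked += 1
    assert checked == 39


def test_composite_identity_on_every_populated_row(variant_table):
    """Ci_Tot = 2*Ci_Univ + 2*Ci_1ry + Ci_2ry holds for every row that
    prints all four values, including the half-integer ones."""
    checked = 0
    for row in variant_table:
        if row["ci_tot"] == "NI":
            continue
        u = int(row["ci_univ"])
        p = float(row["ci_1ry"])
        s = float(row["ci_2ry"])
        assert ci_tot(u, p, s) == float(row["ci_tot"]), row["gene_notation"]
        checked += 1
    assert checked == 39


@pytest.mark.parametrize("u,p,s,total", [
    (4, 5, 5, 23),     # the most conserved decoding-site variant
    (1, 1, 4.5, 8.5),  # a half-integer secondary score
    (0, 0, 0, 0),
])
def test_ci_tot_examples(u, p, s, total):
    assert ci_tot(u, p, s) == total


def test_ci_tot_validates_component_ranges():
    for bad in [(6, 0, 0), (-1, 0, 0), (0, 7, 0), (0, 0, 5.2), (0, 0, 6)]:
        with pytest.raises(CiError):
            ci_tot(*bad)


def _window_maps(mito_bases, ref_bases, seq_aligned=False):
    """Two unpaired 5-mers linked by identity, window centred at 3."""
    mito = make_map("m", [(i, b, None, None)
                          for i, b in enumerate(mito_bases, 1)])
    ref = make_map("r", [(i, b, None, None)
                         for i, b in enumerate(ref_bases, 1)])
    equiv = EquivalenceTable(links={i: i for i in range(1, 6)},
                             seq_aligned={3} if seq_aligned else set())
    return mito, ref, equiv


class TestCi1ry:
    def test_maximum_with_seq_aligned_bonus(self):
        mito, ref, equiv = _window_maps("ACGUA", "ACGUA", seq_aligned=True)
        assert ci_1ry(mito, ref, equiv, 3) == 6

    def test_minimum(self):
        mito, ref, equiv = _window_maps("ACGUA", "CAUGC")
        assert ci_1ry(mito, ref, equiv, 3) == 0

    def test_three_of_five_matches(self):
        mito, ref, equiv = _window_maps("ACGUA", "AGGUC")
        assert ci_1ry(mito, ref, equiv, 3) == 3

    def test_window_truncates_at_molecule_ends(self):
        mito, ref, equiv = _window_maps("ACGUA", "ACGUA")
        assert ci_1ry(mito, ref, equiv, 1) == 3  # slots -1, 0 missing

    def test_slots_without_equivalent_score_zero(self):
        mito, ref, _ = _window_maps("ACGUA", "ACGUA")
        equiv = EquivalenceTable(links={1: None, 2: 2, 3: 3, 4: 4, 5: None})
        assert ci_1ry(mito, ref, equiv, 3) == 3

    def test_unaligned_centre_is_an_error(self):
        mito, ref, _ = _window_maps("ACGUA", "ACGUA")
        equiv = EquivalenceTable(links={i: None for i in range(1, 6)})
        with pytest.raises(CiError):
            ci_1ry(mito, ref, equiv, 3)


def _paired_window(ref_partner_bases, mito_partner_bases,
                   unpair_ref=(), unpair_mito=()):
    """Five positions 1..5 paired with 11..15 (or unpaired where listed)."""
    def build(name, partner_bases, unpair):
        spec = []
        for i in range(1, 6):
            partner = 10 + i
            if i in unpair:
                spec.append((i, "A", None, None))
                spec.append((partner, partner_bases[i - 1], None, None))
            else:
                spec.append((i, "A", partner, "h1"))
                spec.append((partner, partner_bases[i - 1], i, "h1"))
        return make_map(name, spec)

    mito = build("m", mito_partner_bases, unpair_mito)
    ref = build("r", ref_partner_bases, unpair_ref)
    equiv = EquivalenceTable(links={i: i for i in list(range(1, 6)) +
                                   list(range(11, 16))})
    return mito, ref, equiv


class TestCi2ry:
    def test_all_unpaired_full_match(self):
        mito, ref, equiv = _window_maps("ACGUA", "ACGUA")
        assert ci_2ry(mito, ref, equiv, 3) == 5

    def test_half_penalty_for_mismatch_vs_canonical(self):
        # all five A:U pairs in the reference; one mito pair turned A:C
        mito, ref, equiv = _paired_window("UUUUU", "UUCUU")
        assert ci_2ry(mito, ref, equiv, 3) == 4.5

    def test_wobble_counts_as_canonical(self):
        # G:U in place of a Watson-Crick pair predicts the same structure
        mito, ref, equiv = _paired_window("UUUUU", "UUUUU")
        mito.bases[3] = "G"  # A:U -> G:U, still canonical-equivalent
        assert ci_2ry(mito, ref, equiv, 3) == 5

    def test_mixed_window(self):
        # 2 matches + 1 mismatch-vs-canonical + 2 paired-vs-unpaired
        mito, ref, equiv = _paired_window("UUUUU", "UUCUU",
                                          unpair_mito=(4, 5))
        assert ci_2ry(mito, ref, equiv, 3) == 2.5

    def test_monotone_when_half_penalty_slot_turns_matching(self):
        # restoring the broken pair lifts the half-penalty to a full point
        broken = _paired_window("UUUUU", "UUCUU")
        fixed = _paired_window("UUUUU", "UUUUU")
        assert ci_2ry(*broken, 3) < ci_2ry(*fixed, 3)


def test_ci_1ry_monotone_when_base_turns_matching():
    """Turning any mismatched window base into a match never lowers ci_1ry
    at any position (checked over a diverged synthetic pair)."""
    pair = generate_structure_pair(n_helices=4, divergence=0.3, seed=6)
    mito, ref, equiv = pair.map_mito, pair.map_ref, pair.equivalence
    mismatched = [w for w in mito.positions if mito.bases[w] != ref.bases[w]]
    assert mismatched, "fixture must contain diverged bases"
    for w in mismatched[:10]:
        affected = [p for p in range(w - 2, w + 3) if p in mito.bases]
        before = {p: ci_1ry(mito, ref, equiv, p) for p in affected}
        old = mito.bases[w]
        mito.bases[w] = ref.bases[w]
        try:
            for p in affected:
                assert ci_1ry(mito, ref, equiv, p) >= before[p]
        finally:
            mito.bases[w] = old


class TestScoreVariant:
    def make_conservation(self, letters):
        records = []
        for pos, letter in enumerate(letters, 1):
            if letter is None:
                records.append(ConservationEntry(position=pos, aligned=False))
            else:
                records.append(ConservationEntry(position=pos, cv=1.0,
                                                 crw_letter=letter))
        return ConservationTable.from_records(records, length=len(letters))

    def test_full_scores_on_synthetic_fixture(self):
        mito, ref, equiv = _window_maps("ACGUA", "ACGUA", seq_aligned=True)
        conservation = self.make_conservation(["G"] * 5)
        scores = score_variant(parse_variant("3G>A"), conservation,
                               mito, ref, equiv)
        assert scores == CiScores(ci_univ=4, ci_1ry=6, ci_2ry=5, ci_tot=25)

    def test_no_information_when_equivalent_missing(self):
        mito, ref, _ = _window_maps("ACGUA", "ACGUA")
        equiv = EquivalenceTable(links={i: None for i in range(1, 6)})
        conservation = self.make_conservation(["G"] * 5)
        assert score_variant(parse_variant("3G>A"), conservation,
                             mito, ref, equiv) == NO_INFORMATION

    def test_invariant_under_organism_relabeling(self):
        pair = generate_structure_pair(n_helices=3, divergence=0.2, seed=8)
        pos = pair.map_mito.positions[len(pair.map_mito.positions) // 2]
        a = ci_1ry(pair.map_mito, pair.map_ref, pair.equivalence, pos)
        pair.map_mito.organism = "renamed"
        pair.map_ref.organism = "also-renamed"
        assert ci_1ry(pair.map_mito, pair.map_ref, pair.equivalence, pos) == a


def test_ciscores_invariant_enforced():
    with pytest.raises(CiError):
        CiScores(ci_univ=4, ci_1ry=5, ci_2ry=5, ci_tot=22)  # identity broken
    with pytest.raises(CiError):
        CiScores(ci_univ=4, ci_1ry=5, ci_2ry=4.2, ci_tot=22.2)  # not half-step
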