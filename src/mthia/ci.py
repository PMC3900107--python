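"""Conservation-index scoring of mitochondrial 12S rRNA positions.

Four indexes are computed per tested position:

``Ci_Univ`` (0..5)
    Universal conservation of the residue across the whole phylogenetic
    tree, mapped from the CRW conservation-category letter:
    x -> 0, w -> 1, o -> 2, lowercase a/c/g/u/n -> 3, uppercase A/C/G/U/N
    -> 4.  The value 5 is reserved for a hypothetical invariant class and is
    accepted in inputs but never produced by this mapping.

``Ci_1ry`` (0..6)
    Primary-sequence conservation around the residue: 1 point per matched
    base within the five-residue window centred on the tested position
    (each window slot scores only if it has a heterologous equivalent and
    the two base identities agree, U and T being interchangeable), plus one
    extra point when the tested position's link was also predicted by
    primary-sequence alignment of the two molecules.

``Ci_2ry`` (0..5, half-point steps)
    Secondary-structure conservation over the same window: 1 point when the
    two maps predict the same structure at a slot (both unpaired, or both
    paired with G:U/U:G treated as equivalent to Watson-Crick); half a point
    when a phylogenetically predicted mismatch pair is replaced by a
    canonical/wobble pair or vice versa; 0 when one side is paired and the
    other unpaired, or the slot has no equivalent.

``Ci_Tot``
    The weighted composite  Ci_Tot = 2*Ci_Univ + 2*Ci_1ry + Ci_2ry, with the
    primary-conservation terms double-weighted.

Windows truncate at molecule ends (missing slots score 0) and run over
ungapped gene positions.  Positions without a heterologous equivalent get
no score (``no information``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .nomenclature import VariantDescriptor, as_rna
from .structure import (EquivalenceTable, StructureMap, find_equivalent,
                        GU_WOBBLE, MISMATCH, WATSON_CRICK, structural_state)

CI_UNIV_BY_LETTER = {
    "x": 0, "w": 1, "o": 2,
    "a": 3, "c": 3, "g": 3, "u": 3, "n": 3,
    "A": 4, "C": 4, "G": 4, "U": 4, "N": 4,
}

WINDOW = 2  # +/- residues around the tested position (five-residue window)

NO_INFORMATION = "NI"


class CiError(ValueError):
    """Invalid input to a conservation-index computation."""


@dataclass(frozen=True)
class CiScores:
    """The four conservation indexes of one position/variant."""

    ci_univ: int
    ci_1ry: float
    ci_2ry: float
    ci_tot: float

    def __post_init__(self) -> None:
        if not 0 <= self.ci_univ <= 5:
            raise CiError(f"ci_univ {self.ci_univ} outside 0..5")
        if not 0 <= self.ci_1ry <= 6:
            raise CiError(f"ci_1ry {self.ci_1ry} outside 0..6")
        if not 0 <= self.ci_2ry <= 5 or (self.ci_2ry * 2) % 1:
            raise CiError(f"ci_2ry {self.ci_2ry} not a half-point in 0..5")
        if self.ci_tot != 2 * self.ci_univ + 2 * self.ci_1ry + self.ci_2ry:
            raise CiError("ci_tot violates the composite identity")


def ci_univ(letter: str) -> int:
    """Map a CRW conservation-category letter to the universal index."""
    try:
        return CI_UNIV_BY_LETTER[letter]
    except KeyError:
        raise CiError(f"unknown CRW category letter {letter!r}") from None


def ci_1ry(
    map_mito: StructureMap,
    map_ref: StructureMap,
    equiv: EquivalenceTable,
    pos: int,
) -> float:
    """Windowed primary-sequence conservation score (0..6)."""
    if pos not in map_mito:
        raise CiError(f"position {pos} not in {map_mito.organism} map")
    if find_equivalent(equiv, pos) is None:
        raise CiError(f"position {pos} has no heterologous equivalent")
    score = 0.0
    for w in range(pos - WINDOW, pos + WINDOW + 1):
        if w not in map_mito:
            continue  # window truncates at molecule ends
        q = find_equivalent(equiv, w) if w in equiv else None
        if q is None or q not in map_ref:
            continue
        if as_rna(map_mito.bases[w]) == as_rna(map_ref.bases[q]):
            score += 1.0
    if pos in equiv.seq_aligned:
        score += 1.0
    return score


_CANONICAL = {WATSON_CRICK, GU_WOBBLE}


def _slot_2ry(map_mito: StructureMap, map_ref: StructureMap,
              equiv: EquivalenceTable, w: int) -> float:
    if w not in map_mito:
        return 0.0
    q = find_equivalent(equiv, w) if w in equiv else None
    if q is None or q not in map_ref:
        return 0.0
    state_m, class_m = structural_state(map_mito, w)
    state_r, class_r = structural_state(map_ref, q)
    if state_m == "unpaired" and state_r == "unpaired":
        return 1.0
    if state_m != state_r:
        return 0.0
    # both paired; canonical and wobble count as the same predicted structure
    canon_m = class_m in _CANONICAL
    canon_r = class_r in _CANONICAL
    if canon_m == canon_r:
        return 1.0
    return 0.5  # predicted mismatch replaced by canonical/wobble, or vice versa


def ci_2ry(
    map_mito: StructureMap,
    map_ref: StructureMap,
    equiv: EquivalenceTable,
    pos: int,
) -> float:
    """Windowed secondary-structure conservation score (0..5, half steps)."""
    if pos not in map_mito:
        raise CiError(f"position {pos} not in {map_mito.organism} map")
    if find_equivalent(equiv, pos) is None:
        raise CiError(f"position {pos} has no heterologous equivalent")
    return sum(_slot_2ry(map_mito, map_ref, equiv, w)
               for w in range(pos - WINDOW, pos + WINDOW + 1))


def ci_tot(u: Union[int, float], p: float, s: float) -> float:
    """Weighted composite index: 2*Ci_Univ + 2*Ci_1ry + Ci_2ry.

    Half-integer arithmetic is exact in binary floating point, so the result
    carries no rounding error.
    """
    if not 0 <= u <= 5 or u != int(u):
        raise CiError(f"ci_univ component {u} outside 0..5")
    if not 0 <= p <= 6:
        raise CiError(f"ci_1ry component {p} outside 0..6")
    if not 0 <= s <= 5 or (s * 2) % 1:
        raise CiError(f"ci_2ry component {s} not a half-point in 0..5")
    return 2 * int(u) + 2 * p + s


def score_position(
    pos: int,
    crw_letter: str,
    map_mito: StructureMap,
    map_ref: StructureMap,
    equiv: EquivalenceTable,
) -> Union[CiScores, str]:
    """All four indexes for a gene position, or ``NO_INFORMATION`` when the
    position has no heterologous equivalent."""
    if find_equivalent(equiv, pos) is None:
        return NO_INFORMATION
    u = ci_univ(crw_letter)
    p = ci_1ry(map_mito, map_ref, equiv, pos)
    s = ci_2ry(map_mito, map_ref, equiv, pos)
    return CiScores(ci_univ=u, ci_1ry=p, ci_2ry=s, ci_tot=ci_tot(u, p, s))


def score_variant(
    variant: VariantDescriptor,
    conservation,  # ConservationTable
    map_mito: StructureMap,
    map_ref: StructureMap,
    equiv: EquivalenceTable,
) -> Union[CiScores, str]:
    """Score the position affected by a variant (gene coordinates are used;
    genomic descriptors are converted first)."""
    gene = variant.to_gene()
    entry = conservation[gene.position]
    if not entry.aligned or entry.crw_letter is None:
        return NO_INFORMATION
    return score_position(gene.position, entry.crw_letter,
                          map_mito, map_ref, equiv)


__all__ = [
    "CI_UNIV_BY_LETTER", "WINDOW", "NO_INFORMATION", "CiError", "CiScores",
    "ci_univ", "ci_1ry", "ci_2ry", "ci_tot", "score_position", "score_variant",
]
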