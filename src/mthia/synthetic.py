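"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here aims at evolutionary realism: the generators plant exact
counts, exact structures and exact evidence so that each downstream module
can be checked against constructive ground truth without any external data.

* :func:`generate_population` — a collection of consensus mtDNA-like
  sequences with planted variants at exact appearance counts (including a
  hotspot emulating the hypervariable m.827 site), plus the ground-truth
  census.
* :func:`generate_conservation` — a per-position conservation table whose
  bin composition mirrors the real 12S gene's (115/150/239/277/13 aligned
  sites per C_v bin plus 161 not-aligned, rescaled to the requested
  length).
* :func:`generate_structure_pair` — two secondary-structure maps sharing a
  helix architecture, with controlled divergence and constructively
  computed ground-truth equivalence and per-position window scores.
* :func:`generate_evidence` — evidence records with known expected
  categories.

All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .binning import (BIN_HIGH, BIN_LOW, BIN_MID, BIN_NEG, BIN_TOP,
                      ConservationEntry, ConservationTable)
from .census import VariantCensus
from .hia import EvidenceRecord
from .nomenclature import VariantDescriptor, as_rna, parse_variant
from .structure import EquivalenceTable, StructureMap

_BASES = "ACGT"
_RNA = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SpecError(ValueError):
    """Infeasible or inconsistent generator specification."""


@dataclass
class PopulationSpec:
    """Specification of a planted-variant sequence population."""

    n_sequences: int
    reference_length: int = 1601
    variants: Sequence[Tuple[Union[VariantDescriptor, str], int]] = ()
    hotspot: Optional[Tuple[int, int]] = None  # (genomic position, count)
    seed: int = 0

    def normalized_variants(self) -> List[Tuple[VariantDescriptor, int]]:
        out = []
        for v, count in self.variants:
            if isinstance(v, str):
                v = parse_variant(v)
            out.append((v.to_genomic(), count))
        return out


@dataclass
class Population:
    reference: str
    samples: List[Tuple[str, str]]
    truth: VariantCensus
    seed: int


def generate_population(spec: PopulationSpec) -> Population:
    """Generate the population and its ground-truth census.

    Each planted variant appears in exactly its target count of sequences;
    assignment of variants to sequences is pseudo-random but reproducible
    from the seed.  Variant positions must be pairwise at least 3 apart so
    that alignments stay unambiguous and the census round-trips exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.reference_length
    if n < 0 or L <= 0:
        raise SpecError("population needs n_sequences >= 0 and a reference")

    planted = spec.normalized_variants()
    if spec.hotspot is not None:
        pos, count = spec.hotspot
        planted.append((None, count))  # placeholder resolved after ref draw
        hotspot_pos = pos
    else:
        hotspot_pos = None

    positions = [v.position for v, _ in planted if v is not None]
    if hotspot_pos is not None:
        positions.append(hotspot_pos)
    for p in positions:
        if not 1 <= p <= L:
            raise SpecError(f"variant position {p} outside reference 1..{L}")
    positions_sorted = sorted(positions)
    for a, b in zip(positions_sorted, positions_sorted[1:]):
        if b - a < 3:
            raise SpecError(
                f"planted positions {a} and {b} closer than the minimum "
                "spacing of 3"
            )
    for v, count in planted:
        if not 0 <= count <= n:
            raise SpecError(f"target count {count} infeasible for n={n}")

    ref = "".join(rng.choice(list(_BASES), size=L))
    # force the reference base demanded by each planted descriptor
    ref_list = list(ref)
    for v, _ in planted:
        if v is not None and v.ref_base is not None:
            ref_list[v.position - 1] = v.ref_base
    ref = "".join(ref_list)

    # resolve the hotspot into a concrete substitution now that ref is fixed
    resolved: List[Tuple[VariantDescriptor, int]] = []
    for v, count in planted:
        if v is None:
            r = ref[hotspot_pos - 1]
            alt = next(b for b in _BASES if b != r)
            v = VariantDescriptor(position=hotspot_pos,
                                  coordinate_system="genomic",
                                  kind="substitution", ref_base=r, alt_base=alt)
        resolved.append((v, count))

    carriers: Dict[int, List[VariantDescriptor]] = {i: [] for i in range(n)}
    for v, count in resolved:
        chosen = rng.choice(n, size=count, replace=False) if count else []
        for i in chosen:
            carriers[int(i)].append(v)

    samples: List[Tuple[str, str]] = []
    for i in range(n):
        seq = _apply_variants(ref, carriers[i])
        samples.append((f"synthetic_{spec.seed}_{i:05d}", seq))

    truth = VariantCensus(
        counts={v: c for v, c in resolved if c > 0}, n_sequences=n)
    return Population(reference=ref, samples=samples, truth=truth,
                      seed=spec.seed)


def _apply_variants(reference: str, variants: Sequence[VariantDescriptor]) -> str:
    seq = list(reference)
    # apply right to left so earlier positions stay valid
    for v in sorted(variants, key=lambda v: -v.position):
        idx = v.position - 1
        if v.kind == "substitution":
            seq[idx] = v.alt_base
        elif v.kind == "deletion":
            del seq[idx]
        else:  # insertion after the anchor position
            seq[idx + 1:idx + 1] = [v.alt_base] * v.insert_length
    return "".join(seq)


# -- conservation tables ---------------------------------------------------

_BIN_WEIGHTS = {  # real 12S composition: sites per bin
    BIN_TOP: 115, BIN_HIGH: 150, BIN_MID: 239, BIN_LOW: 277, BIN_NEG: 13,
    "not_aligned": 161,
}
_BIN_CV_RANGE = {
    BIN_TOP: (1.9, 2.0), BIN_HIGH: (1.5, 1.9), BIN_MID: (1.0, 1.5),
    BIN_LOW: (0.0, 1.0), BIN_NEG: (-1.0, 0.0),
}
_BIN_LETTER = {BIN_TOP: "AUGC", BIN_HIGH: "augc", BIN_MID: "o",
               BIN_LOW: "w", BIN_NEG: "x"}


def generate_conservation(length: int = 954, seed: int = 0) -> ConservationTable:
    """A synthetic conservation table whose bin composition mirrors the
    real gene's proportions."""
    rng = np.random.default_rng(seed)
    labels = list(_BIN_WEIGHTS)
    weights = np.array([_BIN_WEIGHTS[l] for l in labels], dtype=float)
    weights /= weights.sum()
    draws = rng.choice(len(labels), size=length, p=weights)
    records = []
    for pos in range(1, length + 1):
        label = labels[draws[pos - 1]]
        if label == "not_aligned":
            records.append(ConservationEntry(position=pos, aligned=False))
        else:
            lo, hi = _BIN_CV_RANGE[label]
            cv = float(rng.uniform(lo, hi))
            letter = str(rng.choice(list(_BIN_LETTER[label])))
            records.append(ConservationEntry(position=pos, cv=cv,
                                             crw_letter=letter))
    return ConservationTable.from_records(records, length=length)


# -- structure-map pairs ---------------------------------------------------

@dataclass
class StructurePair:
    """Two maps sharing a helix architecture plus constructive ground truth."""

    map_mito: StructureMap
    map_ref: StructureMap
    equivalence: EquivalenceTable
    ci_1ry_truth: Dict[int, float] = field(default_factory=dict)
    ci_2ry_truth: Dict[int, float] = field(default_factory=dict)
    seed: int = 0


def generate_structure_pair(
    n_helices: int = 8,
    divergence: float = 0.1,
    seed: int = 0,
    stem_range: Tuple[int, int] = (4, 8),
    loop_range: Tuple[int, int] = (3, 6),
    linker_range: Tuple[int, int] = (1, 4),
    seq_aligned_rate: float = 0.5,
    pair_break_rate: Optional[float] = None,
) -> StructurePair:
    """Generate a reference map and a diverged copy with ground truth.

    The reference is a chain of hairpin helices separated by single-stranded
    linkers; stems are fully Watson-Crick.  The diverged map keeps the
    architecture (so the ground-truth equivalence is the identity) and
    perturbs it two ways: base substitutions (rate ``divergence`` per
    position) and removal of a base pair (rate ``pair_break_rate``,
    defaulting to ``divergence/2``; pass 0 to keep the pairing registers
    identical, which register-based equivalence reconstruction needs to
    recover the links exactly).  No indels.  Window scores are
    computed constructively during generation with the same published
    rules the scoring engine implements, but in independent code.
    """
    if n_helices < 1:
        raise SpecError("need at least one helix")
    if not 0.0 <= divergence <= 1.0:
        raise SpecError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)

    bases_r: Dict[int, str] = {}
    partners_r: Dict[int, Optional[int]] = {}
    helices_r: Dict[int, Optional[str]] = {}
    pos = 0

    def add_unpaired(k: int) -> None:
        nonlocal pos
        for _ in range(k):
            pos += 1
            bases_r[pos] = str(rng.choice(list(_RNA)))
            partners_r[pos] = None
            helices_r[pos] = None

    for h in range(1, n_helices + 1):
        add_unpaired(int(rng.integers(*linker_range, endpoint=True)))
        stem = int(rng.integers(*stem_range, endpoint=True))
        loop = int(rng.integers(*loop_range, endpoint=True))
        five = list(range(pos + 1, pos + stem + 1))
        loop_pos = list(range(pos + stem + 1, pos + stem + loop + 1))
        three = list(range(pos + stem + loop + 1, pos + 2 * stem + loop + 1))
        for p5, p3 in zip(five, reversed(three)):
            b = str(rng.choice(list(_RNA)))
            bases_r[p5] = b
            bases_r[p3] = _COMPLEMENT[b]
            partners_r[p5] = p3
            partners_r[p3] = p5
            helices_r[p5] = helices_r[p3] = f"h{h}"
        for p in loop_pos:
            bases_r[p] = str(rng.choice(list(_RNA)))
            partners_r[p] = None
            helices_r[p] = f"h{h}"
        pos += 2 * stem + loop
    add_unpaired(int(rng.integers(*linker_range, endpoint=True)))

    map_ref = StructureMap(organism="reference", bases=dict(bases_r),
                           partners=dict(partners_r), helices=dict(helices_r))

    # diverged copy: same architecture, perturbed bases and pairings
    bases_m = dict(bases_r)
    partners_m = dict(partners_r)
    for p in list(bases_m):
        if rng.random() < divergence:
            others = [b for b in _RNA if b != bases_m[p]]
            bases_m[p] = str(rng.choice(others))
    if pair_break_rate is None:
        pair_break_rate = divergence / 2
    for p in list(partners_m):
        q = partners_m.get(p)
        if q is not None and p < q and rng.random() < pair_break_rate:
            partners_m[p] = None
            partners_m[q] = None
    map_mito = StructureMap(organism="synthetic-mito", bases=bases_m,
                            partners=partners_m, helices=dict(helices_r))

    all_pos = sorted(bases_r)
    flagged: Set[int] = {p for p in all_pos if rng.random() < seq_aligned_rate}
    equivalence = EquivalenceTable(links={p: p for p in all_pos},
                                   seq_aligned=set(flagged))

    # constructive ground-truth window scores (independent of the Ci engine)
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
          ("G", "U"), ("U", "G")}
    ci1: Dict[int, float] = {}
    ci2: Dict[int, float] = {}
    for p in all_pos:
        s1 = 0.0
        s2 = 0.0
        for w in range(p - 2, p + 3):
            if w not in bases_m:
                continue
            if bases_m[w] == bases_r[w]:
                s1 += 1.0
            qm, qr = partners_m.get(w), partners_r.get(w)
            if qm is None and qr is None:
                s2 += 1.0
            elif qm is not None and qr is not None:
                cm = (bases_m[w], bases_m[qm]) in wc
                cr = (bases_r[w], bases_r[qr]) in wc
                s2 += 1.0 if cm == cr else 0.5
        if p in flagged:
            s1 += 1.0
        ci1[p] = s1
        ci2[p] = s2
    return StructurePair(map_mito=map_mito, map_ref=map_ref,
                         equivalence=equivalence, ci_1ry_truth=ci1,
                         ci_2ry_truth=ci2, seed=seed)


# -- evidence records ------------------------------------------------------

_EVIDENCE_TEMPLATES = [
    # (direct, indirect, context, het aligned, expected category)
    ("supports_disruption", "none", "yes", True, "expectedly"),
    ("none", "supports_disruption", "yes", True, "likely"),
    ("none", "supports_tolerance", "yes", True, "unlikely"),
    ("supports_tolerance", "none", "yes", True, "unlikely"),
    ("none", "none", "yes", True, "NEE"),
    ("none", "none", "unknown", False, "undetermined"),
    ("none", "none", "no", True, "undetermined"),
]


def generate_evidence(n: int, seed: int = 0
                      ) -> List[Tuple[EvidenceRecord, str]]:
    """Random evidence records paired with their expected category."""
    rng = np.random.default_rng(seed)
    out: List[Tuple[EvidenceRecord, str]] = []
    # avoid the default proven-list positions so expected categories hold
    candidates = np.array([p for p in range(1, 955) if p not in (847, 908)])
    positions = rng.choice(candidates, size=n, replace=False)
    for i in range(n):
        direct, indirect, context, aligned, expected = _EVIDENCE_TEMPLATES[
            int(rng.integers(len(_EVIDENCE_TEMPLATES)))]
        pos = int(positions[i])
        ref = str(rng.choice(list(_RNA)))
        alt = str(rng.choice([b for b in _RNA if b != ref]))
        rec = EvidenceRecord(
            mito_variant=VariantDescriptor(
                position=pos, coordinate_system="gene", kind="substitution",
                ref_base=ref, alt_base=alt),
            heterologous_position=pos + 100 if aligned else None,
            direct_mutagenesis=direct,
            indirect_evidence=indirect,
            structural_context_conserved=context,
            citations=("synthetic mutagenesis record",) if direct != "none" else (),
        )
        out.append((rec, expected))
    return out


__all__ = [
    "SpecError", "PopulationSpec", "Population", "generate_population",
    "generate_conservation", "StructurePair", "generate_structure_pair",
    "generate_evidence",
]
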