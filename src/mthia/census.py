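"""Variant-appearance census of mtDNA sequence collections against a reference.

Each sample consensus sequence is globally aligned to the reference (affine
gap penalties, defaults match +1 / mismatch -1 / gap open -2 / gap extend
-1), per-position differences are called in reference coordinates, and
appearance counts are tallied over the collection.  A rarity screen then
labels each variant by its combined appearance count: variants never seen in
the reference collections are the prime candidates for functional follow-up,
while anything seen more than the review threshold (default 15) is treated
as a population polymorphism.

Pre-aligned FASTA pairs are accepted as well, so a census can be computed on
alignments produced by an external multiple-alignment tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .nomenclature import VariantDescriptor, format_variant, parse_variant

_VALID_CHARS = frozenset("ACGTUN")
_GAP = "-"


class InputError(ValueError):
    """Invalid sequence or census input."""


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap global-alignment parameters."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0    # cost of the first base of a gap
    gap_extend: float = -1.0  # cost of each further base


@dataclass
class AlignedPair:
    """A gapped reference/sample row pair from one global alignment."""

    reference_row: str
    sample_row: str
    score: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.reference_row) != len(self.sample_row):
            raise InputError("aligned rows must have equal length")
        for row in (self.reference_row, self.sample_row):
            bad = set(row) - _VALID_CHARS - {_GAP}
            if bad:
                raise InputError(f"invalid characters in alignment row: {bad}")


def _clean(seq: str, what: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise InputError(f"empty {what} sequence")
    bad = set(s) - _VALID_CHARS
    if bad:
        raise InputError(f"non-nucleotide characters in {what}: {sorted(bad)}")
    return s


def align_to_reference(
    sample: str,
    reference: str,
    scoring: AlignmentScoring = AlignmentScoring(),
    length_tolerance: float = 0.10,
    provenance: str = "",
) -> AlignedPair:
    """Globally align one sample sequence to the reference.

    The optimal alignment under the affine-gap scoring is computed with
    Biopython's pairwise aligner; among co-optimal alignments the aligner's
    first enumerated path is taken, which is deterministic for fixed inputs
    and parameters.  Samples whose length deviates from the reference by
    more than ``length_tolerance`` are rejected up front, as they are
    unlikely to be complete sequences of the same molecule.
    """
    ref = _clean(reference, "reference")
    smp = _clean(sample, "sample")
    if length_tolerance is not None:
        lo = len(ref) * (1 - length_tolerance)
        hi = len(ref) * (1 + length_tolerance)
        if not lo <= len(smp) <= hi:
            raise InputError(
                f"sample length {len(smp)} outside +/-{length_tolerance:.0%} "
                f"of reference length {len(ref)}"
            )
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # N matches nothing and costs nothing either way: treat as wildcard-neutral
    # by scoring it as a mismatch (the caller never gets calls at N anyway).
    aln = aligner.align(ref, smp)[0]
    ref_row, smp_row = str(aln[0]), str(aln[1])
    return AlignedPair(ref_row, smp_row, score=aln.score, provenance=provenance)


def call_variants(pair: AlignedPair) -> List[VariantDescriptor]:
    """Extract variant calls (genomic/reference coordinates) from an alignment.

    Substitutions are reported at their reference position, deletions at the
    deleted reference position, and insertions anchored to the preceding
    reference position with ``insert_length`` equal to the run length
    (mixed-base insertion runs are reported base by base).  ``N`` in the
    sample never yields a call.
    """
    calls: List[VariantDescriptor] = []
    ref_pos = 0
    i = 0
    ref_row, smp_row = pair.reference_row, pair.sample_row
    n = len(ref_row)
    while i < n:
        r, s = ref_row[i], smp_row[i]
        if r == _GAP:
            # insertion run relative to the reference
            j = i
            while j < n and ref_row[j] == _GAP:
                j += 1
            inserted = smp_row[i:j].replace(_GAP, "")
            anchor = ref_pos  # preceding reference position
            if anchor >= 1 and inserted:
                k = 0
                while k < len(inserted):
                    base = inserted[k]
                    run = 1
                    while k + run < len(inserted) and inserted[k + run] == base:
                        run += 1
                    if base != "N":
                        calls.append(VariantDescriptor(
                            position=anchor, coordinate_system="genomic",
                            kind="insertion", alt_base=base, insert_length=run,
                        ))
                    k += run
            i = j
            continue
        ref_pos += 1
        if s == _GAP:
            calls.append(VariantDescriptor(
                position=ref_pos, coordinate_system="genomic",
                kind="deletion", ref_base=r,
            ))
        elif s != r and s != "N" and r != "N":
            calls.append(VariantDescriptor(
                position=ref_pos, coordinate_system="genomic",
                kind="substitution", ref_base=r, alt_base=s,
            ))
        i += 1
    return calls


@dataclass
class VariantCensus:
    """Per-variant appearance counts over a sequence collection.

    ``counts`` maps each variant to the number of samples carrying it;
    ``site_totals`` aggregates counts over all variant types at a site.
    Variants with count zero are never stored.
    """

    counts: Dict[VariantDescriptor, int] = field(default_factory=dict)
    n_sequences: int = 0

    def __post_init__(self) -> None:
        systems = {v.coordinate_system for v in self.counts}
        if len(systems) > 1:
            raise InputError("census mixes coordinate systems")
        if any(c <= 0 for c in self.counts.values()):
            raise InputError("census counts must be positive")

    @property
    def coordinate_system(self) -> str:
        for v in self.counts:
            return v.coordinate_system
        return "genomic"

    @property
    def site_totals(self) -> Dict[int, int]:
        totals: Dict[int, int] = {}
        for v, c in self.counts.items():
            totals[v.position] = totals.get(v.position, 0) + c
        return totals

    @property
    def total_variations(self) -> int:
        return sum(self.counts.values())

    def count(self, variant: VariantDescriptor | str) -> int:
        if isinstance(variant, str):
            variant = parse_variant(variant)
        if variant.coordinate_system != self.coordinate_system and self.counts:
            variant = (variant.to_genomic() if self.coordinate_system == "genomic"
                       else variant.to_gene())
        return self.counts.get(variant, 0)

    def to_gene(self) -> "VariantCensus":
        """Convert a genomic-coordinate census to 12S gene coordinates,
        dropping variants outside MT-RNR1."""
        from .nomenclature import GENOMIC_END, GENOMIC_START
        if self.coordinate_system == "gene":
            return self
        counts = {
            v.to_gene(): c for v, c in self.counts.items()
            if GENOMIC_START <= v.position <= GENOMIC_END
        }
        return VariantCensus(counts=counts, n_sequences=self.n_sequences)


def tally(
    calls: Iterable[Sequence[VariantDescriptor]],
    n_sequences: Optional[int] = None,
) -> VariantCensus:
    """Aggregate per-sample call lists into a census.

    Counting is per sequence record: a sample carrying a variant contributes
    one appearance, and identical records are not de-duplicated.
    """
    calls = list(calls)
    systems = {v.coordinate_system for sample in calls for v in sample}
    if len(systems) > 1:
        raise InputError("per-sample call lists mix coordinate systems")
    counts: Dict[VariantDescriptor, int] = {}
    for sample in calls:
        for v in set(sample):  # a variant counts once per sample
            counts[v] = counts.get(v, 0) + 1
    n = len(calls) if n_sequences is None else n_sequences
    return VariantCensus(counts=counts, n_sequences=n)


def run_census(
    samples: Iterable[Tuple[str, str]],
    reference: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> VariantCensus:
    """Align every ``(id, sequence)`` sample to ``reference`` and tally calls."""
    per_sample = []
    for name, seq in samples:
        pair = align_to_reference(seq, reference, scoring=scoring, provenance=name)
        per_sample.append(call_variants(pair))
    return tally(per_sample)


# -- rarity screen ---------------------------------------------------------

EXTREMELY_RARE = "extremely_rare"
REVIEW = "review"
COMMON = "common"


def rarity_screen(
    census: VariantCensus,
    secondary_census: Optional[VariantCensus] = None,
    investigate_threshold: int = 15,
    variants: Optional[Iterable[VariantDescriptor | str]] = None,
) -> Dict[str, str]:
    """Label variants by combined appearance count across the censuses.

    ``extremely_rare``: combined count 0 (never seen); ``review``: between 1
    and the threshold inclusive (worth inspecting source records);
    ``common``: above the threshold (excluded as a population change).
    """
    if secondary_census is not None and census.counts and secondary_census.counts:
        if census.coordinate_system != secondary_census.coordinate_system:
            raise InputError("censuses use different coordinate systems")
    if variants is None:
        keys = set(census.counts)
        if secondary_census is not None:
            keys |= set(secondary_census.counts)
        queried: List[VariantDescriptor] = sorted(
            keys, key=lambda v: (v.position, v.kind, str(v.alt_base)))
    else:
        queried = [parse_variant(v) if isinstance(v, str) else v for v in variants]
    report: Dict[str, str] = {}
    for v in queried:
        combined = census.count(v)
        if secondary_census is not None:
            combined += secondary_census.count(v)
        if combined == 0:
            label = EXTREMELY_RARE
        elif combined <= investigate_threshold:
            label = REVIEW
        else:
            label = COMMON
        report[format_variant(v)] = label
    return report


# -- IO --------------------------------------------------------------------

def read_fasta(path: str | Path) -> List[Tuple[str, str]]:
    """Read a multi-record FASTA file as ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_prealigned_fasta(path: str | Path, reference_id: str | None = None
                          ) -> List[AlignedPair]:
    """Read pre-aligned FASTA (first record or ``reference_id`` = reference)
    into reference/sample row pairs."""
    recs = read_fasta(path)
    if len(recs) < 2:
        raise InputError("pre-aligned FASTA needs a reference and >=1 sample")
    if reference_id is None:
        ref_name, ref_row = recs[0]
        samples = recs[1:]
    else:
        matches = [r for r in recs if r[0] == reference_id]
        if not matches:
            raise InputError(f"reference record {reference_id!r} not found")
        ref_name, ref_row = matches[0]
        samples = [r for r in recs if r[0] != reference_id]
    return [AlignedPair(ref_row.upper(), row.upper(), provenance=name)
            for name, row in samples]


def write_census_tsv(census: VariantCensus, path: str | Path) -> None:
    """Write a census as TSV: variant, gene_pos, genomic_pos, count."""
    from .nomenclature import GENOMIC_END, GENOMIC_START
    lines = ["variant\tgene_pos\tgenomic_pos\tcount"]
    for v in sorted(census.counts, key=lambda v: (v.position, v.kind,
                                                  str(v.alt_base), str(v.ref_base))):
        g = v.to_genomic() if v.coordinate_system == "gene" else v
        in_gene = GENOMIC_START <= g.position <= GENOMIC_END
        gene_pos = str(g.to_gene().position) if in_gene else ""
        lines.append(f"{format_variant(g)}\t{gene_pos}\t{g.position}\t"
                     f"{census.counts[v]}")
    lines.append(f"#n_sequences\t\t\t{census.n_sequences}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_census_tsv(path: str | Path) -> VariantCensus:
    counts: Dict[VariantDescriptor, int] = {}
    n_sequences = 0
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("variant\t"):
            continue
        if line.startswith("#n_sequences"):
            n_sequences = int(line.rsplit("\t", 1)[1])
            continue
        variant, _gene, _genomic, count = line.split("\t")
        counts[parse_variant(variant)] = int(count)
    return VariantCensus(counts=counts, n_sequences=n_sequences)


def write_census_json(census: VariantCensus, path: str | Path) -> None:
    payload = {
        "n_sequences": census.n_sequences,
        "counts": {format_variant(v): c for v, c in sorted(
            census.counts.items(), key=lambda kv: (kv[0].position, kv[0].kind,
                                                   str(kv[0].alt_base)))},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_census_json(path: str | Path) -> VariantCensus:
    payload = json.loads(Path(path).read_text())
    return VariantCensus(
        counts={parse_variant(k): v for k, v in payload["counts"].items()},
        n_sequences=payload["n_sequences"],
    )


__all__ = [
    "AlignmentScoring", "AlignedPair", "VariantCensus", "InputError",
    "align_to_reference", "call_variants", "tally", "run_census",
    "rarity_screen", "EXTREMELY_RARE", "REVIEW", "COMMON",
    "read_fasta", "read_prealigned_fasta",
    "write_census_tsv", "read_census_tsv",
    "write_census_json", "read_census_json",
]
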