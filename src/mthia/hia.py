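"""Heterologous inferential analysis (HIA): rule-based disruptive-potential
classification of mitochondrial 12S rRNA variants.

The disruptive power of the structurally equivalent residue in a
heterologous (typically bacterial) ribosome is first classified from
curated evidence:

* ``C`` certainly disruptive — supportive direct mutagenesis data exist for
  the tested residue or its base-pairing partner;
* ``N`` certainly not disruptive — direct mutagenesis data support
  tolerance;
* ``L`` likely disruptive / ``U`` unlikely disruptive — no direct
  mutagenesis data, but enough indirect evidence one way or the other;
* ``NEE`` not enough evidence — nothing argues for or against.

The heterologous verdict is then lifted to the mitochondrial variant as
long as the local structural context is not in disagreement: ``C`` lifts to
``expectedly`` disruptive, ``L`` to ``likely``, ``U`` and ``N`` to
``unlikely``, ``NEE`` stays ``NEE``.  Variants whose position has no
heterologous equivalent, or whose structural context is too divergent, are
``undetermined``.  Variants on the configured proven-pathogenic list
(default: the deafness mutations 847C>U / m.1494C>T and 908A>G / m.1555A>G)
are reported as ``proven`` regardless of evidence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

from .nomenclature import VariantDescriptor, format_variant, parse_variant

# heterologous classes
HET_N, HET_U, HET_NEE, HET_L, HET_C = "N", "U", "NEE", "L", "C"
# mitochondrial categories
UNLIKELY = "unlikely"
UNDETERMINED = "undetermined"
NEE = "NEE"
LIKELY = "likely"
EXPECTEDLY = "expectedly"
PROVEN = "proven"

CATEGORY_ORDER = [UNLIKELY, UNDETERMINED, NEE, LIKELY, EXPECTEDLY, PROVEN]

DEFAULT_PROVEN = ("847C>U", "908A>G")

Evidence = Literal["none", "supports_disruption", "supports_tolerance"]
ContextConserved = Literal["yes", "no", "unknown"]


class HiaError(ValueError):
    """Invalid evidence record or classification input."""


@dataclass(frozen=True)
class EvidenceRecord:
    """Curated heterologous evidence for one mitochondrial variant.

    ``heterologous_position`` is the E. coli-numbered equivalent residue or
    ``None`` when the position has no structural equivalent.  Direct
    mutagenesis evidence requires at least one citation.
    ``structural_context_conserved`` records whether the higher-order
    structural elements around the residue are conserved between the
    mitochondrial and heterologous ribosomes; ``no`` forces the
    undetermined path, ``unknown`` is treated as conserved (heterologous
    conclusions transfer unless the structural data disagree).
    """

    mito_variant: VariantDescriptor
    heterologous_position: Optional[int] = None
    direct_mutagenesis: Evidence = "none"
    indirect_evidence: Evidence = "none"
    structural_context_conserved: ContextConserved = "unknown"
    citations: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.direct_mutagenesis != "none" and not self.citations:
            raise HiaError(
                f"{format_variant(self.mito_variant)}: direct mutagenesis "
                "evidence requires at least one citation"
            )


@dataclass(frozen=True)
class HiaClassification:
    """Heterologous class and lifted mitochondrial category of one variant."""

    mito_variant: VariantDescriptor
    heterologous_class: Optional[str]
    mito_category: str

    def __post_init__(self) -> None:
        if (self.heterologous_class is None) != (self.mito_category == UNDETERMINED):
            raise HiaError(
                "heterologous_class is none exactly for undetermined variants"
            )


def classify_heterologous(ev: EvidenceRecord) -> str:
    """Classify the heterologous residue's disruptive power (N/U/NEE/L/C).

    Callers must route not-aligned records to the undetermined path first.
    """
    if ev.heterologous_position is None:
        raise HiaError(
            f"{format_variant(ev.mito_variant)} has no heterologous "
            "equivalent; route to the undetermined path"
        )
    if ev.direct_mutagenesis == "supports_disruption":
        return HET_C
    if ev.direct_mutagenesis == "supports_tolerance":
        return HET_N
    if ev.indirect_evidence == "supports_disruption":
        return HET_L
    if ev.indirect_evidence == "supports_tolerance":
        return HET_U
    return HET_NEE


_LIFT = {HET_C: EXPECTEDLY, HET_L: LIKELY, HET_U: UNLIKELY,
         HET_N: UNLIKELY, HET_NEE: NEE}


def lift_to_mitochondrial(
    ev: EvidenceRecord,
    het_class: Optional[str],
    proven_list: Sequence[VariantDescriptor | str] = DEFAULT_PROVEN,
) -> HiaClassification:
    """Lift a heterologous verdict to the mitochondrial variant.

    Proven-list membership overrides everything; a missing equivalent or a
    divergent structural context yields ``undetermined``.
    """
    proven = {_as_gene_key(v) for v in proven_list}
    if _as_gene_key(ev.mito_variant) in proven:
        return HiaClassification(ev.mito_variant, het_class or HET_C, PROVEN)
    if ev.heterologous_position is None or ev.structural_context_conserved == "no":
        return HiaClassification(ev.mito_variant, None, UNDETERMINED)
    if het_class not in _LIFT:
        raise HiaError(f"unknown heterologous class {het_class!r}")
    return HiaClassification(ev.mito_variant, het_class, _LIFT[het_class])


def classify(ev: EvidenceRecord,
             proven_list: Sequence[VariantDescriptor | str] = DEFAULT_PROVEN,
             ) -> HiaClassification:
    """Full rubric for one record: heterologous class, then the lift."""
    het: Optional[str] = None
    if ev.heterologous_position is not None:
        het = classify_heterologous(ev)
    return lift_to_mitochondrial(ev, het, proven_list)


def classify_all(records: Iterable[EvidenceRecord],
                 proven_list: Sequence[VariantDescriptor | str] = DEFAULT_PROVEN,
                 ) -> List[HiaClassification]:
    return [classify(ev, proven_list) for ev in records]


def category_census(classifications: Iterable[HiaClassification]) -> Dict[str, int]:
    """Exact per-category counts; every category key is present."""
    counts = Counter(c.mito_category for c in classifications)
    return {cat: counts.get(cat, 0) for cat in CATEGORY_ORDER}


def _as_gene_key(v: VariantDescriptor | str) -> str:
    if isinstance(v, str):
        v = parse_variant(v)
    return format_variant(v.to_gene())


# -- IO --------------------------------------------------------------------

def evidence_from_dict(obj: dict) -> EvidenceRecord:
    het = obj.get("heterologous_position")
    return EvidenceRecord(
        mito_variant=parse_variant(obj["variant"]),
        heterologous_position=int(het) if het is not None else None,
        direct_mutagenesis=obj.get("direct_mutagenesis", "none"),
        indirect_evidence=obj.get("indirect_evidence", "none"),
        structural_context_conserved=obj.get("structural_context_conserved",
                                             "unknown"),
        citations=tuple(obj.get("citations", ())),
    )


def read_evidence_json(path: str | Path) -> List[EvidenceRecord]:
    """Read an evidence collection (JSON list, one object per variant)."""
    return [evidence_from_dict(o) for o in json.loads(Path(path).read_text())]


def load_packaged_evidence() -> List[EvidenceRecord]:
    """The curated evidence records behind the packaged 49-variant table."""
    text = (resources.files("mthia.data") / "evidence.json").read_text()
    return [evidence_from_dict(o) for o in json.loads(text)]


def write_classification_tsv(
    classifications: Sequence[HiaClassification],
    path: str | Path,
    ci_by_variant: Optional[Dict[str, Tuple]] = None,
    equivalents: Optional[Dict[str, str]] = None,
) -> None:
    """Write a classification report grouped by category (one section per
    category, mirroring the shape of a per-category variant table)."""
    lines = ["category\tvariant\tgenomic\tecoli_equivalent\t"
             "ci_univ\tci_1ry\tci_2ry\tci_tot"]
    for cat in CATEGORY_ORDER:
        for c in sorted(
            (c for c in classifications if c.mito_category == cat),
            key=lambda c: c.mito_variant.to_gene().position,
        ):
            key = format_variant(c.mito_variant.to_gene())
            genomic = format_variant(c.mito_variant.to_genomic())
            equivalent = (equivalents or {}).get(key, "")
            ci = (ci_by_variant or {}).get(key)
            ci_cells = ("\t".join(str(x) for x in ci) if ci
                        else "NI\tNI\tNI\tNI")
            lines.append(f"{cat}\t{key}\t{genomic}\t{equivalent}\t{ci_cells}")
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = [
    "HET_N", "HET_U", "HET_NEE", "HET_L", "HET_C",
    "UNLIKELY", "UNDETERMINED", "NEE", "LIKELY", "EXPECTEDLY", "PROVEN",
    "CATEGORY_ORDER", "DEFAULT_PROVEN", "HiaError",
    "EvidenceRecord", "HiaClassification",
    "classify_heterologous", "lift_to_mitochondrial", "classify",
    "classify_all", "category_census",
    "read_evidence_json", "load_packaged_evidence", "evidence_from_dict",
    "write_classification_tsv",
]
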