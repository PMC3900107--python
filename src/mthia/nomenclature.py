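"""Variant notation and coordinate systems for the human mitochondrial 12S rRNA.

The 12S rRNA gene (MT-RNR1) spans positions m.648-m.1601 of the revised
Cambridge Reference Sequence (rCRS, NC_012920.1), so gene residue ``p``
(1..954) sits at genomic position ``p + 647``.  Two notations are in common
use and both are supported here:

* gene notation, RNA alphabet — ``908A>G``, ``314InsC(5)``, ``314delU``
* genomic (rCRS) notation, DNA alphabet — ``m.1555A>G``, ``m.961InsC(5)``,
  ``m.961delT``

Comparisons are always carried out on the RNA alphabet internally (U and T
are interchangeable on input); the writer picks the alphabet from the
coordinate system of the descriptor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional

GENE_LENGTH = 954
GENOMIC_OFFSET = 647
GENOMIC_START = GENOMIC_OFFSET + 1          # m.648
GENOMIC_END = GENOMIC_OFFSET + GENE_LENGTH  # m.1601

CoordinateSystem = Literal["gene", "genomic"]
VariantKind = Literal["substitution", "insertion", "deletion"]

_RNA_BASES = frozenset("ACGU")


class CoordinateError(ValueError):
    """A position falls outside the valid interval of its coordinate system."""


class ParseError(ValueError):
    """A variant notation string does not match the supported grammar."""


class ValidationError(ValueError):
    """A descriptor (or reference check) is internally inconsistent."""


def gene_to_genomic(pos: int) -> int:
    """Convert a 12S gene position (1..954) to an rCRS m. position (648..1601)."""
    if not 1 <= pos <= GENE_LENGTH:
        raise CoordinateError(
            f"gene position {pos} outside MT-RNR1 [1, {GENE_LENGTH}]"
        )
    return pos + GENOMIC_OFFSET


def genomic_to_gene(pos: int) -> int:
    """Convert an rCRS m. position within MT-RNR1 to a gene position."""
    if not GENOMIC_START <= pos <= GENOMIC_END:
        raise CoordinateError(
            f"genomic position {pos} outside MT-RNR1 [{GENOMIC_START}, {GENOMIC_END}]"
        )
    return pos - GENOMIC_OFFSET


def _normalize_base(base: str, system: CoordinateSystem) -> str:
    b = base.upper()
    if b == "T":
        b = "U"
    if b not in _RNA_BASES:
        raise ParseError(f"invalid base {base!r}")
    if system == "genomic" and b == "U":
        return "T"
    return b


def as_rna(base: str) -> str:
    """Uppercase a base and map T to U (the internal comparison alphabet)."""
    b = base.upper()
    return "U" if b == "T" else b


@dataclass(frozen=True)
class VariantDescriptor:
    """One base substitution, insertion or deletion in gene or genomic coordinates.

    ``ref_base`` is absent for pure insertions and ``alt_base`` for deletions.
    ``insert_length`` only matters for insertions (the ``(n)`` of the
    ``InsC(n)`` notation) and defaults to 1.
    """

    position: int
    coordinate_system: CoordinateSystem
    kind: VariantKind
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    insert_length: int = 1

    def __post_init__(self) -> None:
        if self.coordinate_system == "gene":
            if not 1 <= self.position <= GENE_LENGTH:
                raise CoordinateError(
                    f"gene position {self.position} outside [1, {GENE_LENGTH}]"
                )
        elif self.coordinate_system == "genomic":
            # any positive reference position; the MT-RNR1 window
            # [GENOMIC_START, GENOMIC_END] is enforced on conversion to gene
            # coordinates, since a census may cover the whole molecule
            if self.position < 1:
                raise CoordinateError(
                    f"genomic position {self.position} must be >= 1"
                )
        else:
            raise ValidationError(
                f"unknown coordinate system {self.coordinate_system!r}"
            )
        if self.kind == "substitution":
            if self.ref_base is None or self.alt_base is None:
                raise ValidationError("substitution needs ref and alt bases")
            if as_rna(self.ref_base) == as_rna(self.alt_base):
                raise ValidationError(
                    f"substitution at {self.position} has identical ref/alt"
                )
        elif self.kind == "insertion":
            if self.ref_base is not None:
                raise ValidationError("insertion carries no reference base")
            if self.alt_base is None:
                raise ValidationError("insertion needs the inserted base")
            if self.insert_length < 1:
                raise ValidationError("insert_length must be >= 1")
        elif self.kind == "deletion":
            if self.alt_base is not None:
                raise ValidationError("deletion carries no alternate base")
            if self.ref_base is None:
                raise ValidationError("deletion needs the deleted base")
        else:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        # normalise stored alphabet to the coordinate system's convention
        for field in ("ref_base", "alt_base"):
            val = getattr(self, field)
            if val is not None:
                object.__setattr__(
                    self, field, _normalize_base(val, self.coordinate_system)
                )

    # -- conversions -------------------------------------------------------

    def to_genomic(self) -> "VariantDescriptor":
        if self.coordinate_system == "genomic":
            return self
        return VariantDescriptor(
            position=gene_to_genomic(self.position),
            coordinate_system="genomic",
            kind=self.kind,
            ref_base=self.ref_base,
            alt_base=self.alt_base,
            insert_length=self.insert_length,
        )

    def to_gene(self) -> "VariantDescriptor":
        if self.coordinate_system == "gene":
            return self
        return VariantDescriptor(
            position=genomic_to_gene(self.position),
            coordinate_system="gene",
            kind=self.kind,
            ref_base=self.ref_base,
            alt_base=self.alt_base,
            insert_length=self.insert_length,
        )


_SUB_RE = re.compile(r"^(m\.)?(\d+)([ACGTUacgtu])>([ACGTUacgtu])$")
_INS_RE = re.compile(r"^(m\.)?(\d+)[Ii]ns([ACGTUacgtu])(?:\((\d+)\))?$")
_DEL_RE = re.compile(r"^(m\.)?(\d+)del([ACGTUacgtu])$")


def parse_variant(text: str) -> VariantDescriptor:
    """Parse a variant notation string into a normalized descriptor.

    The ``m.`` prefix selects the genomic coordinate system; its absence
    selects gene coordinates.  U and T are accepted interchangeably.
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        prefix, pos, ref, alt = m.groups()
        system: CoordinateSystem = "genomic" if prefix else "gene"
        return VariantDescriptor(
            position=int(pos), coordinate_system=system, kind="substitution",
            ref_base=ref, alt_base=alt,
        )
    m = _INS_RE.match(text)
    if m:
        prefix, pos, base, n = m.groups()
        system = "genomic" if prefix else "gene"
        return VariantDescriptor(
            position=int(pos), coordinate_system=system, kind="insertion",
            alt_base=base, insert_length=int(n) if n else 1,
        )
    m = _DEL_RE.match(text)
    if m:
        prefix, pos, base = m.groups()
        system = "genomic" if prefix else "gene"
        return VariantDescriptor(
            position=int(pos), coordinate_system=system, kind="deletion",
            ref_base=base,
        )
    raise ParseError(f"unrecognized variant notation: {text!r}")


def format_variant(variant: VariantDescriptor) -> str:
    """Render a descriptor in its canonical notation (``m.`` prefix for genomic)."""
    prefix = "m." if variant.coordinate_system == "genomic" else ""
    p = variant.position
    if variant.kind == "substitution":
        return f"{prefix}{p}{variant.ref_base}>{variant.alt_base}"
    if variant.kind == "insertion":
        n = f"({variant.insert_length})" if variant.insert_length != 1 else ""
        return f"{prefix}{p}Ins{variant.alt_base}{n}"
    return f"{prefix}{p}del{variant.ref_base}"


def format_dual(variant: VariantDescriptor) -> str:
    """Render the gene notation with the genomic one in brackets, e.g.
    ``908A>G (m.1555A>G)``."""
    return f"{format_variant(variant.to_gene())} ({format_variant(variant.to_genomic())})"


def validate_against_reference(variant: VariantDescriptor, reference: str) -> None:
    """Check that ``ref_base`` matches ``reference`` (a genomic-coordinate,
    1-based sequence string) at the variant's position.

    Raises :class:`ValidationError` on disagreement; silently accepts
    insertions (which carry no reference base).
    """
    if variant.ref_base is None:
        return
    g = variant.to_genomic()
    if g.position > len(reference):
        raise ValidationError(
            f"position {g.position} beyond reference of length {len(reference)}"
        )
    ref_there = as_rna(reference[g.position - 1])
    if ref_there != as_rna(g.ref_base):
        raise ValidationError(
            f"reference disagreement at m.{g.position}: descriptor says "
            f"{g.ref_base}, reference has {ref_there}"
        )


__all__ = [
    "GENE_LENGTH", "GENOMIC_OFFSET", "GENOMIC_START", "GENOMIC_END",
    "VariantDescriptor", "CoordinateError", "ParseError", "ValidationError",
    "gene_to_genomic", "genomic_to_gene", "parse_variant", "format_variant",
    "format_dual", "validate_against_reference", "as_rna",
]
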