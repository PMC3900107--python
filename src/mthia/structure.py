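"""Secondary-structure maps of SSU rRNAs and cross-species residue equivalence.

A :class:`StructureMap` holds, for every position of one molecule, the base
identity, the base-pairing partner (or none) and a helix label following the
standard small-subunit nomenclature (helices named after the E. coli 16S
model, lowercase ``h``).  Maps are read from CT or BPSEQ files plus a
sidecar annotation TSV carrying the helix labels, which neither format
encodes.

An :class:`EquivalenceTable` links mitochondrial 12S positions to their
structurally equivalent residues in a heterologous SSU rRNA (E. coli
numbering).  Positions lying in regions of little structural homology have
no equivalent (``not aligned``), which downstream forces the
``undetermined`` classification path.  The curated human/E. coli links for
the positions analysed in the packaged variant table ship as a fixture;
:func:`build_equivalence` reconstructs a table algorithmically for
synthetic or novel map pairs by aligning corresponding helices by pairing
register.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

from .nomenclature import GENE_LENGTH, as_rna

WATSON_CRICK = "watson_crick"
GU_WOBBLE = "gu_wobble"
MISMATCH = "mismatch"

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


class StructureError(ValueError):
    """Invalid structure map or equivalence input."""


def pair_class(b1: str, b2: str) -> str:
    """Classify a base pair: Watson-Crick, G:U wobble, or mismatch.

    G:U/U:G is kept distinct from canonical pairs here; scoring layers that
    follow the phylogenetic-map convention treat the two as structurally
    equivalent.  Symmetric in its arguments.
    """
    a, b = as_rna(b1), as_rna(b2)
    if a not in "ACGU" or b not in "ACGU":
        raise StructureError(f"invalid RNA bases for pairing: {b1!r}, {b2!r}")
    if (a, b) in _WC_PAIRS:
        return WATSON_CRICK
    if (a, b) in _GU_PAIRS:
        return GU_WOBBLE
    return MISMATCH


@dataclass
class StructureMap:
    """Per-position base, partner and helix label for one molecule."""

    organism: str
    bases: Dict[int, str]
    partners: Dict[int, Optional[int]]
    helices: Dict[int, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, base in self.bases.items():
            b = as_rna(base)
            if b not in "ACGU":
                raise StructureError(f"invalid base {base!r} at {pos}")
            self.bases[pos] = b
        for pos in self.bases:
            self.partners.setdefault(pos, None)
            self.helices.setdefault(pos, None)
        for pos, partner in self.partners.items():
            if partner is None:
                continue
            if partner == pos:
                raise StructureError(f"position {pos} pairs with itself")
            if partner not in self.bases:
                raise StructureError(f"partner {partner} of {pos} not in map")
            if self.partners.get(partner) != pos:
                raise StructureError(
                    f"asymmetric pairing {pos}:{partner} in {self.organism}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def __contains__(self, pos: int) -> bool:
        return pos in self.bases

    @property
    def positions(self) -> List[int]:
        return sorted(self.bases)

    def partner(self, pos: int) -> Optional[int]:
        if pos not in self.bases:
            raise StructureError(f"position {pos} not in {self.organism} map")
        return self.partners.get(pos)


def structural_state(smap: StructureMap, pos: int) -> Tuple[str, Optional[str]]:
    """Return ``("unpaired", None)`` or ``("paired", pair_class)`` for a
    position, combining partner lookup and base-pair classification."""
    partner = smap.partner(pos)
    if partner is None:
        return ("unpaired", None)
    return ("paired", pair_class(smap.bases[pos], smap.bases[partner]))


# -- CT / BPSEQ readers ----------------------------------------------------

def read_ct(path: str | Path, organism: str = "") -> StructureMap:
    """Read a CT file (1-based; column 5 = partner, 0 = unpaired).  The
    header line is optional."""
    bases: Dict[int, str] = {}
    partners: Dict[int, Optional[int]] = {}
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    for i, line in enumerate(lines):
        parts = line.split()
        if i == 0 and (len(parts) < 6 or not parts[0].isdigit()):
            continue  # header
        if len(parts) < 6:
            raise StructureError(f"malformed CT line: {line!r}")
        pos, base, partner = int(parts[0]), parts[1], int(parts[4])
        bases[pos] = base
        partners[pos] = partner if partner else None
    return StructureMap(organism=organism or Path(path).stem,
                        bases=bases, partners=partners)


def read_bpseq(path: str | Path, organism: str = "") -> StructureMap:
    """Read a BPSEQ file (``pos base partner`` triples, 0 = unpaired)."""
    bases: Dict[int, str] = {}
    partners: Dict[int, Optional[int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or ":" in line:
            continue  # skip headers/comments
        pos_s, base, partner_s = line.split()
        pos, partner = int(pos_s), int(partner_s)
        bases[pos] = base
        partners[pos] = partner if partner else None
    return StructureMap(organism=organism or Path(path).stem,
                        bases=bases, partners=partners)


def read_helix_annotation(path: str | Path) -> Dict[int, str]:
    """Read a sidecar helix-annotation TSV: position, helix_label."""
    labels: Dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["helix"].strip():
                labels[int(row["position"])] = row["helix"].strip()
    return labels


def attach_helices(smap: StructureMap, labels: Mapping[int, str]) -> StructureMap:
    for pos, label in labels.items():
        if pos not in smap:
            raise StructureError(f"helix annotation at unknown position {pos}")
        smap.helices[pos] = label
    return smap


# -- equivalence -----------------------------------------------------------

@dataclass
class EquivalenceTable:
    """Mapping mito gene position -> heterologous reference position (or
    not aligned).  ``seq_aligned`` flags links additionally supported by
    primary-sequence alignment of the two molecules."""

    links: Dict[int, Optional[int]]
    seq_aligned: Set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        aligned = [p for p, q in self.links.items() if q is not None]
        targets = [self.links[p] for p in aligned]
        if len(set(targets)) != len(targets):
            raise StructureError("equivalence must be injective on aligned positions")
        stray = self.seq_aligned - {p for p in aligned}
        if stray:
            raise StructureError(
                f"seq_aligned flag on unaligned positions: {sorted(stray)[:5]}"
            )

    def __contains__(self, pos: int) -> bool:
        return pos in self.links

    def inverse(self) -> "EquivalenceTable":
        inv = {q: p for p, q in self.links.items() if q is not None}
        return EquivalenceTable(links=inv)


def find_equivalent(equiv: EquivalenceTable, pos: int) -> Optional[int]:
    """Look up the heterologous equivalent of a mito position; ``None``
    (not aligned) signals the undetermined classification path."""
    return equiv.links.get(pos)


def _helix_pairs(smap: StructureMap, label: str) -> List[Tuple[int, int]]:
    """Base pairs of a helix ordered from the helix-closing pair outward
    (i.e. by ascending 5' position)."""
    pairs = []
    for pos in sorted(smap.bases):
        if smap.helices.get(pos) == label:
            partner = smap.partners.get(pos)
            if partner is not None and pos < partner:
                pairs.append((pos, partner))
    return pairs


def build_equivalence(
    map_a: StructureMap,
    map_b: StructureMap,
    helix_correspondence: Mapping[str, str],
) -> EquivalenceTable:
    """Link residues of two maps through corresponding helices.

    Within each corresponding helix, base pairs are aligned by pairing
    register: the k-th pair of one helix (counting along the 5' strand from
    the closing pair outward) links to the k-th pair of the other, partners
    linked symmetrically.  Unpaired residues (bulges, loops, junctions) are
    then aligned segment-wise between consecutive anchored positions, from
    the 5' end of each segment, ties toward 5'.  Positions in helices absent
    from the correspondence stay not aligned.
    """
    labels_a = {l for l in map_a.helices.values() if l}
    labels_b = {l for l in map_b.helices.values() if l}
    for la, lb in helix_correspondence.items():
        if la not in labels_a:
            raise StructureError(f"helix {la!r} absent from {map_a.organism} map")
        if lb not in labels_b:
            raise StructureError(f"helix {lb!r} absent from {map_b.organism} map")

    links: Dict[int, Optional[int]] = {p: None for p in map_a.bases}
    for la, lb in helix_correspondence.items():
        pairs_a = _helix_pairs(map_a, la)
        pairs_b = _helix_pairs(map_b, lb)
        for (a5, a3), (b5, b3) in zip(pairs_a, pairs_b):
            links[a5] = b5
            links[a3] = b3

    # segment-wise alignment of unanchored residues between anchors
    anchors = sorted(p for p, q in links.items() if q is not None)
    pos_a = map_a.positions
    pos_b = map_b.positions
    idx_b = {p: i for i, p in enumerate(pos_b)}
    used_b = {q for q in links.values() if q is not None}

    def segment_after(anchor_a: Optional[int], next_a: Optional[int]
                      ) -> Tuple[List[int], List[int]]:
        lo_a = pos_a.index(anchor_a) + 1 if anchor_a is not None else 0
        hi_a = pos_a.index(next_a) if next_a is not None else len(pos_a)
        seg_a = pos_a[lo_a:hi_a]
        if anchor_a is not None:
            lo_b = idx_b[links[anchor_a]] + 1
        else:
            lo_b = 0
        if next_a is not None:
            hi_b = idx_b[links[next_a]]
        else:
            hi_b = len(pos_b)
        seg_b = pos_b[lo_b:hi_b] if lo_b <= hi_b else []
        return seg_a, seg_b

    bounds = [None] + anchors + [None]
    for i in range(len(bounds) - 1):
        seg_a, seg_b = segment_after(bounds[i], bounds[i + 1])
        for qa, qb in zip(seg_a, seg_b):  # ties toward 5': zip truncates at 3'
            if qb not in used_b:
                links[qa] = qb
                used_b.add(qb)
    return EquivalenceTable(links=links)


# -- IO --------------------------------------------------------------------

def read_equivalence_tsv(path: str | Path) -> EquivalenceTable:
    """Read an equivalence TSV: gene_pos, ref_pos (empty = not aligned),
    seq_aligned (0/1)."""
    links: Dict[int, Optional[int]] = {}
    flags: Set[int] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pos = int(row["gene_pos"])
            ref = row["ref_pos"].strip()
            links[pos] = int(ref) if ref else None
            if row.get("seq_aligned", "0").strip() == "1" and ref:
                flags.add(pos)
    return EquivalenceTable(links=links, seq_aligned=flags)


def write_equivalence_tsv(equiv: EquivalenceTable, path: str | Path) -> None:
    lines = ["gene_pos\tref_pos\tseq_aligned"]
    for pos in sorted(equiv.links):
        ref = equiv.links[pos]
        lines.append(f"{pos}\t{'' if ref is None else ref}\t"
                     f"{1 if pos in equiv.seq_aligned else 0}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_curated_equivalence() -> EquivalenceTable:
    """Curated human 12S -> E. coli 16S residue links for the packaged
    variant table's positions; every other gene position is not aligned.

    The underlying map alignment was expert-curated from the
    phylogenetically derived secondary-structure maps of the two molecules,
    so it ships as data rather than being recomputed.
    """
    text = (resources.files("mthia.data") / "table2_variants.tsv").read_text()
    links: Dict[int, Optional[int]] = {p: None for p in range(1, GENE_LENGTH + 1)}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        ref = row["ecoli_pos"].strip()
        if ref:
            links[int(row["gene_pos"])] = int(ref)
    return EquivalenceTable(links=links)


__all__ = [
    "WATSON_CRICK", "GU_WOBBLE", "MISMATCH", "StructureError",
    "StructureMap", "EquivalenceTable", "pair_class", "structural_state",
    "find_equivalent", "build_equivalence",
    "read_ct", "read_bpseq", "read_helix_annotation", "attach_helices",
    "read_equivalence_tsv", "write_equivalence_tsv", "load_curated_equivalence",
]
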