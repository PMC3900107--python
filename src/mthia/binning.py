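"""Conservation-value binning of 12S rRNA positions and per-bin statistics.

Every gene position carries either a universal conservation value C_v
(computed at the Comparative RNA Web site from cross-domain SSU rRNA
alignments; ~2 means universal conservation, <0 none) or a ``not aligned``
flag for residues with no counterpart in the universal alignment.  Positions
are assigned to the standard C_v bins

    2 > C_v >= 1.9,  1.9 > C_v >= 1.5,  1.5 > C_v >= 1,
    1 > C_v >= 0,    C_v < 0,           Not aligned

(half-open, closed at the lower bound; C_v = 2 falls in the top bin), and a
variant census is summarized per bin: number of sites carrying variations,
total variations, percentages, per-site rates, and size-normalized counts.
Normalization scales each bin to the size of a reference bin, by default the
bin with the most variant-carrying sites (1 > C_v >= 0).

Known hotspot outliers can be subtracted before recomputation via an
explicit exclusion list; the packaged raw-count fixture carries the
hypervariable position 180 (m.827) with its 330 appearances.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .census import VariantCensus
from .nomenclature import GENE_LENGTH

BIN_TOP = "2 > Cv >= 1.9"
BIN_HIGH = "1.9 > Cv >= 1.5"
BIN_MID = "1.5 > Cv >= 1"
BIN_LOW = "1 > Cv >= 0"
BIN_NEG = "Cv < 0"
BIN_NOT_ALIGNED = "Not aligned"

BIN_ORDER = [BIN_TOP, BIN_HIGH, BIN_MID, BIN_LOW, BIN_NEG, BIN_NOT_ALIGNED]

DEFAULT_REFERENCE_BIN = BIN_LOW

_CRW_LETTERS = frozenset("ACGUN") | frozenset("acgun") | frozenset("owx")


class BinningError(ValueError):
    """Invalid conservation-table or binning input."""


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero at ``digits`` decimals (table convention)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConservationEntry:
    """Per-position conservation record: C_v and CRW category letter, or
    a not-aligned flag for residues absent from the universal alignment."""

    position: int
    cv: Optional[float] = None
    crw_letter: Optional[str] = None
    aligned: bool = True

    def __post_init__(self) -> None:
        if self.aligned:
            if self.cv is None or self.crw_letter is None:
                raise BinningError(
                    f"aligned position {self.position} needs cv and crw_letter"
                )
            if self.crw_letter not in _CRW_LETTERS:
                raise BinningError(
                    f"unknown CRW category letter {self.crw_letter!r}"
                )


@dataclass
class ConservationTable:
    """Conservation records for every position 1..length, exactly once."""

    entries: Dict[int, ConservationEntry]
    length: int = GENE_LENGTH

    def __post_init__(self) -> None:
        expected = set(range(1, self.length + 1))
        got = set(self.entries)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise BinningError(
                f"conservation table must cover 1..{self.length} exactly once "
                f"(missing {missing}, extra {extra})"
            )

    def __getitem__(self, pos: int) -> ConservationEntry:
        return self.entries[pos]

    @classmethod
    def from_records(cls, records: Iterable[ConservationEntry],
                     length: int = GENE_LENGTH) -> "ConservationTable":
        return cls(entries={r.position: r for r in records}, length=length)


def assign_bin(entry: ConservationEntry) -> str:
    """Assign a conservation record to its C_v bin label."""
    if not entry.aligned:
        return BIN_NOT_ALIGNED
    cv = entry.cv
    assert cv is not None
    if cv >= 1.9:
        return BIN_TOP
    if cv >= 1.5:
        return BIN_HIGH
    if cv >= 1.0:
        return BIN_MID
    if cv >= 0.0:
        return BIN_LOW
    return BIN_NEG


def normalize_count(count: float, bin_size: int, reference_bin_size: int) -> float:
    """Scale ``count`` from a bin of ``bin_size`` sites to the reference bin's
    size; reported to 2 decimals (half-up)."""
    if bin_size <= 0:
        raise BinningError("bin size must be positive")
    return round_half_up(count * reference_bin_size / bin_size)


@dataclass
class BinRawCounts:
    """Raw per-bin tallies from which every derived statistic follows."""

    size: int
    sites_with_variations: int
    total_variations: int
    excluded_sites: int = 0       # sites zeroed by outlier exclusion
    excluded_variations: int = 0  # variations removed by outlier exclusion

    def __post_init__(self) -> None:
        if self.sites_with_variations > self.size:
            raise BinningError("more variant-carrying sites than sites in bin")
        if self.excluded_variations > self.total_variations:
            raise BinningError("cannot exclude more variations than recorded")
        if self.excluded_sites > self.sites_with_variations:
            raise BinningError("cannot exclude more sites than carry variations")


@dataclass
class BinRow:
    """Derived statistics for one bin (plus outlier-excluded duplicates)."""

    label: str
    size: int
    sites_with_variations: int
    total_variations: float
    pct_sites_in_bin: float
    pct_sites_of_all_variant_sites: float
    normalized_sites: float
    normalized_variations: float
    variations_per_site: float
    sites_with_variations_excl: int
    total_variations_excl: float
    pct_sites_in_bin_excl: float
    normalized_variations_excl: float
    variations_per_site_excl: float


@dataclass
class BinStatistics:
    """Per-bin distribution statistics of a variant census (table shape:
    one row per bin plus totals)."""

    rows: Dict[str, BinRow]
    reference_bin: str
    totals: BinRow = field(init=False)

    def __post_init__(self) -> None:
        r = self.rows
        self.totals = BinRow(
            label="Totals",
            size=sum(x.size for x in r.values()),
            sites_with_variations=sum(x.sites_with_variations for x in r.values()),
            total_variations=sum(x.total_variations for x in r.values()),
            pct_sites_in_bin=float("nan"),
            pct_sites_of_all_variant_sites=100.0,
            normalized_sites=round_half_up(
                sum(x.normalized_sites for x in r.values())),
            normalized_variations=round_half_up(
                sum(x.normalized_variations for x in r.values())),
            variations_per_site=float("nan"),
            sites_with_variations_excl=sum(
                x.sites_with_variations_excl for x in r.values()),
            total_variations_excl=sum(
                x.total_variations_excl for x in r.values()),
            pct_sites_in_bin_excl=float("nan"),
            normalized_variations_excl=round_half_up(
                sum(x.normalized_variations_excl for x in r.values())),
            variations_per_site_excl=float("nan"),
        )

    def __getitem__(self, label: str) -> BinRow:
        return self.rows[label]


def derive_bin_statistics(
    raw: Mapping[str, BinRawCounts],
    reference_bin: str = DEFAULT_REFERENCE_BIN,
) -> BinStatistics:
    """Compute every derived column of the bin table from raw counts.

    Percentages and normalized counts are reported to 2 decimals (half-up).
    Normalization uses the actual bin sizes throughout.
    """
    if reference_bin not in raw:
        raise BinningError(f"reference bin {reference_bin!r} not in raw counts")
    ref_size = raw[reference_bin].size
    all_sites = sum(r.sites_with_variations for r in raw.values())
    rows: Dict[str, BinRow] = {}
    for label, r in raw.items():
        sites_excl = r.sites_with_variations - r.excluded_sites
        var_excl = r.total_variations - r.excluded_variations
        rows[label] = BinRow(
            label=label,
            size=r.size,
            sites_with_variations=r.sites_with_variations,
            total_variations=r.total_variations,
            pct_sites_in_bin=round_half_up(
                100.0 * r.sites_with_variations / r.size),
            pct_sites_of_all_variant_sites=round_half_up(
                100.0 * r.sites_with_variations / all_sites) if all_sites else 0.0,
            normalized_sites=normalize_count(
                r.sites_with_variations, r.size, ref_size),
            normalized_variations=normalize_count(
                r.total_variations, r.size, ref_size),
            variations_per_site=round_half_up(r.total_variations / r.size),
            sites_with_variations_excl=sites_excl,
            total_variations_excl=var_excl,
            pct_sites_in_bin_excl=round_half_up(100.0 * sites_excl / r.size),
            normalized_variations_excl=normalize_count(var_excl, r.size, ref_size),
            variations_per_site_excl=round_half_up(var_excl / r.size),
        )
    return BinStatistics(rows=rows, reference_bin=reference_bin)


def raw_counts_from_census(
    census: VariantCensus,
    conservation: ConservationTable,
    exclusions: Sequence[Tuple[int, int]] = (),
) -> Dict[str, BinRawCounts]:
    """Tally a gene-coordinate census into per-bin raw counts.

    ``exclusions`` lists ``(gene_position, excluded_count)`` hotspot outliers
    whose counts are subtracted in the ``*_excl`` columns; a site is removed
    from the excluded site tally only if the exclusion empties it.
    """
    census = census.to_gene()
    site_totals = census.site_totals
    for pos, cnt in exclusions:
        if site_totals.get(pos, 0) < cnt:
            raise BinningError(
                f"exclusion of {cnt} at position {pos} exceeds recorded "
                f"count {site_totals.get(pos, 0)}"
            )
    excl_by_pos = dict(exclusions)
    raw: Dict[str, BinRawCounts] = {}
    for label in BIN_ORDER:
        positions = [p for p in range(1, conservation.length + 1)
                     if assign_bin(conservation[p]) == label]
        if not positions:
            continue
        carrying = [p for p in positions if site_totals.get(p, 0) > 0]
        total = sum(site_totals.get(p, 0) for p in positions)
        excl_var = sum(excl_by_pos.get(p, 0) for p in positions)
        excl_sites = sum(
            1 for p in carrying if excl_by_pos.get(p, 0) == site_totals[p])
        raw[label] = BinRawCounts(
            size=len(positions),
            sites_with_variations=len(carrying),
            total_variations=total,
            excluded_sites=excl_sites,
            excluded_variations=excl_var,
        )
    return raw


def bin_statistics(
    census: VariantCensus,
    conservation: ConservationTable,
    exclusions: Sequence[Tuple[int, int]] = (),
    reference_bin: str = DEFAULT_REFERENCE_BIN,
) -> BinStatistics:
    """Full path: census + conservation table -> per-bin statistics."""
    raw = raw_counts_from_census(census, conservation, exclusions)
    return derive_bin_statistics(raw, reference_bin=reference_bin)


# -- IO --------------------------------------------------------------------

def read_conservation_tsv(path: str | Path) -> ConservationTable:
    """Read a conservation table TSV: gene_pos, cv (empty when not aligned),
    crw_letter, aligned (0/1)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            aligned = row["aligned"].strip() == "1"
            records.append(ConservationEntry(
                position=int(row["gene_pos"]),
                cv=float(row["cv"]) if aligned else None,
                crw_letter=row["crw_letter"] or None if aligned else None,
                aligned=aligned,
            ))
    length = max(r.position for r in records)
    return ConservationTable.from_records(records, length=length)


def write_conservation_tsv(table: ConservationTable, path: str | Path) -> None:
    lines = ["gene_pos\tcv\tcrw_letter\taligned"]
    for pos in range(1, table.length + 1):
        e = table[pos]
        cv = "" if e.cv is None else repr(e.cv)
        letter = e.crw_letter or ""
        lines.append(f"{pos}\t{cv}\t{letter}\t{1 if e.aligned else 0}")
    Path(path).write_text("\n".join(lines) + "\n")


_TABLE_COLUMNS = [
    "bin", "size", "sites_with_variations", "normalized_sites",
    "total_variations", "normalized_variations", "pct_sites_in_bin",
    "pct_sites_of_all_variant_sites", "variations_per_site",
    "sites_with_variations_excl", "total_variations_excl",
    "pct_sites_in_bin_excl", "normalized_variations_excl",
    "variations_per_site_excl",
]


def _fmt(x: float) -> str:
    return "" if x != x else f"{x:.2f}"  # NaN -> empty cell


def write_bin_table_tsv(stats: BinStatistics, path: str | Path) -> None:
    """Write the per-bin summary table (one row per bin plus totals)."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for label in BIN_ORDER + ["Totals"]:
        row = stats.totals if label == "Totals" else stats.rows.get(label)
        if row is None:
            continue
        lines.append("\t".join([
            row.label, str(row.size), str(row.sites_with_variations),
            _fmt(row.normalized_sites), _fmt(float(row.total_variations)),
            _fmt(row.normalized_variations), _fmt(row.pct_sites_in_bin),
            _fmt(row.pct_sites_of_all_variant_sites),
            _fmt(row.variations_per_site),
            str(row.sites_with_variations_excl),
            _fmt(float(row.total_variations_excl)),
            _fmt(row.pct_sites_in_bin_excl),
            _fmt(row.normalized_variations_excl),
            _fmt(row.variations_per_site_excl),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_bin_series_tsv(stats: BinStatistics, path: str | Path) -> None:
    """Long-format series (bin, statistic, value), the shape behind grouped
    bar charts of per-bin percentages and rates."""
    lines = ["bin\tstatistic\tvalue"]
    for label in BIN_ORDER:
        if label not in stats.rows:
            continue
        row = stats.rows[label]
        for stat in ("pct_sites_in_bin", "pct_sites_of_all_variant_sites",
                     "variations_per_site", "variations_per_site_excl",
                     "normalized_sites", "normalized_variations"):
            lines.append(f"{label}\t{stat}\t{_fmt(getattr(row, stat))}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_packaged_bin_counts() -> Dict[str, BinRawCounts]:
    """Raw per-bin counts for the GenBank 12S census (packaged fixture),
    including the m.827 hotspot exclusion in the top bin."""
    text = (resources.files("mthia.data") / "bin_counts.tsv").read_text()
    raw: Dict[str, BinRawCounts] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        label, size, sites, total, esites, evar = line.split("\t")
        raw[label] = BinRawCounts(
            size=int(size), sites_with_variations=int(sites),
            total_variations=int(total),
            excluded_sites=int(esites), excluded_variations=int(evar),
        )
    return raw


__all__ = [
    "BIN_TOP", "BIN_HIGH", "BIN_MID", "BIN_LOW", "BIN_NEG", "BIN_NOT_ALIGNED",
    "BIN_ORDER", "DEFAULT_REFERENCE_BIN", "BinningError",
    "ConservationEntry", "ConservationTable", "BinRawCounts", "BinRow",
    "BinStatistics", "assign_bin", "normalize_count", "derive_bin_statistics",
    "raw_counts_from_census", "bin_statistics", "round_half_up",
    "read_conservation_tsv", "write_conservation_tsv",
    "write_bin_table_tsv", "write_bin_series_tsv", "load_packaged_bin_counts",
]
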