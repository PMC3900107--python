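# Methods

## The inference problem

Direct biochemical tests of mitoribosome function are not available, so the
disruptive potential of a 12S rRNA variant is inferred from three sources:
how rare the variant is in large sequence collections, how universally
conserved its position is, and what is known — structurally and by
mutagenesis — about the structurally equivalent residue in a heterologous
ribosome (E. coli numbering throughout, since the bacterial SSU is the
best-characterized reference). The package implements each step as an
independent module so any of them can be used alone.

## Coordinates and notation

MT-RNR1 spans m.648–m.1601 of the rCRS (NC_012920.1); gene position p maps
to genomic position p+647, held in a single offset constant. Both
coordinate systems are 1-based and closed. Internally all base comparisons
run on the RNA alphabet (T→U); writers choose the alphabet from the
coordinate system, matching how the two notations are printed in the
clinical literature. The insertion multiplicity `(n)` defaults to 1 when
absent. Only this notation dialect is parsed — full HGVS is out of scope.

## Census

Samples are aligned to the reference one at a time with Biopython's
`PairwiseAligner` in global mode under affine-gap scoring (defaults:
match +1, mismatch −1, gap open −2, gap extend −1; the first base of a gap
costs the open penalty). Among co-optimal alignments the aligner's first
enumerated path is taken, which is deterministic for fixed inputs, so
calls are reproducible. Pre-aligned FASTA is accepted for users who prefer
an external multiple aligner. Samples deviating more than 10% from the
reference length are rejected up front.

Calling walks alignment columns: substitutions at the reference position,
deletions at the deleted position, insertions anchored to the preceding
reference position with the run length as multiplicity; mixed-base
insertion runs are reported base by base. `N` never yields a call and a
variant counts once per sequence record, with no haplotype de-duplication —
counts are per deposited record, as in the underlying databases.

The rarity screen is inclusive at the threshold: a combined count of
exactly 15 (the default) is still `review`.

## Conservation bins

Bins follow the standard C_v intervals, half-open and closed at the lower
bound; C_v = 2 falls in the top bin. Derived statistics are recomputed from
raw per-bin counts (bin size, variant-carrying sites, total variations), so
the same code serves both the census path and the packaged raw-count
fixture. Normalization scales a count by `reference_size / bin_size`; the
reference bin is configurable and defaults to `1 > C_v ≥ 0`, the bin with
the most variant-carrying sites. All reported derived values are rounded
half-up to 2 decimals.

Outlier exclusion takes an explicit `(position, count)` list; a site leaves
the carrying-sites tally only when the exclusion empties it. The packaged
fixture carries the m.827 hotspot (330 of the top bin's 333 appearances).

Two printed quirks of the source table are deliberately not reproduced: the
top bin's normalized values imply a divisor of 114 although the bin holds
115 sites (the recomputation uses 115 and yields 9.63/802.10 instead of
9.72/809.13), and the printed bin sizes sum to 955 for a 954-residue gene;
the totals row reports the fixture's sums as-is.

## Structure maps and equivalence

CT and BPSEQ are parsed 1-based with 0 = unpaired; the CT header line is
optional. Helix labels arrive via a sidecar TSV since neither format
carries them. Pairing must be symmetric and self-pairing is rejected.

The curated human↔E. coli equivalence for the analysed variant positions is
expert-derived from the phylogenetic secondary-structure maps and therefore
ships as data. For synthetic or novel map pairs, `build_equivalence` links
the k-th base pair of corresponding helices (counting along the 5′ strand
from the closing pair outward), partners symmetrically, then aligns
unanchored residues segment-wise between consecutive anchors from the 5′
end, ties toward 5′. The exact rule the original curators used for
loop/junction residues is not recorded anywhere; this register rule is a
deterministic reconstruction, and the table it produces is symmetric up to
inversion on aligned positions.

## Conservation indexes

The CRW letter → Ci_Univ map (x 0, w 1, o 2, lowercase 3, uppercase 4) is
not published as a table; it is fixed by requiring every (letter, value)
pair in the packaged variant table to hold simultaneously, which the test
suite re-verifies over all 39 fully populated rows. The value 5 is reserved
(accepted in inputs, never produced).

Window scores use the five ungapped gene positions centred on the tested
residue; windows truncate at molecule ends and slots without a heterologous
equivalent score 0 — the conservative reading of a "five-residue window".
For Ci_2ry, Watson–Crick and G:U/U:G count as the same predicted structure
(the convention of phylogenetically derived maps); a slot where one map
predicts a mismatch pair and the other a canonical/wobble pair earns the
half point, and paired-vs-unpaired earns nothing. Half-integer arithmetic
is exact in floating point, so `Ci_Tot = 2·Ci_Univ + 2·Ci_1ry + Ci_2ry` is
an identity enforced by the `CiScores` container itself.

Positions with no heterologous equivalent return `NI` (no information)
rather than a score. The `seq_aligned` bonus flag of the curated table is
not recoverable from the published record and is left unset there; it is
exercised through the synthetic generator, and the printed Ci values of the
analysed variants are carried as data.

## HIA rubric

Evidence is categorical: direct mutagenesis outranks indirect evidence,
and direct evidence requires at least one citation. Two deliberate mapping
choices: `N` (certainly not disruptive) lifts to the mitochondrial
`unlikely` bucket, because no mitochondrial "certainly-not" category exists
and the only tolerance-backed variant in the curated table sits under
`unlikely`; and `structural_context_conserved = unknown` is treated as
conserved, because heterologous conclusions transfer unless the structural
data actively disagree. The proven list is configuration, defaulting to
{847C>U, 908A>G}.

Among the 18 undetermined variants, the published record distinguishes the
two undetermined paths only implicitly: rows printed with an unknown
equivalent are encoded as not-aligned, and the eight rows that print Ci
values despite being undetermined (67A>U, 125A>G, 167A>G, 282A>U, 296G>A,
361A>U, 364C>A, 485U>C) are encoded as divergent-context.

## Synthetic data

The generators trade realism for exactness:

* **Populations** plant each variant in exactly its target count of
  sequences (uniform random carriers, seeded) on a uniform-random
  reference; planted positions must be ≥3 apart so alignments stay
  unambiguous and the align–call–tally round trip recovers every count
  exactly. Default reference length 1601 keeps rCRS 12S coordinates valid.
  No haplogroup structure, no sequencing error, no heteroplasmy — so a
  passing round trip shows the calling arithmetic is exact, not that the
  aligner is robust to messy real data.
* **Conservation tables** draw each position's bin from the real gene's
  composition (115/150/239/277/13 aligned + 161 not-aligned per 955) with
  a bin-consistent letter, so bin statistics see realistic proportions.
* **Structure pairs** are chains of hairpins (stems 4–8 bp, loops 3–6 nt,
  linkers 1–4 nt) with fully Watson–Crick stems; divergence applies base
  substitutions at the given rate and breaks pairs at `pair_break_rate`
  (default half the substitution rate; zero keeps pairing registers
  identical, which register-based equivalence reconstruction needs to
  recover links exactly). Ground-truth window scores are computed during
  generation by a separate straightforward loop, so the scoring engine is
  checked against independent code, not against itself.

## Pipeline and reporting

TSV is the canonical dialect (tab-delimited, UTF-8, `.` decimal, fixed
2-decimal formatting for derived statistics) with JSON mirrors; results
never go to stderr, logs never to stdout. Reruns with an identical config
are byte-identical. Stage failures propagate with the stage name.

## Problem sizes

The packaged fixtures are desk-scale (49 variants, 6 bins) and recompute in
well under a second. The census path is exercised at n = 1000 synthetic
sequences of length 1601 — the full public collection behind the original
counts (~17 850 genomes) is external data, and 1000 sequences exercise the
identical code path — plus 20-seed round trips at n = 25.

## Known limitations

* Ci_1ry/Ci_2ry for the real human/E. coli pair require the full curated
  structure maps, which are not redistributable here; the engine computes
  them for any supplied maps and is validated on synthetic pairs, while the
  published per-variant index values ship as data.
* C_v values and CRW letters are inputs, never recomputed from alignments.
* Evidence records are curated inputs; there is no literature mining, and
  no numeric weighting of citations — the rubric is categorical by design.
* Per-category averages of the published variant table are not reproduced:
  several printed averages are inconsistent with their own rows, so any
  summary statistics should be recomputed from row data.
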