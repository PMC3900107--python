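# mthia

Disruptive-potential analysis of human mitochondrial 12S rRNA (MT-RNR1)
variants.

More than 550 mtDNA variants have been linked to disease, but the rRNA
genes are the hardest place to establish pathogenicity: biochemical assays
on the mitoribosome are largely impossible, penetrance is incomplete, and
only two 12S mutations — 908A>G (m.1555A>G) and 847C>U (m.1494C>T), both
causes of aminoglycoside-sensitized hearing loss — are proven pathogenic.
`mthia` implements an inference chain for everyone who has to rank the
rest: clinical genetics labs triaging rare MT-RNR1 findings, and ribosome
biologists choosing which variants deserve mutagenesis follow-up.

## What it computes

**Variant census and rarity screen.** Sample sequences are globally aligned
to the rCRS reference (affine gaps, defaults +1/−1/−2/−1), differences are
called in reference coordinates and appearance counts tallied per variant.
Variants with 0 combined appearances are `extremely_rare`, 1–15 `review`,
more `common`.

**Conservation binning.** Every gene position carries a universal
conservation value C_v (≈2 = universally conserved, <0 = unconserved) or a
*not aligned* flag. Positions fall into the standard bins
`2 > C_v ≥ 1.9 … C_v < 0, Not aligned` (closed at the lower bound) and the
census is summarized per bin: % of sites carrying variations, variations
per site, and counts normalized to a reference bin's size, with explicit
subtraction of hotspot outliers such as m.827.

**Structure equivalence.** Secondary-structure maps (CT/BPSEQ plus a helix
annotation sidecar) of the mitochondrial 12S and a heterologous SSU rRNA
(E. coli numbering) are linked residue-by-residue; the curated human↔E. coli
links for all analysed variants ship as a fixture, and
`build_equivalence` reconstructs links for novel map pairs by pairing
register within corresponding helices.

**Conservation indexes.** Per position:

    Ci_Univ ∈ 0..5   from the CRW category letter (x→0, w→1, o→2,
                     lowercase→3, uppercase→4)
    Ci_1ry  ∈ 0..6   matched bases in the 5-residue window (+1 if the link
                     is also predicted by primary-sequence alignment)
    Ci_2ry  ∈ 0..5   matched structural states in the window, half a point
                     when a predicted mismatch is replaced by a
                     canonical/G:U pair or vice versa
    Ci_Tot  = 2·Ci_Univ + 2·Ci_1ry + Ci_2ry

**HIA classification.** Heterologous inferential analysis classifies the
structurally equivalent residue from curated evidence — direct mutagenesis
(→ `C` certainly / `N` certainly-not disruptive), otherwise indirect
evidence (→ `L` likely / `U` unlikely), otherwise `NEE` — and lifts the
verdict to the mitochondrial variant (`C`→expectedly, `L`→likely,
`U`/`N`→unlikely) unless the position has no equivalent or its structural
context diverges (→ undetermined). A configured proven list overrides
everything.

## Worked example

```python
from mthia import category_census, classify_all, load_packaged_evidence

counts = category_census(classify_all(load_packaged_evidence()))
print(counts)
```

prints

```
{'unlikely': 1, 'undetermined': 18, 'NEE': 14, 'likely': 5, 'expectedly': 9, 'proven': 2}
```

— of the 49 curated rare variants, 18 cannot be judged because the local
structure diverges too much or has no heterologous counterpart, 14 lack
evidence either way, and 14 are likely or expectedly disruptive; the two
proven deafness mutations are reported separately. The `examples/`
directory holds one short script per capability (coordinates, census,
binning, Ci scoring, classification, full pipeline); each prints the
numbers it computes and a line on what they mean. A thin CLI wraps the same
calls: `mthia census|screen|bins|ci|classify|simulate|run`.

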