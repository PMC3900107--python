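"""Variant notation and the two coordinate systems of the 12S rRNA gene.

The gene occupies positions m.648-m.1601 of the rCRS, so gene position p
maps to genomic position p + 647.  Gene notation uses the RNA alphabet
(U), genomic notation the DNA alphabet (T).
"""

from mthia import format_dual, gene_to_genomic, genomic_to_gene, parse_variant

# the two proven pathogenic deafness mutations, in both systems
for text in ("908A>G", "847C>U", "m.827A>G", "314InsC(5)", "314delU"):
    v = parse_variant(text)
    print(f"{text:>12}  ->  {format_dual(v)}")

print()
print("gene 908  -> m.", gene_to_genomic(908))
print("m.1494    -> gene", genomic_to_gene(1494))
# The dual rendering above is exactly how these variants are cited in the
# clinical literature: gene position first, rCRS position in brackets.
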