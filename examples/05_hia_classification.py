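"""HIA classification of the packaged 49-variant evidence collection.

Each variant's heterologous equivalent is classified from curated evidence
(direct mutagenesis > indirect evidence > nothing), then lifted to the
mitochondrial category unless the position has no equivalent or its
structural context diverges (undetermined).  The two established deafness
mutations sit on the proven list.
"""

from mthia import category_census, classify_all, load_packaged_evidence
from mthia.hia import CATEGORY_ORDER
from mthia.nomenclature import format_dual

records = load_packaged_evidence()
classifications = classify_all(records)
counts = category_census(classifications)

for cat in CATEGORY_ORDER:
    print(f"{cat:>13}: {counts[cat]}")
print()
print("expectedly disruptive variants:")
for c in classifications:
    if c.mito_category == "expectedly":
        print("  ", format_dual(c.mito_variant))
# Counts 1/18/14/5/9 (+2 proven): most rare variants cannot be judged
# (undetermined/NEE), but 14 carry enough heterologous evidence to be
# called likely or expectedly disruptive - the prioritization list a
# diagnostic lab would take into functional follow-up.
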