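"""Distribution of variant appearances across conservation-value bins.

Recomputes the per-bin statistics from the packaged raw counts of the
GenBank 12S census: sites carrying variations, variations per site, and
counts normalized to the reference bin's size.  The hypervariable site at
m.827 (330 of the top bin's 333 appearances) is subtracted in the
outlier-corrected columns.
"""

from mthia import derive_bin_statistics, load_packaged_bin_counts
from mthia.binning import BIN_ORDER

stats = derive_bin_statistics(load_packaged_bin_counts())

print(f"{'bin':<16}{'sites':>6}{'varying':>9}{'%':>7}"
      f"{'vars':>7}{'vars/site':>11}{'corrected':>11}")
for label in BIN_ORDER:
    row = stats[label]
    print(f"{label:<16}{row.size:>6}{row.sites_with_variations:>9}"
          f"{row.pct_sites_in_bin:>7.2f}{row.total_variations:>7.0f}"
          f"{row.variations_per_site:>11.2f}"
          f"{row.variations_per_site_excl:>11.2f}")
t = stats.totals
print(f"{'Totals':<16}{t.size:>6}{t.sites_with_variations:>9}{'':>7}"
      f"{t.total_variations:>7.0f}")
# Only 3.48% of the near-universally conserved sites vary at all, and after
# removing the m.827 hotspot they average 0.03 variations/site, against
# 41.40 in the not-aligned bin: variation is strongly anti-correlated with
# universal conservation, which is what makes rarity + conservation a
# usable screen for candidate disruptive variants.
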