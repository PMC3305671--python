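"""Score a synthetic stained section with randomly placed square regions.

Mimics the blinded liver protocol: five square scoring regions of roughly
200 cells each, placed at random fully inside the tissue, each subdivided
by a 10 x 10 graticule; the per-animal value is the pooled percent positive.
"""

import mosaicstripes as ms
from mosaicstripes.sections import score_section

section = ms.simulate_section(n_cells=10_000, p=0.7, seed=7)
# cells are 8 px squares here, so a 113 px region holds ~200 cell centroids
counts = score_section(section, region_size=113, n_regions=5, seed=7)

for c in counts:
    print(f"region {c.region_id} at {c.region_origin}: "
          f"{c.n_positive:4d} positive, {c.n_negative:4d} negative "
          f"({100 * c.fraction_positive:.1f}% positive)")

pooled = ms.section_percent_positive(counts)
print(f"\npooled percent positive: {100 * pooled:.1f}%  "
      f"(true mixing fraction: {100 * section.p_true:.0f}%)")
print("Pooling the raw tallies gives the per-animal value entered into the")
print("genotype x age comparison.")
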