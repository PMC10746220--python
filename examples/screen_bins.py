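"""Screen toy genome bins for putative eukaryotic MAGs and tier them.

Generates bins straddling the screening thresholds (2.5 Mbp length, 90%
eukaryotic content by length, scaled down 50x here for speed), screens
each, and dereplicates a trio of genomes by ANI.
"""

import numpy as np

from eukmag import (
    ANIMatrix, BinRecord, dereplicate, screen_eukaryotic_bin,
    tier_prokaryotic_quality, make_toy_bins,
)
from eukmag.bin_screen import build_bin_records

THRESHOLD = 50_000  # toy scale; the field default is 2_500_000 bp

bins = make_toy_bins(n_bins=5, seed=1, length_threshold=THRESHOLD)
records = build_bin_records(bins.membership, bins.domains, bins.quality)

print("bin screening (pass needs length >", THRESHOLD,
      "AND euk fraction > 0.9):")
for rec in records:
    res = screen_eukaryotic_bin(rec, THRESHOLD, 0.9)
    print(f"  {rec.bin_id:22s} len={rec.total_length:7d} "
          f"euk={res.euk_fraction:5.3f} -> {'PASS' if res.passed else 'fail'}"
          + (f"  ({'; '.join(res.reasons)})" if res.reasons else ""))

print("\nprokaryote quality tiers (completeness, contamination):")
for comp, cont in [(95, 2), (90, 2), (80, 8), (80, 12)]:
    print(f"  ({comp:4.1f}, {cont:4.1f}) -> {tier_prokaryotic_quality(comp, cont).value}")

# ANI dereplication: A and B are the same population (>=99% identity);
# A wins representative because S = comp - 5*cont + 0.5*log10(N50) favors it.
ani = ANIMatrix(["A", "B", "C"], np.array(
    [[100.0, 99.5, 90.0], [99.5, 100.0, 90.0], [90.0, 90.0, 100.0]]))
genomes = [
    BinRecord("A", [], 5_000_000, 0, checkm_completeness=96,
              checkm_contamination=1, n50=100_000),
    BinRecord("B", [], 5_100_000, 0, checkm_completeness=99,
              checkm_contamination=4, n50=100_000),
    BinRecord("C", [], 4_000_000, 0, checkm_completeness=80,
              checkm_contamination=2, n50=50_000),
]
result = dereplicate(genomes, ani)
print("\nANI >= 99% clusters and their representatives:")
for members, rep in zip(result.clusters, result.representatives):
    print(f"  cluster {members} -> representative {rep}")
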