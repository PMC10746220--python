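"""Reconcile ab initio and protein-evidence exon tracks for two loci.

Locus g1: 4 ab initio vs 3 evidence exons (agreement 0.75 >= 0.70), so
the unsupported interior ab initio exon is deleted.  Locus g2: 2 vs 4
(agreement 0.5 < 0.70), so nothing is deleted but evidence-only exons
are added.
"""

from eukmag.gene_merge import AB_INITIO, EVIDENCE, Exon, GeneLocus, merge_locus


def mk(ivs, src):
    return [Exon("ctg1", s, e, "+", src) for s, e in ivs]


g1 = GeneLocus(
    "g1",
    mk([(1, 100), (200, 300), (400, 500), (600, 700)], AB_INITIO),
    mk([(1, 100), (400, 500), (600, 700)], EVIDENCE),
)
g2 = GeneLocus(
    "g2",
    mk([(1, 100), (600, 700)], AB_INITIO),
    mk([(1, 100), (200, 300), (400, 500), (600, 700)], EVIDENCE),
)

for locus in (g1, g2):
    merged = merge_locus(locus)
    print(f"{locus.locus_id}: |ab|={len(locus.ab_exons)} |ev|={len(locus.ev_exons)} "
          f"agreement={merged.agreement_ratio:.2f}")
    for exon, src in zip(merged.exons, merged.provenance):
        print(f"   [{exon.start:4d}, {exon.end:4d}]  {src}")
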