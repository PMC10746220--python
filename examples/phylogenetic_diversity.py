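"""Phylogenetic diversity and gain on a toy tree.

Tree ((A:1,B:2):1,C:4): the leaf pair {A,B} spans only its two pendant
edges (PD = 3); adding C traverses the remaining 5 units of branch
length, so gain({C} | {A,B}) = 5.
"""

from eukmag import phylogenetic_diversity, phylogenetic_gain
from eukmag.io_formats import read_newick, total_tree_length

tree = read_newick("((A:1,B:2):1,C:4);", is_string=True)
print("total tree length:", total_tree_length(tree))

for leaves in ({"A", "B"}, {"A", "C"}, {"A", "B", "C"}):
    res = phylogenetic_diversity(tree, leaves)
    print(f"PD{sorted(leaves)} = {res.diversity:g} "
          f"({res.diversity_percent:.1f}% of the tree)")

res = phylogenetic_gain(tree, focal={"C"}, base={"A", "B"})
print(f"gain of C over {{A,B}}: {res.gain:g} "
      f"({res.gain_percent:.1f}% of the combined PD {res.diversity:g})")
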