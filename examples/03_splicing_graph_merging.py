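"""Merge 'always showing together' read types via the splicing graph.

Read types generated by exactly the same set of isoforms carry the same
signal; merging them cuts the number of hypotheses per gene without
losing the equivalence between the type-level and isoform-level nulls.
"""

import sys

from sgnb import build_graph, merge_always_together

# observed chains of a gene with a skipped exon: isoforms 1-2-3 and 1-3
chains = [(1,), (1, 2), (1, 3), (2,), (2, 3), (3,)]
sg = build_graph("demo", chains)
sg.to_dot(sys.stdout)

groups = merge_always_together(sg)
print("\nmerged groups:")
for g in groups:
    print(" ", g.label)
# Node "1" keeps out-degree 2 (continuations 1-2 and 1-3), so it stays a
# singleton: both isoforms generate it. The exon-2 types ("1-2", "2",
# "2-3") chain together with in/out degree 1 and merge into one group --
# they all require the exon-inclusion isoform. 6 tests become 4.
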