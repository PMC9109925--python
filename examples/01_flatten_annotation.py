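"""Flatten overlapping GTF exons into integer-ID exon bins.

Read types are only unambiguous over disjoint exons: a read landing in a
region shared by two annotated exons has no unique exon ID until the
annotation is partitioned.
"""

import io

from sgnb import flatten_annotation, parse_annotation, write_flat_annotation

GTF = """\
chr1\tdemo\texon\t100\t250\t.\t+\t.\tgene_id "demo_gene"; transcript_id "t1";
chr1\tdemo\texon\t200\t400\t.\t+\t.\tgene_id "demo_gene"; transcript_id "t2";
chr1\tdemo\texon\t600\t800\t.\t+\t.\tgene_id "demo_gene"; transcript_id "t1";
"""

models = flatten_annotation(parse_annotation(io.StringIO(GTF)))
out = io.StringIO()
write_flat_annotation(models, out)
print(out.getvalue())
# The two overlapping exons (100-250, 200-400) become three disjoint bins
# with IDs 1..3 (the overlap 200-250 is its own bin), and the distal exon
# becomes bin 4. Every genomic base now belongs to exactly one exon ID,
# so every aligned read maps to exactly one exon-ID chain.
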