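# sgnb — isoform-level differential expression without isoform annotation

`sgnb` implements a splicing-graph negative binomial (SGNB) test for
two-condition RNA-seq differential expression at the *isoform* level that
needs only exon ranges, not transcript structures. It is aimed at studies —
in particular of non-model organisms — where isoform annotation is missing
or unreliable, and at the scenario that defeats gene-level tools: an
**isoform switch**, where a gene's total expression is unchanged but its
isoform composition flips.

## The method

Gene-level tools compare the total isoform size of a gene, Σᵢ kᵢ·lᵢ
(copy number × length), between conditions. SGNB instead tests **read
types**: each aligned single-end read is reduced to the ordered chain of
exon IDs it touches ("1", "2-4", ...), after the gene's annotated exons
have been flattened into non-overlapping exons numbered 1..E. For gene g,
read type h and sample j the counts are modeled as

    X_ghj ~ NB(N*_j · θ_gh, φ_gh),

where N\*_j is the TMM-effective library size, θ_gh the relative
expression of the type and φ_gh an overdispersion common to the two
conditions. The type-level means relate to the unobserved isoform copy
numbers through θ⃗_g = P_g k⃗_g, with P_g the type-by-isoform matrix of
start-position fractions; when P_g has full column rank, the isoform-level
null k⃗⁰ = k⃗¹ is equivalent to the testable type-level null θ⃗⁰ = θ⃗¹.

Estimation and testing follow the quantile-adjusted conditional maximum
likelihood scheme: counts are mapped to a common library size N\* by NB
mid-quantile matching ("pseudo counts"), φ is estimated by maximizing the
conditional likelihood given each condition's pseudo-count sum, θ by a
Gamma–Poisson EM, and the two-condition comparison is an exact conditional
test of Z⁰ | Z⁰+Z¹. Per gene, read-type p-values are Bonferroni-combined
(gene_p = m · min p); across genes either Bonferroni or Benjamini–Hochberg
is applied.

To avoid testing every read type, a **splicing graph** over the observed
chains (edges: append-one-exon or drop-first-exon continuations, plus
pseudo START/END nodes) identifies types that are "always showing
together" — generated by exactly the same isoform set, hence proportional
rows of P_g. Chains of nodes with out-degree = in-degree = 1 are merged
into a single test, reducing hypotheses without losing rank.

The package also ships a polyester-style mechanistic read simulator
(fragmentation, truncated-Normal fragment lengths, per-transcript NB
noise) with exhaustive start-position oracles (l_gih, P_g, true
always-showing-together classes), and a gene-level total-count exact test
as the built-in baseline.

## Worked example

`examples/04_isoform_switch_test.py` simulates a 10-gene transcriptome in
which one gene has two similar-length isoforms at expected copies (10, 50)
in condition 0 and (50, 10) in condition 1 — equal totals, flipped
composition — with 20 samples per condition, and analyzes it both ways:

```
SGNB gene-level results (sorted by gene p):
          m         min_p        gene_p    bonferroni            bh
gene_id
switch    4  7.797118e-68  3.118847e-67  2.806962e-66  2.806962e-66
gene0002  1  3.703279e-02  3.703279e-02  3.332951e-01  1.666476e-01
gene0005  4  6.391704e-02  2.556681e-01  1.000000e+00  7.670044e-01

gene-level total-count baseline, switch gene:
            z0     z1   p_value  bonferroni
switch   45836  46050  0.933606         1.0
```

The switch gene's read-type composition flips five-fold, so the SGNB test
(m = 4 merged read-type groups) drives its gene-level p-value to ~1e-67,
while the total-count baseline sees nearly identical condition sums
(45 836 vs 46 050 pseudo reads) and reports p = 0.93: the switch is
invisible at the gene level. The other examples cover exon flattening,
SAM-based read-type counting, graph merging, and FDR/TPR benchmarking; a
thin CLI (`sgnb flatten|count|merge|test|simulate|benchmark`) wraps the
same functions for shell use.

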