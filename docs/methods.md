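# Methods

This note records the model, the estimation choices, what the synthetic
data does and does not emulate, and the numerical decisions a maintainer
would want to know. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

Reads are summarized to **read types**: the gene's annotated exons are
flattened into disjoint exons numbered 1..E left-to-right (strand is
recorded but ignored for numbering — the method only needs a consistent
order), and a read's type is the ordered chain of exon IDs its aligned
blocks touch. Reads with bases outside all flat exons, or touching exons
of more than one gene, are discarded: the model assumes each read comes
from one gene, and a partial-type notion does not exist.

Under simple random sampling of reads, the count of type h of gene g in
sample j is Poisson with mean proportional to N_j Σᵢ p_gih K_gij l_gi·/S_j,
where p_gih = l_gih / l_gi· is the fraction of start positions on isoform
i yielding type h. Because all isoforms share one exon structure, l_gih is
either 0 or a type constant l_g·h ("two-valuedness"; asserted exactly in
the tests). Letting the per-sample copy numbers be Gamma-distributed and
integrating them out gives the working marginal

    X_ghj ~ NB(N*_j θ_gh, φ_gh),   Var = μ + φ μ²,

with common dispersion across conditions. The isoform-level null
k⃗⁰ = k⃗¹ equals the type-level null θ⃗⁰ = θ⃗¹ whenever P_g = (p_gih) has
full column rank; the test suite checks rank preservation of the merging
step on every simulated gene where full rank holds.

## Normalization

TMM with the published defaults: reference sample = the one whose
upper-quartile count fraction is closest to the across-sample mean; per
sample, a precision-weighted mean of log2 ratios M after trimming 30% of
M at each end and 5% of A; factors renormalized to geometric mean 1;
effective size N*_j = N_j f_j. The implementation is pinned by a
dual-implementation oracle and by a direct comparison against edgeR's
`calcNormFactors` (agreement to ~1e-6 apart from rank ties at the trim
boundaries, which R may resolve differently in floating point).

## Estimation

For one read-type group with counts x_j:

1. **θ for fixed φ** — EM on the latent Gamma rates of the Gamma–Poisson
   mixture: E-step E[Θ_j|x_j] = (x_j + 1/φ)/(N*_j + 1/(φθ)), M-step θ ←
   mean of posterior means; stop at relative change < 1e-8 or 200
   iterations; φ = 0 (or all-zero counts) returns Σx/ΣN* in closed form.
   The EM is validated against a fine grid search of the marginal NB
   likelihood and checked to ascend it, so its correctness does not hinge
   on the specific update chosen.
2. **Pseudo counts** — each count is pushed through the mid-quantile
   u = F(x) − p(x)/2 of NB(N*_j θ, φ) and inverted on the NB(N* θ, φ)
   scale, interpolating linearly between integer support points. N* is
   the geometric mean of the effective sizes — the common-size target is
   otherwise arbitrary, and the geometric mean minimizes distortion in
   both directions. Equal sizes give the exact identity; zero maps to
   zero; counts whose mid-quantile falls below the target's first support
   point are clamped at zero (mapping is then weakly monotone). The θ
   used here is the pooled-condition estimate, matching the use of pooled
   abundance in edgeR's quantile adjustment.
3. **φ by CML** — maximize the sum over the two conditions of the
   conditional log-likelihood given each condition's pseudo-count sum
   (the four-log-gamma form; terms free of φ dropped; the φ→0 limit
   −z·log J is used at φ = 0). Scalar bounded search on [1e-6, 10],
   xatol 1e-6; bound hits are flagged. Steps 1–3 alternate until
   |Δφ|/max(φ, 1e-4) < 1e-4 or 20 outer iterations.

Pseudo counts stay real-valued through estimation and are rounded (half
up) only when forming the condition sums z⁰, z¹ for the exact test, which
needs integer support. Per-condition θ̂⁰, θ̂¹ are re-estimated once at the
final φ̂ for reporting.

## Testing

With A ~ NB(J⁰N*θ̂, φ̂/J⁰) and B ~ NB(J¹N*θ̂, φ̂/J¹), the conditional mass
of a = z⁰ given z = z⁰+z¹ is q(a) ∝ P(A=a)P(B=z−a). The two-sided p-value
sums all outcomes with q(a) ≤ q(z⁰)(1+1e-10) — the standard minimum-
likelihood convention for two-sided exact tests; a doubled-smaller-tail
convention would be an equally defensible reading, and the choice is
pinned by enumeration and Poisson-limit oracles. θ̂ here is the pooled
conditional estimate (z⁰+z¹)/((J⁰+J¹)N*). For dispersions below 1e-8 the
rising factorial in the NB log-pmf is accumulated directly
(Σ log(r+i)) because gammaln(a+r) − gammaln(r) cancels catastrophically
for r ≫ 1e8; z = 0 returns p = 1.

Genes: gene_p = min(1, m · min p) over the gene's tested groups; groups
with zero total count carry no information and are excluded from both
testing and m. Across genes both Bonferroni and BH are emitted; the
caller picks (the benchmark uses Bonferroni; `gene_p` can be used
unadjusted for calibration studies).

The **gene-level baseline** collapses each gene to one total count per
sample and runs the identical NB machinery with m = 1. It is the
package's internal stand-in for classic gene-level exact-test tools and
is deliberately blind to composition changes.

## Splicing graph and merging

The graph over a gene's observed chains has an edge u → v iff v extends u
by exactly one exon appended after its last ID, or v is u with its first
ID dropped; START attaches to the lexicographically smallest chain, the
largest chain attaches to END (elementwise integer order, shorter prefix
first). An edge u → v with out-degree(u) = in-degree(v) = 1 (pseudo-node
edges counted — the conservative reading at gene ends) forces u and v to
share their generating isoform set, and such stretches merge
transitively. The construction cannot be proven complete for arbitrary
unknown isoform structures; instead, the suite verifies on hundreds of
simulated gene models that (a) every merged pair truly shares its
generating-isoform set, and (b) row-summing merged groups preserves the
rank of P_g whenever it has full column rank. Merging operates on
observed types only (total count ≥ 1); with finite reads a branch type
may go unobserved and allow a merge the full type set would forbid, which
matters only when the unobserved branch carries information — i.e. never
at the counts where the test has power.

## Synthetic data

The mechanistic simulator emulates a polyester-style single-end study:

| parameter | default | meaning |
|---|---|---|
| copy law | NB(μ=10, σ²=210) | base isoform copy numbers k_gi |
| fragment length | Normal(250, 25) bp, truncated to [read_len, L] | fragmentation |
| read length | 100 bp | leftmost bases of the fragment |
| reads per gene | 1000 per sample | ~20M reads / 20k genes scaled down |
| dispersion const c | 5 (low) or 30 (high) | per-transcript NB size = mean/c |
| DE fraction | 0.30 | genes with per-isoform log2 FC ~ N(0, 1) |
| gene structure | 3–10 exons of 80–500 bp, 1–4 isoforms | both mergeable chains and branch points |

Gene structures are random stand-ins (with both terminal exons forced
into every isoform) for a real chromosome-scale annotation, which would
require an external download. Per-sample copies get NB noise with size
mean·yield/c (yield = expected reads per copy), so read counts inherit
the var = μ + c·μ relation; reads are then allocated multinomially with
weights K_gij × usable length and typed by the same exhaustive
start-position walk that defines l_gih. The isoform-switch preset uses
five exons with two equal-length alternative internal exons, isoforms
1-2-3-5 / 1-2-4-5 at copies (10, 50) vs (50, 10).

Two deliberate departures from idealization are worth knowing:

- **Fragment-end bias.** Because the read is the leftmost 100 bp of a
  ~250 bp fragment, start positions in the last ~150 bp of a transcript
  are undersampled, so observed type frequencies are *not* exactly
  proportional to l_gih. The simulator's exact fragment-averaged type law
  is exposed (`expected_type_probabilities`) and is the oracle used by
  the distributional tests; l-proportionality holds exactly only for the
  pure start-position walk. SGNB itself never uses l, so this bias is a
  realism feature, not a nuisance.
- **Compositional coupling.** Each sample's reads total a fixed number,
  so gene counts are shares of a multinomial. For transcriptomes of a
  handful of genes where one gene is a large fraction of the library,
  the NB model is visibly misspecified and the tests (including the
  gene-total baseline) become anti-conservative; at the 10-gene scale
  and above the null behavior is uniform (checked by KS in the suite).
  Real transcriptomes are far into the safe regime.

Passing tests on these simulations show the pipeline recovers what this
generator encodes — NB-like type counts with isoform-driven composition;
they do not certify behavior under positional/GC bias, sequencing error,
multi-mapping or paired-end inserts, none of which are modeled.

The model-based sampler (`simulate_counts_model`) draws NB counts
directly at the type level and is the fast path for estimator tests.

## Problem sizes

The shipped checks use desk-scale versions of the study design, chosen
to make every stage verifiable by brute force: the switch experiment is
100 replicates of 10 genes × 40 samples × 1000 reads/gene; type-I
calibration uses one all-null replicate of 300 genes at 15 samples per
condition; merging soundness enumerates 200 random gene models; power
ordering uses 10 replicates of 100 genes. The per-group sample size for
the switch experiment is fixed at 20 per condition (the larger-scale
simulations span 5–20).

## Known limitations

- Two-sided region convention for the exact test is the
  minimum-likelihood rule; ranks of ties are tolerated at 1e-10 relative.
- Dispersion is estimated per read-type group with no
  information-sharing across groups (no empirical-Bayes moderation);
  at very small sample sizes the test inherits the usual CML noise and,
  as the calibration tests show, needs moderate sample sizes (≈15+ per
  condition) for near-nominal type-I error.
- Paired-end mates, if present in a SAM, are typed as two single-end
  reads; insert-size information is unused.
- Multi-mapped reads: only primary alignments are counted.
- Genes whose exons overlap another gene's exons are flattened
  independently; reads in shared regions are discarded rather than
  assigned.
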