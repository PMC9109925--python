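"""Synthetic RNA-seq generator and brute-force ground-truth oracles.

The mechanistic simulator emulates a polyester-style single-end study:
isoform copy numbers are NB(mean 10, variance 210); per-sample copies
get NB noise whose size parameter is mean·yield/c for a per-transcript
dispersion constant c (5 = low noise, 30 = high); fragments are
Normal(250, 25) long, truncated to [read length, transcript length];
the read is the leftmost 100 bases of the fragment; each sample yields
1000 reads per gene on average. About 30% of genes can be made DE with
per-isoform log2 fold changes drawn from N(0, 1), and a dedicated
isoform-switch preset flips two isoforms between expected copies
(10, 50) and (50, 10) while holding the gene's total size fixed.

The oracles are exhaustive walks over read start positions: they yield
the per-isoform start-position counts l_gih, the type-by-isoform matrix
P_g with entries p_gih = l_gih / l_gi., and the true "always showing
together" classes (types with identical generating-isoform sets), which
pin down the splicing-graph merging and the rank-preservation argument
at desk scale. A model-based sampler draws read-type counts directly
from NB(N*_j θ_gh, φ_gh) as a fast path for estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FlatExon, GeneModel, GenomicInterval
from .read_typing import CountTable, DesignInfo, chain_label

Chain = tuple[int, ...]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic transcriptome."""

    n_genes: int = 10
    samples_per_condition: int = 20
    copy_mean: float = 10.0
    copy_var: float = 210.0
    frag_mean: float = 250.0
    frag_sd: float = 25.0
    read_len: int = 100
    reads_per_gene: int = 1000
    dispersion_const: float = 5.0
    de_fraction: float = 0.30
    lfc_mean: float = 0.0
    lfc_sd: float = 1.0
    exon_count_range: tuple[int, int] = (3, 10)
    exon_len_range: tuple[int, int] = (80, 500)
    isoform_range: tuple[int, int] = (1, 4)
    intron_len_range: tuple[int, int] = (100, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copy_var <= self.copy_mean:
            raise ValueError("copy_var must exceed copy_mean (NB overdispersion)")
        for name in ("n_genes", "samples_per_condition", "read_len", "reads_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def copy_nb_size(self) -> float:
        """NB size parameter of the copy-number law: mu^2 / (var - mu)."""
        return self.copy_mean**2 / (self.copy_var - self.copy_mean)


@dataclass
class IsoformModel:
    """Ground-truth isoform structure of one simulated gene."""

    gene_id: str
    chains: list[Chain]
    exon_lengths: dict[int, int]
    read_len: int

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("gene needs >= 1 isoform")
        exon_ids = sorted(self.exon_lengths)
        first, last = exon_ids[0], exon_ids[-1]
        for c in self.chains:
            if list(c) != sorted(set(c)):
                raise ValueError(f"chain {c} not strictly increasing")
            if c[0] != first or c[-1] != last:
                raise ValueError(f"chain {c} must contain terminal exons {first},{last}")

    def transcript_length(self, chain: Chain) -> int:
        return sum(self.exon_lengths[e] for e in chain)

    def usable_length(self, chain: Chain) -> int:
        """l_gi.: number of possible read start positions on the isoform."""
        return self.transcript_length(chain) - self.read_len + 1


def _types_along(chain: Chain, exon_lengths: dict[int, int], read_len: int):
    """Type id per start position, plus the id -> chain mapping.

    A read starting at transcript position s (1-based) covers bases
    s..s+read_len-1; its type is the sub-chain of exons those bases
    touch. Returns (type_ids array over starts, list of chains).
    """
    lengths = np.array([exon_lengths[e] for e in chain])
    total = int(lengths.sum())
    n_starts = total - read_len + 1
    if n_starts <= 0:
        return np.empty(0, dtype=np.int64), []
    cum = np.cumsum(lengths)
    s = np.arange(1, n_starts + 1)
    i0 = np.searchsorted(cum, s)
    i1 = np.searchsorted(cum, s + read_len - 1)
    key = i0 * (len(chain) + 1) + i1
    uniq, ids = np.unique(key, return_inverse=True)
    chains = [tuple(chain[k // (len(chain) + 1): k % (len(chain) + 1) + 1]) for k in uniq]
    return ids, chains


def enumerate_start_positions(chain: Chain, exon_lengths: dict[int, int], read_len: int) -> dict[Chain, int]:
    """Exact per-type start-position counts on one isoform (brute force).

    Walks every start position 1..L-read_len+1; the counts sum to the
    usable length. A transcript shorter than the read yields {}.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    ids, chains = _types_along(chain, exon_lengths, read_len)
    counts = np.bincount(ids, minlength=len(chains))
    return {c: int(n) for c, n in zip(chains, counts)}


@dataclass
class TypeStartCounts:
    """l_gih table, matrix P_g and true always-showing-together classes."""

    gene_id: str
    isoforms: list[Chain]
    types: list[Chain]
    l_table: pd.DataFrame      # rows: type labels; cols: isoform index; entries l_gih
    usable: np.ndarray         # l_gi. per isoform

    @property
    def P(self) -> np.ndarray:
        """p_gih = l_gih / l_gi. (types x isoforms)."""
        return self.l_table.to_numpy(dtype=float) / self.usable[None, :]

    def generating_sets(self) -> dict[Chain, frozenset[int]]:
        l = self.l_table.to_numpy()
        return {t: frozenset(np.flatnonzero(l[k] > 0)) for k, t in enumerate(self.types)}

    def classes(self) -> list[tuple[Chain, ...]]:
        """Partition of types by identical generating-isoform sets."""
        by_set: dict[frozenset[int], list[Chain]] = {}
        for t, s in self.generating_sets().items():
            by_set.setdefault(s, []).append(t)
        return sorted(tuple(sorted(v)) for v in by_set.values())

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.P))

    def merged_rank(self, groups) -> int:
        """Rank of P_g after summing the rows of each group of types."""
        idx = {t: k for k, t in enumerate(self.types)}
        P = self.P
        rows = [P[[idx[m] for m in g.members if m in idx]].sum(axis=0) for g in groups]
        rows = [r for r in rows if r.size]
        return int(np.linalg.matrix_rank(np.array(rows)))


def ground_truth(model: IsoformModel) -> TypeStartCounts:
    """Brute-force l_gih for every isoform and every generable type."""
    per_iso = [enumerate_start_positions(c, model.exon_lengths, model.read_len) for c in model.chains]
    types = sorted(set().union(*[set(d) for d in per_iso]))
    l = np.zeros((len(types), len(model.chains)), dtype=int)
    for i, d in enumerate(per_iso):
        for k, t in enumerate(types):
            l[k, i] = d.get(t, 0)
    table = pd.DataFrame(l, index=[chain_label(t) for t in types],
                         columns=range(len(model.chains)))
    usable = np.array([model.usable_length(c) for c in model.chains])
    return TypeStartCounts(model.gene_id, list(model.chains), types, table, usable)


def ground_truth_groups(model: IsoformModel) -> list[tuple[Chain, ...]]:
    """True always-showing-together partition of the gene's types."""
    return ground_truth(model).classes()


def expected_type_probabilities(model: IsoformModel, chain: Chain, config: SimConfig) -> dict[Chain, float]:
    """Exact type law of the mechanistic simulator for one isoform.

    Marginalizes over the discretized truncated Normal fragment length:
    a fragment of length f starts uniformly on 1..L-f+1 and the read is
    its leftmost ``read_len`` bases, so start positions near the 3' end
    are undersampled relative to the pure start-position walk.
    """
    L = model.transcript_length(chain)
    r = config.read_len
    ids, chains = _types_along(chain, model.exon_lengths, r)
    if not chains:
        return {}
    fls = np.arange(r, L + 1)
    w = stats.norm.cdf(fls + 0.5, config.frag_mean, config.frag_sd) - stats.norm.cdf(
        fls - 0.5, config.frag_mean, config.frag_sd)
    # rounding+clipping mass outside [r, L] onto the bounds, as the sampler does
    w[0] += stats.norm.cdf(fls[0] - 0.5, config.frag_mean, config.frag_sd)
    w[-1] += stats.norm.sf(fls[-1] + 0.5, config.frag_mean, config.frag_sd)
    w /= w.sum()
    # prefix counts of each type among the first m start positions
    onehot = np.zeros((len(chains), ids.size))
    onehot[ids, np.arange(ids.size)] = 1.0
    prefix = onehot.cumsum(axis=1)
    m = L - fls + 1  # number of admissible starts for each fragment length
    probs = (prefix[:, m - 1] / m) @ w
    return {c: float(p) for c, p in zip(chains, probs)}


def generate_gene_models(config: SimConfig, rng: np.random.Generator) -> tuple[dict[str, GeneModel], dict[str, IsoformModel]]:
    """Random flat gene models and isoform structures, laid out on one chromosome.

    Per gene: 3-10 flat exons with lengths uniform on 80-500 bp separated
    by introns, and 1-4 distinct isoforms, each an increasing exon subset
    containing both terminal exons. Deterministic given the generator
    state.
    """
    models: dict[str, GeneModel] = {}
    isoforms: dict[str, IsoformModel] = {}
    pos = 1
    chrom = "chrS"
    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        lengths = rng.integers(config.exon_len_range[0], config.exon_len_range[1] + 1, size=n_exons)
        exons = []
        for k, ln in enumerate(lengths, start=1):
            exons.append(FlatExon(gene_id, k, GenomicInterval(chrom, pos, pos + int(ln) - 1, "+")))
            pos += int(ln) + int(rng.integers(*config.intron_len_range))
        pos += 10_000  # keep genes well separated
        models[gene_id] = GeneModel(gene_id, exons)
        n_iso = int(rng.integers(config.isoform_range[0], config.isoform_range[1] + 1))
        chains: set[Chain] = set()
        attempts = 0
        while len(chains) < n_iso and attempts < 50:
            attempts += 1
            middle = [e for e in range(2, n_exons) if rng.random() < 0.5]
            chains.add(tuple([1] + middle + [n_exons]))
        isoforms[gene_id] = IsoformModel(
            gene_id, sorted(chains), {k: int(v) for k, v in zip(range(1, n_exons + 1), lengths)},
            config.read_len)
    return models, isoforms


@dataclass
class GeneExpression:
    """Expression ground truth for one gene: base copies, fold changes, per-sample copies."""

    gene_id: str
    base_copies: np.ndarray          # k_gi, condition-0 expected copies
    lfc: np.ndarray                  # per-isoform log2 fold change (condition 1 vs 0)
    is_de: bool
    K: np.ndarray | None = None  # realized per-sample copies, shape (I, J)

    def expected_copies(self, condition: int) -> np.ndarray:
        return self.base_copies * (2.0**self.lfc if condition == 1 else 1.0)


def draw_copy_numbers(
    isoforms: dict[str, IsoformModel],
    config: SimConfig,
    design: DesignInfo,
    rng: np.random.Generator,
    *,
    fixed: dict[str, GeneExpression] | None = None,
) -> dict[str, GeneExpression]:
    """Draw base copy numbers, DE fold changes and per-sample copies.

    Base copies k_gi ~ NB(mean copy_mean, variance copy_var). A fraction
    ``de_fraction`` of genes is DE: each of their isoforms gets a log2
    fold change ~ N(lfc_mean, lfc_sd) applied in condition 1. Realized
    per-sample copies are NB with mean k (scaled) and size mean·yield/c,
    where yield is the expected reads per copy, so read counts inherit
    the polyester-style mean/variance relation var = mean + c·mean.
    Entries of ``fixed`` (e.g. the switch gene) bypass the random base
    draw but still receive per-sample noise.
    """
    fixed = fixed or {}
    genes = list(isoforms)
    size = config.copy_nb_size
    p = size / (size + config.copy_mean)
    expr: dict[str, GeneExpression] = {}
    for g in genes:
        n_iso = len(isoforms[g].chains)
        if g in fixed:
            fx = fixed[g]
            expr[g] = GeneExpression(g, np.asarray(fx.base_copies, dtype=float),
                                     np.asarray(fx.lfc, dtype=float), fx.is_de)
            continue
        base = rng.negative_binomial(size, p, size=n_iso).astype(float)
        is_de = bool(rng.random() < config.de_fraction)
        lfc = rng.normal(config.lfc_mean, config.lfc_sd, size=n_iso) if is_de else np.zeros(n_iso)
        expr[g] = GeneExpression(g, base, lfc, is_de)

    # expected reads per copy, from the condition-0 transcriptome size
    usable = {g: np.array([isoforms[g].usable_length(c) for c in isoforms[g].chains])
              for g in genes}
    total_size = sum(float(expr[g].base_copies @ usable[g]) for g in genes)
    if total_size <= 0:
        raise ValueError("transcriptome has zero expected expression")
    total_reads = config.reads_per_gene * config.n_genes
    samples = design.samples
    for g in genes:
        yld = total_reads * usable[g] / total_size
        K = np.zeros((len(isoforms[g].chains), len(samples)))
        for j, s in enumerate(samples):
            mean = expr[g].expected_copies(design.conditions[s])
            sz = mean * yld / config.dispersion_const
            pos = mean > 0
            draw = np.zeros_like(mean)
            if pos.any():
                pp = sz[pos] / (sz[pos] + mean[pos])
                draw[pos] = rng.negative_binomial(sz[pos], pp)
            K[:, j] = draw
        expr[g].K = K
    return expr


def simulate_reads_mechanistic(
    models: dict[str, GeneModel],
    isoforms: dict[str, IsoformModel],
    expression: dict[str, GeneExpression],
    config: SimConfig,
    design: DesignInfo,
    rng: np.random.Generator,
    sam_dir=None,
) -> CountTable:
    """Fragment-and-sequence simulation; returns the read-type count table.

    Per sample: reads are allocated to isoforms by a multinomial with
    weights K_gij x usable length, totalling reads_per_gene x n_genes;
    each read's start is uniform among the starts its truncated-Normal
    fragment admits, and its type is read off the exhaustive start-walk.
    The returned table IS the simulator's truth tally. With ``sam_dir``
    set, one SAM file per sample is written ('<sample>.sam') for
    exercising the alignment-based counting path.
    """
    samples = design.samples
    genes = list(isoforms)
    iso_index = [(g, i) for g in genes for i in range(len(isoforms[g].chains))]
    usable = np.array([isoforms[g].usable_length(isoforms[g].chains[i]) for g, i in iso_index], dtype=float)
    walk = {}
    for g, i in iso_index:
        chain = isoforms[g].chains[i]
        walk[(g, i)] = _types_along(chain, isoforms[g].exon_lengths, config.read_len)
    total_reads = config.reads_per_gene * config.n_genes

    counts: dict[tuple[str, str], np.ndarray] = {}
    sam_records: dict[str, list[str]] = {s: [] for s in samples} if sam_dir is not None else {}
    for j, s in enumerate(samples):
        K = np.concatenate([expression[g].K[:, j] for g in genes])
        w = K * usable
        if w.sum() <= 0:
            raise ValueError(f"sample {s!r} would receive zero reads")
        n_iso_reads = rng.multinomial(total_reads, w / w.sum())
        for (g, i), n in zip(iso_index, n_iso_reads):
            if n == 0:
                continue
            model = isoforms[g]
            chain = model.chains[i]
            L = model.transcript_length(chain)
            fl = np.rint(rng.normal(config.frag_mean, config.frag_sd, size=n)).astype(int)
            fl = np.clip(fl, config.read_len, L)
            starts = (rng.random(n) * (L - fl + 1)).astype(int) + 1
            ids, chains_i = walk[(g, i)]
            type_ids = ids[starts - 1]
            tallies = np.bincount(type_ids, minlength=len(chains_i))
            for t_id, cnt in enumerate(tallies):
                if cnt == 0:
                    continue
                key = (g, chain_label(chains_i[t_id]))
                if key not in counts:
                    counts[key] = np.zeros(len(samples), dtype=int)
                counts[key][j] += cnt
            if sam_dir is not None:
                sam_records[s].extend(
                    _sam_lines(models[g], model, chain, starts, config.read_len, s))
    order = sorted(counts, key=lambda k: (k[0], tuple(int(t) for t in k[1].split("-"))))
    idx = pd.MultiIndex.from_tuples(order, names=["gene_id", "read_type"])
    df = pd.DataFrame([counts[k] for k in order], index=idx, columns=samples)
    lib = pd.Series({s: float(total_reads) for s in samples})
    if sam_dir is not None:
        _write_sam_files(models, sam_records, sam_dir)
    return CountTable(df, lib)


def _sam_lines(gene: GeneModel, model: IsoformModel, chain: Chain, starts: np.ndarray,
               read_len: int, sample: str) -> list[str]:
    """Pre-aligned SAM records for reads at the given transcript starts."""
    exon_by_id = {e.exon_id: e.interval for e in gene.exons}
    lengths = np.array([model.exon_lengths[e] for e in chain])
    cum = np.cumsum(lengths)
    lines = []
    for q, s in enumerate(starts):
        s = int(s)
        i0 = int(np.searchsorted(cum, s))
        i1 = int(np.searchsorted(cum, s + read_len - 1))
        off = s - 1 - (cum[i0 - 1] if i0 > 0 else 0)  # offset within first exon
        gstart = exon_by_id[chain[i0]].start + int(off)
        remaining = read_len
        cigar = []
        prev_end = None
        for k in range(i0, i1 + 1):
            iv = exon_by_id[chain[k]]
            begin = gstart if k == i0 else iv.start
            take = min(remaining, iv.end - begin + 1)
            if prev_end is not None:
                cigar.append(f"{begin - prev_end - 1}N")
            cigar.append(f"{take}M")
            remaining -= take
            prev_end = begin + take - 1
        lines.append("\t".join([
            f"{sample}:{gene.gene_id}:{q}", "0", gene.chrom, str(gstart), "60",
            "".join(cigar), "*", "0", "0", "A" * read_len, "*",
        ]))
    return lines


def _write_sam_files(models: dict[str, GeneModel], sam_records: dict[str, list[str]], sam_dir) -> None:
    from pathlib import Path

    sam_dir = Path(sam_dir)
    sam_dir.mkdir(parents=True, exist_ok=True)
    chrom_len: dict[str, int] = {}
    for m in models.values():
        chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), m.exons[-1].interval.end + 1000)
    header = ["@HD\tVN:1.6\tSO:unsorted"] + [f"@SQ\tSN:{c}\tLN:{ln}" for c, ln in sorted(chrom_len.items())]
    for sample, lines in sam_records.items():
        (sam_dir / f"{sample}.sam").write_text("\n".join(header + lines) + "\n")


def simulate_counts_model(theta, phi, lib_sizes, rng: np.random.Generator,
                          n_samples: int | None = None) -> np.ndarray:
    """Direct NB sampling of read-type counts: X_hj ~ NB(N_j θ_h, φ_h).

    ``theta`` has one entry per type, ``lib_sizes`` one per sample; φ may
    be scalar or per-type. φ == 0 draws Poisson. Returns an (H, J) array.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    lib = np.atleast_1d(np.asarray(lib_sizes, dtype=float))
    if n_samples is not None and lib.size == 1:
        lib = np.full(n_samples, lib[0])
    phi_arr = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), theta.shape)
    mean = theta[:, None] * lib[None, :]
    out = np.zeros(mean.shape, dtype=int)
    for h in range(theta.size):
        if phi_arr[h] == 0:
            out[h] = rng.poisson(mean[h])
        else:
            r = 1.0 / phi_arr[h]
            p = r / (r + mean[h])
            pos = mean[h] > 0
            row = np.zeros(lib.size, dtype=int)
            row[pos] = rng.negative_binomial(r, p[pos])
            out[h] = row
    return out


def make_switch_gene(gene_id: str = "switch", chrom: str = "chrS",
                     offset: int = 1, read_len: int = 100) -> tuple[GeneModel, IsoformModel]:
    """The isoform-switch gene: two equal-length isoforms over 5 exons.

    Isoforms 1-2-3-5 and 1-2-4-5 differ in one internal exon of the same
    length, so swapping their copy numbers changes the read-type
    composition while leaving the gene's total isoform size untouched.
    """
    lengths = [300, 250, 150, 150, 300]
    pos = offset
    exons = []
    for k, ln in enumerate(lengths, start=1):
        exons.append(FlatExon(gene_id, k, GenomicInterval(chrom, pos, pos + ln - 1, "+")))
        pos += ln + 400
    model = GeneModel(gene_id, exons)
    iso = IsoformModel(gene_id, [(1, 2, 3, 5), (1, 2, 4, 5)],
                       dict(zip(range(1, 6), lengths)), read_len)
    return model, iso


def simulate_switch_dataset(config: SimConfig, rng: np.random.Generator,
                            copies_low: float = 10.0, copies_high: float = 50.0,
                            sam_dir=None):
    """One replicate of the 10-gene isoform-switch experiment.

    ``config.n_genes`` genes in total: n-1 null genes with NB(10, 210)
    copies shared across conditions, plus the switch gene at expected
    copies (low, high) in condition 0 and (high, low) in condition 1.
    Returns (models, isoforms, expression, design, count table); the
    switch gene is the only DE gene.
    """
    null_cfg = replace(config, n_genes=config.n_genes - 1, de_fraction=0.0)
    models, isoforms = generate_gene_models(null_cfg, rng)
    last_end = max(m.exons[-1].interval.end for m in models.values()) if models else 0
    sw_model, sw_iso = make_switch_gene(offset=last_end + 10_000, read_len=config.read_len)
    models[sw_model.gene_id] = sw_model
    isoforms[sw_iso.gene_id] = sw_iso
    design = DesignInfo({
        **{f"c0_s{k + 1}": 0 for k in range(config.samples_per_condition)},
        **{f"c1_s{k + 1}": 1 for k in range(config.samples_per_condition)},
    })
    # switch gene: log2 fold changes realize (low,high) -> (high,low)
    lfc = np.array([np.log2(copies_high / copies_low), np.log2(copies_low / copies_high)])
    fixed = {sw_model.gene_id: GeneExpression(
        sw_model.gene_id, np.array([copies_low, copies_high]), lfc, True)}
    expr_cfg = replace(config, de_fraction=0.0)  # the switch gene is the only DE gene
    expression = draw_copy_numbers(isoforms, expr_cfg, design, rng, fixed=fixed)
    table = simulate_reads_mechanistic(models, isoforms, expression, config, design, rng,
                                       sam_dir=sam_dir)
    return models, isoforms, expression, design, table
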