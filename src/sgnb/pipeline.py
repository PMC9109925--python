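"""End-to-end SGNB runs and the simulation benchmark loop.

``run_sgnb`` chains flatten -> count -> merge -> normalize -> fit -> test
on real inputs (GTF + SAM/BAM, or a precomputed count table) and returns
the per-group and per-gene result tables plus a stage report.
``run_benchmark`` repeats a simulated two-condition experiment, scores
calls against the simulation truth and reports FDR / TPR (or the type-I
rejection rate on all-null configurations) for the SGNB arms and the
gene-level total-count baseline.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate as sim
from .annotation import GeneModel, flatten_annotation, parse_annotation
from .nb_inference import tmm_normalize
from .read_typing import CountTable, DesignInfo, count_read_types, iter_sam
from .splicing_graph import merge_table
from .testing import gene_total_test, test_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one SGNB run."""

    annotation: str | None = None          # GTF path
    alignments: dict[str, str] | None = None  # sample -> SAM/BAM path
    counts: str | None = None              # precomputed count-table TSV
    design: dict[str, int] = field(default_factory=dict)
    alpha: float = 0.05
    adjust: str = "bonferroni"
    merge: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SGNBResult:
    """Outcome of a full run: result tables plus the stage report."""

    groups: pd.DataFrame
    genes: pd.DataFrame
    report: dict

    def de_genes(self, alpha: float = 0.05, adjust: str = "bonferroni") -> list[str]:
        return list(self.genes.index[self.genes[adjust] < alpha])


def run_sgnb(
    table: CountTable,
    design: DesignInfo,
    *,
    merge: bool = True,
    alpha: float = 0.05,
) -> SGNBResult:
    """Run merging, normalization, estimation and testing on a count table."""
    design.require_replicates()
    t0 = time.perf_counter()
    report: dict = {
        "samples": len(table.samples),
        "genes_in": len(table.genes()),
        "types_in": int(table.counts.shape[0]),
        "merge": merge,
    }
    if merge:
        merged, groups_by_gene = merge_table(table)
        report["groups_tested"] = int(merged.counts.shape[0])
        work = merged
    else:
        report["groups_tested"] = int(table.counts.shape[0])
        work = table
    norm = tmm_normalize(work)
    report["tmm_reference"] = norm.reference
    group_df, gene_df = test_table(work, design, norm)
    report["genes_tested"] = int(gene_df.shape[0])
    report["seconds"] = round(time.perf_counter() - t0, 3)
    logger.info("SGNB run: %s", report)
    return SGNBResult(group_df, gene_df, report)


def run_from_files(config: RunConfig) -> SGNBResult:
    """Load inputs per the run configuration and execute the pipeline."""
    design = DesignInfo(dict(config.design))
    if config.counts is not None:
        with open(config.counts) as fh:
            table = CountTable.from_tsv(fh)
    else:
        if not config.annotation or not config.alignments:
            raise ValueError("need either counts TSV or annotation + alignments")
        models = load_flat_models(config.annotation)
        streams = {s: iter_sam(path, s) for s, path in config.alignments.items()}
        table = count_read_types(streams, models, design)
    return run_sgnb(table, design, merge=config.merge, alpha=config.alpha)


def load_flat_models(gtf_path: str) -> dict[str, GeneModel]:
    with open(gtf_path) as fh:
        return flatten_annotation(parse_annotation(fh))


def score_calls(called: set[str], truth_de: set[str], scored_genes: set[str]) -> dict:
    """Confusion summary of DE calls against simulation truth."""
    called = called & scored_genes
    tp = len(called & truth_de)
    fp = len(called - truth_de)
    n_de = len(truth_de & scored_genes)
    return {
        "n_called": len(called),
        "tp": tp,
        "fp": fp,
        "fdr": fp / max(len(called), 1),
        "tpr": tp / n_de if n_de else float("nan"),
        "rejection_rate": len(called) / max(len(scored_genes), 1),
    }


ARMS = ("sgnb_merged", "sgnb_unmerged", "gene_total")


def run_benchmark(
    config: sim.SimConfig,
    n_replicates: int,
    seed: int,
    *,
    arms: tuple[str, ...] = ARMS,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    switch: bool = False,
) -> pd.DataFrame:
    """Simulate, analyze and score ``n_replicates`` experiments.

    Each replicate simulates a transcriptome (the isoform-switch preset
    when ``switch`` is set, otherwise random genes with ``de_fraction``
    DE), runs the requested arms, and calls DE genes at level ``alpha``
    after the across-gene adjustment. Returns one row per replicate and
    arm with FDR/TPR/rejection counts and the number of hypotheses
    tested.
    """
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(2**31, size=n_replicates)
    rows = []
    for rep, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        if switch:
            models, isoforms, expression, design, table = sim.simulate_switch_dataset(config, rng)
        else:
            models, isoforms = sim.generate_gene_models(config, rng)
            design = DesignInfo({
                **{f"c0_s{k + 1}": 0 for k in range(config.samples_per_condition)},
                **{f"c1_s{k + 1}": 1 for k in range(config.samples_per_condition)},
            })
            expression = sim.draw_copy_numbers(isoforms, config, design, rng)
            table = sim.simulate_reads_mechanistic(models, isoforms, expression, config, design, rng)
        truth_de = {g for g, e in expression.items() if e.is_de}
        scored = set(table.genes())
        for arm in arms:
            if arm == "gene_total":
                norm = tmm_normalize(table)
                gene_df = gene_total_test(table, design, norm)
                n_tests = int(gene_df.shape[0])
            else:
                res = run_sgnb(table, design, merge=(arm == "sgnb_merged"), alpha=alpha)
                gene_df = res.genes
                n_tests = res.report["groups_tested"]
            called = set(gene_df.index[gene_df[adjust] < alpha])
            row = {"replicate": rep, "seed": int(rs), "arm": arm, "n_tests": n_tests}
            row.update(score_calls(called, truth_de, scored))
            if switch:
                row["switch_detected"] = "switch" in called
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_benchmark(bench: pd.DataFrame) -> pd.DataFrame:
    """Average FDR / TPR / rejection rate per arm across replicates."""
    cols = [c for c in ("fdr", "tpr", "rejection_rate", "n_tests") if c in bench.columns]
    return bench.groupby("arm")[cols].mean()
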