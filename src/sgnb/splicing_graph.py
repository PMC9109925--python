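"""Splicing graph over read types and "always showing together" merging.

Testing every read type of a gene separately multiplies hypotheses and
estimation noise. Two read types generated by exactly the same set of
isoforms ("always showing together") have proportional rows in the
type-by-isoform start-probability matrix P_g, so summing their counts
into one group leaves the column rank of P_g — and hence the
equivalence of the isoform-level and type-level null hypotheses —
intact, while halving the number of tests.

Isoform sets are unknown without transcript annotation, so mergeable
pairs are found structurally: build a directed graph whose nodes are the
observed read-type chains, with an edge u -> v when v continues u by
exactly one exon appended after u's last exon, or v is u with its first
exon dropped. Pseudo START/END nodes attach to the leftmost and
rightmost chains. Along any stretch where out-degree of the earlier
node and in-degree of the later node are both 1, there is no branch an
isoform could take to show one type without the other, so the stretch is
merged into a single group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import networkx as nx
import pandas as pd

from .read_typing import CountTable, chain_label, parse_chain

START = "START"
END = "END"

Chain = tuple[int, ...]


@dataclass
class ReadTypeGroup:
    """A set of read-type chains merged into one test unit."""

    gene_id: str
    members: tuple[Chain, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty group")
        self.members = tuple(sorted(self.members))

    @property
    def label(self) -> str:
        return "+".join(chain_label(c) for c in self.members)


class SplicingGraph:
    """Directed read-type graph with pseudo START and END nodes."""

    def __init__(self, gene_id: str, graph: nx.DiGraph):
        self.gene_id = gene_id
        self.graph = graph

    @property
    def chains(self) -> list[Chain]:
        return sorted(n for n in self.graph.nodes if n not in (START, END))

    def out_degree(self, node) -> int:
        return self.graph.out_degree(node)

    def in_degree(self, node) -> int:
        return self.graph.in_degree(node)

    def to_dot(self, stream: IO[str]) -> None:
        stream.write(f'digraph "{self.gene_id}" {{\n')
        for u, v in self.graph.edges:
            lu = u if isinstance(u, str) else chain_label(u)
            lv = v if isinstance(v, str) else chain_label(v)
            stream.write(f'  "{lu}" -> "{lv}";\n')
        stream.write("}\n")


def build_graph(gene_id: str, chains: Iterable[Chain]) -> SplicingGraph:
    """Build the splicing graph over one gene's observed chains.

    Edge rule: u -> v iff v == u + (one exon appended after u's last ID)
    or v == u[1:] with len(u) >= 2. START connects to the lexicographically
    smallest (leftmost) chain only; only the largest (rightmost) chain
    connects to END. Lexicographic order is elementwise integer order with
    shorter prefixes first, e.g. (1,) < (1,2) < (1,3) < (2,).
    """
    nodes = sorted(set(chains))
    if not nodes:
        raise ValueError(f"gene {gene_id}: no chains")
    node_set = set(nodes)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u in nodes:
        # append-one-exon continuations
        for v in node_set:
            if len(v) == len(u) + 1 and v[: len(u)] == u and v[-1] > u[-1]:
                g.add_edge(u, v)
        # drop-first-exon continuation
        if len(u) >= 2 and u[1:] in node_set:
            g.add_edge(u, u[1:])
    g.add_edge(START, nodes[0])
    g.add_edge(nodes[-1], END)
    return SplicingGraph(gene_id, g)


def merge_always_together(sg: SplicingGraph) -> list[ReadTypeGroup]:
    """Partition chains into groups via the degree rule.

    For an edge u -> v between real nodes: if out-degree(u) == 1 and
    in-degree(v) == 1 (degrees include pseudo-node edges), u and v must
    be generated by the same isoform set, so they merge; merging is
    closed transitively along such chains. Everything else stays a
    singleton. The result partitions the gene's observed chains.
    """
    g = sg.graph
    uf = nx.utils.UnionFind(sg.chains)
    for u, v in g.edges:
        if u in (START, END) or v in (START, END):
            continue
        if g.out_degree(u) == 1 and g.in_degree(v) == 1:
            uf.union(u, v)
    groups = [ReadTypeGroup(sg.gene_id, tuple(members)) for members in uf.to_sets()]
    groups.sort(key=lambda gr: gr.members[0])
    return groups


def group_chains(gene_id: str, chains: Iterable[Chain]) -> list[ReadTypeGroup]:
    """Convenience: build the graph and merge in one step."""
    return merge_always_together(build_graph(gene_id, chains))


def group_counts(table: CountTable, groups_by_gene: dict[str, Sequence[ReadTypeGroup]]) -> CountTable:
    """Sum member rows of each group; per-sample column totals unchanged.

    Group labels join member chains with "+" ("1+1-2+2"). Raises if a
    group references a chain absent from the table or the groups do not
    partition a gene's observed types.
    """
    frames = []
    for gene_id, groups in groups_by_gene.items():
        sub = table.gene(gene_id)
        observed = {parse_chain(label) for label in sub.index}
        members_seen: list[Chain] = []
        rows = {}
        for group in groups:
            for m in group.members:
                if m not in observed:
                    raise KeyError(f"gene {gene_id}: chain {chain_label(m)} not in table")
            members_seen.extend(group.members)
            labels = [chain_label(m) for m in group.members]
            rows[group.label] = sub.loc[labels].sum(axis=0)
        if len(members_seen) != len(set(members_seen)) or set(members_seen) != observed:
            raise ValueError(f"gene {gene_id}: groups do not partition observed read types")
        frame = pd.DataFrame(rows).T
        frame.index = pd.MultiIndex.from_product([[gene_id], frame.index], names=["gene_id", "read_type"])
        frames.append(frame)
    merged = pd.concat(frames).sort_index()
    return CountTable(merged.astype(table.counts.dtypes.iloc[0]), table.lib_sizes, table.discards)


def merge_table(table: CountTable) -> tuple[CountTable, dict[str, list[ReadTypeGroup]]]:
    """Merge every gene of a count table; returns grouped table + groups."""
    groups_by_gene = {}
    for gene_id in table.genes():
        chains = [parse_chain(label) for label in table.gene(gene_id).index]
        groups_by_gene[gene_id] = group_chains(gene_id, chains)
    return group_counts(table, groups_by_gene), groups_by_gene
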