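"""Hi-C contacts to gene pairs, thresholded interaction networks and clusters.

A "substantial" spatial interaction between two genes means the number of
Hi-C contacts observed between them reaches a contact threshold (inclusive:
count >= t). Nodes of an interaction network are the interacting genes, i.e.
endpoints of at least one surviving edge. No contact-matrix normalisation
(ICE/coverage balancing) is applied anywhere; comparability across datasets
is achieved instead by calibrating thresholds to a common node count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .genome import GeneCatalog

__all__ = [
    "ContactRecord",
    "read_contacts",
    "map_contacts_to_gene_pairs",
    "InteractionNetwork",
    "build_network",
    "threshold_sweep",
    "calibrate_threshold",
    "connected_clusters",
    "write_network",
    "read_network",
]

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    """Canonical unordered key for a gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ContactRecord:
    """One Hi-C contact observation between two genomic positions."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"contact count must be >= 1, got {self.count}")
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("contact positions must be >= 1")


def read_contacts(path: str | Path) -> Iterator[ContactRecord]:
    """Stream tab-delimited contact records.

    Accepted layouts per row: ``chromA posA chromB posB [count]`` with an
    optional leading read-id column (detected when column 2 is not an
    integer). ``#`` lines are comments. Malformed rows are skipped with a
    logged warning and counted.
    """
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 5 and not _is_int(fields[1]):
                    fields = fields[1:]  # leading read id
                chrom_a, pos_a, chrom_b, pos_b = fields[:4]
                count = int(fields[4]) if len(fields) > 4 and fields[4] else 1
                yield ContactRecord(chrom_a, int(pos_a), chrom_b, int(pos_b), count)
            except (ValueError, IndexError):
                skipped += 1
                logger.warning("%s: skipping malformed contact row at line %d", path, lineno)
    if skipped:
        logger.warning("%s: skipped %d malformed contact rows", path, skipped)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def map_contacts_to_gene_pairs(
    records: Iterable[ContactRecord], catalog: GeneCatalog
) -> dict[PairKey, int]:
    """Accumulate contact counts onto unordered gene pairs.

    Each read end is assigned to every gene whose body contains it; a record
    credits every cross product pair of distinct genes. Records with either
    end in intergenic space contribute nothing; self pairs (both ends in the
    same gene) are excluded.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    pairs: dict[PairKey, int] = {}
    for rec in records:
        genes_a = catalog.genes_at(rec.chrom_a, rec.pos_a)
        if not genes_a:
            continue
        genes_b = catalog.genes_at(rec.chrom_b, rec.pos_b)
        if not genes_b:
            continue
        for ga in genes_a:
            for gb in genes_b:
                if ga.gene_id == gb.gene_id:
                    continue
                key = pair_key(ga.gene_id, gb.gene_id)
                pairs[key] = pairs.get(key, 0) + rec.count
    return pairs


@dataclass
class InteractionNetwork:
    """Gene-gene interaction network at a fixed contact threshold.

    ``graph`` is an undirected networkx graph whose edges carry the
    ``count`` attribute; every node is incident to at least one edge.
    """

    threshold: int
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> dict[PairKey, int]:
        return {pair_key(u, v): d["count"] for u, v, d in self.graph.edges(data=True)}

    def neighbors(self, gene_id: str) -> list[str]:
        return sorted(self.graph.neighbors(gene_id))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.graph


def build_network(pairs: dict[PairKey, int], threshold: int) -> InteractionNetwork:
    """Keep pairs with ``count >= threshold`` as edges; nodes are endpoints."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    g = nx.Graph()
    for (a, b), count in pairs.items():
        if count >= threshold:
            g.add_edge(a, b, count=count)
    return InteractionNetwork(threshold=threshold, graph=g)


def connected_clusters(net: InteractionNetwork) -> list[set[str]]:
    """Maximal connected components, sorted by size descending.

    Genes connected by at least one path form a cluster; the first entry is
    the largest cluster. Ties sorted by smallest member id for determinism.
    """
    comps = [set(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def threshold_sweep(
    pairs: dict[PairKey, int], thresholds: list[int]
) -> list[tuple[int, int, int, int]]:
    """Node/edge/largest-cluster counts at each threshold.

    Returns ``(threshold, node_count, edge_count, largest_cluster_size)``
    rows; all three counts are non-increasing in the threshold.
    """
    if not thresholds:
        raise ValueError("threshold list is empty")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    out = []
    for t in thresholds:
        net = build_network(pairs, t)
        clusters = connected_clusters(net)
        largest = len(clusters[0]) if clusters else 0
        out.append((t, net.graph.number_of_nodes(), net.graph.number_of_edges(), largest))
    return out


def calibrate_threshold(pairs: dict[PairKey, int], target_node_count: int) -> int:
    """Most stringent threshold retaining at least ``target_node_count`` genes.

    Returns the largest integer t whose network has node count >=
    ``target_node_count`` — the most stable network at least as large as the
    target. Node counts only change at observed pair counts, so candidates
    are the distinct counts, scanned from strongest down while growing the
    node set incrementally.
    """
    if target_node_count < 2:
        raise ValueError("target_node_count must be >= 2")
    if not pairs:
        raise ValueError("no gene pairs")
    by_count: dict[int, list[PairKey]] = {}
    for key, c in pairs.items():
        by_count.setdefault(c, []).append(key)
    nodes: set[str] = set()
    for t in sorted(by_count, reverse=True):
        for a, b in by_count[t]:
            nodes.add(a)
            nodes.add(b)
        if len(nodes) >= target_node_count:
            return t
    raise ValueError(
        f"target {target_node_count} unattainable: maximum node count at "
        f"threshold 1 is {len(nodes)}"
    )


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """TSV edge list with a header comment recording the threshold."""
    with open(path, "w") as fh:
        fh.write(f"# threshold={net.threshold}\n")
        fh.write("gene_a\tgene_b\tcontact_count\n")
        for (a, b), count in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{count}\n")


def read_network(path: str | Path) -> InteractionNetwork:
    threshold = 1
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# threshold="):
                threshold = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            a, b, count = line.split("\t")
            g.add_edge(a, b, count=int(count))
    return InteractionNetwork(threshold=threshold, graph=g)
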