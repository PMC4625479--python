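"""Gene catalogs: genomic intervals, position lookup and sequential distance.

Genes are flat intervals (no exon substructure), stored 1-based inclusive.
BED input (0-based half-open) is converted on load. Only entries whose
feature class matches a configurable filter (default ``"GENE"``) are kept;
pseudogene/RNA/CDS/UTR rows are dropped.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Gene",
    "GeneCatalog",
    "load_gene_catalog",
    "write_gene_catalog",
    "genomic_distance",
]

#: Sentinel for quantities that have no value (e.g. inter-chromosomal distance).
UNDEFINED = None

_TABLE_COLUMNS = ("gene_id", "symbol", "chromosome", "start", "end", "feature_class")


@dataclass(frozen=True)
class Gene:
    """A gene as a genomic interval, coordinates 1-based inclusive."""

    gene_id: str
    symbol: str
    chromosome: str
    start: int
    end: int
    feature_class: str = "GENE"
    strand: str = "."  # read if present, never used in computations

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneCatalog:
    """An indexed collection of genes supporting position -> gene lookup.

    The per-chromosome index is a sorted list of intervals queried with a
    bisect-bounded scan; overlapping genes are all returned for a position
    contained in several of them.
    """

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self._genes.values():
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, glist in self._by_chrom.items():
            glist.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[chrom] = [g.start for g in glist]
            self._max_len[chrom] = max(g.length for g in glist)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[Gene]:
        """Genes on a chromosome, sorted by start coordinate."""
        return list(self._by_chrom.get(chromosome, ()))

    def genes_at(self, chromosome: str, position: int) -> set[Gene]:
        """All genes whose interval contains ``position`` (1-based).

        Unknown chromosomes and intergenic positions yield an empty set.
        """
        if position < 1:
            raise ValueError(f"position must be >= 1, got {position}")
        glist = self._by_chrom.get(chromosome)
        if not glist:
            return set()
        starts = self._starts[chromosome]
        hi = bisect.bisect_right(starts, position)
        # genes starting earlier than position - max_len + 1 cannot reach it
        lo = bisect.bisect_left(starts, position - self._max_len[chromosome] + 1)
        return {g for g in glist[lo:hi] if g.start <= position <= g.end}


def genomic_distance(a: Gene, b: Gene) -> int | None:
    """Sequential genomic distance: |start_a - start_b| in bp.

    Undefined (``None``) for genes on different chromosomes, which are
    excluded from all distance-based analyses.
    """
    if a.chromosome != b.chromosome:
        return UNDEFINED
    return abs(a.start - b.start)


def _parse_bed_row(fields: list[str], lineno: int) -> Gene:
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: BED row needs >= 3 columns")
    chrom = fields[0]
    start0, end0 = int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else f"{chrom}:{start0}-{end0}"
    strand = fields[5] if len(fields) > 5 else "."
    # BED is 0-based half-open; store 1-based inclusive
    return Gene(
        gene_id=name,
        symbol=name,
        chromosome=chrom,
        start=start0 + 1,
        end=end0,
        feature_class="GENE",
        strand=strand,
    )


def load_gene_catalog(path: str | Path, feature_filter: str = "GENE") -> GeneCatalog:
    """Load a catalog from BED or a tab-delimited gene table.

    A file whose first non-comment line is a header containing ``gene_id``
    is treated as a gene table (columns ``gene_id, symbol, chromosome,
    start, end, feature_class`` with optional ``strand``); anything else is
    parsed as BED. Only table rows with ``feature_class == feature_filter``
    are retained (BED rows carry no feature class and are all retained).
    """
    path = Path(path)
    genes: list[Gene] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if header is None and "gene_id" in fields:
                header = fields
                for col in _TABLE_COLUMNS:
                    if col not in header:
                        raise ValueError(f"line {lineno}: missing column {col!r}")
                continue
            try:
                if header is not None:
                    row = dict(zip(header, fields))
                    if row["feature_class"] != feature_filter:
                        continue
                    genes.append(
                        Gene(
                            gene_id=row["gene_id"],
                            symbol=row["symbol"],
                            chromosome=row["chromosome"],
                            start=int(row["start"]),
                            end=int(row["end"]),
                            feature_class=row["feature_class"],
                            strand=row.get("strand", "."),
                        )
                    )
                else:
                    genes.append(_parse_bed_row(fields, lineno))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: unparseable row at line {lineno}: {exc}") from exc
    return GeneCatalog(genes)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    """Write the canonical TSV gene table (round-trips with the loader)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS + ("strand",)) + "\n")
        for chrom in catalog.chromosomes:
            for g in catalog.genes_on(chrom):
                fh.write(
                    f"{g.gene_id}\t{g.symbol}\t{g.chromosome}\t{g.start}\t{g.end}"
                    f"\t{g.feature_class}\t{g.strand}\n"
                )
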