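"""Synthetic genomes, ontologies, annotations, sequences and Hi-C contacts.

The generator emulates the statistical structure the analysis pipeline
assumes so every stage can be exercised without external downloads:

* a gene catalog on several chromosomes, genes laid left to right with
  exponential lengths and intergenic gaps;
* a small multi-namespace GO DAG (balanced is_a trees per namespace, with a
  configurable fraction of part_of edges) and gene annotations organised
  into planted functional modules — module members share a module core term
  (function similarity 1 within a module) plus private random terms;
* protein sequences in which a fraction of same-module gene pairs are
  near-identical duplicates (high sequence identity AND identical
  function), the rest independent random sequences;
* Hi-C contact records with power-law genomic-distance decay, Poisson
  counts, and a module boost factor beta multiplying the expected count of
  same-module pairs. beta = 1 is the null model in which spatial
  interaction carries no functional signal; beta >> 1 plants the
  "strong interaction <-> near-identical function" association.

Contacts are emitted as positional records at gene midpoints so the real
read-end-to-gene mapping code path is exercised rather than bypassed.
All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import ContactRecord
from .genome import Gene, GeneCatalog
from .ontology import GOAnnotationSet, GODag

__all__ = [
    "SyntheticConfig",
    "SyntheticAnnotations",
    "generate_genome",
    "generate_go_and_annotations",
    "generate_sequences",
    "generate_contacts",
    "SyntheticDataset",
    "generate_dataset",
    "write_obo",
    "write_gaf",
    "write_fasta",
    "write_contacts",
]

_NS_DIGIT = {"BP": "1", "CC": "2", "MF": "3"}
_NS_LONG = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
_AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic data.

    The defaults are the desk-scale conditions used throughout the test
    suite: 4 chromosomes x 250 genes, 10 planted functional modules and a
    module contact boost beta = 30; beta = 1 switches the generator to the
    null model. ``background_contact_rate`` is the expected Hi-C count of a
    non-module gene pair at the reference genomic distance
    (``contact_reference_bp``); expected counts scale as
    rate * (d0 / d)^alpha with distance d.
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 250
    gene_length_mean: int = 30_000
    intergenic_gap_mean: int = 70_000
    dag_depth: int = 4
    dag_branching: int = 3
    part_of_fraction: float = 0.15
    n_roots_per_namespace: int = 1
    n_modules: int = 10
    terms_per_gene: int = 3
    module_parent_prob: float = 0.5
    duplication_fraction: float = 0.4
    sequence_divergence: float = 0.05
    sequence_length_mean: int = 300
    background_contact_rate: float = 30.0
    contact_reference_bp: int = 100_000
    distance_decay_exponent: float = 1.0
    module_boost_factor: float = 30.0
    inter_chromosomal_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_decay_exponent <= 0:
            raise ValueError("distance_decay_exponent must be > 0")
        if self.module_boost_factor < 1:
            raise ValueError("module_boost_factor must be >= 1")
        for f in ("background_contact_rate", "inter_chromosomal_rate",
                  "duplication_fraction", "sequence_divergence"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(cfg: SyntheticConfig, stage: int, extra: int | None = None) -> np.random.Generator:
    key = [cfg.seed, stage] if extra is None else [cfg.seed, stage, extra]
    return np.random.default_rng(key)


def generate_genome(cfg: SyntheticConfig) -> GeneCatalog:
    """Non-overlapping genes per chromosome with exponential lengths/gaps."""
    rng = _rng(cfg, 1)
    genes: list[Gene] = []
    idx = 0
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = 1
        for _ in range(cfg.genes_per_chromosome):
            gap = 1 + int(rng.exponential(cfg.intergenic_gap_mean))
            length = 1 + int(rng.exponential(cfg.gene_length_mean))
            start = pos + gap
            end = start + length - 1
            idx += 1
            genes.append(
                Gene(
                    gene_id=f"SG{idx:05d}",
                    symbol=f"SYN{idx}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                )
            )
            pos = end
    return GeneCatalog(genes)


class SyntheticAnnotations(GOAnnotationSet):
    """Annotation set that also records the planted module of each gene."""

    def __init__(self, dag: GODag | None = None):
        super().__init__(dag)
        self.module_of: dict[str, int] = {}


def _build_namespace_tree(
    ns: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[tuple[str, str, str]], list[list[str]]]:
    """One namespace: a forest of balanced trees; returns (namespaces, edges,
    terms-by-depth)."""
    namespaces: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    by_depth: list[list[str]] = [[] for _ in range(cfg.dag_depth + 1)]
    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{_NS_DIGIT[ns]}{counter:06d}"

    for _root in range(cfg.n_roots_per_namespace):
        root = new_term()
        namespaces[root] = _NS_LONG[ns]
        by_depth[0].append(root)
        frontier = [root]
        for depth in range(1, cfg.dag_depth + 1):
            nxt = []
            for parent in frontier:
                for _ in range(cfg.dag_branching):
                    term = new_term()
                    namespaces[term] = _NS_LONG[ns]
                    relation = (
                        "part_of" if rng.random() < cfg.part_of_fraction else "is_a"
                    )
                    edges.append((term, parent, relation))
                    by_depth[depth].append(term)
                    nxt.append(term)
            frontier = nxt
    return namespaces, edges, by_depth


def generate_go_and_annotations(
    cfg: SyntheticConfig, catalog: GeneCatalog
) -> tuple[GODag, SyntheticAnnotations]:
    """Balanced multi-namespace DAG plus module-structured annotations.

    Genes are partitioned at random into ``n_modules`` modules. In every
    namespace each module owns a deep internal term ("module parent") and
    its leaf children; every member carries the same designated leaf (the
    module core term, forcing within-module similarity 1), optionally the
    parent and one extra leaf, plus ``terms_per_gene`` private terms drawn
    uniformly from the namespace. With several roots per namespace, modules
    under different roots share no ancestry (similarity 0).
    """
    rng = _rng(cfg, 2)
    namespaces: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    by_depth_ns: dict[str, list[list[str]]] = {}
    for ns in ("BP", "CC", "MF"):
        ns_map, ns_edges, by_depth = _build_namespace_tree(ns, cfg, rng)
        namespaces.update(ns_map)
        edges.extend(ns_edges)
        by_depth_ns[ns] = by_depth
    dag = GODag(namespaces, edges)
    ann = SyntheticAnnotations(dag)

    gene_ids = sorted(g.gene_id for g in catalog)
    order = rng.permutation(len(gene_ids))
    modules: list[list[str]] = [[] for _ in range(max(cfg.n_modules, 1))]
    for pos, gi in enumerate(order):
        modules[pos % len(modules)].append(gene_ids[gi])
    for m, members in enumerate(modules):
        for g in members:
            ann.module_of[g] = m

    # child -> parent lookup for picking module parents' leaves
    children: dict[str, list[str]] = {}
    for child, parent, _rel in edges:
        children.setdefault(parent, []).append(child)

    for ns in ("BP", "CC", "MF"):
        by_depth = by_depth_ns[ns]
        parent_pool = by_depth[cfg.dag_depth - 1] if cfg.dag_depth >= 1 else by_depth[0]
        parent_idx = rng.choice(
            len(parent_pool), size=len(modules), replace=len(parent_pool) < len(modules)
        )
        all_terms = sorted(namespaces_of(dag, ns))
        for m, members in enumerate(modules):
            parent = parent_pool[int(parent_idx[m])]
            leaves = sorted(children.get(parent, [parent]))
            core = leaves[int(rng.integers(len(leaves)))]
            for g in members:
                ann.add(g, core, ns)
                if rng.random() < cfg.module_parent_prob:
                    ann.add(g, parent, ns)
                if len(leaves) > 1 and rng.random() < 0.5:
                    ann.add(g, leaves[int(rng.integers(len(leaves)))], ns)
                for t in rng.choice(len(all_terms), size=cfg.terms_per_gene, replace=False):
                    ann.add(g, all_terms[int(t)], ns)
    return dag, ann


def namespaces_of(dag: GODag, ns: str) -> set[str]:
    return {t for t, n in dag.namespace.items() if n == ns}


def generate_sequences(
    cfg: SyntheticConfig, catalog: GeneCatalog, annotations: SyntheticAnnotations
) -> dict[str, str]:
    """One protein sequence per gene, with duplicated families inside modules.

    In each module, a ``duplication_fraction`` of the members form a
    duplicated gene family: every family member carries the family founder
    sequence independently mutated by per-site substitutions at rate
    ``sequence_divergence``, so all within-family pairs have high sequence
    identity while sharing their module's (identical) function — the
    signature of duplicated genes that kept near-identical sequence and
    function. All other genes get independent random sequences.
    """
    rng = _rng(cfg, 3)
    seqs: dict[str, str] = {}
    gene_ids = sorted(g.gene_id for g in catalog)
    for g in gene_ids:
        length = max(50, int(rng.poisson(cfg.sequence_length_mean)))
        seqs[g] = bytes(rng.choice(_AMINO_ACIDS, size=length)).decode("ascii")
    modules: dict[int, list[str]] = {}
    for g in gene_ids:
        modules.setdefault(annotations.module_of.get(g, -1), []).append(g)

    def mutate(seq_bytes: np.ndarray) -> str:
        seq = seq_bytes.copy()
        hits = rng.random(len(seq)) < cfg.sequence_divergence
        seq[hits] = rng.choice(_AMINO_ACIDS, size=int(hits.sum()))
        return bytes(seq).decode("ascii")

    for m in sorted(modules):
        if m < 0:
            continue
        members = modules[m]
        family_size = int(round(cfg.duplication_fraction * len(members)))
        if family_size < 2:
            continue
        family = [members[int(i)] for i in rng.permutation(len(members))[:family_size]]
        founder = np.frombuffer(seqs[family[0]].encode("ascii"), dtype=np.uint8)
        for g in family:
            seqs[g] = mutate(founder)
    return seqs


def generate_contacts(
    cfg: SyntheticConfig,
    catalog: GeneCatalog,
    annotations: SyntheticAnnotations,
    seed: int | None = None,
) -> list[ContactRecord]:
    """Poisson contact records at gene midpoints with distance decay.

    Intra-chromosomal pair expectation:
    ``background_contact_rate * (d0 / d)^alpha``, multiplied by the module
    boost beta for same-module pairs; inter-chromosomal pairs use
    ``inter_chromosomal_rate`` (times beta). Pairs drawing 0 emit nothing.
    ``seed`` overrides the configuration seed for replicate contact draws
    over a fixed genome and annotation set.
    """
    rng = (
        _rng(cfg, 4)
        if seed is None
        else np.random.default_rng([seed % (2**31), 4])
    )
    records: list[ContactRecord] = []
    module = annotations.module_of
    chrom_data = []
    for chrom in catalog.chromosomes:
        glist = catalog.genes_on(chrom)
        mids = np.array([(g.start + g.end) // 2 for g in glist])
        mods = np.array([module.get(g.gene_id, -1) for g in glist])
        chrom_data.append((chrom, mids, mods))
    beta = cfg.module_boost_factor
    d0 = float(cfg.contact_reference_bp)
    alpha = cfg.distance_decay_exponent
    for chrom, mids, mods in chrom_data:
        n = len(mids)
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, k=1)
        d = np.maximum(np.abs(mids[iu] - mids[ju]), 1).astype(float)
        lam = cfg.background_contact_rate * (d0 / d) ** alpha
        same = (mods[iu] == mods[ju]) & (mods[iu] >= 0)
        lam = np.where(same, lam * beta, lam)
        counts = rng.poisson(lam)
        nz = counts > 0
        for i, j, c in zip(iu[nz], ju[nz], counts[nz]):
            records.append(ContactRecord(chrom, int(mids[i]), chrom, int(mids[j]), int(c)))
    for a in range(len(chrom_data)):
        for b in range(a + 1, len(chrom_data)):
            chrom_a, mids_a, mods_a = chrom_data[a]
            chrom_b, mids_b, mods_b = chrom_data[b]
            same = (mods_a[:, None] == mods_b[None, :]) & (mods_a[:, None] >= 0)
            lam = np.where(same, cfg.inter_chromosomal_rate * beta, cfg.inter_chromosomal_rate)
            counts = rng.poisson(lam)
            ii, jj = np.nonzero(counts)
            for i, j in zip(ii, jj):
                records.append(
                    ContactRecord(
                        chrom_a, int(mids_a[i]), chrom_b, int(mids_b[j]), int(counts[i, j])
                    )
                )
    return records


@dataclass
class SyntheticDataset:
    """A fully generated study: genome, ontology, annotations, sequences."""

    config: SyntheticConfig
    catalog: GeneCatalog
    dag: GODag
    annotations: SyntheticAnnotations
    sequences: dict[str, str]

    def contacts(self, seed: int | None = None) -> list[ContactRecord]:
        """Draw a contact dataset; ``seed`` yields replicate/second datasets."""
        return generate_contacts(self.config, self.catalog, self.annotations, seed=seed)


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    catalog = generate_genome(cfg)
    dag, ann = generate_go_and_annotations(cfg, catalog)
    seqs = generate_sequences(cfg, catalog, ann)
    return SyntheticDataset(cfg, catalog, dag, ann, seqs)


# ---------------------------------------------------------------------------
# writers for the standard text formats the pipeline reads back


def write_obo(dag: GODag, path: str | Path) -> None:
    """Minimal OBO 1.2 serialisation (id, name, namespace, is_a, part_of)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.namespace):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            fh.write(f"namespace: {_NS_LONG[dag.namespace[term]]}\n")
            for parent, relation in sorted(dag.parents[term]):
                if relation == "is_a":
                    fh.write(f"is_a: {parent} ! synthetic term {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! synthetic term {parent}\n")


_ASPECT = {"BP": "P", "CC": "C", "MF": "F"}


def write_gaf(annotations: GOAnnotationSet, path: str | Path) -> None:
    """GAF 2.2 with the columns the reader uses (object id, GO id, aspect)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in annotations.genes():
            for ns in ("BP", "CC", "MF"):
                for term in sorted(annotations.terms(gene, ns)):
                    cols = [
                        "SYN", gene, gene, "", term, "SYN:0000001", "IEA", "",
                        _ASPECT[ns], gene, "", "protein", "taxon:9606",
                        "20150101", "SYN", "", "",
                    ]
                    fh.write("\t".join(cols) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gene in sorted(sequences):
            fh.write(f">{gene}\n")
            seq = sequences[gene]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_contacts(records: list[ContactRecord], path: str | Path) -> None:
    """Tab-delimited 'chromA posA chromB posB count' with a comment header."""
    with open(path, "w") as fh:
        fh.write("# chrom_a\tpos_a\tchrom_b\tpos_b\tcount\n")
        for r in records:
            fh.write(f"{r.chrom_a}\t{r.pos_a}\t{r.chrom_b}\t{r.pos_b}\t{r.count}\n")
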