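"""Gene Ontology DAG, Wang semantic similarity and gene-pair function similarity.

The Wang measure scores two terms by their shared ancestry in the GO DAG.
For a term t, every ancestor a receives an S-value: S_t(t) = 1 and
S_t(a) = max over children c of a lying on a path to t of w(c->a) * S_t(c),
with edge contribution factors w strictly inside (0, 1) so S-values decay
with distance from t. The similarity of t1 and t2 is

    sum over common ancestors a of (S_t1(a) + S_t2(a))
    -------------------------------------------------
    sum over anc(t1) of S_t1  +  sum over anc(t2) of S_t2

which lies in [0, 1], equals 1 iff the terms share their full weighted
ancestry (in particular when t1 == t2), and is 0 when no ancestor is shared.
Gene-pair function similarity in a category is the maximum term-term
similarity over the two genes' annotation sets in that category; it is
undefined (None) when either gene lacks annotations there, and such pairs
are excluded from analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import obonet

__all__ = [
    "NAMESPACES",
    "SemanticWeights",
    "GODag",
    "load_go_dag",
    "GOAnnotationSet",
    "load_gaf",
    "wang_similarity",
    "gene_pair_similarity",
    "GenePairSimilarity",
]

#: The three GO categories, by their short names.
NAMESPACES = ("BP", "CC", "MF")

_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
    "BP": "BP",
    "CC": "CC",
    "MF": "MF",
    "P": "BP",
    "C": "CC",
    "F": "MF",
}


@dataclass(frozen=True)
class SemanticWeights:
    """Edge contribution factors of the Wang measure.

    Defaults are the measure's published contribution factors: 0.8 for
    is_a, 0.6 for part_of. Both must be strictly inside (0, 1) so S-values
    decay.
    """

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for name, w in (("w_is_a", self.w_is_a), ("w_part_of", self.w_part_of)):
            if not 0.0 < w < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {w}")

    def weight(self, relation: str) -> float:
        if relation == "is_a":
            return self.w_is_a
        if relation == "part_of":
            return self.w_part_of
        raise KeyError(relation)


class GODag:
    """GO terms with typed child->parent edges (is_a, part_of) and namespaces."""

    _uid_counter = 0

    def __init__(
        self,
        namespaces: dict[str, str],
        edges: list[tuple[str, str, str]],  # (child, parent, relation)
    ):
        GODag._uid_counter += 1
        self._uid = GODag._uid_counter  # distinguishes DAGs in similarity caches
        self.namespace: dict[str, str] = {}
        for term, ns in namespaces.items():
            short = _NAMESPACE_ALIASES.get(ns)
            if short is None:
                raise ValueError(f"term {term}: unknown namespace {ns!r}")
            self.namespace[term] = short
        self.parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.namespace}
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace)
        for child, parent, relation in edges:
            if relation not in ("is_a", "part_of"):
                continue
            if child not in self.namespace or parent not in self.namespace:
                raise ValueError(f"edge references unknown term: {child} -> {parent}")
            self.parents[child].append((parent, relation))
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    def __len__(self) -> int:
        return len(self.namespace)

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via is_a/part_of edges, including ``term``."""
        seen = {term}
        stack = [term]
        while stack:
            for parent, _ in self.parents[stack.pop()]:
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def s_values(self, term: str, weights: SemanticWeights) -> dict[str, float]:
        """S-values of every ancestor of ``term`` (semantic contributions).

        Computed by relaxing edges outward from the term in breadth order;
        each pass propagates max(w * S(child)) to parents until stable
        (the DAG is finite and weights < 1, so this terminates quickly).
        """
        anc = self.ancestors(term)
        s = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt = []
            for u in frontier:
                su = s[u]
                for parent, relation in self.parents[u]:
                    if parent not in anc:
                        continue
                    cand = weights.weight(relation) * su
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return s


def load_go_dag(obo_path: str | Path) -> GODag:
    """Parse an OBO 1.2 ontology, keeping is_a and part_of edges only.

    Obsolete terms are dropped (obonet's default); all other relationship
    types are ignored. A cycle raises an error naming one offending cycle.
    """
    g = obonet.read_obo(obo_path)
    namespaces = {}
    edges = []
    for term, data in g.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            continue
        namespaces[term] = ns
    for child, parent, relation in g.edges(keys=True):
        if relation in ("is_a", "part_of") and child in namespaces and parent in namespaces:
            edges.append((child, parent, relation))
    return GODag(namespaces, edges)


class GOAnnotationSet:
    """Per-gene GO term sets, split by category (BP / CC / MF)."""

    def __init__(self, dag: GODag | None = None):
        self._ann: dict[str, dict[str, set[str]]] = {}
        self._dag = dag

    def add(self, gene_id: str, term: str, namespace: str | None = None) -> None:
        ns = None
        if namespace is not None:
            ns = _NAMESPACE_ALIASES.get(namespace)
        if ns is None and self._dag is not None and term in self._dag:
            ns = self._dag.namespace[term]
        if ns is None:
            raise ValueError(f"cannot determine namespace for term {term}")
        if self._dag is not None:
            if term not in self._dag:
                raise ValueError(f"term {term} not in ontology")
            if self._dag.namespace[term] != ns:
                raise ValueError(
                    f"term {term} is {self._dag.namespace[term]}, annotated as {ns}"
                )
        slot = self._ann.setdefault(gene_id, {n: set() for n in NAMESPACES})
        slot[ns].add(term)

    def terms(self, gene_id: str, category: str) -> set[str]:
        """Terms of a gene in a category; empty set when unannotated."""
        return set(self._ann.get(gene_id, {}).get(category, ()))

    def genes(self) -> list[str]:
        return sorted(self._ann)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._ann

    def __len__(self) -> int:
        return len(self._ann)


def load_gaf(path: str | Path, dag: GODag | None = None) -> GOAnnotationSet:
    """Read a GAF 2.x annotation file.

    Uses column 2 (DB object id -> gene), column 5 (GO id) and column 9
    (aspect P/C/F -> namespace); ``!`` lines are comments. Terms absent from
    the supplied DAG (e.g. annotations to obsolete terms) are skipped.
    """
    ann = GOAnnotationSet(dag)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            gene, term, aspect = fields[1], fields[4], fields[8]
            if dag is not None and term not in dag:
                continue
            ann.add(gene, term, aspect)
    return ann


class _WangCache:
    """Memoises S-value tables per (dag, term, weights) and term-pair scores."""

    def __init__(self):
        self.s_tables: dict[tuple, dict[str, float]] = {}
        self.pair: dict[tuple, float] = {}


_cache = _WangCache()


def _s_table(term: str, dag: GODag, weights: SemanticWeights) -> dict[str, float]:
    key = (dag._uid, term, weights)
    table = _cache.s_tables.get(key)
    if table is None:
        table = dag.s_values(term, weights)
        _cache.s_tables[key] = table
    return table


def clear_similarity_cache() -> None:
    """Drop memoised S-values and term-pair scores (e.g. between ontologies)."""
    _cache.s_tables.clear()
    _cache.pair.clear()


def wang_similarity(
    t1: str,
    t2: str,
    dag: GODag,
    weights: SemanticWeights = SemanticWeights(),
    use_cache: bool = True,
) -> float:
    """Wang semantic similarity of two terms in the same namespace, in [0, 1]."""
    if t1 not in dag or t2 not in dag:
        raise KeyError(f"term not in ontology: {t1 if t1 not in dag else t2}")
    if dag.namespace[t1] != dag.namespace[t2]:
        raise ValueError(
            f"cross-namespace pair: {t1} ({dag.namespace[t1]}) vs {t2} ({dag.namespace[t2]})"
        )
    if t1 == t2:
        return 1.0
    key = (dag._uid, t1, t2, weights) if t1 <= t2 else (dag._uid, t2, t1, weights)
    if use_cache and key in _cache.pair:
        return _cache.pair[key]
    s1 = _s_table(t1, dag, weights) if use_cache else dag.s_values(t1, weights)
    s2 = _s_table(t2, dag, weights) if use_cache else dag.s_values(t2, weights)
    common = s1.keys() & s2.keys()
    if not common:
        sim = 0.0
    else:
        sim = sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))
    if use_cache:
        _cache.pair[key] = sim
    return sim


def gene_pair_similarity(
    gene_a: str,
    gene_b: str,
    annotations: GOAnnotationSet,
    dag: GODag,
    category: str,
    weights: SemanticWeights = SemanticWeights(),
) -> float | None:
    """Function similarity of two genes in one GO category.

    The maximum Wang similarity over all cross pairs of the genes' terms;
    ``None`` (undefined) when either gene has no annotation in the category.
    Annotations are used as given — the DAG-aware term similarity already
    accounts for shared ancestry, so no up-propagation is applied first.
    """
    terms_a = annotations.terms(gene_a, category)
    terms_b = annotations.terms(gene_b, category)
    if not terms_a or not terms_b:
        return None
    if terms_a & terms_b:
        return 1.0
    return max(
        wang_similarity(t1, t2, dag, weights) for t1 in terms_a for t2 in terms_b
    )


class GenePairSimilarity:
    """Convenience wrapper binding a DAG + annotations for repeated queries."""

    def __init__(
        self,
        dag: GODag,
        annotations: GOAnnotationSet,
        weights: SemanticWeights = SemanticWeights(),
    ):
        self.dag = dag
        self.annotations = annotations
        self.weights = weights

    def __call__(self, gene_a: str, gene_b: str, category: str) -> float | None:
        return gene_pair_similarity(
            gene_a, gene_b, self.annotations, self.dag, category, self.weights
        )
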