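"""End-to-end workflows: association analyses and function prediction.

`run_association` executes, from one configuration, the full chain
contact mapping -> thresholded network -> per-category function-similarity
binning, genomic-distance and sequence-identity statistics, correlation
contrasts and factor-threshold sets, writing one TSV per analysis plus a
machine-readable run manifest. `run_prediction` trains the neighbor
conditional-probability GO model on one dataset and evaluates predictions
on another over a threshold sweep and a k sweep.

Configurations are validated before any stage runs (fail fast, no partial
outputs); manifests record the tool version, a configuration hash, seeds
and SHA-256 checksums of every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    FactorThresholds,
    bin_statistics,
    correlation_report,
    distance_decile_bins,
    identify_high_similarity_pairs,
    sample_noninteracting_pairs,
    split_by_median_distance,
    welch_t_test,
)
from .contacts import (
    InteractionNetwork,
    PairKey,
    build_network,
    calibrate_threshold,
    connected_clusters,
    map_contacts_to_gene_pairs,
    read_contacts,
    threshold_sweep,
    write_network,
)
from .genome import GeneCatalog, genomic_distance, load_gene_catalog
from .ontology import NAMESPACES, GenePairSimilarity, load_gaf, load_go_dag
from .prediction import (
    ConditionalGOModel,
    accuracy_histogram,
    evaluate_prediction,
    predict_gene_function,
)
from .seqident import lcs_identity, nw_identity, read_protein_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "build_pair_table",
    "run_association",
    "run_prediction",
]


@dataclass
class RunConfig:
    """Inputs and settings of one pipeline run.

    Exactly one of (real input paths) or (synthetic configuration) must be
    given per dataset; thresholds may be explicit or calibrated to a target
    node count. All randomness derives from ``seed``.
    """

    genes: str | None = None
    contacts: str | None = None
    obo: str | None = None
    gaf: str | None = None
    fasta: str | None = None
    synth: "object | None" = None  # SyntheticConfig
    contact_seed: int | None = None  # replicate contact draw over a fixed synth genome
    threshold: int | None = None
    target_nodes: int | None = None
    n_random_pairs: int = 20000
    compute_nw: bool = True
    distance_analyses: bool = True
    identity_analyses: bool = True
    sweep_thresholds: list[int] = field(default_factory=lambda: [1, 2, 4, 8, 16, 32, 64])
    out_dir: str = "spatialgo-out"
    seed: int = 0

    def validate(self) -> None:
        real = [self.genes, self.contacts, self.obo, self.gaf]
        if self.synth is not None and any(p is not None for p in real):
            raise ValueError("give either real input paths or a synthetic config, not both")
        if self.synth is None:
            missing = [n for n, p in zip(("genes", "contacts", "obo", "gaf"), real) if p is None]
            if missing:
                raise ValueError(f"missing inputs: {', '.join(missing)}")
            for p in [p for p in real + [self.fasta] if p is not None]:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.threshold is not None and self.target_nodes is not None:
            raise ValueError("give threshold or target_nodes, not both")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: dict, seed: int):
        self.out_dir = out_dir
        self.data = {
            "tool": "spatialgo",
            "version": __version__,
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": seed,
            "outputs": {},
            "warnings": [],
        }

    def add(self, path: Path) -> None:
        self.data["outputs"][path.name] = _sha256(path)

    def warn(self, msg: str) -> None:
        logger.warning(msg)
        self.data["warnings"].append(msg)

    def write(self) -> None:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True, default=str) + "\n")


def _load_inputs(config: RunConfig):
    """Materialise (catalog, contact records, dag, annotations, sequences)."""
    if config.synth is not None:
        from .synthetic import generate_dataset

        ds = generate_dataset(config.synth)
        return (
            ds.catalog,
            ds.contacts(seed=config.contact_seed),
            ds.dag,
            ds.annotations,
            ds.sequences,
        )
    catalog = load_gene_catalog(config.genes)
    records = list(read_contacts(config.contacts))
    dag = load_go_dag(config.obo)
    ann = load_gaf(config.gaf, dag)
    seqs = read_protein_fasta(config.fasta) if config.fasta else {}
    return catalog, records, dag, ann, seqs


def _resolve_network(pairs, config: RunConfig) -> InteractionNetwork:
    if config.target_nodes is not None:
        t = calibrate_threshold(pairs, config.target_nodes)
        logger.info("calibrated threshold %d for target of %d nodes", t, config.target_nodes)
        return build_network(pairs, t)
    return build_network(pairs, config.threshold if config.threshold is not None else 1)


def build_pair_table(
    pairs: dict[PairKey, int],
    pair_keys: list[PairKey],
    catalog: GeneCatalog,
    similarity: GenePairSimilarity,
    sequences: dict[str, str] | None = None,
    compute_nw: bool = False,
) -> pd.DataFrame:
    """Assemble the per-pair analysis table for a list of gene pairs.

    Columns: gene_a, gene_b, contact_count (0 for non-interacting pairs),
    distance (NaN inter-chromosomal), sim_BP/sim_CC/sim_MF (NaN when a gene
    is unannotated in the category) and, when sequences are given,
    lcs_identity (and nw_identity if requested).
    """
    rows = []
    for a, b in pair_keys:
        rec: dict[str, object] = {
            "gene_a": a,
            "gene_b": b,
            "contact_count": pairs.get((a, b) if a <= b else (b, a), 0),
        }
        d = genomic_distance(catalog[a], catalog[b])
        rec["distance"] = np.nan if d is None else d
        for ns in NAMESPACES:
            s = similarity(a, b, ns)
            rec[f"sim_{ns}"] = np.nan if s is None else s
        if sequences is not None and a in sequences and b in sequences:
            rec["lcs_identity"] = lcs_identity(sequences[a], sequences[b])
            if compute_nw:
                rec["nw_identity"] = nw_identity(sequences[a], sequences[b])
        else:
            rec["lcs_identity"] = np.nan
            if compute_nw:
                rec["nw_identity"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def run_association(config: RunConfig) -> Path:
    """Run the association analyses; returns the report directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.__dict__ | {"mode": "association"}, config.seed)
    rng = np.random.default_rng(config.seed)

    catalog, records, dag, ann, seqs = _load_inputs(config)
    pairs = map_contacts_to_gene_pairs(records, catalog)
    net = _resolve_network(pairs, config)
    write_network(net, out / "network_edges.tsv")
    manifest.add(out / "network_edges.tsv")

    sweep = threshold_sweep(pairs, sorted(set(config.sweep_thresholds)))
    pd.DataFrame(
        sweep, columns=["threshold", "nodes", "edges", "largest_cluster"]
    ).to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
    manifest.add(out / "threshold_sweep.tsv")

    clusters = connected_clusters(net)
    pd.DataFrame(
        {"cluster": range(1, len(clusters) + 1), "size": [len(c) for c in clusters]}
    ).to_csv(out / "cluster_sizes.tsv", sep="\t", index=False)
    manifest.add(out / "cluster_sizes.tsv")

    similarity = GenePairSimilarity(dag, ann)
    net_keys = sorted(net.edges)
    table = build_pair_table(
        pairs, net_keys, catalog, similarity, seqs or None, compute_nw=config.compute_nw
    )
    table.to_csv(out / "network_pairs.tsv", sep="\t", index=False)
    manifest.add(out / "network_pairs.tsv")

    random_keys = sample_noninteracting_pairs(
        catalog, pairs, n=config.n_random_pairs, seed=rng
    )
    random_table = build_pair_table(
        pairs, random_keys, catalog, similarity, seqs or None, compute_nw=config.compute_nw
    )
    random_table.to_csv(out / "random_pairs.tsv", sep="\t", index=False)
    manifest.add(out / "random_pairs.tsv")

    welch_rows = []
    for ns in NAMESPACES:
        stats = bin_statistics(table, "contact_count", ns)
        stats.to_csv(out / f"bin_contacts_{ns}.tsv", sep="\t")
        manifest.add(out / f"bin_contacts_{ns}.tsv")
        sim = table[f"sim_{ns}"].dropna()
        bins = np.minimum(np.floor(sim * 10).astype(int) + 1, 10)
        g9 = table.loc[sim.index[bins == 9], "contact_count"]
        g10 = table.loc[sim.index[bins == 10], "contact_count"]
        if len(g9) >= 2 and len(g10) >= 2:
            res = welch_t_test(g9, g10)
            welch_rows.append({"category": ns, "n_bin9": len(g9), "n_bin10": len(g10), **res})
        else:
            manifest.warn(f"{ns}: bins 9/10 too small for the Welch test")
    pd.DataFrame(welch_rows).to_csv(out / "welch_bin9_bin10.tsv", sep="\t", index=False)
    manifest.add(out / "welch_bin9_bin10.tsv")

    if config.distance_analyses:
        for ns in NAMESPACES:
            bin_statistics(table, "distance", ns).to_csv(
                out / f"bin_distance_{ns}.tsv", sep="\t"
            )
            manifest.add(out / f"bin_distance_{ns}.tsv")
            try:
                distance_decile_bins(table, ns).to_csv(
                    out / f"distance_deciles_{ns}.tsv", sep="\t"
                )
                manifest.add(out / f"distance_deciles_{ns}.tsv")
            except ValueError as exc:
                manifest.warn(f"{ns}: distance deciles skipped ({exc})")
        short, long_ = split_by_median_distance(table)
        pd.DataFrame(
            {
                "group": ["short_range", "long_range"],
                "n": [len(short), len(long_)],
                "median_distance": [short["distance"].median(), long_["distance"].median()],
                **{
                    f"mean_sim_{ns}": [short[f"sim_{ns}"].mean(), long_[f"sim_{ns}"].mean()]
                    for ns in NAMESPACES
                },
            }
        ).to_csv(out / "median_distance_split.tsv", sep="\t", index=False)
        manifest.add(out / "median_distance_split.tsv")

    if config.identity_analyses and seqs:
        corr_rows = []
        for ns in NAMESPACES:
            for label, tab in (("interacting", table), ("random", random_table)):
                try:
                    rep = correlation_report(tab, "lcs_identity", f"sim_{ns}")
                except ValueError as exc:
                    manifest.warn(f"{ns}/{label}: correlation skipped ({exc})")
                    continue
                corr_rows.append({"category": ns, "pair_set": label, **rep})
        rep = correlation_report(table, "lcs_identity", "contact_count")
        corr_rows.append({"category": "all", "pair_set": "identity_vs_contacts", **rep})
        pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t", index=False)
        manifest.add(out / "correlations.tsv")

        for ns in NAMESPACES:
            bin_statistics(table, "lcs_identity", ns).to_csv(
                out / f"bin_identity_{ns}.tsv", sep="\t"
            )
            manifest.add(out / f"bin_identity_{ns}.tsv")
            sets = identify_high_similarity_pairs(table, FactorThresholds(), ns)
            with open(out / f"factor_sets_{ns}.tsv", "w") as fh:
                fh.write("gene_a\tgene_b\tby_interactions\tby_distance\tby_identity\n")
                union = sorted(set().union(*sets.values()))
                for key in union:
                    flags = [int(key in sets[s]) for s in ("by_interactions", "by_distance", "by_identity")]
                    fh.write(f"{key[0]}\t{key[1]}\t" + "\t".join(map(str, flags)) + "\n")
            manifest.add(out / f"factor_sets_{ns}.tsv")

    manifest.write()
    return out


def run_prediction(
    train_config: RunConfig,
    predict_config: RunConfig,
    thresholds: list[int] = (1, 2, 3, 4, 6, 8, 10, 12, 14, 16),
    k_values: list[int] = tuple(range(1, 11)),
    out_dir: str | Path = "spatialgo-predict",
    seed: int = 0,
    category: str = "BP",
) -> Path:
    """Train on one dataset, predict on another; sweep thresholds and k.

    The conditional model is trained once on the training dataset's network;
    the prediction network is rebuilt at each threshold of the sweep and
    per-gene accuracies (max predicted-vs-true term similarity) are binned
    into ten-bin histograms. The k sweep is evaluated at the highest
    threshold, mirroring the protocol of evaluating term-list length.
    """
    train_config.validate()
    predict_config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(
        out,
        {"train": train_config.__dict__, "predict": predict_config.__dict__, "mode": "prediction"},
        seed,
    )

    catalog_tr, records_tr, dag, ann_tr, _ = _load_inputs(train_config)
    pairs_tr = map_contacts_to_gene_pairs(records_tr, catalog_tr)
    net_tr = _resolve_network(pairs_tr, train_config)
    model = ConditionalGOModel.train(net_tr, ann_tr, category, network_name="train")
    model.write(out / f"model_{category}.tsv")
    manifest.add(out / f"model_{category}.tsv")

    catalog_pr, records_pr, dag_pr, ann_pr, _ = _load_inputs(predict_config)
    pairs_pr = map_contacts_to_gene_pairs(records_pr, catalog_pr)
    shared = net_tr.nodes & set(
        g for pair in pairs_pr for g in pair
    )
    manifest.data["shared_genes_train_predict"] = len(shared)

    rng = np.random.default_rng(seed)
    rows = []
    max_k = max(k_values)
    for t in thresholds:
        net_pr = build_network(pairs_pr, t)
        evals, no_pred, no_truth = _evaluate_network(
            net_pr, ann_pr, model, dag, max_k, rng
        )
        hist = accuracy_histogram(evals)
        rows.append(
            {
                "threshold": t,
                "n_predicted": len(evals),
                "n_no_prediction": no_pred,
                "n_no_truth": no_truth,
                **{f"bin{i + 1}": hist[i] for i in range(10)},
            }
        )
        pd.DataFrame(
            [{"gene": e.gene_id, "accuracy": e.accuracy} for e in evals]
        ).to_csv(out / f"evaluation_t{t}.tsv", sep="\t", index=False)
        manifest.add(out / f"evaluation_t{t}.tsv")
    pd.DataFrame(rows).to_csv(out / "threshold_histograms.tsv", sep="\t", index=False)
    manifest.add(out / "threshold_histograms.tsv")

    k_rows = []
    net_pr = build_network(pairs_pr, max(thresholds))
    for k in k_values:
        rng_k = np.random.default_rng([seed, k])
        evals, _, _ = _evaluate_network(net_pr, ann_pr, model, dag, k, rng_k)
        hist = accuracy_histogram(evals)
        k_rows.append(
            {"k": k, "n_predicted": len(evals), **{f"bin{i + 1}": hist[i] for i in range(10)}}
        )
    pd.DataFrame(k_rows).to_csv(out / "k_histograms.tsv", sep="\t", index=False)
    manifest.add(out / "k_histograms.tsv")

    manifest.write()
    return out


def _evaluate_network(net, annotations, model, dag, k, rng):
    """Predict and score every predictable annotated gene of a network."""
    evals, no_pred, no_truth = [], 0, 0
    for gene in sorted(net.nodes):
        truth = annotations.terms(gene, model.category)
        if not truth:
            no_truth += 1
            continue
        pred = predict_gene_function(gene, net, annotations, model, k=k, seed=rng)
        if pred.no_prediction:
            no_pred += 1
            continue
        evals.append(evaluate_prediction(pred, truth, dag))
    return evals, no_pred, no_truth
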