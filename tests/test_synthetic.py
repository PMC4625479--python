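"""The synthetic-data generator: planted structure and determinism."""

import numpy as np
import pytest

from spatialgo.contacts import map_contacts_to_gene_pairs
from spatialgo.genome import genomic_distance
from spatialgo.ontology import gene_pair_similarity, load_gaf, load_go_dag
from spatialgo.seqident import lcs_identity, nw_identity, read_protein_fasta
from spatialgo.synthetic import (
    SyntheticConfig,
    generate_contacts,
    generate_dataset,
    generate_genome,
    generate_go_and_annotations,
    generate_sequences,
    write_contacts,
    write_fasta,
    write_gaf,
    write_obo,
)
from spatialgo.genome import load_gene_catalog, write_gene_catalog
from spatialgo.contacts import read_contacts

TINY = SyntheticConfig(
    n_chromosomes=2,
    genes_per_chromosome=30,
    n_modules=4,
    seed=5,
)


def test_genome_ordered_nonoverlapping_and_deterministic():
    cfg = SyntheticConfig(n_chromosomes=1, genes_per_chromosome=5, seed=9)
    cat = generate_genome(cfg)
    genes = cat.genes_on("chr1")
    assert len(genes) == 5
    for a, b in zip(genes, genes[1:]):
        assert a.end < b.start  # ordered, non-overlapping
    cat2 = generate_genome(cfg)
    assert {(g.gene_id, g.start, g.end) for g in cat} == {
        (g.gene_id, g.start, g.end) for g in cat2
    }
    empty = generate_genome(cfg.replace(genes_per_chromosome=0))
    assert len(empty) == 0


def test_dag_size_matches_balanced_tree():
    cfg = TINY.replace(dag_depth=2, dag_branching=2)
    cat = generate_genome(cfg)
    dag, _ = generate_go_and_annotations(cfg, cat)
    for ns in ("BP", "CC", "MF"):
        assert sum(1 for t, n in dag.namespace.items() if n == ns) == 1 + 2 + 4


def test_same_module_pairs_share_function(tiny_dataset=None):
    ds = generate_dataset(TINY)
    by_module = {}
    for g, m in ds.annotations.module_of.items():
        by_module.setdefault(m, []).append(g)
    for members in by_module.values():
        a, b = sorted(members)[:2]
        for ns in ("BP", "CC", "MF"):
            assert gene_pair_similarity(a, b, ds.annotations, ds.dag, ns) == 1.0


def test_modules_under_different_roots_have_zero_similarity():
    cfg = TINY.replace(n_roots_per_namespace=2, n_modules=2, terms_per_gene=0,
                       module_parent_prob=0.0)
    cat = generate_genome(cfg)
    dag, ann = generate_go_and_annotations(cfg, cat)
    by_module = {}
    for g, m in ann.module_of.items():
        by_module.setdefault(m, []).append(g)
    a = sorted(by_module[0])[0]
    b = sorted(by_module[1])[0]
    sims = {ns: gene_pair_similarity(a, b, ann, dag, ns) for ns in ("BP", "CC", "MF")}
    # modules were assigned to disjoint trees in at least one namespace when
    # their parents fall under different roots; all sims must be 0 or low,
    # and cross-root term pairs give exactly 0
    roots = {ns: None for ns in sims}
    for ns in sims:
        terms_a = ann.terms(a, ns)
        terms_b = ann.terms(b, ns)
        anc_a = set().union(*(dag.ancestors(t) for t in terms_a))
        anc_b = set().union(*(dag.ancestors(t) for t in terms_b))
        if not (anc_a & anc_b):
            assert sims[ns] == 0.0
            roots[ns] = "disjoint"
    assert any(v == "disjoint" for v in roots.values())


def test_duplicate_families_have_high_identity_and_shared_function():
    cfg = TINY.replace(sequence_divergence=0.0)
    ds_cat = generate_genome(cfg)
    dag, ann = generate_go_and_annotations(cfg, ds_cat)
    seqs = generate_sequences(cfg, ds_cat, ann)
    by_module = {}
    for g, m in ann.module_of.items():
        by_module.setdefault(m, []).append(g)
    found_identical = 0
    for members in by_module.values():
        seqs_m = [seqs[g] for g in sorted(members)]
        n_copies = len(seqs_m) - len(set(seqs_m))
        found_identical += n_copies
    assert found_identical > 0  # with divergence 0, family members are exact copies


def test_divergent_duplicates_still_high_identity():
    cfg = TINY.replace(sequence_divergence=0.05)
    cat = generate_genome(cfg)
    dag, ann = generate_go_and_annotations(cfg, cat)
    seqs = generate_sequences(cfg, cat, ann)
    cfg0 = cfg.replace(duplication_fraction=0.0)
    seqs0 = generate_sequences(cfg0, cat, ann)
    changed = [g for g in seqs if seqs[g] != seqs0[g]]
    assert changed
    # every family pair keeps identity far above random background
    by_module = {}
    for g in changed:
        by_module.setdefault(ann.module_of[g], []).append(g)
    for members in by_module.values():
        if len(members) < 2:
            continue
        a, b = sorted(members)[:2]
        assert lcs_identity(seqs[a], seqs[b]) > 0.8


def test_random_pairs_have_low_nw_identity():
    cfg = TINY.replace(duplication_fraction=0.0, seed=11,
                       n_chromosomes=1, genes_per_chromosome=60)
    cat = generate_genome(cfg)
    _, ann = generate_go_and_annotations(cfg, cat)
    seqs = generate_sequences(cfg, cat, ann)
    ids = sorted(seqs)
    rng = np.random.default_rng(0)
    below = 0
    n_pairs = 60
    for _ in range(n_pairs):
        a, b = rng.choice(ids, size=2, replace=False)
        if nw_identity(seqs[a], seqs[b]) < 0.3:
            below += 1
    assert below / n_pairs >= 0.95


def test_contact_null_model_equalises_module_status():
    # beta = 1: same-module and cross-module pairs at comparable distance
    # have equal expected counts
    cfg = TINY.replace(module_boost_factor=1.0, seed=21)
    cat = generate_genome(cfg)
    _, ann = generate_go_and_annotations(cfg, cat)
    recs = generate_contacts(cfg, cat, ann)
    pairs = map_contacts_to_gene_pairs(recs, cat)
    same, cross = [], []
    for (a, b), c in pairs.items():
        ga, gb = cat[a], cat[b]
        d = genomic_distance(ga, gb)
        if d is None or not 200_000 <= d <= 2_000_000:
            continue
        (same if ann.module_of[a] == ann.module_of[b] else cross).append(c)
    assert same and cross
    assert np.mean(same) == pytest.approx(np.mean(cross), rel=0.5)


def test_module_boost_scales_expected_counts():
    # compare same- vs cross-module mean counts at matched distance with a
    # large boost; the ratio must reflect beta within Monte-Carlo error
    cfg = SyntheticConfig(
        n_chromosomes=1, genes_per_chromosome=120, n_modules=2,
        module_boost_factor=50.0, seed=3,
        background_contact_rate=5.0, inter_chromosomal_rate=0.0,
    )
    cat = generate_genome(cfg)
    _, ann = generate_go_and_annotations(cfg, cat)
    mids = {g.gene_id: (g.start + g.end) // 2 for g in cat}
    lam_same, lam_cross, obs_same, obs_cross = [], [], [], []
    pairs = map_contacts_to_gene_pairs(generate_contacts(cfg, cat, ann), cat)
    genes = sorted(mids)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            d = max(abs(mids[a] - mids[b]), 1)
            lam = cfg.background_contact_rate * (cfg.contact_reference_bp / d)
            c = pairs.get((a, b), 0)
            if ann.module_of[a] == ann.module_of[b]:
                lam_same.append(lam * 50)
                obs_same.append(c)
            else:
                lam_cross.append(lam)
                obs_cross.append(c)
    assert np.mean(obs_same) == pytest.approx(np.mean(lam_same), rel=0.2)
    assert np.mean(obs_cross) == pytest.approx(np.mean(lam_cross), rel=0.2)


def test_expected_count_nonincreasing_in_distance():
    cfg = TINY.replace(seed=2)
    cat = generate_genome(cfg)
    _, ann = generate_go_and_annotations(cfg, cat)
    pairs = map_contacts_to_gene_pairs(generate_contacts(cfg, cat, ann), cat)
    # aggregate observed counts in distance bands; means must trend down
    bands = {}
    for (a, b), c in pairs.items():
        d = genomic_distance(cat[a], cat[b])
        if d is None:
            continue
        bands.setdefault(min(d // 500_000, 5), []).append(c)
    means = [np.mean(bands[k]) for k in sorted(bands)]
    assert means[0] > means[-1]


def test_outputs_identical_under_fixed_seed(tmp_path):
    for sub in ("one", "two"):
        ds = generate_dataset(TINY)
        out = tmp_path / sub
        out.mkdir()
        write_gene_catalog(ds.catalog, out / "genes.tsv")
        write_obo(ds.dag, out / "go.obo")
        write_gaf(ds.annotations, out / "ann.gaf")
        write_fasta(ds.sequences, out / "prot.fa")
        write_contacts(ds.contacts(), out / "contacts.tsv")
    for name in ("genes.tsv", "go.obo", "ann.gaf", "prot.fa", "contacts.tsv"):
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


def test_writers_round_trip_through_readers(tmp_path):
    ds = generate_dataset(TINY)
    write_gene_catalog(ds.catalog, tmp_path / "genes.tsv")
    write_obo(ds.dag, tmp_path / "go.obo")
    write_gaf(ds.annotations, tmp_path / "ann.gaf")
    write_fasta(ds.sequences, tmp_path / "prot.fa")
    recs = ds.contacts()
    write_contacts(recs, tmp_path / "contacts.tsv")

    cat = load_gene_catalog(tmp_path / "genes.tsv")
    assert len(cat) == len(ds.catalog)
    dag = load_go_dag(tmp_path / "go.obo")
    assert dag.terms == ds.dag.terms
    assert {t: set(ps) for t, ps in dag.parents.items()} == {
        t: set(ps) for t, ps in ds.dag.parents.items()
    }
    ann = load_gaf(tmp_path / "ann.gaf", dag)
    for g in ds.annotations.genes()[:20]:
        for ns in ("BP", "CC", "MF"):
            assert ann.terms(g, ns) == ds.annotations.terms(g, ns)
    seqs = read_protein_fasta(tmp_path / "prot.fa")
    assert seqs == ds.sequences
    assert list(read_contacts(tmp_path / "contacts.tsv")) == recs


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(distance_decay_exponent=0.0)
    with pytest.raises(ValueError):
        SyntheticConfig(module_boost_factor=0.5)
    with pytest.raises(ValueError):
        SyntheticConfig(background_contact_rate=-1.0)
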