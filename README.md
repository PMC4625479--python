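# spatialgo

Spatial gene–gene interaction networks from Hi-C chromosomal contact data,
and what they say about gene function.

`spatialgo` is for genomics researchers who want to relate the 3D
organisation of a genome to gene function. It builds gene–gene interaction
networks from Hi-C contacts, quantifies how spatial interaction strength
relates to Gene Ontology (GO) function similarity, genomic distance and
protein sequence identity, and predicts gene function from network
neighbors by guilt-by-association. A synthetic-data generator with planted
functional modules makes the entire pipeline testable without downloads.

## The model

**Interaction networks.** Hi-C read ends are assigned to the genes whose
bodies contain them; each contact record credits every resulting gene pair.
A pair is a *substantial* spatial interaction when its accumulated contact
count *c* satisfies *c* ≥ *t* for a contact threshold *t* (inclusive).
Nodes are the interacting genes; thresholds can be calibrated across
datasets to yield networks of equal size — the package's only
normalisation, since matrix balancing does not apply to gene-level contact
counts.

**Function similarity.** Term–term similarity is Wang's semantic measure:
for a term *t*, each ancestor *a* gets an S-value, S_t(t) = 1 and
S_t(a) = max over children *c* of *a* on paths to *t* of w(c→a)·S_t(c),
with edge contribution factors w_is_a = 0.8, w_part_of = 0.6; then

    sim(t1, t2) = Σ_{a ∈ anc(t1) ∩ anc(t2)} (S_t1(a) + S_t2(a))
                  ────────────────────────────────────────────────
                  Σ_{a ∈ anc(t1)} S_t1(a) + Σ_{a ∈ anc(t2)} S_t2(a)

Gene-pair similarity in a category (BP/CC/MF) is the maximum term-level
similarity over the two genes' annotation sets, binned into ten bins with
bin 10 = [0.9, 1] ("near-identical function").

**Sequence identity.** Two measures side by side: the classic longest
common subsequence recursion c[i,j] = c[i−1,j−1]+1 on a match, else
max(c[i,j−1], c[i−1,j]), normalised by the longer sequence's length; and
Needleman–Wunsch global alignment under BLOSUM62 (gap open 10, extend 0.5)
scored as identical columns over alignment length.

**Function prediction.** From an annotated training network the package
estimates P(gene has term G_j | a neighbor has term G_i) over ordered
adjacent gene pairs. To predict for a gene, one annotated neighbor is drawn
at random, every candidate term accumulates P(G_j | G_i) over the
neighbor's terms, and the top-k terms are reported. Prediction accuracy is
the maximum Wang similarity between any predicted and any true term.

## Worked example

```python
from spatialgo import SyntheticConfig, generate_dataset, build_network, \
    map_contacts_to_gene_pairs
from spatialgo.ontology import GenePairSimilarity
from spatialgo.pipeline import build_pair_table
from spatialgo.association import bin_statistics

cfg = SyntheticConfig(seed=1)            # 4 x 250 genes, 10 modules, beta = 30
ds = generate_dataset(cfg)
pairs = map_contacts_to_gene_pairs(ds.contacts(), ds.catalog)
net = build_network(pairs, threshold=18)
print(f"network: {net.graph.number_of_nodes()} genes, {net.graph.number_of_edges()} edges")

sim = GenePairSimilarity(ds.dag, ds.annotations)
table = build_pair_table(pairs, sorted(net.edges), ds.catalog, sim, ds.sequences)
print(bin_statistics(table, "contact_count", "BP")[["mean", "median", "n"]].round(1))
```

prints

```
network: 1000 genes, 5725 edges
      mean  median     n
bin
1      NaN     NaN     0
2     63.8    29.0    13
3     42.8    34.0    37
...
9     43.7    29.0   221
10   104.3    36.0  4608
```

Gene pairs with near-identical function (bin 10) average 104 contacts
against ~44 for every other bin — the planted "strong spatial interaction ↔
shared function" association recovered by the pipeline. With the module
boost turned off (`module_boost_factor=1`), bin 10 loses its excess.

The same workflows are scriptable from the shell:

```sh
spatialgo synth --out data/ --seed 1
spatialgo build-network --genes data/genes.tsv --contacts data/contacts.tsv \
    --threshold 18 --out edges.tsv
spatialgo associate --synth-config cfg.yaml --threshold 18 --out report/ --seed 1
spatialgo run-all --out report/ --seed 1
```

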