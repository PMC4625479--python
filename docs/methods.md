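# Methods

## From Hi-C contacts to interaction networks

A contact record is a pair of genomic positions (optionally with a
pre-aggregated count; absent, each row counts one). Each end is assigned to
*every* gene whose body contains it — the record then credits every cross
pair of distinct genes. Positions falling between genes contribute nothing
and self pairs are excluded. This read-end-in-gene-body counting is the
simplest defensible rule when the assay's fragment structure is not
modelled; promoter windows or fragment-level assignment would be natural
refinements but are not implemented.

Thresholding is inclusive: an edge survives at threshold *t* when its count
is ≥ *t*. The networks at increasing thresholds are nested, which the test
suite asserts. Inter-chromosomal contacts are kept in networks; only the
distance-based analyses drop pairs whose genomic distance (|Δ start|, same
chromosome) is undefined. No contact-matrix normalisation is applied —
gene-level counts have no equal-width bin structure for ICE-style balancing
to act on. Instead, `calibrate_threshold` finds, for a target network size,
the *largest* threshold whose node count still reaches the target: the most
stringent, hence most stable, comparable network. Thresholds in the 7–18
range are sensible defaults for deeply sequenced datasets (documented
defaults, not reproducible constants, since they depend on sequencing
depth).

## Wang similarity

S-values are computed by relaxing edges outward from the query term; since
every contribution factor lies strictly inside (0, 1) the relaxation
terminates and equals the max-product-over-paths definition, which the test
suite checks against an exhaustive path-enumeration oracle on random DAGs.
Contribution factors default to 0.8 (is_a) and 0.6 (part_of) — the
published defaults of the measure — and are configurable because analyses
in this area rarely state them. Annotations are used exactly as given: no
up-propagation to ancestors before taking the max, because the DAG-aware
term similarity already credits shared ancestry, and propagating first
would inflate every similarity toward 1. One similarity measure serves both
the association analyses and the prediction evaluation, so that the two
halves of the package are comparable; per-DAG caches of S-value tables and
term-pair scores change runtime only, never values (asserted in tests).

Gene-pair similarity is undefined when either gene lacks annotations in the
category; undefined pairs are excluded statistic by statistic rather than
imputed.

## Binned statistics

Similarity bins follow the fixed convention bin b = [(b−1)/10, b/10) for
b = 1..9 and bin 10 = [0.9, 1] closed. Equal-count genomic-distance deciles
rank pairs by (distance, gene_a, gene_b) — a stable, reproducible tie rule
— with the remainder spread over the lowest bins. The bin-9 vs bin-10
contact-count comparison uses Welch's unequal-variance two-sample t-test,
two-sided, with Welch–Satterthwaite degrees of freedom. Zero-contact
control pairs are sampled uniformly without replacement (rejection sampling
against the sparse nonzero-pair map); distance-matched sampling accepts a
candidate when its distance is within 35 bp of the reference — printed
tolerance, configurable, and surprisingly tight for genomic distances,
which is noted rather than silently widened. Factor thresholds for flagging
near-identical-function pairs default to ≥ 50 contacts, distance ≤ 1 Mb
(BP, MF) or ≤ 2 Mb (CC), and identity ≥ 25 %.

## Sequence identity

The LCS table is the full (m+1)×(n+1) integer dynamic program (numba-jitted;
protein lengths make the quadratic table cheap), normalised by the longer
length. The Needleman–Wunsch comparison delegates global affine-gap
alignment to Biopython's `PairwiseAligner` with BLOSUM62 and EMBOSS-style
penalties (open 10, extend 0.5 — unstated in the analyses this mirrors, so
the community defaults are used); "identity" is identical columns over the
full alignment length, gap columns included, taking the first co-optimal
alignment in the aligner's deterministic order. Residues outside the
BLOSUM62 alphabet score through its X row. When several proteins map to one
gene the longest is the representative. Both identities are always computed
and reported side by side, since figures in this literature switch between
them without flagging which is which.

## Function prediction

P(G_j | G_i) is estimated as joint/marginal counts over ordered adjacent
pairs (u, v): each undirected edge contributes in both directions, v is the
conditioning neighbor, and pairs with an unannotated endpoint contribute to
neither table (an unobservable co-annotation event must not deflate the
conditional). Unseen (G_j, G_i) combinations have probability zero; Laplace
smoothing exists behind a flag, off by default. Prediction uses a single
uniformly drawn annotated neighbor — as the five-step procedure prescribes
— with an extension flag for averaging over all annotated neighbors, off by
default. Ranking ties break lexicographically by term id for
reproducibility. Models are per category (BP/CC/MF); pooling across
categories is never done. Training and prediction networks are distinct
objects, and the pipeline records the size of their gene overlap in the run
manifest, because shared genes let the model partially memorise the
training annotations (see "Negative control" below).

## The synthetic generator

The generator emulates exactly the structure the analyses assume:

* **Genome** — genes laid left to right per chromosome, exponential lengths
  (mean 30 kb) and gaps (mean 70 kb): roughly one gene per 100 kb, the
  density of gene-rich human chromosome arms. Defaults: 4 chromosomes × 250
  genes.
* **Ontology and annotations** — three namespaces, each a balanced is_a
  tree (depth 4, branching 3 by default; ~15 % of edges re-typed part_of).
  Genes are partitioned randomly into 10 modules; each module owns a deep
  internal term and its leaves, every member carries the same module core
  leaf (within-module similarity exactly 1), optionally the parent and one
  extra leaf, plus 3 private uniform terms. The coarse default tree is
  deliberate: it produces a well-populated spread of pairwise similarities
  across bins 1–10, including the parent–child scores (~0.84) that fill
  bin 9.
* **Sequences** — one protein per gene (length ~Poisson, mean 300). Within
  each module, 40 % of members form a duplicated family: independent
  mutated copies (5 % per-site substitutions) of a founder sequence, so all
  within-family pairs combine high identity with identical function, the
  signature of duplicated gene families.
* **Contacts** — for an intra-chromosomal pair at distance d the expected
  count is rate·(d0/d)^α·β^[same module], with rate 30 at the d0 = 100 kb
  reference, α = 1 (the field-standard power-law contact decay), and module
  boost β = 30; inter-chromosomal pairs use a flat expectation 0.02·β^[·].
  Counts are Poisson draws emitted as positional records at gene midpoints,
  so the real read-end mapping path is exercised. β = 1 is the null model:
  contacts then carry no functional signal because modules are assigned
  independently of position.

Everything is a deterministic function of the configuration seed.

What the generator does *not* emulate: GC/mappability and restriction-site
biases, fragment-level resolution, strand effects, unannotated genes,
population heterogeneity of cell ensembles, and realistic GO term depth
heterogeneity. Passing tests therefore demonstrate that the pipeline
recovers plantable associations of this shape — not that any particular
real dataset exhibits them.

## Study conditions for the checks

Association analyses (signal recovery, null calibration, correlation
contrast) run at the desk-scale defaults above with contact threshold 18 at
seed fixed by the caller; the null calibration holds genome and annotations
fixed and redraws contacts per replicate, which isolates the stochastic
stage under test and keeps 100 replicates inside a minute.

The prediction study uses the same genome and contact model but 50 smaller
modules on a depth-7, branching-3 ontology (3 280 terms per namespace).
With the coarse association ontology the accuracy metric saturates: ten
predicted terms can cover all ten planted function groups, and in a
shallow tree every term is semantically near every other, so any method —
including a deliberately broken one — scores ≈ 0.9. A fine ontology keeps
the evaluation discriminative.

**Negative control.** Because training and prediction datasets share the
genome, adjacent genes are connected in both networks, and a model trained
and evaluated on the *same* permuted annotation file simply memorises the
permuted annotations through those shared edges — measured lift under that
protocol is ≈ 0 regardless of annotation content. The control used here
permutes the annotations consulted for neighbor selection and neighbor
terms at prediction time, while the trained model and the evaluation truth
stay fixed. This ablates precisely the guilt-by-association channel (does
the neighbor's actual function matter?) and yields a mean-accuracy drop
from ≈ 0.86 to ≈ 0.43 at k = 10 under the default conditions.

## Numerical and degenerate-input conventions

* Welch test on two identical constant groups returns t = 0, p = 1 by
  convention; two different constant groups are an error.
* Pearson correlation with a constant input is reported as undefined, not 0.
* Min–max count normalisation after dropping the top 20 outliers maps an
  all-equal remainder to 0.
* Median-distance splits send ties to the short-range group.
* Empty similarity bins are reported with n = 0 and NaN statistics, never
  fabricated.
* All samplers accept either an integer seed or a live numpy Generator;
  pipeline stages derive their streams from the single run seed recorded in
  the manifest.

## Known limitations

Threshold calibration assumes node counts change at observed pair counts
only (exact, but the returned threshold is one of the observed counts).
The conditional model ignores term co-occurrence within the neighbor's set
(each G_i contributes independently). Prediction from a single random
neighbor is faithful to the described procedure but noisier than averaging
over neighbors. Real-data runs require externally supplied gene tables,
contact lists, OBO/GAF and FASTA files; no downloading is performed.
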