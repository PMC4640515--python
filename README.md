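# phagenet

Gene-sharing network classification of bacteriophage genomes.

Phage taxonomy resists tree-based methods: rampant horizontal transfer and
mosaicism mean different genes tell different stories. A robust alternative
treats each genome as the *set of protein families* it encodes and asks, for
every pair of genomes, whether they share more families than chance allows.
The resulting weighted network is decomposed into clusters of densely
connected genomes — candidate genera — while genomes whose edges spread over
several clusters are flagged as mosaics. `phagenet` implements this pipeline
end to end, together with the pairwise comparative genomics used to place a
newly sequenced phage among its relatives, and a synthetic-community
generator with planted ground truth so that every stage can be validated
without any external database.

## The model

Let the community contain *n* genomes annotated against *N* protein
families. For genomes *A* and *B* with repertoire sizes *a* and *b* sharing
*c* families, the chance of an overlap at least as large under random
sampling is the hypergeometric upper tail

P(X ≥ c) = Σᵢ₌ c^min(a,b) C(a,i) C(N−a, b−i) / C(N,b).

Correcting for the T = n(n−1)/2 pairwise comparisons gives the edge weight

**Sig(A,B) = max(0, −log₁₀(P · T))**,

and pairs with Sig > 1 form the gene-sharing network. The network is
partitioned by Markov clustering (MCL): the column-stochastic adjacency
matrix is alternately squared (expansion) and raised elementwise to the
inflation power (inflation, with renormalization) until convergence;
attractor systems of the limit matrix are the clusters. Inflation is swept
over 1.2–5.0 in steps of 0.2 and the clustering maximizing the intra-cluster
clustering-coefficient homogeneity (ICCC) is kept. Each node's *membership*
in cluster *k* is the proportion of its incident Sig weight carried by edges
into *k* — a row-stochastic matrix whose spread quantifies mosaicism.
Upstream, protein families are built from pairwise local-alignment evidence
(E < 10⁻⁴, single linkage, optional reference-family adoption); downstream,
reciprocal-best-hit (RBH) ORF pairing yields per-genome-pair amino-acid
identity statistics, and small genome utilities report GC content and exact
direct terminal repeats (DTRs).

## Worked example

Simulate a 3-cluster community of 30 genomes (20 core families per cluster,
10 accessory at 50% carriage, 3 private background families per genome) plus
one 50/50 mosaic, then run the full pipeline:

```bash
phagenet simulate --n-clusters 3 --genomes-per-cluster 10 \
    --core-families 20 --accessory-families 10 --background-families 3 \
    --n-mosaic 1 --mosaic-mixture 0.5,0.5,0 --seed 1 --outdir sim
phagenet families --fasta sim/proteins.faa \
    --out-families families.tsv --out-profile profile.tsv
phagenet network --profile profile.tsv --out net.graphml
phagenet mcl-sweep --graph net.graphml \
    --out-clusters clusters.tsv --out-sweep sweep.tsv
phagenet membership --graph net.graphml --clusters clusters.tsv \
    --out membership.tsv
phagenet topology --graph net.graphml --out topology.tsv \
    --out-summary topology.json
```

prints

```
seed=1
wrote 31 proteomes, 868 proteins to sim
868 proteins -> 178 families
31 nodes, 151 edges (Sig > 1.0, N = 178, T = 465)
best inflation 1.2: 3 clusters, homogeneity 1.0000
31 nodes x 3 clusters
mean CC 0.9667; 2 component(s) of sizes [21, 10]
```

Reading the numbers: the 868 simulated protein sequences collapse to 178
families; the Sig network recovers the planted structure — the inflation
sweep finds exactly 3 clusters at perfect homogeneity (every cluster is a
clique-like module, hence the mean clustering coefficient near 1), and the
mosaic genome bridges two planted clusters into one 21-node component while
the third cluster stays a separate 10-node component. `membership.tsv`
contains each genome's row-stochastic affiliation to the three clusters;
`clusters.tsv`, `sweep.tsv` and `topology.tsv` hold the partition, the full
inflation sweep table, and per-node degree/CC/betweenness. The network file
is Cytoscape-readable (GraphML; edge-TSV and SIF also supported).

Comparative genomics on protein FASTA files (`phagenet compare`) emits RBH
tables and a mean-identity matrix; `phagenet genome-stats` reports genome
length, GC% and the exact terminal-repeat length.

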