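# refdbkit

Curation, comparison, and simulated-classification evaluation of
nucleotide **sequence taxonomy reference databases** — the reference
materials behind marker-gene (16S rRNA, ITS, COI, …) and metagenome
taxonomic profiling.

Reference databases such as SILVA, Greengenes, GTDB, NCBI-RefSeq, UNITE
or BOLD differ in size, rank conventions, label quality, and sequence
quality, and those differences propagate directly into downstream
community profiles. `refdbkit` gives researchers a reproducible,
scriptable way to:

- **parse and standardize taxonomies** from SILVA-style three-file
  releases (taxrank / taxmap / Newick taxtree) and NCBI taxdump-style
  tables onto a fixed rank schema, with optional *rank propagation*
  (forward-filling unannotated ranks with the last observed ancestor
  label) and species labels derived from organism names;
- **quality-filter sequences** (homopolymer runs, ambiguous bases,
  global and per-taxon length bounds, minimum annotation depth);
- **dereplicate and cluster** sequences into OTUs at a percent-identity
  threshold, reconciling member taxonomies by LCA, majority, or
  rank-wise ("super") consensus;
- **measure database information content**: per-rank unique labels,
  Shannon entropy `H = −Σ pᵢ ln pᵢ` of label / sequence / k-mer
  frequency vectors, terminal-rank distributions, genus–species label
  consistency, and prefix-collapsed cross-database label overlap;
- **simulate classification accuracy** with a k-mer multinomial
  naive-Bayes classifier under two regimes: *fit-classifier*
  (train = test, deliberately leaky, the best-case upper bound) and
  stratified *k-fold cross-validation* with LCA truncation of
  taxonomic-singleton expectations, scored per rank as precision /
  recall / F-measure.

A seeded synthetic-database generator (`refdbkit.synth`) emulates all of
these inputs — hierarchical lineages, per-species sequence families at
controlled divergence, planted quality defects and ambiguous labels —
so every stage is testable offline, with ground truth attached.

## Worked example

```python
from refdbkit import (FixtureSpec, generate_reference_db, cluster_greedy,
                      evaluate_taxonomy, evaluate_fit_classifier,
                      evaluate_cross_validate)

spec = FixtureSpec(seed=1, n_genera_per_family=2, n_species_per_genus=3,
                   seqs_per_species=5)
seqs, tax, truth = generate_reference_db(spec)
print(f"{len(seqs)} records, {len(truth.species_members)} planted species")

result = cluster_greedy(seqs, tax, perc_identity=0.97)
print(f"clusters at 97% identity: {result.n_clusters}")

print(evaluate_taxonomy(tax).round(3))

fit_rep = evaluate_fit_classifier(seqs, tax)
cv_rep = evaluate_cross_validate(seqs, tax, seed=1)
print(f"species F: fit={fit_rep.loc['species','f_measure']:.2f} "
      f"cv={cv_rep.loc['species','f_measure']:.2f}")
```

prints

```
60 records, 12 planted species
clusters at 97% identity: 12
         unique_labels  entropy  unclassified  terminal
rank
domain               1    0.000             0         0
phylum               2    0.693             0         0
class                2    0.693             0         0
order                2    0.693             0         0
family               2    0.693             0         0
genus                4    1.386             0         0
species             12    2.485             0        60
species F: fit=1.00 cv=1.00
```

Reading the output: the 60 generated sequences fall into 12 planted
species (4 genera), and greedy clustering at 97% identity recovers
exactly those 12 clusters, because within-species identity (0.99) is
above the threshold and between-species divergence (0.10) is well below
it. The per-rank report shows label richness and evenness: two
equally-sized phyla give entropy ln 2 ≈ 0.693, twelve equally-sized
species give ln 12 ≈ 2.485, and every record's annotation terminates at
species. On this cleanly separable database both evaluation regimes
reach a species-level F-measure of 1.0; on noisier databases the
cross-validated score drops below the best-case fit-classifier score.

The same operations are available as a CLI mirroring the library
(`refdbkit cull-seqs`, `filter-seqs-length`, `filter-seqs-length-by-taxon`,
`dereplicate`, `evaluate-taxonomy`, `evaluate-seqs`,
`evaluate-fit-classifier`, `evaluate-cross-validate`,
`evaluate-classifications`, `parse-silva-taxonomy`,
`build-ncbi-taxonomy`, `compare-taxonomies`, `generate-fixture`); each
run writes a JSON provenance sidecar with the effective parameters.

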