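# Methods

This note documents the models, procedures, numerical choices and
limitations behind `refdbkit`, in the order the pipeline runs.

## Taxonomy model

A taxonomy is a fixed, ordered **rank schema** (e.g. `d__` domain …
`g__` genus, or `k__` … `s__` species) plus, per record, a **lineage**:
one label per rank and a parallel *informative* mask. The mask is the
load-bearing design choice: empty labels, labels matching a
configurable ambiguous vocabulary (case-insensitive substrings
`unidentified, uncultured, unknown, unclassified, metagenome,
environmental`), and labels produced by rank propagation are all
flagged non-informative. Every "unclassified", "terminal rank" and
annotation-depth computation reads this mask rather than re-parsing
label text, so a propagated database evaluates identically to its
unpropagated source. This resolves an ambiguity in how "unclassified"
should be counted after forward-filling: propagated labels are treated
as placeholders, not annotations, and the switch is the mask itself.

**Rank propagation** forward-fills *empty* ranks with the last observed
non-empty label above. Non-empty but ambiguous labels (e.g.
`c__uncultured`) are deliberately preserved rather than overwritten:
they are observed values in the source data, and the mask already
records that they carry no information. Propagation is idempotent and
never changes the mask.

**Consensus modes.** `lca` is the longest rank-wise common prefix;
`majority` is the modal full lineage, with ties resolved to the LCA of
the tied lineages (deterministic and conservative — a tie means the
data cannot distinguish the candidates, so only their agreement is
kept); `super` builds the lineage top-down, at each rank taking the
most frequent label among lineages consistent with the prefix chosen so
far and stopping at the first tie.

**Prefix collapsing** (used for cross-database label overlap) groups
labels transitively when one is a string prefix of another
(`Lactobacillus` / `Lactobacillus_A`) and represents each group by its
shortest member, so subclade suffixes do not undercount sharing.

## Importers

*SILVA triplet.* Each accession's taxid resolves through the Newick
taxtree to a root-to-leaf path; node names whose rank matches a schema
rank (exact, case-insensitive) are assigned; with propagation, an
unassigned schema rank takes the name of the last path node observed
before the next assigned rank — so an unmapped sub-phylum fills the
empty class–genus slots below it, exactly reproducing the standard
forward-fill behaviour on such paths. Species labels are optionally
derived from the taxmap organism name as its **first two whitespace
tokens** (sub-species detail in organism names degrades label
consistency). Tokens are kept verbatim, including markers like "sp." —
a documented caveat, not corrected. Ranks above the first assigned rank
are never filled (propagation is downward only).

*NCBI taxdump.* Parent chains are ascended to the root (the root is its
own parent; cycles are detected and reported), ranks below species
(strain, subspecies, …) are dropped, and `superkingdom` aliases to the
schema's top rank through a configurable alias map. Projection and
forward fill share the SILVA code path. Both the classic `|`-delimited
dialect and plain TSV are accepted; online retrieval is out of scope —
tables are local files.

## Sequence curation

All comparisons are strict (`>`), matching the usual thresholds'
phrasing: a record is culled when its longest single-base run exceeds
`max_homopolymer` (default 8) **or** its count of non-ACGT IUPAC codes
exceeds `max_ambiguous` (default 5). Homopolymers are measured after
degapping (gaps would otherwise hide runs); `U` is normalized to `T` on
read. Within `cull_seqs` the homopolymer rule is checked first — this
affects only the reason attributed in the report, never the kept set.
Length filters are inclusive on both bounds; the per-taxon variant
(e.g. Archaea ≥ 900 nt, Bacteria ≥ 1200 nt) matches constrained labels
anywhere in the lineage by default (an `at_rank` option restricts
matching to one rank), and a record matching several constraints must
satisfy all of them. Every filter preserves input order and reports
`kept + removed = input`, with each removal attributed to exactly one
reason.

## Dereplication and clustering

Pairwise identity is computed from a Needleman–Wunsch global alignment
(match +1, mismatch −1, gap open −5, gap extend −2) as matching columns
divided by alignment columns, with terminal-gap columns excluded from
the denominator. End gaps are *penalized* in the alignment itself:
scoring them free lets unrelated sequences meet in a short perfect
overlap and report spuriously high identity. Clustering is greedy and
deterministic: records sorted by decreasing length (ties by
identifier), each joining the first centroid — in creation order — at
or above the threshold, else founding a new centroid.
First-created-centroid tie-breaking is a documented choice; it makes
results independent of hash ordering. The optional shared-k-mer
prescreen only skips alignments that cannot reach the threshold on the
test fixtures; it is off by default. Complexity is O(n²) alignments,
appropriate for the desk-scale databases this package targets, not for
million-record releases.

## Database metrics

Shannon entropy is reported in **nats** (natural log), delegating to
`scipy.stats.entropy`; a bits option exists for display. Unique-label
counting at rank *r* uses full lineage prefixes to depth *r* (identical
genus names under different families count separately); cross-database
overlap instead compares bare rank-label tokens after prefix
collapsing, since label sharing between databases is a question about
names, not about paths. Both conventions are separately exposed.
Sequence entropy uses occurrence frequencies of distinct sequence
strings (a richness-only switch exists); k-mer entropy pools all
overlapping forward-strand k-mers across records at k ∈ {2, 4, 8, 16}
by default, skipping k-mers containing ambiguous characters, with no
canonicalization (a documented switch could add it; forward-strand-only
is correct for single-stranded marker-gene reference sets).

## Naive-Bayes classifier

One class per distinct full training lineage; features are k-mer counts
(default k = 7), smoothed as `(count + α) / (total + α·4^k)` with
α = 0.001; priors are uniform. All arithmetic is in log space with
log-sum-exp normalization — with 1000+ nt sequences the likelihood
products underflow double precision by hundreds of orders of magnitude
otherwise. K-mers containing ambiguous characters are skipped rather
than expanded over IUPAC codes, for determinism and speed.
Classification walks the taxonomy from the root: posterior mass is
aggregated over classes sharing each candidate label, the
highest-mass child is followed (ties broken lexicographically) while
its aggregated posterior stays ≥ the confidence threshold (default
0.7), and the deepest accepted prefix is reported; depth 0 is
"Unassigned". Aggregated mass along the chosen chain is non-increasing
with depth, so the reported depth is well defined. Models serialize to
a single versioned `.npz` archive and reload bit-identically.

## Evaluation regimes

`stratified_kfold` groups entries by full lineage and deals members
round-robin over k folds (default k = 3) in seeded-shuffled order; the
starting fold rotates across groups so singleton lineages spread over
folds instead of stacking in the first. Groups smaller than k appear in
fewer folds; every record is tested exactly once.

For a test fold, the **expected** taxonomy keeps lineages that also
occur in the training fold and truncates the rest to their longest
rank-wise prefix shared with any training lineage — the LCA with the
nearest training taxon, read as a pure taxonomy distance (no sequence
distance is involved; this is the minimal operationalization of
"nearest"). Truncation applies whenever the full lineage is absent from
the training fold, which generalizes the singleton case: a non-singleton
group that a fold split leaves unrepresented in training is truncated
the same way.

Scoring is per rank over the pooled queries of all folds (a single
micro-averaged confusion tally — deterministic, and independent of fold
sizes): TP when expected and observed are both informative at the rank
and their full prefixes to that rank match; over-classification counts
only against precision, under-classification only against recall,
misclassification against both; empty denominators score 0 and are
flagged. `evaluate_fit_classifier` trains and tests on the full
database — the leakage is intentional and bounds accuracy from above,
which is why its species-level F always dominates the cross-validated
score on the same inputs.

## Synthetic databases

The generator plants a known hierarchy and returns it as ground truth.
Sequences evolve by substitution only, along a family → genus → species
ancestor chain: genus ancestors at `between_genus_divergence / 2`
(default 0.20) from the family ancestor, species ancestors at
`between_species_divergence / 2` (default 0.10), members at
`1 − within_species_identity` (default 0.99) from the species ancestor
— with substitutions at exact counts, member-to-ancestor identity
equals the spec value by construction, and gap-free alignments recover
it exactly. Defaults (2 phyla × 2 genera × 3 species × 4–5 members,
300 nt) keep the planted clusters unambiguous at a 97% threshold:
within-species pairs sit near 0.98 identity, between-species pairs near
0.81. Background homopolymer runs are capped at 6 during generation, so
the only records failing the default quality filters are the injected
ones; injected homopolymers are written with explicit differing flanks
(run length exact) and injection categories use disjoint record sets,
making filter attribution unambiguous. Ambiguous species labels
("uncultured organism") replace the true label in the emitted taxonomy
while the truth table keeps the original. All randomness flows from one
`numpy` PRNG seeded by the spec, and outputs are byte-identical across
runs.

What the generator does *not* emulate: indels (an indel mode exists for
stress tests but is off by default, so planted identities stay exact),
realistic phylogenetic branch-length distributions, chimeras, rank
heterogeneity within a database, or the heavy-tailed redundancy of real
releases. Passing tests therefore demonstrate algorithmic correctness
on controlled structure, not expected accuracy figures on real
databases — real-database scores depend on curation depth and sequence
space coverage in ways no synthetic fixture reproduces.

## Problem sizes and determinism

Tests and the acceptance script use 48–100 record databases with 300 nt
(filter fixtures: 1300 nt) sequences — large enough that every planted
property is non-trivial, small enough that the O(n²) clustering sweep
and repeated cross-validation stay fast on one CPU. Exhaustive oracles
run over complete small domains (all ≤4-multisets of 27 lineages for
consensus; all ≤3-query two-rank label configurations for the scorer).
All CLI subcommands are pure functions of (inputs, options): identical
re-runs produce byte-identical primary outputs, and effective
parameters are recorded in a JSON provenance sidecar per run.

## Known limitations

- No nomenclatural validation against the codes of nomenclature
  (ICNP/ICNafp/ICZN/ICTV); labels are strings.
- No chimera detection, primer-region trimming, or abundance-weighted
  clustering.
- The greedy clusterer emulates centroid-based OTU picking but is not a
  drop-in replacement for any specific external tool's output.
- Online retrieval from SILVA/NCBI is out of scope; importers read
  local files only.
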