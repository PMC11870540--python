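# Methods

## Scope and model

motortrace answers a comparative-genomics question: in which bacterial
genomes are the inner-membrane scaffold components of complex flagellar
motors present, how do they co-distribute with the flagellar gene set and
with type IV pilus (T4P) systems across a species tree, and what does that
imply about their ancestral presence?  The pipeline operates entirely on
evidence tables (profile and pairwise sequence hits), gene coordinate
tables, protein feature annotations and a rooted species tree; it never
runs a search tool itself, so any HMMER/BLAST-compatible producer can feed
it.

Screens combine three kinds of signal:

1. **Evidence quality.** E-value cutoffs follow strict-inequality wording
   (a hit at exactly 1e−3 does not qualify) except in the core-gene
   census, where the ceiling is inclusive.  Defaults: 1e−3 for scaffold
   screens and best-hit calls, 1e−5 for T4P components and the census.
2. **Genomic context.** Distances are intervening-gene counts, strand
   agnostic: the number of genes strictly between two genes on a replicon
   (0 for adjacent or identical genes; circular replicons take the shorter
   arc when flagged).  A "flagellar gene cluster" is a maximal run of
   core-family genes with ≤ 5 intervening genes between consecutive
   markers; the context rule accepts a candidate within 5 genes of the
   nearest cluster *member* (equivalent to edge counting at cluster
   boundaries).  Operons are maximal runs of same-strand,
   index-consecutive genes with ≤ 150 bp intergenic gaps (overlapping
   genes always group).
3. **Protein features.** Transmembrane motifs, signal peptides, the
   antiparallel β-pair flag and enzymatic domain labels are externally
   supplied inputs; the blacklist (glycosyltransferase, methyltransferase,
   acetyltransferase, sulfotransferase, metalloprotease) is absolute — a
   TPR protein carrying any of these is never called a scaffold.

Family-specific logic and tie-breaks:

* The census classifies a species as flagellated at ≥ 20 of 24 core
  families; the relaxation absorbs incomplete assemblies and pseudogenes.
  The census E-value ceiling (1e−5, inclusive) is a package default — the
  rule itself specifies no cutoff — and is exposed in configuration.
* FlgY rescue candidates (genes within ±2 of *fliJ*/*fliK* in flagellated
  genomes with no validated call) are a review tier: they are reported but
  never counted in presence matrices.
* "Sequential" TPR motifs are runs of PF00515 hits, ordered by envelope
  start, with ≤ 50 aa between consecutive envelopes; the run threshold is
  3.  The 50 aa gap bound is our quantification of "sequential" and is
  configurable.
* Candidates lacking the structural β-pair flag default to PflA-like; the
  flag is a 3D feature that sequence evidence cannot establish.
* Fcp vs Pil discrimination is mechanized neighborhood curation: a
  PilN-anchored triplet with *pilP*/*pilQ* within 5 genes is a pilus
  cluster; one with other TFF genes nearby goes to a review report rather
  than being silently decided; one with no TFF genes nearby is the
  flagellar cage operon, with an immediately upstream (strand-aware)
  *miaB* recorded as supporting evidence but not required.
* Best-hit calls (used for close-range screens within a phylum, and for
  PflD, which has no usable profile) take the minimal E-value below 1e−3,
  breaking ties by higher bit score, then lexicographically smallest
  locus tag.  PflD is deliberately screened only this way: profile-based
  search for it across distant phyla would be biased by the narrow
  training set, so the domain-wide pipeline carries PflD solely through
  best-hit evidence.
* Gene fusions are called when one protein carries qualifying hits to both
  profiles whose best envelopes overlap by ≤ 10 % of the shorter span.
* T4P detection requires the canonical *pilMNOPQ* gene order on one strand
  (cluster gap ≤ 3), reading in either genomic direction, and ≥ 2 of the
  four motor/platform genes genome-wide.

## Curation

Quality filtering removes genomes with completeness strictly below 70 % or
contamination strictly above 10 %; boundary values are retained, matching
the rule's wording, and pinned by tests.  Taxonomic balancing caps groups
at 200 genomes (complete assemblies first, then one genome per genus).
Within a genus the choice is by descending model-organism priority — a
supplied integer column; no organism list is embedded — then smallest
accession; this tie-break is our own, as is applying balancing before the
quality filter (both orders are exposed on the CLI).  Selection is made
order-invariant by sorting outputs on accession.

## Phylogenetic profiling

Presence matrices count `context_validated` and `best_hit` call tiers by
default.  Co-occurrence is summarized by the Jaccard index (primary) with
a right-tail hypergeometric probability of at-least-observed overlap as a
supplementary statistic — the underlying claim of "strict co-occurrence"
is qualitative, so the test quantifies rather than replaces it.  Ancestral
presence uses generalized Fitch small parsimony (sequential
intersection/union merge at polytomies; exact minimum on binary trees),
our explicit formalization of the verbal inference that a trait present
throughout a clade existed in its common ancestor; a Dollo variant
(single gain at the MRCA of present leaves, losses only below it) is
provided for traits where regain is implausible.  Tree construction is out
of scope; trees are inputs.

## Synthetic pangenome generator

The generator plants the structures the screens assume, with full
per-gene truth labels:

* a random rooted binary tree (sequential joins, unit branch lengths —
  topology, not branch length, drives everything downstream);
* flagellation either planted on the clade whose size best matches the
  target fraction (default 60 % of 50 species) or evolved by per-branch
  Markov flips; scaffold traits mirror flagellation in both modes so
  that planted genomes stay internally consistent (a scaffold gene needs
  a flagellar cluster to sit near), which also realizes the perfect
  co-occurrence regime; T4P presence is an independent Bernoulli draw
  (default 0.5), with *pilM–pilN* fusion at 0.5 among T4P-positive
  genomes;
* genomes of 1,000 genes (small-bacterial-genome scale) on one replicon,
  with the 24 core families split over 3 contiguous clusters, scaffold
  genes attached within the 5-gene context distance, *fliJ*/*fliK* beside
  one cluster, the *miaB–fcpMNO* operon and the *pilMNOPQ* cluster (plus
  *pilBCTU* elsewhere) planted in separate genome segments, and decoy TPR
  enzymes (3 per genome) placed strictly farther from any flagellar
  cluster than the context rule allows;
* evidence tables in which every true gene emits hits far below threshold
  (E = 10^−U(6,50)) through two channels (profile and sequence), false
  negatives drop rows independently at the configured rate, and false
  positives hit random background genes at E = 10^−U(1,4) — straddling
  the 1e−3/1e−5 cutoffs so threshold behavior is exercised on both sides;
* Fcp and Pil queries cross-hit each other's genes, as real homologs
  would, which is precisely what the neighborhood discrimination has to
  resolve;
* assembly metadata with completeness ~ U(50,100) and contamination ~
  U(0,20), so the quality filter removes a substantial fraction (~70 %)
  and downstream metrics are computed over the curated set only;
* protein FASTA stubs contain random residues: all evidence flows through
  hit tables, decoupling the pipeline from any live search tool.

What the generator does *not* emulate: sequence evolution (hit E-values
are drawn, not computed), horizontal transfer, paralogy beyond the planted
decoys and Fcp/Pil cross-hits, multi-replicon architecture, assembly
fragmentation, and correlated errors between evidence channels.  Passing
recovery tests therefore demonstrate that the *decision rules* are
implemented and discriminate correctly under the stated noise model — not
that any particular profile or query set would achieve the same accuracy
on real genomes.

## Numerical and determinism choices

All randomness flows from a single integer seed through per-stage
`numpy` SeedSequence streams, so identical configurations yield
byte-identical emitted files and run reports (checked by hashing).
E-values and scores are rounded to their serialized precision at
generation time, making emit→parse an exact identity on every table.
Coordinates are 1-based inclusive (GFF3); ordinal gene indices 0-based.
Degenerate inputs are defined, not special-cased: a single-species tree
has no internal nodes; genes on different replicons are at infinite
distance; an empty marker set yields no clusters; prevalence over an
empty subset is an error rather than a NaN.

## Problem sizes

Tests and the acceptance script run the pipeline at 50 simulated species
with 1,000 genes per genome (recovery: 1 run; noise robustness: 20
replicates at 5 % false-positive and false-negative rates), and verify the
parsimony implementation against an exhaustive-minimum oracle on every
rooted binary topology with up to 6 leaves under every leaf labeling, the
distance function against span enumeration on 1,000 random cases, and the
hypergeometric tail against complete enumeration of C(20,10) draws.
These sizes were chosen to exercise every rule path while keeping a full
run in the tens of seconds.

## Known limitations

The balancing rule's "group" is whatever rank column the caller selects;
no taxonomy parsing is performed.  Rescue candidates require external
structural confirmation by design and are never auto-promoted.  The
hypergeometric co-occurrence test assumes exchangeable species and ignores
phylogenetic autocorrelation; treat it as descriptive.  Fitch parsimony
reports state *sets*; ties at the root are genuinely ambiguous and left
so.
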