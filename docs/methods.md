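# Methods

## Problem and model

`pangmark` implements a comparative-genomics route to subspecies
diagnostics for *Lactobacillus delbrueckii* (six subspecies: *bulgaricus*,
*lactis*, *delbrueckii*, *indicus*, *jakobsenii*, *sunkii*), and for any
organism with the same structure: a set of labeled genomes whose
protein-coding genes can be grouped into ortholog families.  The pipeline
is

1. greedy identity-based clustering of all CDS into gene families,
2. a family × genome presence/absence matrix and its partition into core
   (all genomes), accessory (≥ 2 but not all) and unique (exactly one),
3. a gene-cluster-frequency dendrogram over genomes and a
   nearest-neighbour check for mislabeled deposits,
4. per-subspecies marker selection: families in the subspecies' core and
   absent from every other genome,
5. an in silico specificity screen producing a marker × genome identity
   heatmap and the confirmed marker panel,
6. assignment of unlabeled (species-level) genomes against the panel, and
7. primer evaluation: in silico PCR products and qPCR standard-curve
   efficiency.

## Pairwise identity and clustering

Identity is computed from a global alignment with free end gaps
(Bio.Align.PairwiseAligner; match +1, mismatch −1, internal gap open −2,
extend −0.5, end gaps free).  Identity = matches / aligned columns between
the first and last aligned residue pair (end overhangs excluded);
coverage = fraction of the shorter sequence inside that span.  Arguments
are canonically ordered before alignment so the function is exactly
symmetric.

Clustering is greedy and length-sorted, the incremental-centroid scheme of
CD-HIT/USEARCH: sequences are visited longest-first (ties by
`(genome_id, gene_id)`), each joining the first cluster — in founding
order — whose centroid it matches at ≥ 50% identity (default) with ≥ 80%
coverage of the shorter sequence, else founding a new cluster.  A shared
5-mer prefilter skips centroid alignments that cannot plausibly match;
sequences shorter than the word size bypass the filter.  The procedure is
deterministic and, by construction, a partition of the input genes.
Clustering operates on protein sequences (supplied `.faa` or
standard-table translation of the CDS; internal stops are kept and
counted).  Paralogs may join one cluster; presence is binary and copy
numbers are retained.

The 50% default mirrors the conventional pangenome cutoff for
intra-species comparisons.  Because greedy centroid clustering is
tool-specific, counts on real data are expected to differ from any other
clustering implementation; only the partition-conservation invariant
(core + accessory + unique = pangenome size) is implementation-independent.

## Tree and mislabel detection

Genome profiles are the copy-number columns of the matrix.  The dendrogram
uses Euclidean distance with Ward linkage by default (Jaccard-on-presence
and UPGMA are configurable); genomes are processed in lexicographic order,
making the newick output order-invariant and deterministic.

Mislabel detection replaces visual tree inspection with a k-nearest-
neighbour vote (k = 3 by default, same metric as the tree): each genome's
inferred label is the majority declared label among its k nearest labeled
neighbours (self excluded; ties broken toward the genome's own declared
label, then lexicographically).  Genomes whose inferred label differs from
the declared one are flagged; species-level genomes are inferred but never
flagged.  By default the pipeline *corrects* flagged labels before marker
selection, and reports both declared and corrected labels.

Known limitation: a neighbourhood vote cannot identify mislabels once a
group is half-swapped with a consistent wrong label — with 2 of 4 genomes
mislabeled the same way, the genuine pair is outvoted.  The synthetic
generator therefore plants at most one mislabel per true subspecies,
matching the scenario the detector is designed for (isolated stray
deposits).

## Marker selection and the specificity screen

Candidates for a target subspecies are the set difference between the
subspecies' core families and everything present in any non-target genome
(species-level genomes are excluded from both sides).  The marker sequence
is the cluster centroid's nucleotide CDS, since primers are designed at
the nucleotide level.

The screen aligns the marker against every CDS of every genome
(free-end-gap global, BLASTN-like scoring: match +2, mismatch −3, gap open
−5, extend −2) after an 11-mer prefilter; the best hit per genome is the
heatmap entry.  Screen identity is **marker-relative** — matches divided
by marker length — so a short accidental alignment against an unrelated
gene cannot reach a high identity; the stiff gap costs serve the same
purpose (with permissive gap costs, unrelated genes can chain matches up
to ~0.65 marker-relative identity; with BLASTN-like costs spurious hits
stay below ~0.05).

A candidate is **confirmed** when identity ≥ 0.95 with coverage ≥ 0.90 in
every target genome, and every non-target genome shows either no hit or
identity < 0.70.  The band between 0.70 and 0.95 is a dead zone: hits
there reject the candidate rather than count as absence.  Confirmed
markers are ranked by (mean target identity − max non-target identity).
Assignment of an unlabeled genome takes the label of the best marker
meeting the presence rule, with `unassigned` and `conflict` outcomes when
none or more than one label qualifies.

## Primer evaluation

In silico PCR scans both template strands for primer binding sites.  The
default rule is exact matching; with `max_mismatch > 0`, mismatches are
tolerated anywhere except the three 3′-terminal bases of each primer
(polymerase-extension clamp).  Product length is measured inclusively from
the 5′ end of the forward site to the 5′ end of the reverse site, the
convention under which the published assay sizes (102/113/110 bp) are
reproduced, and predictions are invariant under reverse-complementing the
template (strand labels swap, coordinates mirror).

Primer Tm uses the Wallace rule 2(A+T) + 4(G+C) below 14 nt and
64.9 + 41·(GC − 16.4)/N otherwise — a design filter, not nearest-neighbour
thermodynamics, which the pipeline has no parameters for.  The scanner
enumerates 18–24-nt windows with 40–60% GC and Tm in 45–65 °C, pairs them
into 80–150-bp products with non-overlapping footprints, and ranks by
forward/reverse Tm difference.

The standard curve is an OLS fit of Ct on log10 template amount;
efficiency = 100·(10^(−1/slope) − 1), undefined (with a warning) for
non-negative slopes.  R² is the squared Pearson correlation.

## Synthetic data

The generator's defaults are the study conditions used throughout the
tests: 3 subspecies × 4 genomes, 30 universal-core families, 10
subspecies-core families per label of which 2 are planted markers, 15
accessory families at presence probability 0.5, 3 private genes per
genome, gene lengths 300–900 nt, 2% within-family divergence, 2 mislabeled
genomes.  These sizes are a deliberate ~30-fold scale-down of a real
lactobacillus pangenome that preserves every structural feature the
pipeline consumes; they keep the full 10-seed recovery suite in the
minutes range on one CPU.

Design choices that matter:

* **Divergence semantics.** `within_family_divergence` is the expected
  *pairwise* divergence between two family members; each copy is mutated
  at half that rate from a family ancestor.  Under this definition a 2%
  family screened at the 95% presence threshold has ~3 percentage points
  of margin instead of sitting on the threshold.
* **Non-marker subspecies-core families** are shared between pairs of
  subspecies (present in all genomes of both).  Per-subspecies cores
  thereby exceed the universal core — as in real pangenomes — while the
  planted markers remain the only families whose presence pattern exactly
  matches one subspecies.
* **Accessory patterns** are redrawn until they have 2..n−1 carriers and
  do not coincide with a subspecies pattern, so a random accessory family
  cannot masquerade as a marker.  With presence probability near 0 or 1
  the redraw can fail and is reported as a validation error.
* **Sequences** are ORF-like (ATG + sense codons + stop), i.i.d.-uniform
  in composition, so inter-family protein identity sits near the random
  baseline (~5–10%), far below the 50% clustering cutoff.  Mutation is
  substitution-only; identities are therefore analytic (no indel
  ambiguity).  Mutations may create internal stops; translation keeps
  them and logs a count, as annotation pipelines do for pseudogenes.
* **Reproducibility.** One RNG stream per genome, derived from
  (seed, genome index); identical configurations produce byte-identical
  FASTA output.

What the generator does *not* emulate: genome architecture (operons,
synteny, intergenic DNA), horizontal transfer, indels, composition bias,
and annotation noise.  Passing the recovery suite therefore shows the
pipeline's logic is correct under its stated assumptions, not that any
particular real dataset will yield the same counts.

qPCR simulation: Ct = Ct₁ₙg − log10(amount)/log10(1 + E/100) + N(0, σ),
the textbook dilution-series model; it ignores plateau effects, inhibition
and pipetting error beyond the Gaussian term.

## Numerical and procedural conventions

* Coordinates are reported 1-based inclusive; internal arithmetic is
  0-based half-open.
* All tie-breaks (cluster joining, neighbour ordering, marker ranking,
  primer ranking) are lexicographic and documented at the function level;
  two runs with identical inputs produce byte-identical outputs.
* Degenerate inputs: empty genomes screen as no-hit; an empty genome set,
  single-genome partition, unknown labels, and k ≤ 0 are validation
  errors; GC of an empty genome is reported as absent, not 0.
* Exit codes in the CLI: 0 success, 2 validation error, 3 I/O error.

## Scale of the shipped checks

The acceptance script (`scripts/acceptance.py`) uses 5 pipeline seeds with
6 held-out genomes each and 20 standard-curve seeds; the test suite uses
10 pipeline seeds, 10 held-out genomes per seed, 20 clustering-oracle
seeds and 20 curve seeds.  These sizes were chosen to make every recovery
rate a stable 0-or-100 signal rather than a borderline average.
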