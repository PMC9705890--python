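# pangmark

Pangenome-based discovery of subspecies-specific genetic markers, with in
silico PCR and qPCR standard-curve evaluation.

## The problem

*Lactobacillus delbrueckii* comprises six subspecies (*bulgaricus*,
*lactis*, *delbrueckii*, *indicus*, *jakobsenii*, *sunkii*) that matter
commercially — yogurt and cheese starters, probiotic label claims — but
that classical markers (16S rRNA, 16S–23S spacers, *tuf*) cannot tell
apart.  A pangenome offers a cleaner route: cluster every protein-coding
gene from a collection of labeled genomes into ortholog families, and look
for families present in **every** genome of one subspecies and **no**
other genome.  Such a family is a subspecies-specific marker; a primer
pair inside it gives a qPCR assay that types an isolate or a product
without sequencing.

`pangmark` implements that route end to end, for anyone working with a
labeled bacterial genome collection:

* greedy identity-based gene clustering (default 50% identity cutoff,
  CD-HIT/USEARCH style) into a presence/absence pangenome, partitioned
  into core / accessory / unique genes;
* a gene-cluster-frequency dendrogram over genomes and a
  k-nearest-neighbour check that flags **mislabeled deposits** before they
  poison marker selection (labels are corrected by default);
* marker selection as the set difference between a subspecies' core
  genome and the rest of the pangenome, followed by an in silico
  **specificity screen** (presence ≥ 95% identity in all target genomes,
  absence < 70% everywhere else) that yields the marker × genome identity
  heatmap and a confirmed panel;
* subspecies **assignment** of genomes registered only at species level;
* **in silico PCR** (strand-symmetric binding-site search, 3′-clamp
  mismatch rule) and **qPCR standard curves**: slope, R², and efficiency
  E = 100·(10^(−1/slope) − 1);
* a synthetic pangenome generator with planted ground truth (families,
  markers, mislabels, dilution series), so every stage is testable
  without downloading a single genome.

Three published tables ship with the package as desk-scale inputs: the
survey of 41 public *L. delbrueckii* assemblies, the three
subspecies-specific primer pairs, and the label claims of 26 monitored
probiotic/dairy products.

## Worked example

Generate a synthetic collection — 3 subspecies × 4 genomes, 2 planted
markers per subspecies, 2% within-family divergence, 2 deliberately
mislabeled genomes — and run the full pipeline:

```bash
pangmark generate --out demo/data --mislabels 2 --seed 3
pangmark run --manifest demo/data/manifest.tsv --out demo/run
```

The run summary (abridged):

```json
{
  "genes_in": 620,
  "n_clusters": 99,
  "partition": {"core": 30, "accessory": 33, "unique": 36},
  "mislabels": [["bulgaricus01", "delbrueckii", "bulgaricus"],
                ["lactis01", "delbrueckii", "lactis"]],
  "labels": {
    "bulgaricus":  {"genomes": 4, "subspecies_core": 42, "candidates": 2, "confirmed": 2},
    "delbrueckii": {"genomes": 4, "subspecies_core": 40, "candidates": 2, "confirmed": 2},
    "lactis":      {"genomes": 4, "subspecies_core": 41, "candidates": 2, "confirmed": 2}
  }
}
```

Reading it: 620 genes collapsed into 99 families; 30 are universal core,
36 private to single genomes.  Two genomes whose declared subspecies
disagreed with their gene-content neighbourhood were flagged
(`bulgaricus01` and `lactis01` had both been deposited as *delbrueckii*)
and corrected before marker selection.  Each subspecies' core
(40–42 families) exceeds the universal core; comparing it against the
rest of the pangenome leaves exactly 2 candidate families per subspecies,
and all 6 survive the specificity screen — precisely the planted markers.
`demo/run/` also contains the cluster table, the presence/absence matrix,
the newick tree, the marker FASTA and the screen heatmap TSV.

Primer-level checks from the library:

```python
>>> from pangmark import efficiency_from_slope, standard_curve
>>> round(efficiency_from_slope(-3.44), 1)   # published bulgaricus slope
95.3
```

## Layout

```
src/pangmark/
  genome_io.py        manifest + CDS FASTA I/O, summaries, translation
  pangenome.py        pairwise identity, greedy clustering, matrix,
                      partition, tree, mislabel detection
  marker_selection.py candidate selection, specificity screen, assignment
  primer_insilico.py  primer stats, in silico PCR, standard curves, design
  synthetic_data.py   generator with planted truth; qPCR simulation
  pipeline.py         orchestration, label-claim compliance reports
  cli.py              `pangmark` command (generate/cluster/pangenome/
                      markers/pcr/curve/monitor/run/summary)
  data/               bundled published tables (TSV)
docs/methods.md       model, conventions, design choices, limitations
```
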