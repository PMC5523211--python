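# barcodegap

Species delimitation from DNA barcodes (COI-style alignments), for
taxonomists who have an aligned set of barcode sequences, a table of
specimens with putative species labels, and want the standard molecular
evidence package:

- **p-distance matrices** under pairwise deletion, with per-pair overlap
  counts;
- **per-species intra/interspecific distance summaries** (Min / Max /
  Mean ± SD) — the table that exhibits (or fails to exhibit) the *barcode
  gap* between intraspecific and interspecific divergence;
- a **neighbor-joining tree** with column-bootstrap supports and per-species
  **monophyly checks**;
- alignment **site statistics** (variable, parsimony-informative sites);
- **character-based "pure" diagnostic sites**: alignment positions at which
  a species is fixed for a nucleotide state absent from every other species
  in the comparison set;
- a seeded **synthetic barcode-data generator** with known ground truth, so
  the whole pipeline is testable end to end without any sequence downloads.

## The statistics

For two aligned sequences the **p-distance** is

p = n<sub>diff</sub> / n<sub>overlap</sub>,

where n<sub>overlap</sub> counts sites unambiguously determined in *both*
sequences (pairwise deletion: gaps, `N`, `?` and IUPAC ambiguity codes are
skipped) and n<sub>diff</sub> counts the differing ones among them. Trees
use the Saitou–Nei **neighbor-joining** agglomeration on the Q-criterion,
which exactly recovers any tree whose path lengths generated the input
matrix; supports are bootstrap percentages over column resamples. A site j
is a **pure diagnostic** for species s with fixed state x when all
determined characters of s at j equal x and no determined character of any
other species equals x.

## Worked example

Generate a default synthetic dataset (10 species with 1–9 specimens each,
664 sites, 4 outgroups, 3 planted diagnostic sites per species) and analyse
it:

```bash
barcodegap simulate --out demo --seed 42
barcodegap run --alignment demo/synthetic.fasta --metadata demo/synthetic.tsv \
    --out demo/report --replicates 100 --seed 42
```

`demo/report/summary.tsv` begins (distances are proportions; `NA` marks the
intraspecific fields of a single-specimen species, for which no
within-species pair exists):

```
species    n  intra_min  intra_max   intra_mean  intra_sd    intra_n_pairs
species01  1  NA         NA          NA          NA          0
species02  2  0.0046875  0.0046875   0.0046875   0           1
species03  9  0.00469484 0.0165663   0.0100951   0.00279682  36
species04  6  0.0060241  0.0225904   0.0146567   0.00536832  15
```

The run log reports the group-level aggregates: the largest intraspecific
distance is 0.0226 while the smallest interspecific one is 0.0859 (between
species02 and species06) — a clean barcode gap. `monophyly.tsv` shows every
species recovered as a clade with bootstrap support 100 (support `NA` for
the single-specimen species), `sitestats.json` reports 514 variable and 293
parsimony-informative of 664 sites, and `diagnostics.tsv` lists the pure
diagnostic sites per species (282 here, a superset of the 30 planted ones),
e.g. species01 fixed for `G` at site 83. `tree.nwk` holds the NJ tree with
supports as internal node labels, and `matrix.tsv` the species-by-site
diagnostic grid with `-` where a species is wholly unsequenced.

The same analysis runs on real data: point `--alignment` at any aligned
FASTA and `--metadata` at a TSV with columns `seq_id`, `species`, `role`
(`ingroup`/`outgroup`).

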