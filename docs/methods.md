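# Methods

## Data model

A dataset is an aligned DNA matrix (rows = specimens, columns = sites) plus
a specimen table assigning each sequence a species label and a role
(`ingroup` — a putative species under delimitation — or `outgroup`). Rows
are upper-cased and `U` is mapped to `T` on input. The characters `-`, `N`,
`?` and all ten IUPAC ambiguity codes are treated uniformly as *missing*
everywhere: p-distances skip them under pairwise deletion, site statistics
never count them as states, and the diagnostic detector lets them neither
support nor contradict a diagnosis. This is deliberately conservative — an
ambiguous base call is weaker evidence than a determined one, and barcode
alignments typically carry missing data only as unsequenced leading/trailing
runs. Site indices are 1-based alignment columns in every user-facing
output.

## Distances and the summary table

The p-distance of a pair is the differing fraction of the sites determined
in both sequences; a pair with zero overlap is undefined (NaN) and excluded
from summaries with a logged count. The per-species table reports, for each
species, Min/Max/Mean/SD of (a) all within-species pairs and (b) all pairs
against members of other in-scope species. Choices made where convention
varies:

- **SD is the sample standard deviation** (n−1 denominator) over the set of
  pairwise distances, not a bootstrap standard error of the mean. With
  exactly one pair the SD is reported as 0.0 rather than NA, with the pair
  count (`*_n_pairs`) alongside so the degeneracy stays visible.
- Intraspecific fields are NA iff the species has fewer than two sequences.
- The default scope is `ingroup_only`: outgroup specimens contribute to no
  summary row and no interspecific set; `--scope all` includes them.
- Matrices store proportions; the `--percent` flag scales the rendered
  summary by 100.

## Neighbor joining and bootstrap

The tree builder is the classical Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion and the standard two-point branch-length
formulas. Ties in Q are broken by the smallest (row, column) index pair in
the current working order, making the output deterministic; the joined node
replaces the smaller index. On additive input the algorithm reproduces the
generating tree's topology and path-length matrix (verified to 1e-9 in the
tests, including against an exhaustive least-squares fit over all unrooted
topologies for 4 and 5 tips). Negative branch lengths, a normal artifact of
NJ arithmetic, are retained by default; `--clamp-negative` zeroes them and
transfers the deficit to the sister branch of the join, preserving the
joined pair's path length.

Bootstrap supports use column resampling: each replicate draws L columns
with replacement from a single seeded `numpy` generator, recomputes the
p-distance matrix and NJ tree, and each internal edge of the full-data tree
is labeled with the rounded percentage of replicates containing the same
bipartition. Replicates whose resampled matrix has an undefined entry are
redrawn (counted; more than 10× the replicate count aborts as degenerate).
The default of 1000 replicates is field convention; tests and the
acceptance script use 100, which is ample for the clean separations the
generator produces. Bipartitions are canonicalized as the tip-set side not
containing the lexicographically smallest tip, so supports are invariant to
input order.

A species is monophyletic iff the split (its tips | all other tips) occurs
in the tree; its support is that edge's bootstrap label. Single-specimen
species are monophyletic by convention with support NA. When outgroups are
present, an extra `<ingroup>` row reports whether the ingroup as a whole is
monophyletic with respect to them.

## Diagnostic sites

Site j is a pure diagnostic for species s with state x iff at least
`min_observed` focal characters at j are determined, all of them equal x,
and no determined character of any other species in the comparison universe
equals x. `min_observed` defaults to 1 so that single-specimen species can
own diagnostics — fixation inferred from one sequence is weak evidence,
which is why the threshold is exposed. The comparison universe defaults to
the ingroup species; outgroups can be included explicitly. A species wholly
missing at a site is rendered `-` in the matrix view and neither gains nor
blocks diagnostics there.

## Synthetic data generator

The generator emulates a typical barcoding study design: 10 species with
specimen counts (1, 2, 9, 6, 6, 4, 3, 6, 4, 3) — 44 ingroup sequences — a
664-site alignment, and 4 outgroup sequences. Substitutions are per-site
Bernoulli events moving to one of the three alternative bases uniformly; no
transition/transversion bias, rate heterogeneity, or indel process is
modeled (barcodes are treated as gap-free apart from unsequenced ends).
Defaults: `inter_sub = 0.05` per site from root to each species haplotype,
`intra_sub = 0.005` from haplotype to specimen, `outgroup_sub = 0.15`,
3 planted diagnostic sites per species, and a 20% chance per specimen of a
missing terminal run of up to 60 sites. These rates place realized
intraspecific distances mostly below 1% (max ≈ 2%) and interspecific ones
at roughly 8–13%, the regime in which distance-based barcoding is
considered reliable.

Planted diagnostics are laid out on disjoint sites drawn **outside the
maximal truncation window**, the focal species receives a non-root state
there while all other species are reset to the root state, and the planted
sites are **exempt from specimen-level mutation for every specimen**. The
last two points are what make the planted truth exact: without them, a
foreign specimen can mutate onto the focal state (breaking purity) or a
truncation can hide a singleton species' only observation of its site, so
recovery tests would measure simulation luck rather than detector
correctness. The cost is a slight idealization — real diagnostic sites can
of course be polymorphic or unobserved.

`expected_distance` gives closed-form expectations under this scheme. A
site differs between two sequences separated by substitution events with
probabilities a₁…a_k with probability ¾(1 − ∏(1 − 4aᵢ/3)) — the
Jukes–Cantor-style eigenvalue composition of the one-event transition
matrix; for the two-branch intraspecific path this is 2p(1−p) + ⅔p².
Planted sites are handled exactly: identical within species and between
species at third-party sites, certain differences at the pair's own 2k
planted sites. Both expectations are verified against Monte-Carlo
simulation in the tests (pairs within one dataset share specimens and
haplotypes, so the tolerance allows for that correlation).

### What passing on synthetic data does and does not show

The generator produces star-shaped species radiations with independent
per-site substitutions, exact planted diagnostics, and terminal-run missing
data only. Passing tests therefore demonstrate the *correctness of the
computations* — distances, tree recovery, support calibration on clean
signal, detector logic — not robustness to features real COI data can have:
saturation and multiple hits at high divergence, base-composition bias,
pseudogenes, incomplete lineage sorting producing genuinely non-monophyletic
species, or interior missing data. On real alignments the same code runs
unchanged, but those phenomena can legitimately produce non-monophyly, weak
supports, or empty diagnostic lists.

## Numerical and engineering choices

- Distance matrices are computed by Gram-matrix products of per-base
  indicator matrices, so the bootstrap loop is vectorized; results equal a
  per-site double loop to 1e-12 (tested).
- One seeded `numpy` Generator drives each stochastic stage; the pipeline's
  seed is recorded in the run log together with SHA-256 hashes of the
  inputs and the package version.
- Report bundles are written to a `.partial` staging directory and renamed
  into place, so a failed run leaves no partial outputs; all outputs are
  plain TSV/JSON/Newick with stable ordering, making reruns byte-stable.
- Strict binding requires the FASTA and metadata id sets to be equal;
  lenient binding keeps the intersection and logs what was dropped. Output
  order always follows the metadata.
- Problem sizes in the test suite and acceptance script (alignments up to
  ~80 sites for oracle checks, 10-tip trees, 20 simulated datasets, 100
  bootstrap replicates) were chosen as the smallest sizes at which each
  property is meaningfully exercised.

## Known limitations

- Only uncorrected p-distances are implemented; model-corrected distances
  (JC69, K2P) would be a natural extension of the same interfaces.
- The "pure" diagnostic rule is the only character-based criterion
  implemented — no private-but-shared characters, no minimal diagnostic
  set search, no amino-acid translation.
- NJ is O(n³) in dense numpy; fine for hundreds of tips, not for tens of
  thousands.
- Alignment construction is out of scope: inputs must be pre-aligned.
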