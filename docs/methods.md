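# Methods

## Problem and model

A *synolog* is a pair of homologous protein-coding genes in one genome.
Within a single genome, duplication-derived paralogs and horizontally
acquired pseudoparalogs are indistinguishable, so the package makes no such
claim: it detects, groups and counts intra-genome homologs and
characterises their arrangement.  Two detection routes are offered because
the two kinds of input differ fundamentally:

* **De novo** — only sequences are available.  All C(N, 2) intra-genome
  pairs are aligned with an optimal local (Smith–Waterman) affine-gap
  alignment; a pair passes when identity ≥ 0.90 *and* each sequence's
  coverage (aligned span / full length) is ≥ 0.90.  The double coverage
  requirement is what excludes truncated translation products: a fragment
  aligns to its full-length sibling at high identity but low coverage of
  the longer sequence.
* **Family-constrained** — genes carry curated family labels.  Same-genome
  members of one family are synologs with no identity or length rule, so a
  separate truncation filter is needed (below).  Pairs are still aligned —
  globally, since family membership asserts end-to-end homology — to record
  identities, and an optional identity cutoff re-partitions each family
  into connected components of passing pairs (the "high-identity" view of
  the same data).

A *synolog group* is a connected component (single linkage) of passing
pairs with at least two members.  Single linkage is the weakest consistent
reading of "a set of two or more intra-genome homologs": it never splits a
family by an arbitrary clique requirement, it is deterministic, and it
makes group counts monotone in the identity threshold.

## Alignment conventions

* Substitution matrix BLOSUM62 (as shipped with biopython), gap open 11,
  gap extend 1; a gap of length g costs 11 + g, the blastp default.  One
  scoring scheme serves both modes so their identities are comparable.
* Identity denominators differ by mode, mirroring the two conventions in
  the field: local/de novo identity is matches over *all* columns of the
  local alignment (gap columns included, blast-style); global/family
  identity is matches over residue-pair columns only
  (similarity-table-style).  Both are recorded on every hit.
* Residues are the 20 canonical letters plus X.  X scores the floor of the
  partner residue's matrix row and never counts as a match, so masked or
  frameshift-translated stretches cannot inflate identity.  Terminal stop
  characters are stripped at parse time; internal stops are an input error.
* Traceback ties are broken diagonal > vertical > horizontal, making every
  reported alignment bit-reproducible; the test suite verifies score,
  match-count and column-count equality against an independent pure-Python
  dynamic program and, for tiny sequences, an exhaustive alignment
  enumerator.
* Thresholds are compared with ≥ after rounding the fraction to six
  decimals, so boundary pairs (identity exactly 0.90) do not flip with
  platform floating-point noise.

## The 7-mer prescreen (optional, off by default)

All-vs-all alignment is quadratic in proteome size.  An exact-word
prescreen may skip pairs sharing no 7-residue substring.  It is provably
lossless for the default criterion: a passing pair has a local alignment
with C ≥ 27 columns (coverage 0.90 of sequences ≥ 30 residues) and at most
f = floor(0.1·C) non-match columns, which split the ≥ C − f matched columns
into at most f + 1 runs; the longest run is minimised at C = 30 (f = 3,
⌈27/4⌉ = 7) and is ≥ 7 for every C ≥ 27.  An 8-mer screen, by contrast,
would not be safe at C = 30.  Pairs where either sequence is shorter than
30 residues bypass the screen.  The suite checks on complete fixtures that
the screen reproduces the exhaustive passing-pair set exactly; multi-seed
validation runs use it to keep wall-clock time in seconds.

## Truncation filter (family mode)

Within each family of ≥ 2 members, members shorter than 0.5 × the family's
median length are flagged and excluded from pairing and counting.  The
median is taken over all members in one pass; a family dominated by
fragments can therefore hide them (a deliberate simplicity trade-off — an
iterative filter would re-estimate the median after each removal).  De novo
mode needs no filter because coverage already rejects fragment pairs.

## Statistics

Per genome: S = number of genes in groups, G = number of groups,
F = 100·S/N with N the genes in scope after any category filter.  Genes
listed under several subcategories count once (deduplicated by gene id);
each group carries the majority subcategory of its members with a
lexicographic tie-break, so subcategory group counts sum to G.  F is kept
at full precision internally and rounded to one decimal at report time.

Across genomes: median and **unscaled** MAD (no 1.4826 consistency factor —
the outlier rule median + 2·MAD is defined on the raw MAD), min/max, and
the upper outlier threshold median + 2·MAD per metric.  R² is the squared
Pearson correlation (identical to OLS R² for a simple regression) and is
undefined — an error, and omitted from cohort reports — when either
variable is constant.  Mean pairwise identity is summarised over the
genomes that contain groups, since it is undefined elsewhere.  Shares
(zero-synolog genomes, genomes with ≥ 1 high-identity group) are reported
at one decimal by default; integer reporting is available via
`share_decimals=0`.  A group counts as high-identity when it is a component
of pairs passing the 0.90 cutoff — for a family-mode run without a cutoff
this is recomputed from the already-evaluated pairs, with no re-alignment.

## Genomic context

Distances are gene ranks in the start-sorted order of each contig, not base
pairs — robust to intergenic-length variation and usable from an annotation
table alone.  A group is *tandem* when all members share one contig and
consecutive members are separated by ≤ `max_intervening` (default 2)
non-member genes; *dispersed* when members span several contigs or no two
members are within that distance; *mixed* otherwise (only possible on a
single contig, by this definition).  "Tandem" has no standard quantitative
definition, so the operational one is declared and configurable.  Neighbour
profiles tally the categories of up to `window` (default 5) genes per side
of each member, skipping co-members; unlabelled genes count as "unknown".
Operon prediction is deliberately out of scope — the neighbour profile is
its implementable surrogate.

## Synthetic data

The generator emulates what matters statistically about a real proteome for
this pipeline: a large majority of mutually unrelated genes plus a small
number of highly similar duplicate groups.  Copies are mutated from one
ancestor (star topology) by substituting exactly round((1 − t)·L) distinct
positions — no indels by default, so identities are exact by construction.
For two copies at per-copy identity t the mutated position sets union to at
most 2(1 − t)·L positions, guaranteeing pairwise identity ≥ 2t − 1; the
standard fixture uses t = 0.97, so every planted pair is ≥ 0.94, clearing
the 0.90 cutoff with margin, while background genes of length ≥ 50 have
negligible probability of reaching it (the suite demonstrates zero
background false positives across 100 seeds).  Truncated decoys keep the
leading 30% of the ancestor.  Tandem groups occupy consecutive gene ranks;
dispersed members are placed ≥ 20 ranks apart (configurable); coordinates
use gene length 3L + 3 and 100-bp spacers.  Everything is a deterministic
function of the design and its seed.

The **standard fixture** is 300 background genes of 60–180 residues plus 12
planted groups of sizes 2–4 (36 copies) and 3 truncated decoys — a
desk-scale echo of a gene-rich genome where a functional category of a few
hundred genes contains a dozen-odd duplicate groups.  What passing tests on
it *do* show: the criterion, grouping, truncation handling, statistics and
context calls are each correct against planted truth.  What they do *not*
show: robustness to indel-rich divergence, domain shuffling, low-complexity
or compositionally biased sequence, or annotation errors — real proteomes
contain all of these, and the no-indel default means coverage handling is
only stressed by the optional indel-free fragments, not by gapped homologs.

## Numerical and design choices

* Exhaustive DP in numba-jit kernels; integer scores throughout the DP, so
  there is no accumulation error and score equality with the oracle is
  exact.
* Group ids are `<genome>:SG<ordinal>` ordered by smallest member gene id;
  all outputs sort deterministically, and re-running a pipeline with the
  same configuration reproduces the artifact bundle byte for byte.
* Self-pairs are excluded; duplicate gene ids are an input error, not a
  synolog.
* Mean group identity is taken over all evaluated within-group pairs (every
  member pair in family mode and in prescreen-free de novo mode), not just
  the passing edges.
* Degenerate inputs: an empty gene scope makes the synolog fraction
  undefined (error); an empty sequence cannot be aligned (error); a local
  alignment with no positive-scoring pair yields identity 0, coverage 0.
* Problem sizes in the test suite (fixtures of ~90–340 genes, 20-seed
  recovery, 100-seed false-positive sweeps with the prescreen enabled,
  200-pair oracle comparisons) were chosen so the full validation runs in
  well under a minute while still exercising every code path at the scale
  the statistics need.

## Known limitations

* De novo mode is quadratic without the prescreen; hundreds of genes are
  comfortable, whole proteomes of several thousand genes want the prescreen
  or a coarser prefilter.
* The truncation filter is one-pass (see above).
* Family mode trusts its labels: mis-assigned families propagate directly
  into groups.
* No cross-genome orthology, no operon inference, no E-value model — all
  deliberate non-goals.
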