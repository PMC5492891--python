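# Methods

## Coordinate model

All intervals are stranded, 0-based, half-open `[start, end)`. BED input is
taken verbatim; GFF3 (1-based inclusive) is converted on read and back on
write. A single internal convention removes the most common source of
off-by-one drift in interval pipelines; boundary behaviour is therefore
uniform everywhere: `[10,20)` and `[20,30)` are book-ended, share no base,
and do not overlap. Chromosome names are compared by exact string match (no
`chr` aliasing). Sorting is by `(chrom, start, end)` with ties broken by
`(strand, name)` so that every output ordering is deterministic.

## CLIP region calling

Sequence tags are demultiplexed by **exact** barcode match at a fixed
offset (all barcodes equal length and distinct); non-matching or too-short
tags go to an `unassigned` bin and total multiplicity is conserved.
Deduplication collapses to one record per distinct full sequence after
barcode removal — no UMI model, since the tags carry none.

Aligned IP tag intervals are merged with gap 0 (overlapping **and**
book-ended tags merge, matching the default of the standard merge tool);
merging is strand-aware by default because iCLIP libraries are
strand-specific. Control (irrelevant-antibody IP) tags are merged
identically, and any IP region sharing ≥ 1 bp with a control region is
removed **whole** — regions are never truncated, since presence of any
control signal disqualifies the region, and subtraction happens at region
level (a raw-tag alternative is available via `merge_control=False`). No
tag-support threshold is applied by default (`min_tags=1`); the flag exists
for users who want one.

Annotation follows a fixed precedence: a region overlapping any exon is
*exonic*; otherwise overlapping any gene is *intronic*; all other regions
are *intergenic*. UTR and lncRNA overlap are independent flags, not
categories. Annotation overlap is strand-blind (feature files frequently
mix strand conventions), while region calling remains strand-aware; both
behaviours are switchable.

## RIP peak classification

Peaks (GFF3, typically separate plus- and minus-strand caller runs
concatenated) are labelled `repeat` if they overlap ≥ 1 repeat feature,
else `transcript`, else `unannotated` — a strict partition asserted on
every run. Repeat precedence reflects the convention of reporting
repeat-derived RNA before mRNA in repeat-focused RIP analyses and can be
inverted. When several repeats overlap one peak, the class is taken from
the largest overlap, with ties broken by class order LINE < SINE < LTR <
other and then by leftmost feature — arbitrary but deterministic. The
summary additionally counts transcript peaks whose identifier matches a
protein-coding accession pattern (default `^NM_`), separating the
any-transcript count from the mRNA-only count. Minimum overlap for every
classification is 1 bp, the intersect default.

## Gene-ID resolution and symbol harmonisation

Records resolve to Entrez IDs with audited precedence: (1) one-to-one
Ensembl↔Entrez match; (2) unique match via symbol; (3) unique match via
RefSeq; (4) among multiple Entrez candidates, discard miRNA-typed ones and
accept a sole remaining mRNA; (5) drop. Records assigned to two distinct
genes are dropped, and output is deduplicated on Entrez ID. Cross-species
comparison uses uppercase symbol identity only — symbols colliding after
case folding within either universe are excluded, which removes many-to-one
relationships at the cost of missing some true homologs; no ortholog
database is consulted.

## Fisher exact test

`fisher_overlap(N, K, n, k)` returns the hypergeometric upper tail
P(X ≥ k), the one-sided Fisher exact test for enrichment. The tail is
summed in log space with log-gamma terms and `logsumexp`, so p-values down
to ~1e-300 are representable; the value is clamped at 1 and the analytic
expectation Kn/N is reported alongside. When k does not exceed the minimal
achievable overlap max(0, K+n−N), the tail is exactly 1. The
implementation is validated against exhaustive integer-arithmetic pmf
summation on the complete grid N ≤ 60 and against R's
`fisher.test`/`phyper` at study scale.

## Permutation null

Each replicate draws three sets of the observed sizes independently and
uniformly without replacement from the N-symbol background and counts the
four tested exclusive Venn regions (AB-only, AC-only, BC-only, ABC). By
exchangeability the first set is held fixed as indices `0..K_a-1` and only
the other two are randomised; the joint law of the counts is unchanged and
replicates run in O(N). The generator is NumPy PCG64; the seed and
generator name are recorded in the result.

The default one-tailed empirical p-value is **r/n_perm with r counting
replicates whose region count strictly exceeds the observed count**, so a
reported p of 0 states that a larger overlap was never drawn in n_perm
replicates; r and n_perm are reported alongside p to keep that reading
unambiguous. Two alternative conventions are flags: `include_ties` counts
ties as extreme (P(X ≥ k) — the calibrated "at least as extreme"
convention, which is the one that makes null p-values uniform and the one
compared against the Fisher tail in the two-set consistency check, since
the strict convention is smaller by one pmf term at the observed count),
and `add_one` gives (r+1)/(n_perm+1). Null means and SDs per region are
reported and cross-checked against the analytic expectations
E[|A∩B|] = K_aK_b/N, E[|A∩B∩C|] = K_aK_bK_c/N², exclusive regions by
subtraction.

## Synthetic data

`make_annotation` packs genes and lncRNAs onto equal-length chromosomes
without overlap (round-robin across chromosomes, random gaps subject to a
minimum spacing), splits each gene into exons within disjoint chunks, adds
a UTR to a configurable fraction of genes (first half of the first exon),
and drops repeats into intronic or intergenic space with classes drawn
from a configurable LINE/SINE/LTR/other mix. Infeasible packings fail fast
with the violated budget named. Defaults (2 × 200 kb chromosomes, 20
genes, 4 lncRNAs, 30 repeats) give a genome dense enough that every
placement category exists while all brute-force oracles stay cheap.

`simulate_clip_experiment` plants binding regions (default 50 regions of
60 bp at an exonic/intronic/intergenic/repeat mix of 0.4/0.3/0.2/0.1) and
tiles each with `tags_per_target` 30-bp tags (default 5×) spaced so they
always re-merge into exactly the planted span; planted regions are kept
≥ 2 bp apart so merging can never bridge two of them. A
`control_shared_fraction` (default 0.2) of regions also receives control
tags and must be removed downstream; background tags are Poisson-placed
uniformly per chromosome (default rate 0 — the clean-enrichment setting
used by the end-to-end recovery check); FASTA records carry sample
barcodes and a `duplication_rate` fraction of duplicate records to
exercise deduplication. What the simulation does **not** model: alignment
error, crosslink-site truncation bias, non-uniform background, or real
sequence content (tag sequences are random nucleotides) — so passing tests
demonstrate the correctness of the interval logic and bookkeeping, not
performance on real libraries.

`simulate_gene_sets` either draws three sets uniformly (the permutation
null, used for calibration) or constructs sets achieving an exact target
Venn partition by slicing a random permutation of the universe into the
seven exclusive regions; inconsistent targets fail with the violated
identity named. Symbols are `G000001`-style tokens with an optional
mixed-case fraction to exercise case folding.

## Test and validation design

Interval operations are validated against painted-base brute-force oracles
(1,000+ random instances, coordinates < 10,000) plus derandomised property
tests; the Fisher tail against full-grid exact enumeration (N ≤ 60); the
permutation sampler against exhaustive enumeration of all subset triples
at N = 8, sizes (3,3,2); the two inference paths against each other in the
two-set case (3 Monte-Carlo SDs at 20,000 replicates); and p-value
calibration by a KS uniformity test over 200 simulated null studies
(N = 1,000, sizes 150/300/100, 2,000 replicates each — sizes chosen large
enough that the discrete statistic's lattice is fine relative to the KS
critical value at α = 0.01). Full-scale checks run the permutation at
16,760 / (821, 502, 3130) / 50,000 replicates, which takes a few seconds.

## Known limitations

* Control subtraction is binary presence/absence; no enrichment ratio
  between IP and control tag counts is modelled.
* Demultiplexing tolerates no barcode mismatches.
* The permutation null draws the three sets independently; correlated
  nulls (e.g. expression-matched sampling) are out of scope.
* Interval containers are immutable after construction; the overlap index
  is built once per set and not incrementally updated.
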