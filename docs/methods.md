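# Methods

This note documents the models and procedures implemented in
`motudiet`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions
adopted where the underlying methodology left choices open.

## Pipeline overview

Stages run in a fixed order, communicating through typed files
(FASTA/TSV/JSON) so each stage can be tested and resumed
independently:

1. **Demultiplexing** — a read is assigned to a sample iff its 5′
   prefix is *exactly* `tag + primer`; the prefix is trimmed.  Any
   mismatch, including an ambiguous base (N) anywhere in the prefix,
   discards the read.  Exact matching is deliberately conservative:
   with per-base error rates well below 1%, the dominant effect of
   tolerating mismatches would be to admit error reads, not to rescue
   true ones.  Only the forward tag+primer is checked by default
   (single-ended reads); reverse-primer trimming is not performed.
2. **Length filter** — trimmed reads shorter than `min_length` are
   discarded.  Default 141 bases = 90% of the 157-base target
   amplicon; the cutoff is a free parameter because "too short" is
   inherently protocol-specific.
3. **Dereplication** — identical sequences collapse into haplotypes
   carrying total and per-sample abundances.
4. **Singleton removal** — haplotypes seen exactly once in the run are
   discarded as probable sequencing errors.  The default scope is
   *global* (run-wide abundance 1), the conservative reading; a
   per-sample scope is available (`singleton_scope="per_sample"`)
   because protocols differ on whether singleton removal precedes or
   follows per-sample splitting.

Read counts are conserved across the chain
(`input = retained + Σ discards`) and asserted at run time.

## Distances and MOTU clustering

Pairwise divergence is the p-distance on an optimal global
(Needleman–Wunsch) alignment with unit match/mismatch/gap scores and
**free end gaps**: mismatches plus internal gaps divided by the number
of alignment columns between the first and last column where both
sequences have a base.  For equal-length sequences this reduces to the
Hamming fraction.  Argument order is canonicalised before aligning so
the distance is exactly symmetric even when co-optimal alignments
exist.  Distances are rounded to 6 decimals before threshold
comparison to keep `≤` decisions stable at grid boundaries.

MOTUs are the connected components of the graph linking haplotype
pairs at distance ≤ threshold (single linkage).  Single linkage makes
the partitions nested in the threshold, so MOTU counts are
non-increasing across a sweep — an invariant the test suite checks
against a brute-force transitive-closure oracle on all instances of up
to 12 haplotypes.  MOTU ids are assigned deterministically by (size
descending, lexicographically smallest member sequence).

The sweep covers 0–10% divergence in 0.5% steps by default.  The
working threshold is the **inflection point**: the smallest threshold
where the count stops dropping *after* the curve has begun to drop.
The qualification matters: sweep curves are flat over the leading grid
steps too (below the smallest observed pairwise distance, e.g. one
substitution in 157 bases = 0.64% > the first 0.5% step), and that
leading segment reflects nothing having merged yet, not the asymptote
of interest.  A curve that is constant everywhere returns the first
threshold; a curve that never plateaus returns the last threshold with
a warning.  `plateau_tolerance` (default 0 MOTUs per step) loosens the
plateau definition for noisy curves.

Each MOTU is represented by its up-to-three most abundant haplotypes,
ties broken lexicographically by sequence — deterministic across runs.

## Taxonomic assignment

Representatives are scored against a local taxonomy-annotated
reference library as `similarity = 1 − p-distance`, with the same
aligner as clustering for internal consistency.  The three-tier
confidence scheme uses a species threshold (default similarity
> 0.985) and a family threshold (> 0.98):

* level 1 — all qualifying hits name one species, or share one genus;
* level 2 — qualifying hits span genera but exactly one hit species is
  on the regional checklist (an input file, so the scheme generalises
  to any region);
* level 3 — hits above the family threshold stay within one family;
* otherwise unknown.

"Qualifying hits" are all hits above the species threshold or all hits
within 0.5 percentage points of the best hit, whichever set is larger
— a reproducible stand-in for reading a ranked hit page.  If two
checklist species tie, the scheme falls back to the agreement rule
(genus if one genus, else family) and logs the ambiguity.  A MOTU with
several representatives gets the consensus: disagreement degrades the
call to the deepest rank on which all identified representatives
agree, at the weakest of their confidence levels.

The richness-inflation statistic `100 × (n_motus − n_species) /
n_motus` (rounded to integer percent) quantifies how much MOTU counts
overestimate species richness where the reference library is dense
enough to tell.

## Diet statistics

Quantification is by occurrence: `counts[i, j]` = number of predator
*j*'s fecal samples containing resource *i*.  Within-sample read
abundance is deliberately not used — primer bias and differential
digestion make it unreliable as a measure of diet mass.

Levins breadth, Shannon diversity, and Pianka overlap are computed on
occurrence counts normalized to proportions summing to 1.  The raw
definition of *pᵢ* as "fraction of samples containing resource *i*"
does not sum to 1 across resources; normalization is the convention
under which the indices attain their textbook ranges and under which
the worked example's overlap value is reproducible from its table.
For standardized Levins `B_A`, *n* defaults to the number of resources
observed in that predator's diet; a global resource-pool *n* can be
passed instead, since "possible resources" is ambiguous whenever
unidentified taxa exist.

Percent frequency of occurrence at the order level divides the number
of samples containing an order by the total occurrences of all orders,
so values sum to 100%.  Reported percentages are rounded to one
decimal, half-up.  Per-sample richness summaries use the sample
(n−1) SD convention by default (configurable), with SD defined as 0
for a single sample.

## Null models

RA3 independently permutes each predator's count vector across all
resource states, zeros included.  It conserves each predator's
multiset of counts — hence Levins breadth and Shannon diversity
exactly — while scrambling which resources are used.  The test is
one-tailed (observed ≥ null), matching the question "is overlap
greater than chance", and the p-value is the add-one estimator
`(1 + r) / (n + 1)`, which is never 0 and is exactly uniform on its
lattice under the null.  Both conventions are recorded in the result
object so alternative choices can be compared.  Bonferroni correction
divides the family alpha by the number of comparisons.

Calibration checks in the test suite verify that p-values are uniform
under the null (Kolmogorov–Smirnov over 500 replicates of a
200-iteration test on RA3-generated data) and that the type-I error
at nominal 5% is within binomial tolerance.

A caveat observed on the packaged worked example: the shipped table
contains only the *identified* prey taxa (the original analysis also
carried ~24% unidentified MOTUs, mostly single-consumer rows).
Removing many low-count rows concentrates the permutation
distribution, so tail probabilities computed on the identified-only
table are slightly larger than on the full matrix — the packaged
table gives p ≈ 0.002 rather than < 0.001 for the interspecific
overlap.  The package reports whatever the data given to it support.

## Habitat analysis

Prey taxa are classified generalist / grassland specialist / woodland
specialist / unknown from a user-supplied lookup TSV (habitat
associations are data, not code).  The predator × habitat-class
contingency table counts distinct prey taxa (a taxon eaten by both
predators increments both columns); by default generalists and
unknowns are excluded so the test isolates the specialist signal.
Independence is tested with Pearson's chi-square (`scipy`), Yates
continuity correction optional for 2×2 tables; the default is
uncorrected.

## Synthetic data

The generator emulates the study design, not the instrument:

* **Reference panel** — mock taxa with independently drawn random base
  sequences, rejection-sampled so all pairwise divergences exceed the
  interspecific minimum (default > 4%); intraspecific variants carry
  strictly fewer substitutions than the intraspecific maximum (default
  < 2% of length).  Infeasible constraint combinations raise instead
  of silently violating.  Note that independently drawn sequences sit
  ~75% apart — far beyond the 4% floor — so planted taxa are very well
  separated, which is exactly the regime in which threshold-based
  clustering is well-posed.
* **Reads** — `tag + primer + variant` with per-base substitution
  errors (binomial, default 0.2%); within a taxon, haplotypes follow a
  geometric abundance series (ratio `abundance_skew`, default 0.3) so
  singleton removal and representative picking are exercised.  Tags
  are generated at pairwise Hamming distance ≥ 2 to preclude
  demultiplexing ambiguity.  A truth table maps every read to its
  source taxon.
* **Utilization matrices** — each species' profile is a
  `overlap_level`-weighted mixture of a shared profile and a private
  profile on disjoint resource blocks, converted to integer counts by
  largest-remainder rounding: overlap 1 gives exactly identical
  columns, overlap 0 exactly disjoint support, and intermediate levels
  interpolate monotonically on average.

Not emulated: homopolymer/indel sequencing errors (an indel-free
substitution model suffices because clustering is defined on aligned
distance), chimeras, PCR abundance bias, and quality scores beyond a
constant placeholder.  Passing tests on synthetic data therefore
demonstrate correctness of the algorithms under a clean error model,
not robustness to every artifact of real amplicon runs.

## Problem sizes and determinism

Default test and example runs use panels of 4–10 taxa, 157-base
amplicons, tens of samples and a few hundred reads per sample — sizes
at which every stage's output can be checked against brute-force
oracles or planted truth while the full suite runs in seconds.  All
randomness flows from explicit integer seeds (`numpy` Generators); a
pipeline run derives per-stage seeds deterministically from one global
seed, and identical configuration + seed reproduces outputs
byte-for-byte.

## Known limitations

* Demultiplexing does not error-correct tags; reads with tag errors
  are lost rather than misassigned (by design).
* Single-linkage clustering can chain distinct taxa through
  intermediate haplotypes if intraspecific variation approaches half
  the interspecific divergence; the threshold sweep makes this visible
  but cannot prevent it.
* The level-2 assignment rule presumes exactly one checklist species
  among qualifying hits; ties degrade to genus/family with a log
  message.
* Pairwise alignment is exact but O(L²) per pair and O(N²) pairs per
  run; the implementation targets haplotype counts in the hundreds,
  not raw-read scale.
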