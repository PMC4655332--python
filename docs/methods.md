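# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure left room for interpretation.

## Primer design model

A candidate primer's genomic-annealing part is 14 nt: a 12-base SSR core (a
2-base motif repeated six times or a 3-base motif repeated four times)
followed by a 2-base anchor whose last base is C or G.  Admissible anchors
are AC, AG, CC, GG, TC, TG (CG/GC are excluded as mutually reverse
complementary).  Core motifs come in two halves: a *main* set and an
*alternative* set consisting of the main set's reverse complements, so the
two sets prime the opposite ends of the same SSR tracts and can serve as
independent marker panels.  Motif classes:

* three-distinct-base trimers: all 24 permutations, paired by reverse
  complement; the lexicographically smaller member of each pair is assigned
  to the main set (this places ACT and CTA, both members of the published
  recommended set, in the main set);
* dimers: AC/CA (main) and TG/GT (alternative); polypurine (AG/GA),
  polypyrimidine (TC/CT), GC-rich (GC/CG) and GC-poor (AT/TA) dimers are
  excluded as unsuitable general primers;
* two-distinct-base trimers: the AAC- and CCA-rotation classes (main) and
  their reverse complements (alternative).  Rotations are included because
  the published set itself uses GTT and GTG, rotations of TTG and GGT.

Rejection rules on the 14-mer (roman numerals are the published labels):

| rule | condition |
|------|-----------|
| i    | the 14-mer is a pure repeat (period ≤ 3) |
| ii   | Hamming distance exactly 1 from some pure 14-mer repeat of a 2- or 3-base motif |
| iii  | the 3'-terminal three bases are all G/C |
| iv   | fewer than three distinct bases |
| v    | the reverse complement of the 3'-terminal 4-mer occurs within the 14-mer |

A candidate can satisfy several rules at once.  The worked examples that
define the rules are mutually inconsistent with a plain i→v first-match
order ((AC)₆CC is one base from pure (AC)₇ yet is the rule-iii example;
(ACC)₄GG ends in CGG, all G/C, yet is the rule-v example), so the primary
label is assigned by first match in the order **i, v, iii, iv, ii** — the
unique order that reproduces every worked example.  All matching rules are
also recorded.  Rule ii compares against pure repeats of *any* 2–3-base
motif, not only the candidate's own, because the rule's wording is
unqualified.  Rule v scans only the 14-nt annealing part: the rule is
applied before tails are attached.

After tail attachment (forward `CGCTCTTCCGATCT`+`CTG`, reverse
`TGCTCTTCCGATCT`+`GAC`; 31 nt total) two dimer screens follow:

* *self/counterpart screen*: reject when the reverse complement of a
  3'-terminal window longer than three bases (4–6 scanned; a longer match
  implies the 4-mer match) occurs in the primer's own or its counterpart's
  full sequence;
* *multiplex screen*: a set is compatible when no member's 3'-terminal
  3-mer has a reverse-complement match inside any other member's full
  sequence.  Set assembly is deterministic greedy over lexicographically
  ordered candidates with optional seeded restarts; several valid sets
  exist, so reproducing the published membership is not a goal — the
  published set-1 is bundled and validates conflict-free under the same
  screens.

## In-silico PCR

A primer annealing site is any position, on either strand, where the
3'-terminal `exact_3prime_len` bases (default 6 — the anchor plus one
repeat unit) match exactly and the remaining 5' bases match with at most
`max_mismatch_5prime` mismatches (default 0).  The defaults give strict
perfect-site prediction; the mismatch budget exists because the protocol's
low annealing temperature (48 °C) tolerates imperfect 5' pairing, and no
single mismatch count is asserted.  Amplicons are all convergent (+,−)
site pairs on a contig; the library length is the genomic span plus 34
non-genomic bases (17 per end: 14-base tail + 3-base 2nd-PCR anchor), and
size selection keeps 300–800 bp.  Half of the PCR product carries
same-tail adapters (forward–forward / reverse–reverse) and cannot cluster
on the flow cell, recorded as `sequenceable_fraction = 0.5`.  The two
80-nt end windows are reported as sequenced: read 1 on the top strand
immediately interior to the forward footprint, read 2 on the bottom strand
interior to the reverse footprint.  Inserts shorter than 160 nt (possible
only below the size-selection window) are flagged `overlap_risk` rather
than dropped.  Coordinates are 0-based half-open internally and in BED;
FASTA headers carry 1-based spans for human reading.  Overlapping or
shifted sites are all reported; de-duplication is deliberately deferred to
the homology filter, mirroring the pipeline order.

## Synthetic data generator

The generator is the package's study material and its defaults are the
study conditions.

**Genome.**  Uniform-random background with `n_loci` planted convergent
primer-site pairs drawn from the supplied primer set, library lengths
uniform on 300–800 bp, and inter-locus gaps of at least 250 bases — large
enough that no cross-locus convergent pair falls inside the size window,
so a strict scan recovers exactly the planted amplicons.  The background is
scrubbed of accidental annealing sites (any extra exact site gets one base
mutated outside planted footprints).  Every locus carries one segregating
site at a uniform offset in its read-1 window; a `read2_snp_rate` fraction
(default 0.1) also carries a completely linked site in the read-2 window,
giving the paired-end-locus detector planted positives.  Optional knobs
plant shifted-window companion loci (pseudo-loci from shifted priming) and
two-copy loci whose second copy is fixed for the alternate base (the
duplicated-locus artifact, modelled at read level).

**Cohorts.**  Four designs mirror the validation analyses:
`megagametophyte_panel` (default 2 mother replicates + 16 haploids; the
mother is heterozygous at `n_het_loci` loci, default 37% of loci, matching
the observed fraction of polymorphic loci among usable ones; each haploid
draws one maternal allele fairly and independently, with read-2 sites
inheriting the same gamete), `clonal_ramets` (3 genets × 6 ramets,
`somatic_diff_count` = 2 somatic single-locus changes per ramet, genets
redrawn until every pair differs at ≥ 27 loci — the separation reported
for real ramet data), `population_pair` (4 + 4 diploids; per-population
allele frequencies drawn Beta around an ancestral frequency with a
Balding–Nichols-style differentiation parameter, default 0.2), and
`replicate_pair` (independent diploids plus one exact replicate).

**Reads.**  Per sample × locus, fragment count ~ Poisson(`depth_mean`,
default 100); heterozygotes split fragments Binomial(1/2) between
haplotypes; each fragment is amplified forward–reverse or reverse–forward
with equal probability, so each locus end appears in both read pools.
Read 1 is the 80-nt window (the primer region is skipped, as by the
sequencer's dark cycles); read 2 is 94 nt = the 14-nt primer annealing
sequence plus the 80-nt window; the index read is the 6-nt barcode
(barcodes are generated with pairwise Hamming distance ≥ 2; designing them
is otherwise out of scope).  Error model: per-base substitutions at
`seq_error_rate` (default 10⁻³); with probability `pcr_error_rate` per
sample-locus (default 10⁻²) a PCR pseudo-allele — one substitution at a
uniform window position — is carried by a Beta(2,2)-distributed fraction
of that sample-locus's fragments, so biased depth ratios (the PCR-error
chi-square signature) occur; with probability `dropout_rate` (default
0.15) a sample-locus fails to amplify entirely.  The dropout default is a
deliberately milder analogue of the strong detection heterogeneity seen in
real panels, where most putative loci are detected in fewer than 10 of 16
haploid samples.  The published pipeline reports no numeric error rates;
these defaults make replicate discordance rates of a few percent
plausible but are not calibrated to any reported figure.  Base qualities
are constant Q37, with an optional low-quality read fraction to exercise
the quality filter.  Every random draw descends from the single mandatory
seed through fixed integer stream keys (one stream per sample × locus), so
output is byte-identical across runs and platforms, and every read id
encodes its provenance (sample, locus, fragment, haplotype, pseudo-allele
flag, orientation).

**What the simulator does not model** — and hence what passing tests do not
show about real data: amplification-efficiency competition among loci and
primers, indels and chimeric reads, index hopping, GC-coverage bias,
quality-score decay along reads, and genuine genomic repeat structure
beyond the planted artifacts.  Real MIG-seq data also show highly uneven
read counts among primers; the simulator's loci are exchangeable.

## Preprocessing

Demultiplexing is exact 6-base index matching (non-matching reads are
counted as undetermined).  Read 2 loses its first 14 bases (12-base SSR
core + 2-base anchor carried from the 1st-PCR primer), sequence and quality
in lockstep.  The quality filter keeps a read iff at least p % of its bases
have quality ≥ q (defaults q = 30, p = 40, the documented semantics of the
referenced filtering tool; Phred+33 fixed).  The adapter screen drops
read 1 containing the read-2 sequencing-primer sequence and (trimmed)
read 2 containing the read-1 sequencing-primer sequence — the signature of
read-through on an extremely short insert; matching is exact substring by
default with an optional mismatch tolerance (the original screening tool's
fuzzy HMM model is out of scope).  Reads 1 and 2 stay unpaired downstream
by design: because forward–reverse and reverse–forward amplification of
one fragment would otherwise split each locus in two, the two reads are
treated as independent and same-fragment loci are reunited only by the
final linkage-based detector.

## Stack genotyper

Per sample, identical 80-nt reads bundle into stacks; stacks with depth ≥ m
(default 20) seed putative loci in depth order (lexicographic tie-break),
absorbing any remaining stack within M (default 2) mismatches of the seed;
sub-threshold stacks join only as secondary members.  Sample loci built
from more than 3 primary stacks are discarded — a documented simplification
standing in for the original software's deleveraging/removal algorithms,
whose internals the published description does not specify.  Catalog
construction greedily clusters sample-locus consensus sequences at ≤ n
(default 4) mismatches, processing in total-depth order; the catalog
consensus is the founding (highest-depth) member's sequence.  Genotypes
use the published depth-ratio rule rather than the original likelihood
model: at each candidate site the minor allele is rejected when its depth
is below 1/20 of the major's, otherwise the call is heterozygous; haploid
samples are always called as the major allele, with a haploid-heterozygote
flag wherever the diploid rule would have said heterozygous (the raw
signal for duplicated-locus classification).  A site enters the matrix
only if the called genotypes carry ≥ 2 alleles across samples.  Marker
selection keeps loci genotyped in ≥ r (default 0.5) of samples in ≥ p
(default 1) populations, optionally only the first SNP per locus
(single-SNP mode, default on), and drops monomorphic sites.  An undetected
locus is missing data, never homozygous reference.

## Locus QC

Filters run in the pipeline order singleton/replicate → homology →
paired-end; re-running on filtered output is a no-op, and every input locus
appears exactly once in the report.

* **Singleton pseudo-variants**: a locus whose minor allele is carried by
  exactly one sample is removed — random PCR errors cannot be shared among
  samples.  Monomorphic sites are untouched.
* **Replicate discordance**: any genotype disagreement between declared
  replicates removes the locus; the two allele depths in the heterozygous
  replicate are tested against 1:1 by chi-square ((d₁−d₂)²/(d₁+d₂), df 1),
  P < 0.05 marking the biased-depth PCR-error signature.
* **Shifted homology**: pairwise ungapped identity at every offset with
  |shift| < 16, with the *full 80-base read length as denominator* — the
  convention implied by the defining arithmetic (80−16−16)/80 = 0.6.
  Pairs strictly above 0.6 form edges and every locus in a connected
  component of size ≥ 2 is removed (whole-group elimination knowingly
  discards some true loci; a keep-one mode exists but is off by default).
  Comparison is same-strand by default, since shifted priming produces
  same-strand copies; a both-strands flag exists for orientation-mixed
  cases.  The computation one-hot-encodes the consensus matrix and takes
  one matrix product per shift, so all-pairs screening of hundreds of loci
  is immediate.
* **Duplicated loci** (≥ 8 genotyped haploids required): every haploid
  flagged → homo+homo duplication; a 1–3-sample minority class → tight
  linkage (this small-count rule takes precedence); flagged:unflagged not
  rejecting 1:1 by exact two-sided binomial at α = 0.05 → homo+hetero if
  the unflagged haploids carry one allele, hetero+hetero if both
  homozygote classes appear; no flags → normal.  The signatures are
  qualitative in the source description; the binomial test and α are this
  package's operationalisation.
* **Paired-end loci**: two markers from the two ends of one fragment are
  perfectly linked, so pairs whose genotypes determine each other
  bijectively across ≥ 8 co-genotyped samples (both sites polymorphic,
  zero recombinants) are reported and the lower-id locus of each linked
  group is retained.  A Hardy–Weinberg chi-square flag is provided for
  diploid-only cohorts but drives no removal.

## Genetic analyses

**Segregation**: for loci where every mother replicate is concordantly
heterozygous, no genotyped haploid is flagged, and ≥ 10 haploids are
genotyped, the two allele counts are tested by uncorrected chi-square
(a−b)²/(a+b) with df 1 — the standard convention for 1:1 segregation
tests; Yates correction is available by flag but off by default.  With a
complete 16-haploid panel the exact type-I rate of this discrete test at
α = 0.05 is 0.077; with realistic locus dropout mixing the informative
count over 10–16 the rate is ≈ 0.04, which is what the calibration test
measures.

**Clones**: pairwise SNP differences count any allelic mismatch at a
co-genotyped site as one difference (matching the integer "number of
different SNPs" convention); pairs with no shared loci are missing.  The
automatic threshold assumes the bimodal difference distribution observed
for real ramet data (0–6 within clones vs 27–71 between) and takes the
midpoint of the largest gap between consecutive sorted values; genets are
single-linkage components at ≤ threshold.  A unimodal distribution warns
and the threshold should then be set manually.

**Differentiation**: per-population allele frequencies; per-site Hudson-type
F_ST with sample-size-corrected numerator, (p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
p₂(1−p₂)/(n₂−1), over mean between-population diversity p₁(1−p₂)+p₂(1−p₁),
averaged as a ratio of sums; and an allele-sharing distance matrix suitable
for external ordination or clustering (ordination itself is out of scope).

## Problem sizes and verification

The shipped test suite verifies: every published primer-rejection example
and the bundled set-1 (exact string checks); scanner and amplicon agreement
with a naive brute-force oracle on 20 seeded 2-kb genomes at 0 and 1
allowed 5' mismatches, plus exact recovery of planted loci; end-to-end
agreement of called genotypes with the truth table on a 200-locus,
18-sample megagametophyte cohort with all error rates zero, and — with the
default error model — removal of ≥ 90% of genotype-corrupting PCR-error
loci by the singleton/replicate filters at ≤ 5% collateral loss of clean
loci; segregation-test type-I rate within [0.03, 0.07] on 1,000 simulated
1:1 loci × 16 haploids; exact recovery of a planted 3-genet × 18-ramet
clonal design by the automatic threshold; and the homology-filter geometry
(all shifts ≤ 15 of identical reads exceed 0.6; seeded unrelated pairs
never reach it; the minimum-overlap pair sits exactly at 0.6).  These sizes
were chosen as the smallest that exercise every rule with comfortable
statistical margins.  A "PCR-error locus" in the recovery test is a catalog
locus whose pre-QC matrix contains at least one call differing from truth:
an event whose pseudo-allele stays below the calling thresholds, or falls
on a site not retained under single-SNP selection, leaves the marker matrix
identical to truth and is not a removable artifact.

## Known limitations

* The genotyper is a desk-scale functional stand-in, not a bit-exact
  reproduction of the original stack software; secondary-read handling and
  over-merged-locus treatment are simplifications documented above.
* The homology filter's full-length denominator makes identity depend on
  shift even for identical sequences; this is intentional (it reproduces
  the defining arithmetic) but differs from overlap-normalised identity.
* Amplicon prediction treats all perfect (and optionally near-perfect)
  annealing sites as productive; no thermodynamics, no competition.
* The clone-threshold heuristic requires genuine bimodality; closely
  related non-clonal samples can defeat it.
* Population differentiation supports the two-population comparison the
  design targets; multi-population F_ST uses only the first two labels.
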