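# Methods

## The analysis chain

`mircaste` quantifies mature miRNA expression from bulk small-RNA
sequencing libraries and calls differential expression between sample
groups — here the four larval phenotypes of a bumblebee caste study (EW,
LW, EQ, LQ: early/late-instar worker-/queen-destined larvae), each with
four replicate libraries. The chain is:

1. **Read cleaning.** Reads containing any ambiguous base (N) are dropped.
   The 3' adapter is located as the leftmost exact occurrence of its first
   `min_overlap` (default 7) nucleotides at a position that leaves at
   least `hd_length` (default 4) preceding bases; the adapter and the
   `hd_length` bases immediately 5' of it — the degenerate HD signature
   ligated to reduce sequence bias — are removed together. Reads without
   an adapter hit are discarded, as are inserts shorter than 16 nt.
   Surviving inserts are collapsed to distinct tags with counts; the sum
   of counts is the *redundant* total, the number of tags the
   *non-redundant* total. Base qualities are never consulted.
2. **Genome mapping.** Each tag is matched against the genome over its
   full length, ungapped, on both strands, with at most one substitution
   (`k_genome = 1`). A tag maps iff it has at least one hit; redundant and
   non-redundant mapped percentages are reported per library.
3. **Mature-miRNA assignment.** Genome-matching tags are aligned to the
   mature miRNA catalog sense-strand, full-length, ungapped, with at most
   two substitutions (`k_mirbase = 2`); the tag must lie entirely within
   the mature sequence (the mature may overhang the tag, never the
   reverse). Only minimal-mismatch assignments are kept per tag, and a tag
   matching m distinct miRNAs at that stratum contributes count/m to each.
4. **Normalization.** Raw per-miRNA counts are scaled per library by
   `N_norm / accepted_total`, where the accepted total is the post-filter,
   pre-mapping read count and `N_norm` defaults to 4,000,000. With
   `normalization_total: auto`, `N_norm` is the median accepted total
   across libraries rounded up to the nearest million. Normalized values
   stay real-valued.
5. **Library screen.** For each library, over the miRNAs reaching the
   abundance floor in at least one replicate of its phenotype, the score
   is the fraction whose offset fold change against the phenotype's
   replicate-median profile stays below 2-fold. Libraries under
   `score_threshold` (default 0.8) are flagged; an explicit exclusion
   list in the config overrides the scores. Excluded libraries take no
   part in DE calls.
6. **Differential expression.** For each miRNA and phenotype pair, the
   maximal expression interval — [min, max] of normalized counts across
   included replicates — is computed per phenotype, together with the log
   offset fold change of the phenotype means,
   `OFC = log2((mean_A + c) / (mean_B + c))` with offset `c = 20`. The
   miRNA is called differentially expressed when the intervals are
   strictly disjoint, |OFC| >= 1 (inclusive), and the larger phenotype
   mean reaches the abundance floor of 200 normalized reads. The standard
   design compares castes within instars (EW vs EQ, LW vs LQ) and instars
   within castes (EW vs LW, EQ vs LQ). The caller is threshold-based; no
   p-values and no multiplicity correction are involved.

### The matcher

The mismatch-bounded matcher is exhaustive by construction. References
are indexed by exact q-mers (q = 8 for genomes, 5 for mature catalogs);
a query with mismatch budget k takes k + 1 disjoint q-length seed blocks,
and by pigeonhole any alignment with <= k mismatches contains at least one
exact block, so seed lookup plus full-length Hamming verification
enumerates every hit of an exhaustive scan. Queries too short for k + 1
seeds fall back to a windowed scan. Reverse-strand hits reverse-complement
the query; offsets are 0-based window starts on the forward reference in
all cases. The equivalence with a brute-force sliding-window scan is
asserted over randomized instances in the test suite.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `adapter` | TruSeq small-RNA 3' adapter `TGGAATTCTCGGGTGCCAAGG` | trimming target; the kit names no sequence publicly, so the standard RA3 sequence is the default and it is configurable |
| `hd_length` | 4 nt | degenerate bases removed with the adapter; 0 for non-HD libraries |
| `min_overlap` | 7 nt | adapter prefix length that must match exactly |
| `l_min` | 16 nt | minimum insert length (inclusive) |
| `k_genome` / `k_mirbase` | 1 / 2 | mismatch bounds for genome mapping and mature assignment |
| `normalization_total` | 4,000,000 | per-library scaled total; `auto` = median accepted total rounded up to the nearest million |
| `offset` | 20 | OFC additive offset, damping ratios at low counts |
| `ofc_threshold` | 1 | |log2 OFC| DE threshold, inclusive |
| `abundance_floor` | 200 | minimum larger-phenotype mean (normalized reads per 4 M) |
| `score_threshold` | 0.8 | library-screen flagging threshold |
| `ofc_variant` | `mean` | `mean` uses phenotype means; `edge` uses the nearest interval edges (conservative; 0 when intervals overlap) |

Threshold orientation: interval disjointness is strict, the OFC and
abundance thresholds are inclusive, and the 16 nt length floor is
inclusive (15 nt discarded, 16 nt kept).

## The synthetic-data generator

The generator emulates an HD-adapter small-RNA run so the whole chain is
testable without sequencing data. `generate_reference` embeds random
20–24 nt mature miRNA sequences at known coordinates (one per ~2 kb slot,
plus strand) in a random background genome. Each simulated read is
`insert + 4 random HD nucleotides + adapter`, truncated to 50 nt (a
typical HiSeq2000 small-RNA configuration); the simulated adapter extends
the trimming adapter with downstream flanking sequence so short inserts
still fill the read. Per-library category counts are multinomial over the
design proportions; substitution errors are applied uniformly per base;
junk reads (default 25% of each library) are uniform random 16–30 nt
inserts standing in for non-genomic material, so mapping rates are
realistically below 100%.

Design choices that were genuinely open:

* **Replicate noise** is a log-normal multiplicative factor on each
  miRNA's expected proportion (σ = `dispersion`, default 0.2 on the
  natural-log scale), drawn independently per library and miRNA.
* **Spikes.** A spiked fold change f between two phenotypes is realized
  by dividing the miRNA's proportion by f in the *down* phenotype, with
  the junk pool absorbing the freed mass. The alternative — multiplying
  in the up phenotype and renormalizing — makes the realized ratio depend
  on every other proportion and degenerates entirely for a lone miRNA;
  down-scaling keeps the expected between-phenotype ratio exactly f, at
  the cost of a slightly enlarged junk fraction in down libraries.
* **Default abundances** are log-normal (σ = 1) across miRNAs, i.e.
  skewed like real miRNA expression; spiked miRNAs get a fixed base
  proportion of 0.008 so both sides of a 16-fold spike stay comfortably
  quantifiable at 500,000 reads per library.
* **Adapter-confusable inserts** (containing the 7 nt trimming probe, or
  ending in one of its prefixes completable by the random HD bases) are
  redrawn during catalog generation: such inserts would be truncated at
  trimming time, and excluding them keeps the error-free round-trip exact
  rather than merely approximate.
* **Qualities** are written as constant high values; nothing downstream
  reads them.

What the simulator does *not* model — ligation-bias mechanisms (only the
HD read structure is emulated), indels, position-dependent error
profiles, other small-RNA classes (the junk pool is non-genomic, whereas
real unassigned reads are largely genomic degradation products), and
multi-locus miRNA families. Consequently a passing suite shows the
pipeline's bookkeeping and statistics are correct under the stated
model; it does not certify behavior on real libraries, whose
non-redundant mapping rates and incidence fractions are dominated by the
very read classes the junk pool abstracts away.

## Problem sizes and numerical choices

The default synthetic study runs 16 libraries of 500,000 reads (60
miRNAs, 6 spiked 16-fold between LW and LQ, dispersion 0.2, junk 0.25,
error rate 0.005); the error-free round-trip check runs 16 libraries of
100,000 reads. These sizes make the whole suite and the acceptance script
each a few minutes of single-core work while leaving per-miRNA counts in
the thousands, large enough that spike recovery is not borderline.
Normalized counts are never rounded; matrix equality checks against the
simulator truth therefore round only at the final integer comparison.
With the depth scaled to 500,000 reads the auto-selected normalization
total is 1,000,000 (the rounded-up median accepted total), and the
observed spiked fold changes sit slightly below the nominal 16 because
the offset damps the ratio and dispersion spreads the replicate means.

Degenerate inputs: an empty tag set yields mapping percentages reported
as undefined rather than a division error; a phenotype with a single
replicate gets an undefined screen score and is skipped (with a warning)
by comparisons; an empty abundance-qualifying miRNA set gives a screen
score of 1.0 (no evidence of inconsistency); an exact mean tie yields an
empty DE direction.

## Known limitations

* The replicate-median screen is a stand-in for the original
  normalization-efficiency check, whose precise criterion is not public;
  the config exclusion list exists to reproduce an externally chosen
  library set (e.g. EW4, LW4, EQ2, LQ2) exactly.
* Whether published fold changes derive from mean-based or edge-based
  OFC, and with what offset, is not recoverable; both variants are
  implemented (`ofc_variant`) and mean-based is the default.
* Multi-mapping tags are equal-split across miRNAs; no fractional
  re-estimation (EM) is attempted.
* A spiked fold change between one phenotype pair necessarily shows up in
  comparisons sharing the down phenotype (e.g. a LW-vs-LQ spike realized
  by lowering LQ also separates EQ from LQ); "false positives" in the
  tests therefore mean DE calls for *unspiked* miRNAs.
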