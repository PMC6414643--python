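# Methods

## Unit of measurement: the joint editing pattern

The package's central object is the per-read joint editing state of the
eleven A-to-I sites (1, 2, 3, A, B, E, C, D, F, G, H in genomic 5′→3′
order) in the exon Vb window of the 5-Ht2cr amplicon.  A read is reduced
to one label — the concatenation of its edited-site letters in canonical
order, or `NoEdit` — rather than to eleven marginal editing rates.  This
preserves coupling between sites (e.g. the strong co-occurrence of C and
D) that marginal rates discard.  The canonical order is fixed by the
sites' genomic positions; note that E lies between B and C, so labels read
`AECD`, not `ACDE`.

Consequences of this choice:

* a read is only informative if it covers **all** sites with no indel in
  the window; such reads are excluded from pattern counting (but retained
  in splice/mapping tallies, since they are real amplicon molecules);
* a single miscalled site corrupts the whole pattern, so the default
  policy rejects any read with a non-A/G base at a site
  (`rejected_reason=non_AG_base`).  A `lenient` policy that treats such
  sites as unedited is provided for comparison; both are reported, since
  sequencing-error handling at this step is a genuine free parameter.

## Reference model

Two mapping contigs: the full-length splice variant (209 nt, retains exon
Vb and all sites) and the truncated variant (114 nt, exon Vb spliced out
at the alternative donor).  The bundled default reference is **synthetic**:
the real amplicon sequence is not distributed with the package, so a
209/114 nt pair with the same architecture (95 nt exon Vb block at offset
60, sites at offsets 75–104 spanning exactly 30 nt, reference base `A` at
every site) is generated once and frozen.  Real references are supplied as
a two-record FASTA plus a three-column site-map TSV; `validate_reference`
checks the base identity at every site, site ordering and the ≤30 nt
window.  Coordinates are 0-based half-open internally (SAM/BED
interoperability); user-facing reports are 1-based only where stated.

## Read processing

**Alignment input** (`read_alignments`): SAM/BAM against the two contigs.
Secondary/supplementary records are ignored; unmapped reads and reads
below `min_mapq` (default 30 — a conventional high-confidence threshold,
surfaced in every report) are counted as discarded.  Site bases are taken
by walking aligned (query, reference) pairs, so substitutions, indels and
clipping are all handled by the CIGAR, and indels inside the site window
are flagged.

**Raw input** (`classify_raw_reads`): each read is assigned to the contig
with the smaller Needleman–Wunsch edit distance (edlib), trying both
orientations; exact contig ties → `unassigned`, distance above 60 →
`unassigned`.  Because the contigs differ by a 95 nt block, assignment is
effectively error-proof at realistic error rates (misassignment would need
~47 errors).  A Hamming fast path handles reads of exactly contig length
within 25 substitutions — the overwhelming majority in amplicon data —
and a memo on identical read strings makes deep amplicon libraries cheap
to classify.  The two routes are cross-checked against each other and
against an external aligner (bwa mem) in the test suite.

## Quantification

RPKM is computed exactly as `reads / sequence_length × (10⁹ /
total_mapped)`, with

* `sequence_length` = the full-length contig length (209 by default) for
  every editing pattern — the contigs are the mapping targets and the only
  lengths defined; the 30 nt window is not a mapping unit;
* `total_mapped` = the library's mapped reads over **both** contigs, i.e.
  the single pooled per-library figure; reads later discarded for
  pattern-calling reasons still count in the denominator;
* no pseudocounts; empty libraries are an error, not a zero.

The expression filter keeps a pattern when its group-mean RPKM is ≥ the
threshold (default 10) in **either** genotype (inclusive comparison, OR
across groups).  `NoEdit` passes through the filter like any pattern.

Splice summaries average mapped/full/truncated counts per genotype and
report `full/(full+truncated)` percentages; full precision is kept
internally and one decimal is the display convention.

## Differential statistics

Per pattern: two-sided Student's *t*-test (equal variance; Welch available
as an option) on RPKM values across replicates, fold change = group-1 mean
/ group-2 mean (group 1 is the numerator by convention — WT in the
emulated design), and GraphPad-style significance stars on the raw p-value
(\* <0.05, \*\* <0.01, \*\*\* <0.001, \*\*\*\* <0.0001).
Benjamini–Hochberg step-up adjustment (statsmodels `fdr_bh`) is applied
jointly across all patterns surviving the filter; the per-site table is
its own BH family of eleven tests.  Conventions for degenerate input:
both groups constant and equal → p = 1; constant but different → p = 0;
zero denominator → fold change reported as NA, never infinity.

Percentages use the **edited-only denominator**: a pattern's (or
collapsed site's) group-mean RPKM divided by the summed group-mean RPKM of
all edited patterns, ×100.  `NoEdit` is excluded from numerator and
denominator and its percentage reported as NA.  Site percentages can sum
to more than 100 because sites co-occur within patterns.

Single-site collapsing sums, per library, the RPKM of every pattern
containing the site; the group comparison then proceeds exactly as for
patterns.  The overall editing level is the edited share of total
(edited + NoEdit) group-mean expression.

The user-facing surface is a statsmodels-style pair:
`DifferentialEditingModel(matrix, grouping).fit(min_mean_rpkm=10)` returns
a results object carrying the pattern table, the site table, the editing
level, `summary()` and TSV/JSON export.

## Simulator

`simulate_library` draws reads i.i.d.: splice isoform ~
Bernoulli(`splice_full_fraction`); for full-length reads a pattern ~ the
profile's distribution over the 2048 labels, with `G` written at each
edited site; uniform per-base substitution errors at `per_base_error_rate`
(default 0.001, a round figure in the range of amplicon sequencing
platforms), applied at editing sites too — so each site has a false A↔G
flip probability of `error_rate/3` per read.  No indel, PCR-duplicate,
amplification-bias or quality-score model: sites are substitution calls
and indel-bearing reads would be rejected by the caller anyway.  Truncated
reads carry truth pattern `NA`.  Reads are full-amplicon single-end, so
every full-length read covers all sites.  Per-library seeds are derived
by hashing the master seed with the library index (SHA-256, folded to 31
bits), making whole designs byte-reproducible.  A count-level shortcut
(`simulate_pattern_counts`) draws the binomial/multinomial counts directly
— the exact sampling distribution of a zero-error library after perfect
read processing — and is used for calibration studies where simulating the
read channel would only add runtime; the read-level equivalence at zero
error is itself verified by the lossless round-trip test.

### The calibrated profile pair

`reported_profile_pair()` builds WT/LoxP generative profiles from the
published summary tables of the emulated study (stored in
`combedit.reported`): the per-pattern group-mean RPKMs of the 21
differentially expressed patterns, the per-site collapsed means for all
eleven sites, the per-genotype edited totals, the ~45.2/45.3% splice
fractions and the 69% WT editing level.  Because the published tables omit
the non-significant isoforms, the weight table is completed by solving for
"filler" isoforms such that every per-site collapsed sum and the edited
total are reproduced exactly in expectation; the allocation rule (ECD, BD,
then D+minor-site pairs, then single-site isoforms, remainder to the D
singleton) is fixed and documented in the code.  The single-D isoform ends
up with ~59% of edited expression, near the reported ~61%.

Both genotypes are normalized by the **same** total, which makes every
within-pair probability ratio equal the published fold change exactly
(BCD 4.9, AECD 2.8, ABCD 2.5, ABD 1.75, AC 1.6 …).  The price is the LoxP
overall editing level, which comes out ≈60.4% instead of the reported
~64%: the published per-pattern ratios and both editing levels cannot be
satisfied simultaneously under a shared denominator, and the pair
prioritizes the per-pattern effect sizes, which are what the recovery
experiments estimate.

### What passing simulations do and do not show

The generator reproduces the sampling noise of multinomial pattern counts,
the splice split, and uniform substitution errors.  It does not emulate
PCR duplication/jackpotting, position- or motif-dependent error, strand
bias, or overdispersion between biological replicates beyond multinomial
noise — so recovery and calibration results bound what the pipeline can do
on ideal data, not what a real library guarantees.

## Problem sizes and numerical choices in the checks

* Lossless round trip: 12 libraries × 10⁴ reads at zero error, through
  FASTQ on disk; count tables must equal truth histograms exactly.
* Effect recovery: 6+6 libraries × 2×10⁵ reads, zero error (the error
  channel is characterized separately; at zero error the estimator is
  isolated from the miscall-leakage bias), fold changes of the five
  headline patterns within 10% relative error.
* Null calibration: 500 replications of a 6-vs-6 design at 5 000
  reads/library from one profile with six well-expressed patterns (count
  depth chosen so per-pattern counts are ≈100+, keeping the *t*-test in
  its near-normal regime); raw p<0.05 rate must lie in the binomial 99%
  band around 0.05.
* Oracle equivalence: the caller against a naive per-read string re-scan
  (≥10³ reads with injected C/T bases and indels); BH against a hand-coded
  step-up definition on 200 random p-vectors.

## Known limitations

* The built-in classifier is a two-contig assigner, not a spliced aligner;
  chimeric or adapter-contaminated reads end up `unassigned`.
* Editing sites are given, not discovered; there is no statistical
  editing-level model (e.g. beta-binomial) — counting is exact per read.
* RPKM is the single normalization, by design; no TPM/CPM variants.
* The default reference is synthetic; analyses of real data must supply
  the real contigs and site coordinates.
* Published-table arithmetic is reproduced at printed precision; a few
  published cells with one–two significant digits are only checkable up to
  their rounding interval (see the acceptance tests for the exact rule).
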