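# combedit

Combinatorial A-to-I editing-pattern and splice-isoform quantification from
amplicon deep sequencing.

## The problem

The serotonin 2C receptor (5-Ht2cr) pre-mRNA is post-transcriptionally
processed in two coupled ways: alternative splicing of exon Vb (producing a
full-length functional message and a truncated one that lacks the exon) and
A-to-I RNA editing at eleven sites — conventionally labelled
1, 2, 3, A, B, E, C, D, F, G, H in genomic order — packed into a ≤30 nt
window inside exon Vb.  Because ADAR-generated inosine is read as G, an
edited site appears as an A→G substitution in cDNA.

Deep amplicon sequencing of the exon IV–VI RT-PCR product reads through the
whole editing window on every molecule, so each read carries one *joint*
editing pattern — a subset of the 2¹¹ = 2048 possible site combinations,
labelled by concatenating the edited-site letters in canonical order
(`"ABD"`, `"AECD"`, …) or `"NoEdit"`.  combedit implements the full
analysis for a two-genotype, replicated design (e.g. wild-type mice versus
a line ectopically expressing the Snord115 snoRNA in choroid plexus):

1. **Read ingestion** — SAM/BAM alignments against the two splice contigs
   (209 nt full-length `5-Ht2cr`, 114 nt `5-Ht2cr-tr`), CIGAR-walked with a
   mapping-quality filter; or raw FASTQ/FASTA classified by a built-in
   two-contig global aligner (edlib), both orientations tried.
2. **Pattern calling** — per read, site base `G` ⇒ edited, `A` ⇒ unedited;
   reads with an indel in the window, incomplete site coverage, or (under
   the default strict policy) any non-A/G site base are rejected with an
   explicit reason.
3. **Quantification** — per-library pattern counts normalized as

   `RPKM = reads / sequence_length × (10⁹ / total_mapped_reads)`

   with the 209 nt contig length and the library's mapped reads over both
   contigs; patterns are kept when their group-mean RPKM reaches 10 in
   either genotype.
4. **Differential statistics** — per-pattern two-sided Student's *t*-tests
   on RPKM across replicates, Benjamini–Hochberg step-up adjustment over
   the tested family, WT/LoxP fold changes, per-pattern percentages of
   edited expression, single-site collapsing (sum of RPKM over all patterns
   containing a site), and the overall editing level per genotype.
5. **Simulation** — a calibrated generator of amplicon reads with per-read
   ground truth (splice isoform, true pattern, injected errors), including
   a built-in WT/LoxP profile pair whose expected per-pattern and per-site
   abundances match the published summary tables of the study design it
   emulates.

## Worked example

Simulate a twelve-library experiment (6 replicates × 2 genotypes, 20 000
reads each, 0.1% per-base error), quantify it through the read pipeline and
fit the differential model:

```python
from combedit import (AmpliconReference, SimDesign, DifferentialEditingModel,
                      reported_profile_pair, splice_summary)
from combedit.pipeline import quantify_simulated_design

ref = AmpliconReference.default()
wt, loxp = reported_profile_pair()
design = SimDesign([wt, loxp], reads_per_library=20_000,
                   per_base_error_rate=0.001, seed=42)
matrix, stats, _ = quantify_simulated_design(ref, design)

splice = splice_summary(stats, {lib: matrix.genotypes[lib] for lib in matrix.libraries})
print(splice.round(1))
results = DifferentialEditingModel(matrix, ("WT", "LoxP")).fit(min_mean_rpkm=10.0)
print(results.summary(top=6))
```

prints (excerpt):

```
          mapped_reads  full_reads  truncated_reads  pct_full  pct_truncated
genotype
LoxP           20000.0      9049.2          10950.8      45.2           54.8
WT             20000.0      9069.5          10930.5      45.3           54.7

Differential editing-pattern expression
==============================================
groups: WT (numerator) vs LoxP; 12 libraries, 70 patterns tested
overall editing level: WT 69.0% | LoxP 60.4% (difference +8.6 points)
...
single-site contributions:
       mean_WT  mean_LoxP  fold_change   p_value   sig      p_bh  pct_WT  pct_LoxP
site
A    2.176e+05  1.476e+05        1.475 8.958e-09  **** 4.927e-08   14.65     11.36
B    9.749e+04   5.57e+04         1.75 1.247e-07  **** 4.573e-07   6.562     4.287
C    3.439e+05  2.798e+05        1.229 2.117e-07  **** 5.822e-07   23.15     21.53
D    1.326e+06  1.145e+06        1.158 1.846e-10  ****  2.03e-09   89.26     88.14
```

Reading the output: roughly 45% of reads carry the full-length splice
isoform in both genotypes (splicing is unaffected); the D site dominates
editing (~89% of edited expression); and editing at the A, B, C and D
sites is significantly reduced in the LoxP genotype, with per-site fold
changes near the generative values (A 1.5, B 1.8, C 1.2, D 1.2).  At this
shallow depth the rare patterns are noisy; the defaults of the
acceptance script below use 200 000 reads per library.

The same stages are available from the shell:

```sh
combedit simulate --out sim/ --seed 42 --reads-per-library 20000
combedit quantify sim/*.fastq --out quant/ --genotypes genotypes.tsv
combedit differential --matrix quant/ --out diff/
```

## Layout

| module | contents |
| --- | --- |
| `combedit.reference` | contigs, site map, pattern-label algebra, validation |
| `combedit.simulate` | read generator, genotype profiles, design manifests |
| `combedit.reported` | published summary tables used as worked-example inputs |
| `combedit.reads` | SAM/BAM ingestion and built-in raw-read classifier |
| `combedit.calling` | per-read joint pattern calling and counting |
| `combedit.quantify` | RPKM matrix, expression filter, splice summary |
| `combedit.differential` | model/results API: *t*-tests, BH, collapsing |
| `combedit.pipeline` | in-memory end-to-end helpers |
| `combedit.cli` | `combedit simulate / quantify / differential` |

See `docs/methods.md` for the statistical model, simulator calibration and
the numerical conventions.
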