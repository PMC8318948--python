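# Methods

## Model

The read-depth model assumes shotgun reads sample the test genome uniformly,
so the expected number of reads crossing a reference interval is
proportional to the copy number of the orthologous sequence in the test
genome divided by its copy number in the reference. For an interval present
once in the test genome and `c` times (tandemly) in the reference, an
aligner that distributes ambiguous reads uniformly among equal-best
locations yields expected normalized depth 1/c in each copy, and almost all
reads mapping inside the array are ambiguous, so the zero-mapping-quality
fraction q0 approaches 1 (edge reads that straddle an array boundary are
unique, which is why q0 falls slightly below 1 for short units).

Classification is a total function of (RD, p, q0) with strict comparisons:
RD < 0.7 splits into deletion-in-test (q0 < 0.2) versus duplication-in-
reference (q0 > 0.7); RD > 1.5 with q0 < 0.2 is duplication-in-test;
RD > 1.20 with q0 > 0.7 is the "duplicated in both" class, for which only
the RD ratio is reported because absolute copy numbers are not identifiable
from one ratio. Boundary values and the q0 band (0.2, 0.7) are discarded.
Copy number for reference duplications is ⌊1/RD⌋ with a floor of 2: the
floor (rather than nearest-integer rounding) is what makes RD = 0.21 read
as 4 copies and RD = 0.5 as 2, matching how the depth readout is
interpreted in practice; nearest rounding would call 0.21 five copies.

## Synthetic benchmark: what it emulates

`simgenome`/`pipeline` emulate the published validation design: two spike-in
sites per chromosome, one with 2 and one with 4 tandem copies, planted at
copy-number-neutral coordinates. Neutrality is enforced constructively —
the background is rejected until no 150-mer (the read length) occurs twice —
rather than by measuring coverage first; this gives the same property the
empirical site selection aimed for, with a generative guarantee.

Defaults and why:

| parameter    | default        | rationale                                         |
|--------------|----------------|---------------------------------------------------|
| read length  | 150 bp         | standard short-read length                        |
| coverage     | 30×            | inside the 26–36× range of the real data sets     |
| error rate   | 0.001/bp       | typical post-QC substitution rate                 |
| bin size     | 100 bp         | depth SNR (mean/sd of binned counts) ≈ √17 ≈ 4.2 at 26–30×, inside the recommended [4, 5] window |
| copy numbers | (2, 4)         | the two planted genotypes                         |
| unit sizes   | 3–10 kbp (scaled run) | full-scale design uses 3–176 kbp; at 10×1 Mbp the range is capped at 10 kbp so the arrays stay ~2–3% of the genome, mirroring the sub-1% array fraction of the full-scale design — mean-based normalization stays unbiased. The 3 kbp floor is kept as the detectability limit. |
| max mismatches | 2            | with 3 disjoint seeds this finds *every* alignment with ≤ 2 substitutions (pigeonhole); P(>2 errors per read) ≈ 5·10⁻⁴, such reads are dropped and counted |

Reads are single-end and forward-strand, and placement searches the forward
strand only: RD and q0 are strand-symmetric, so pairing and strandedness add
realism but no information at this scale.

What a green benchmark does **not** establish: behavior on repetitive real
genomes (the background here is uniquely mappable by construction, so
sensitivity ~1.0 is a clean-background ceiling, not a claim about real
data, where the original tool achieved 66–75%); robustness to GC-coverage
bias (reads are simulated uniformly; the GC correction is exercised by a
separate planted-bias test); paired-end artifacts; diploid heterozygous
CNVs; and SNP/indel divergence between the species.

## Numerical and algorithmic choices

- **Placement.** Exact 3-bit-packed seed index (seed length
  min(21, read_length/(m+1))); all candidate windows verified by full
  mismatch count; equal-best ties broken uniformly with a seeded RNG and
  assigned MAPQ 0. Unplaceable reads are dropped and counted, never
  silently lost.
- **Binning.** A read counts toward the bin holding its start position;
  raw_depth = count·read_length/bin_size. Terminal partial bins are flagged
  and excluded from all statistics.
- **GC correction.** 1%-wide GC strata; strata with < 100 full bins (or
  zero mean) fall back to the global mean; the profile is then rescaled so
  the mean over full bins is exactly 1 (so "mean RD = 1" is true by
  construction, not approximately). The bin-size selection ratio is
  computed on raw counts, before GC correction.
- **Segmentation.** Centered moving average (3 bins), loss/gain flags at
  0.75/1.25 (strictly between neutrality and the classifier's 0.7/1.2–1.5
  cut-offs, so candidate generation cannot pre-empt classification),
  same-direction runs separated by < 2 bins merged, runs < 1000 bp dropped.
  p-values from a two-sided one-sample t-test of the run's bin RDs against
  1.0; a zero-variance run gets p = 1 when flat at 1.0, else 0.
- **Cohort intersection.** "> 50% overlap" is implemented as *reciprocal*
  overlap (min of the two one-sided fractions): one-sided overlap would make
  the shared set depend on sample order, breaking the permutation invariance
  the pipeline asserts. The shared interval is the union of the supporting
  calls (conservative for gene annotation). Known-CNV exclusion merges the
  known regions first and drops loci covered > 10%; it runs before
  intersection by default but the order is configurable, as the two
  published descriptions of the order disagree.
- **Truth matching.** Reciprocal overlap > 0.5 *or* call-midpoint
  containment, greedy one-to-one by descending overlap — read-depth callers
  have sloppy breakpoints, and a matcher stricter than the caller's
  boundary accuracy would undercount genuine detections.
- **Annotation.** Gene-level category precedence whole_gene > exonic > UTR
  > intronic > upstream > downstream > intergenic (the category vocabulary
  is standard; the precedence is this package's construction). Flank
  5000 bp, configurable — the conventional annotator default.
- **Tandem check.** Exact k-word (k = 11) self dot-plot: verdict "tandem"
  when one off-diagonal offset's matches cover ≥ 50% of the sequence;
  otherwise a gapless k-word chain elsewhere in the genome with ≥ 80%
  identity over ≥ 50% of the length gives "dispersed_duplicate". The source
  locus can be masked so a genuine single-copy sequence is not matched
  against itself.
- **Medians.** For an even number of loci the median length is the lower of
  the two middle values (documented, deterministic).
- **q0 definition.** q0 is the fraction of reads whose best alignment is
  non-unique (≥ 2 equal-best locations, MAPQ 0). A 2-copy tandem array
  yields exactly two best locations per interior read and is expected to
  approach q0 ≈ 1, so the threshold q0 > 0.7 refers to multi-mapping
  generally, not to "more than two" locations.

## Known limitations

- The placer is exhaustive but substitution-only (no indels, no clipping);
  it is a benchmark instrument, not a general aligner.
- `shared_calls` enumerates same-class overlap cliques; it is quadratic in
  local call density and intended for filtered call sets (thousands, not
  hundreds of thousands, of calls).
- The dispersed-duplicate check examines the top five diagonal offsets per
  chromosome; highly fragmented segmental duplications below ~50% coverage
  of the query are reported as "unique".
- Real-data mode trusts upstream duplicate marking and MAPQ conventions of
  the aligner that produced the BAM.
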