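# Methods

`soymir` re-implements, as a deterministic and fully tested pipeline, the
comparative small-RNA profiling workflow used for soybean seed libraries:
two transgenic lines (MON89788 and the stacked DP-3Ø5423×GTS 40-3-2) against
their near-isogenic parents (A3244 and Jack). This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Preprocessing

Raw reads are screened in three ordered steps.

1. **Quality screen.** A read is discarded when *more than*
   `max_low_quality_bases` (default 4) of its Phred scores are *strictly
   below* `low_quality_threshold` (default 15). Both boundaries are sharp
   and unit-tested: exactly four sub-15 scores keep the read; a score of
   exactly 15 is not "low".
2. **3' adapter trim.** The insert is the prefix before the leftmost exact
   match of the first `min_adapter_prefix` (default 7) nt of the adapter.
   Exact matching keeps the stage deterministic; published small-RNA studies
   rarely state their trimmer's mismatch policy, so the strictest rule is
   the reproducible default. Reads with no adapter match are dropped (an
   insert without a reliable 3' adapter cannot be sized); a match at
   position 0 is an adapter contaminant; inserts containing `N` are dropped.
   The adapter itself is configurable and defaults to the TruSeq small-RNA
   3' adapter `TGGAATTCTCGGGTGCCAAGG`.
3. **Collapse.** Identical inserts of 15–30 nt over {A,C,G,T} are merged
   with summed counts, giving the unique/total pair reported per library.

FASTQ decoding assumes Phred+33 (configurable offset).

## Perfect-match mapping and annotation

Only exact, full-length matches count. The index is a 12-mer seed table
with full verification, exhaustive over both strands; minus-strand hits are
reported on forward coordinates, 1-based inclusive (the convention of both
GFF3 and the `chrom_strand_start_end` locus strings). Reads containing `N`
never map. A randomized suite checks the index against a naive
O(genome × query) scan, including tandem-repeat multi-hits and palindromic
(reverse-complement-equal) queries, which legitimately map to both strands
of one interval.

Reads are assigned a single category with precedence
**exon > intron > intergenic** across all their loci, so the composition
table partitions reads disjointly (a multi-mapped read is counted once).
Annotation strand is ignored for this assignment; strandedness enters only
the window strand-bias analysis, where reads are split by locus strand
relative to the annotated feature strand in the window (forward genome
strand when the window is unannotated). Chromosomal distributions split a
multi-locus read's count equally across its loci so bin totals conserve the
mapped total.

## Known-miRNA quantification

A clean read is a known mature miRNA only when it equals a reference mature
sequence exactly, full length. References are U→T normalized at load; all
internal sequences are DNA. Identical matures registered under several
names (miR156-style families) form one statistical unit: a single row
annotated with every name. Precursor matching is exact-substring in either
orientation; a read is counted once per precursor regardless of how many
offsets it matches, and a read matching several precursors counts for each
(the per-precursor tally is not a partition — documented ambiguity).

The Rfam/BLAST screen of the original workflow is replaced by exact
substring matching against a supplied, class-labelled ncRNA FASTA
(rRNA/tRNA/snoRNA/other). Matching is performed in both orientations:
a strandless homology search also removes antisense fragments, and the
antisense reads of the rRNA repeat must be removed upstream of novel-miRNA
prediction. Classes are tallied with fixed priority rRNA > tRNA > snoRNA >
other when a read hits several records.

## The exact count test

For a miRNA with count *x* in the baseline (non-GM) library of *N₁* clean
reads and count *y* in the test (GM) library of *N₂*, the conditional
distribution of the test count given *x* is

    p(k | x) = (N₂/N₁)^k · (x+k)! / (x! k!) · (1 + N₂/N₁)^−(x+k+1),

a negative binomial with *x*+1 successes at probability *N₁/(N₁+N₂)* — the
classical exact statistic for digital expression counts. The reported
p-value is the smaller tail, `min(Σ_{k≤y} p(k|x), Σ_{k≥y} p(k|x))`, clamped
to (0, 1]. No doubling is applied and no multiple-testing correction is
performed, matching the published procedure; both alternatives are noted
here so users can post-process if desired.

Numerics: all accumulation is log-space (`gammaln` + log-sum-exp). When the
lower tail is ≥ 0.5 the minimum can only be the upper tail, which is summed
directly from *k = y* upward with a certified geometric truncation bound
(the term ratio is eventually < 1 and decreasing, so the remainder is
bounded analytically and summation stops when it is negligible). Computing
the upper tail as 1 − lower would destroy tiny tails by cancellation.
`ac_log_p_value` exposes the log-space value for p-values beyond the
range of IEEE doubles. For the exactly balanced case *x = y*, *N₁ = N₂* the
smaller tail equals ½ analytically (Σ_{k≤x} C(x+k,k) 2^−(x+k+1) = ½, the
negative-binomial/binomial tail duality), and 0.5 is returned exactly.

A caution on symmetry: the min-tail definition is *not* exactly symmetric
under (x, N₁) ↔ (y, N₂) at small counts (e.g. x=3, y=10, N₁=N₂ gives
378/8192 against the transposed 470/16384); symmetry holds only
asymptotically. Tests assert the exact balanced identity and the asymptotic
behavior rather than a false finite-sample identity.

Calibration: under a matched-rate null the min-tail test calls *p* < α with
probability at most 2α (each tail is a valid one-sided p-value);
discreteness keeps the realized rate below that bound (measured ≈ 0.0018 at
α = 0.001 for Poisson rates around 150). The suite estimates this by
conditional Monte Carlo — for each drawn baseline count the conditional
probability of the rejection region is accumulated exactly — which is
unbiased over the same draws with negligible variance.

**Normalization and calls.** Expression is normalized per 10⁷:
`count / total clean reads × 1e7`, with the 15–30-nt clean total (not the
mapped total) as denominator. The log₂ ratio is test/baseline on normalized
values; a zero count on either side gives NA and such rows are never
called. A call requires all three gates: *p* < 0.001, |log₂| > 1 (strict),
and raw abundance > 100 reads. The abundance gate applies to *x + y* (the
published wording does not fix a per-library scope; configurable).
Reproducing direction calls from values *printed at two decimals* requires
the inclusive rule |log₂| ≥ 1 (a printed −1.00 is called); the package
implements the strict rule on unrounded values internally and offers
`SignificanceParams(rounded=True)` plus `threshold_calls` for printed-value
reproduction. Both behaviors are tested.

**qPCR verification math.** `ddct_fold_change` implements the comparative
ΔΔCt method, 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target −
Ct_ref)_control, with U6 snRNA as the intended reference gene. No
amplification-efficiency correction is applied.

## Secondary structure and novel miRNA prediction

**Folding.** Candidate hairpins are folded by base-pair maximization
(Nussinov dynamic programming): nested structures, minimum loop of 3
unpaired bases, G:U wobble allowed, deterministic traceback preferring the
pairing with the smallest outer index. The hairpin criteria consume only
pairing topology — which mature bases pair, bulge asymmetry, loop position
— which maximization supplies deterministically without an energy-parameter
dependency; an exhaustive-enumeration oracle pins the optimum for all short
sequences. The trade-off is that maximization has no stacking preference:
over a long window with random flank it can scatter a mature's partners
even when a clean hairpin exists at a shorter extent. Candidate extents are
therefore scanned from the minimum hairpin length upward (step 10 nt),
keeping the first extent whose fold passes the screen — the most compact
passing hairpin — which is then trimmed to the outermost pair enclosing the
mature/star duplex and re-folded for the final verdict.

**Candidate seeding.** Reads surviving preprocessing that map perfectly,
are not known matures and are not ncRNA fragments seed candidates when
their pooled support across libraries is ≥ 5 reads (the smallest published
candidate total), their length is 20–24 nt, and they have at most 10 loci
(repeat-like reads are excluded). Two windows per locus are cut — read at
the 5' end with 200 nt downstream, and at the 3' end with 200 nt upstream —
truncated at chromosome edges and reverse-complemented for minus-strand
loci. The 200-nt flank covers the published precursor span range (61–190
nt).

**Hairpin screen** (canonical plant-miRNA criteria, all configurable):
mature length 20–24 nt; mature entirely on one arm with no base in the
terminal loop; ≤ 4 unpaired mature bases in the miRNA/miRNA* duplex;
≤ 2 nt total asymmetric bulge within the duplex; ≥ 14 paired duplex bases;
hairpin span ≥ 60 nt. The first violated criterion is reported. Star-strand
read evidence is *not* required (the double-strand testing step is
omitted, as in the published procedure); the star is inferred from the
fold with the canonical 2-nt 3' overhang.

**Conservation and bidirectional loci.** A candidate precursor is annotated
with the best known precursor at ≥ 80% ungapped identity over the shorter
sequence (slide-and-count; no gaps). Sense/antisense candidate pairs on one
chromosome with ≥ 80% reciprocal interval overlap are reported as
bidirectional loci. The 5'-nucleotide composition of candidate matures is
reported on the RNA alphabet (plant miRNAs prefer 5' U/A).

## The synthetic fourplex

The simulator is the closed-loop test bed: every downstream stage is
validated against planted truth. It emulates, at desk scale, the structure
of the real four-library seed dataset:

- **Genome**: 3 chromosomes × 30 kb, GmNN names, two 3-exon gene models per
  chromosome.
- **rRNA tandem repeat**: a 250-nt unit × 12 copies on the last chromosome,
  deliberately *not* annotated as a gene (the real repeat was mis-annotated
  in the reference), sourcing 75% of each library's clean reads with a 1%
  antisense fraction (the ~1:100 strand bias).
- **Known miRNAs**: 20 hairpins, matures 20–24 nt starting with U or A,
  geometric base abundances 2500·0.65^i + 10 per 10⁵ reads, two registered
  names sharing one mature sequence (family aggregation). Differential
  design: 4-fold shifts on abundant matures in specific libraries plus one
  1.6-fold near-threshold case that the |log₂| > 1 gate must leave
  uncalled; everything else is null.
- **Novel hairpins**: four loci — one bidirectional pair (a second mature
  on the antisense strand of the same interval, placed near the outer arm
  end so both trimmed hairpins coincide, as in the published pair whose
  intervals differ by two bases), one mature planted at two loci, one
  conserved variant derived from a known hairpin by compensatory mutation
  (ungapped identity kept ≥ 80%, structure preserved), and one plain
  minus-strand hairpin. Published-scale abundances (totals 5–42 per 10⁵).
- **Other classes**: planted tRNA/snoRNA/other genes with fragment reads;
  genomic filler from exons, introns and intergenic spans; reads verified
  absent from the genome ("not matching"); corrupted reads (no adapter,
  ≥ 5 low-quality bases, or N in the insert — default 4% of raw reads,
  emulating the raw→high-quality loss of the real libraries).

Every planted hairpin is verified at build time to pass the folding and
duplex screens at its exact extent, and every planted mature carries at
least one duplex mismatch so it maps to exactly one strand of its locus
(real miRNA/miRNA* duplexes are never perfect; a perfect duplex would make
the mature read map ambiguously to both strands). All inserts are checked
against spurious adapter-prefix matches, including matches straddling the
insert/adapter junction, so that in `exact` count mode preprocessing
retains the planted composition bit-for-bit. In `multinomial` mode the
composition is resampled for sampling-noise studies.

Randomness: one stream per purpose, spawned from `(seed, purpose key)`, so
a single library regenerates independently; the same seed yields
byte-identical FASTA/FASTQ/TSV outputs.

**Problem sizes.** The default study condition is 10⁵ reads per library on
a ~90-kb genome — a deliberate desk-scale surrogate for the real ~2×10⁷
clean reads per library on a 1-Gb genome. Dataset-level percentages
(shared-Venn fractions, per-category compositions beyond the planted rRNA
fraction) therefore reproduce the *structure*, not the published numbers.

**What passing does not show.** The generator draws uniform fragments with
clean qualities: no ligation bias, no sequencing-error model, no isomiR
heterogeneity, no expression dispersion between biological replicates (the
real libraries pooled replicates before sequencing). Exact planted-truth
recovery validates the pipeline's bookkeeping and statistics, not its
behavior under real-data artifacts.

## Known limitations

- Base-pair maximization is not thermodynamic folding; borderline hairpins
  whose acceptance depends on energy differences may be judged differently
  from an MFE-based screen.
- Exact-match quantification ignores isomiRs entirely, as did the original
  counting rule.
- The per-precursor read tally double-counts reads shared between
  precursors (documented above).
- The exact count test models technical (Poisson) variation only; with
  biological replicates a dispersion-aware model would be required.
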