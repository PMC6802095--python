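# Methods

## Library anatomy and coordinate conventions

A restriction-site-anchored library sequences single-end reads of the
form `UMI(8) + sample barcode(8) + genomic insert`.  Every insert begins
at a cut site of the digestion enzyme and runs into the adjacent
restriction fragment; each cut site therefore exposes two independent
molecule sources, one per strand.

Coordinates are 0-based, half-open, and refer to the *start* of the
recognition sequence.  For a palindromic enzyme with top-strand cut
offset *t* and recognition length *L*, the bottom strand cuts at *L − t*.
A read sequences through the single-stranded overhang, so its 5′ genomic
coordinate is the outermost cut boundary on its strand:

* Watson (rightward) reads start at `site + min(t, L − t)`,
* Crick (leftward) reads start at `site + max(t, L − t)`.

For NlaIII (CATG↓, 3′ overhang, *t* = 4) this puts Watson reads at the
recognition start and Crick reads at start + 4; for HindIII (A↓AGCTT, 5′
overhang, *t* = 1) at start + 1 and start + 5.  The restriction fragment
between consecutive sites *i* and *i + 1* spans
`[site_i + min_offset, site_{i+1} + max_offset)`; its Watson read anchors
at site *i*, its Crick read at site *i + 1*.

Inter-site distances, spacing homogeneity, and nearest-site distances are
computed between recognition starts (the cut offset only matters for read
anchoring).  All descriptive SDs are population SDs (divide by *n*):
they summarise fully observed distance sets rather than estimate from
samples.  Windows containing N are never sites; distances spanning
assembly gaps are included as-is.  Degenerate IUPAC recognition codes are
rejected — both built-in enzymes are exact cutters, and ambiguity would
redefine every downstream count.

## Generative model of the simulator

The simulator emulates what the protocol measures, layer by layer:

1. **Genome** — i.i.d. bases at a requested GC fraction.  Real genomes
   have repeats, assembly gaps, and GC waves; the i.i.d. model gives the
   enzyme a renewal-process site distribution (expected NlaIII spacing
   4⁴ = 256 bp) and makes exact-match anchoring well-posed.
2. **Copy-number truth** — per sample, integer copy intervals tiling the
   genome (baseline ploidy 2).
3. **Molecules** — the count at each (site, strand, sample) source is
   Poisson with mean `lambda_per_copy × copy number at the recognition
   start`.  Poisson is the minimal i.i.d. sampling model; it yields the
   even Watson/Crick partitioning and makes depth/recovery analyses
   tractable.  Sources whose fragment is shorter than `min_fragment`
   (default 20 nt) are suppressed — size selection removes the physical
   molecule, so neither flank of a short fragment is amplified.  Placing
   the cut at the molecule stage (rather than dropping reads later) keeps
   the truth table and the recoverable signal consistent.
4. **Reads** — each molecule draws a fresh UMI uniformly from 4⁸
   (collisions allowed, uncorrected — as in plain UMI counting) and emits
   `1 + D` reads, `D ~ Poisson(pcr_dup_mean)` (a geometric alternative is
   available).  Duplicates inherit the molecule's UMI.  Substitution
   errors are applied i.i.d. per base over the whole read, prefix
   included — this is exactly what the directional UMI collapse has to
   repair.  Inserts are truncated at `read_len − 16` (default read
   length 75, matching a 75-cycle run) or at the fragment end.
   Qualities are constant `I`; quality-aware processing is out of scope.

Not modelled: amplification (IVT/PCR) efficiency bias, GC amplification
bias, FFPE fragmentation and deamination artefacts, indel sequencing
errors, UMI-collision correction.  Passing recovery tests on this
generator therefore demonstrates the pipeline's correctness under the
stated sampling model, not robustness to those real-data artefacts.

## Read processing

* **Parsing** — first 8 nt UMI, next 8 nt barcode, remainder insert;
  reads shorter than `16 + min_insert` (default insert minimum 20 nt) are
  rejected and tallied.
* **Demultiplexing** — a read is assigned to the unique whitelist barcode
  within Hamming distance ≤ 2; N counts as a mismatch; ties are rejected
  rather than guessed (prevents sample bleed).  Whitelists warn when any
  barcode pair is closer than Hamming 5, the distance at which 2-mismatch
  assignment stays unambiguous.
* **Anchoring** — full read alignment is out of scope (real libraries
  arrive as SAM/BAM from an external aligner, which is ingested trusting
  its coordinates and MAPQ).  For simulator-scale genomes an exact-match
  locator is provided: 20-mer seeds at offsets 0/10/20/30 and the insert
  tail, both orientations, against a sorted 2-bit k-mer index; candidate
  locations are verified full-length allowing scattered substitutions
  (≤ max(2, L/10)).  A unique verified location is compared with the
  strand-specific cut coordinates; within ±3 bp (configurable) the read
  anchors to that site, otherwise it is off-site; multiply-located
  inserts are discarded as multimapping.  The ±3 bp tolerance absorbs
  overhang-end ambiguity.
* **Filtering** — mapping quality ≥ 30 (inclusive) and sex-chromosome
  exclusion, so profiles always rest on the same autosomal support.
* **Deduplication** — reads are grouped by (chromosome, site, strand,
  sample).  `exact` counts distinct UMIs.  `directional` builds the
  standard UMI network: an edge joins UMIs at Hamming distance 1 when
  `count(u) ≥ 2·count(v) − 1`, and each connected component (rooted at
  its highest-count member) is one molecule.  Exact counts are never
  smaller than directional counts.
* **Error rate** — `100 × (deletions + insertions + mismatches) /
  aligned bases`, from CIGAR/NM for SAM input or from verified mismatch
  counts for the built-in locator.  With the built-in locator the
  estimate runs a few percent *low* of the injected rate: a read whose
  every seed window carries an error (mostly short inserts with several
  errors) cannot be located, and its mismatches are never counted.  At a
  1% substitution rate this bias is ≲ 5% relative, well inside the
  sampling tolerance at the 10⁵-aligned-base scale used for validation.

## Copy-number profiling

* **Binning** — non-overlapping constant-size autosomal windows (1 Mb
  down to 10 kb); a molecule lands in the bin containing its recognition
  start; total autosomal molecules are conserved.
* **Normalisation** — `log2(count / median(positive bin counts))`.  This
  is deliberately simple median scaling (with an optional GC-decile
  correction that divides counts by the smoothed median of their GC
  decile): the mappability/blacklist machinery of dedicated
  shallow-sequencing normalisers is unnecessary for synthetic genomes and
  for relative-ratio analyses, and is out of scope.  Zero-count bins are
  **missing** by default — at low depth a zero is no evidence of deep
  deletion.  A `pseudocount` mode (`log2((count + 0.5)/median)`) exists
  for settings where true copy-0 regions are expected; the end-to-end
  validation uses it because its truth landscape contains a homozygous
  deletion, whose bins would otherwise be reported missing rather than
  deleted.
* **Segmentation** — circular binary segmentation per chromosome (arms
  are not annotated on synthetic genomes; an interval file can impose
  per-arm segmentation by relabelling).  For the current interval the
  arc (i, j] of the circularised series maximising the absolute pooled
  two-sample t-statistic is found by exhaustive vectorised search;
  significance is assessed by permutation of the interval's values
  (default 1000 permutations, α = 0.01, p = (1 + exceedances)/(1 + N),
  early-stopped once significance is impossible); significant splits
  recurse.  Segment values are plain bin means, which minimise the
  residual sum of squares given the breakpoints; splitting never
  increases the RSS.  A zero-variance split with distinct means scores
  +∞ and is then judged by the permutation distribution like any other.
  An optional post-pass merges adjacent segments whose means differ by
  less than a threshold (default off).  The permutation RNG is seeded;
  identical seeds give identical segmentations.  Note that with fewer
  than ~10 bins the permutation p-value cannot reach α = 0.01, so very
  short chromosomes are never split — a floor inherent to permutation
  testing, not a bug.
* **Calling** — ternary states from segmented values:
  +1 above log2(2.5/2) ≈ +0.3219, −1 below log2(1.5/2) ≈ −0.4150, else
  0; missing bins call 0 and carry a missing flag.  The thresholds are
  half-copy gains/losses on a diploid baseline.
* **Profile statistics** — signal fluctuation (mean and SD of
  |raw − segmented| over scored bins), aneuploid genome fraction
  (percentage of scored bins called non-neutral), Pearson correlation of
  two profiles over shared scored bins (segmented values by default, raw
  optional), and genomic lengths of maximal same-state bin runs.

## Heterogeneity analytics

* **Gene states** — a gene takes the call of the segment overlapping the
  largest part of it.  On an exact overlap tie a non-neutral segment
  beats a neutral one (an alteration covering half a gene is the signal
  of interest); a +1/−1 tie resolves to 0 with a conflict flag.  Genes
  overlapping no bin are missing.
* **Recurrence ranking** — genes sorted by the number of samples in the
  queried state, descending; ties break lexicographically.
* **Clustering** — complete-linkage agglomeration on Euclidean distances,
  implemented directly (begin with singletons; repeatedly merge the pair
  with minimal maximum pairwise member distance; ties break on the lowest
  cluster indices, so the procedure is deterministic).  Complete linkage
  guarantees monotone merge heights.  Samples with all-missing features
  are excluded with a warning; features missing in any remaining sample
  are dropped so all distances share support.  Dendrograms export to
  Newick with branch lengths `parent height − child height` and
  smaller-subtree-first leaf order.  The implementation is cross-checked
  against scipy's complete linkage in the tests.
* **Replicate concordance** — per profile, the percentages of bins
  amplified and deleted; amp and del points are pooled across pairs (two
  points per pair) for a Pearson correlation and least-squares slope, and
  also reported separately.
* **Burden comparison** — two-sided Mann–Whitney U (scipy), exact null
  distribution when both groups have ≤ 8 values without ties, otherwise
  the normal approximation with tie correction.  Profiles with no
  detectable alteration (aneuploid fraction 0) are excluded from burden
  comparisons by the `detectable_cna_fractions` helper.

## Validation problem sizes

The recovery experiments run at sizes chosen to exercise every stage at
realistic per-bin depths while keeping a full test run in minutes on one
CPU:

* end-to-end: 5-Mb single-chromosome genome, four multiplexed samples,
  truth copies {0, 1, 2, 4} in blocks, λ = 3 molecules/site/copy, PCR
  duplicate mean 1, substitution rate 0.005, 50-kb bins (~1.8 M reads,
  ~0.9 M molecules, ~2300 molecules per bin per sample);
* error-rate recovery: ~1.4 × 10⁵ aligned bases at 1% injected errors;
* lossless round trip: ~500 molecules over ~1.5 k (site, strand, sample)
  groups — small enough that uniform-UMI collisions within a group
  (probability ∝ group-pair count / 4⁸, uncorrected by design) are
  vanishingly unlikely, so recovery is exact rather than
  exact-in-expectation;
* replicate clustering: 2-Mb genome, 40 bins of 50 kb, three truth
  landscapes × two independent molecule samplings, 100 seeded runs;
* CBS null calibration: 500 flat Gaussian series of 50 bins.

## Known limitations

* The exact-match locator is for simulator-scale genomes; real short-read
  data should be aligned externally and ingested as SAM/BAM.
* Normalisation omits mappability/blacklist corrections; absolute copy
  number, ploidy, tumour purity, and allele-specific states are out of
  scope.
* Paired-end reads, indel errors, and base-quality-aware UMI correction
  are not supported.
* Genome-scale digest statistics of a real reference (e.g. human
  NlaIII/HindIII spacing) require that reference FASTA locally; the
  machinery is identical to what the synthetic-genome tests exercise.
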