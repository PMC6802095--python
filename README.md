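# cutkit

A toolkit for **restriction-site-anchored reduced-representation
sequencing** of the CUTseq family: libraries in which genomic DNA is cut
with a type-II restriction enzyme, every cut site is ligated to an adapter
carrying an 8-nt sample barcode and an 8-nt unique molecular identifier
(UMI), many samples are pooled into one library, and single-end reads of
the form `UMI(8) + barcode(8) + genomic insert` are sequenced from the cut
sites.  The protocol's main use is shallow DNA copy-number profiling of
many low-input samples in parallel — e.g. many small regions of one FFPE
tumour section — and downstream intratumour-heterogeneity analysis.

`cutkit` implements the complete computational side of such an assay:

* **digest design** (`cutkit.enzymes`, `cutkit.digest`) — scan a genome
  for recognition sites of NlaIII (CATG) or HindIII (AAGCTT) (or any
  user-defined exact-sequence enzyme), and compute the statistics that
  drive enzyme choice: inter-site distance distributions, per-bin spacing
  homogeneity, site density in target regions, distance of loci to their
  nearest site;
* **a generative simulator** (`cutkit.simulate`) — synthetic genomes,
  integer copy-number truth landscapes, and FASTQ reads with the full
  library anatomy: per-(site, strand) molecule counts Poisson with mean
  λ·copy, uniform 8-nt UMIs, PCR duplicates sharing the molecule's UMI,
  and i.i.d. substitution errors, so every downstream stage is testable
  against ground truth without any external data;
* **read processing** (`cutkit.readproc`) — prefix parsing, barcode
  demultiplexing with ≤2 mismatches, exact-match site anchoring (or
  ingestion of externally aligned SAM/BAM), MAPQ ≥ 30 and sex-chromosome
  filtering, and UMI deduplication (exact, or the directional network
  collapse: merge UMIs at Hamming distance 1 when
  count(u) ≥ 2·count(v) − 1), plus library QC (off-site fraction,
  sequencing error rate, UMI base balance, Watson/Crick balance);
* **copy-number profiling** (`cutkit.cnprofile`, `cutkit.cbs`) — fixed
  windows (1 Mb … 10 kb), median-scaled log2 ratios with optional
  GC-decile correction, **circular binary segmentation** (max-t arc
  search, permutation test), and ternary calls at
  log2(2.5/2) ≈ +0.32 (amplified) and log2(1.5/2) ≈ −0.42 (deleted);
* **heterogeneity analytics** (`cutkit.heterogeneity`) — gene-level
  amp/neutral/del state matrices, recurrence ranking, complete-linkage
  hierarchical clustering with Newick export, replicate concordance of
  amplified/deleted genome fractions, and two-sided Mann–Whitney burden
  comparisons.

## Worked example

Simulate a two-sample multiplexed library in which sample S2 carries a
4-copy amplification of a 200-kb block, then recover it:

```python
from cutkit import (
    NLAIII, SiteIndex, generate_genome, CopyNumberTruth,
    simulate_molecules, simulate_reads, BarcodeWhitelist, process_fastq,
    BinGrid, build_profile, intersite_distances,
)

# 1. design: how often does the 4-cutter cut?
genome = generate_genome({"chr1": 1_000_000}, gc=0.5, seed=0)
index = SiteIndex.from_sequences(genome.sequences, NLAIII)
_, spacing = intersite_distances(index)
print(f"{index.n_sites()} NlaIII sites; spacing {spacing.mean:.0f} ± {spacing.sd:.0f} bp")

# 2. simulate: 2 molecules/site/copy, 1 PCR duplicate on average, 0.5% errors
barcodes = {"S1": "AAAAAAAA", "S2": "CCCCCCCC"}
truth = CopyNumberTruth.from_blocks(
    genome.lengths, list(barcodes),
    {"S1": [], "S2": [("chr1", 400_000, 600_000, 4)]},
)
sim = simulate_molecules(genome, truth, NLAIII, lambda_per_copy=2.0, seed=1)
prov = simulate_reads(sim, barcodes, "reads.fastq",
                      pcr_dup_mean=1.0, subst_error_rate=0.005, seed=2)
print(f"{len(prov)} reads from {sim.molecule_total()} molecules")

# 3. process: demultiplex, anchor at cut sites, deduplicate by UMI
result = process_fastq("reads.fastq", genome.sequences,
                       BarcodeWhitelist(barcodes), sim.site_index)
qc = result.qc
print(f"off-site {qc['offsite_pct']:.2f}%, error rate {qc['error_rate_pct']:.2f}%, "
      f"Watson fraction {qc['watson_fraction']:.3f}")

# 4. profile: 50-kb bins, CBS, ternary calls
grid = BinGrid.from_chrom_lengths(genome.lengths, 50_000)
for sample in barcodes:
    prof = build_profile(sample, result.molecules, grid, seed=3)
    print(f"{sample}: {len(prof.segments)} segments, "
          f"aneuploid fraction {prof.aneuploid_fraction():.0f}%")
```

Output:

```
3962 NlaIII sites; spacing 252 ± 250 bp
133296 reads from 66650 molecules
off-site 0.54%, error rate 0.49%, Watson fraction 0.499
S1: 1 segments, aneuploid fraction 0%
S2: 3 segments, aneuploid fraction 20%
```

Reading the numbers: the 4-cutter cuts every ~4⁴ = 256 bp, so 50-kb
windows hold ~200 sites each; the pipeline finds almost every read at a
cut site (0.54% off-site — reads whose insert could not be exactly
located because of the injected errors), recovers the injected 0.5%
error rate, and sees the expected even split of molecules between the
Watson and Crick flanks of the cuts.  The flat sample yields a single
neutral segment; the amplified sample splits into three segments and 20%
of its genome (the 200-kb block of 1 Mb = 4 of 20 bins) is called
amplified.

The same workflow is available from the shell:

```sh
cutkit digest --fasta genome.fa --enzyme NlaIII --bin-size 100000
cutkit simulate --config sim.yaml --out-prefix sim
cutkit process --fastq sim.fastq --fasta sim.fasta --whitelist wl.tsv
cutkit profile --molecules proc.molecules.tsv --chrom-sizes sim.chrom_sizes.tsv \
               --sample S1 --bin-size 50000 --seed 1
cutkit het --bins profS1.bins.tsv --bins profS2.bins.tsv
```

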