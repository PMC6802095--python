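"""End-to-end workflows: simulate → process → profile → evaluate.

These drive full recovery experiments against simulation ground truth and
are used both by the test-suite and the reproduction script.  Problem
sizes are parameters; the defaults are the study conditions the package
is validated under (5-Mb genome, four multiplexed samples, a frequent
4-cutter, 3 molecules/site/copy, one PCR duplicate per molecule on
average, 0.5% substitution errors, 50-kb bins).
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnprofile
from .enzymes import NLAIII, RestrictionEnzyme, SiteIndex
from .readproc import BarcodeWhitelist, ProcessResult, process_fastq
from .simulate import (
    CopyNumberTruth,
    SimulationTruth,
    SyntheticGenome,
    generate_genome,
    simulate_molecules,
    simulate_reads,
)

DEFAULT_BARCODES = {
    "S1": "AAAAAAAA",
    "S2": "CCCCCCCC",
    "S3": "GGGGTTTT",
    "S4": "TTTTGGGG",
}

DEFAULT_BLOCKS = [
    ("chr1", 1_000_000, 1_500_000, 1),  # hemizygous loss
    ("chr1", 2_500_000, 3_000_000, 4),  # amplification
    ("chr1", 4_000_000, 4_250_000, 0),  # homozygous loss
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def expected_calls(
    truth: CopyNumberTruth,
    grid: cnprofile.BinGrid,
    sample: str,
    thresholds: cnprofile.CallThresholds = cnprofile.DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Ternary call each bin *should* receive given the truth copy number
    at its midpoint: log2(copy / baseline) against the call thresholds
    (copy 0 maps to -inf, i.e. deleted)."""
    bins = grid.bins
    out = np.zeros(len(bins), dtype=np.int8)
    for chrom in pd.unique(bins["chrom"]):
        sel = np.nonzero((bins["chrom"] == chrom).to_numpy())[0]
        mid = ((bins["start"].to_numpy()[sel] + bins["end"].to_numpy()[sel]) // 2)
        copies = truth.copy_at(sample, chrom, mid)
        with np.errstate(divide="ignore"):
            log2 = np.where(copies > 0, np.log2(np.maximum(copies, 1e-12) / truth.baseline), -np.inf)
        out[sel] = np.where(
            log2 > thresholds.amp_log2, 1, np.where(log2 < thresholds.del_log2, -1, 0)
        )
    return out


def truth_breakpoint_bins(
    truth: CopyNumberTruth, grid: cnprofile.BinGrid, sample: str
) -> list[tuple[str, int]]:
    """Interior truth copy-change positions, in bin units per chromosome."""
    out = []
    sub = truth.intervals[truth.intervals["sample"] == sample]
    for chrom, grp in sub.groupby("chrom"):
        grp = grp.sort_values("start")
        copies = grp["copy"].to_numpy()
        starts = grp["start"].to_numpy()
        for i in range(1, len(grp)):
            if copies[i] != copies[i - 1]:
                out.append((chrom, int(starts[i] // grid.bin_size)))
    return out


@dataclass
class EndToEndResult:
    genome: SyntheticGenome
    sim: SimulationTruth
    process: ProcessResult
    profiles: dict[str, cnprofile.CopyNumberProfile]
    grid: cnprofile.BinGrid
    metrics: dict


def run_end_to_end(
    seed: int,
    genome_length: int = 5_000_000,
    blocks: list[tuple[str, int, int, int]] = DEFAULT_BLOCKS,
    samples: dict[str, str] = DEFAULT_BARCODES,
    enzyme: RestrictionEnzyme = NLAIII,
    lambda_per_copy: float = 3.0,
    pcr_dup_mean: float = 1.0,
    subst_error_rate: float = 0.005,
    bin_size: int = 50_000,
    dedup_method: str = "directional",
    zero_policy: str = "pseudocount",
    alpha: float = 0.01,
    n_perm: int = 1000,
) -> EndToEndResult:
    """Full recovery experiment: simulate a multiplexed library, run the
    processing pipeline, call copy numbers, and score against the truth.

    ``zero_policy="pseudocount"`` is the appropriate mode here because the
    default truth landscape contains a genuine copy-0 block, whose bins
    would otherwise be reported missing rather than deleted.

    Metrics: ``bin_call_accuracy_pct`` (bins whose call matches the
    truth-derived call, over all samples), ``breakpoint_max_offset_bins``
    (worst localisation error over all truth copy-change points; a missed
    breakpoint counts as the chromosome length), plus processing QC.
    """
    g_seed, m_seed, r_seed, p_seed = _child_seeds(seed, 4)
    genome = generate_genome({"chr1": genome_length}, gc=0.5, seed=g_seed)
    sample_names = list(samples)
    truth = CopyNumberTruth.from_blocks(genome.lengths, sample_names, blocks)
    sim = simulate_molecules(
        genome, truth, enzyme, lambda_per_copy=lambda_per_copy, seed=m_seed
    )
    whitelist = BarcodeWhitelist(dict(samples))
    with tempfile.TemporaryDirectory() as tmp:
        fastq = os.path.join(tmp, "reads.fastq")
        simulate_reads(
            sim,
            samples,
            fastq,
            pcr_dup_mean=pcr_dup_mean,
            subst_error_rate=subst_error_rate,
            seed=r_seed,
        )
        result = process_fastq(
            fastq,
            genome.sequences,
            whitelist,
            sim.site_index,
            dedup_method=dedup_method,
        )
    grid = cnprofile.BinGrid.from_chrom_lengths(genome.lengths, bin_size)
    profiles = {}
    correct = 0
    total = 0
    max_offset = 0
    for i, sample in enumerate(sample_names):
        prof = cnprofile.build_profile(
            sample,
            result.molecules,
            grid,
            alpha=alpha,
            n_perm=n_perm,
            seed=p_seed + i,
            zero_policy=zero_policy,
        )
        profiles[sample] = prof
        want = expected_calls(truth, grid, sample)
        correct += int((prof.calls == want).sum())
        total += len(want)
        detected = set()
        for srow in prof.segments.itertuples(index=False):
            detected.add((srow.chrom, int(srow.start_bin)))
        for chrom, bp in truth_breakpoint_bins(truth, grid, sample):
            offs = [abs(bp - b) for c, b in detected if c == chrom]
            max_offset = max(max_offset, min(offs) if offs else len(grid))
    metrics = {
        "bin_call_accuracy_pct": 100.0 * correct / total,
        "breakpoint_max_offset_bins": max_offset,
        "n_reads": result.qc["tally"]["total"],
        "n_molecules": int(result.molecules["n_molecules"].sum()),
        "offsite_pct": result.qc.get("offsite_pct", math.nan),
        "error_rate_pct": result.qc.get("error_rate_pct", math.nan),
        "watson_fraction": result.qc.get("watson_fraction", math.nan),
    }
    return EndToEndResult(genome, sim, result, profiles, grid, metrics)


def run_roundtrip(
    seed: int,
    genome_length: int = 100_000,
    lambda_per_copy: float = 0.15,
    bin_size: int = 10_000,
    enzyme: RestrictionEnzyme = NLAIII,
    dedup_method: str = "exact",
) -> dict:
    """Lossless round-trip: zero errors, zero duplication.

    Simulates a flat diploid library, processes it, and compares per-bin
    molecule counts with the simulation truth.  The scale is deliberately
    small (hundreds of molecules) so that uniform-UMI collisions inside a
    (site, strand, sample) group — which the counting model does not
    correct — have negligible probability and the recovery is exact.

    Returns ``bin_count_mismatches`` (bins differing from truth, summed
    over samples), ``offsite_pct`` and ``unassigned`` tallies.
    """
    g_seed, m_seed, r_seed = _child_seeds(seed, 3)
    genome = generate_genome({"chr1": genome_length}, gc=0.5, seed=g_seed)
    samples = {"S1": DEFAULT_BARCODES["S1"], "S2": DEFAULT_BARCODES["S2"]}
    truth = CopyNumberTruth.from_blocks(genome.lengths, list(samples), [])
    sim = simulate_molecules(genome, truth, enzyme, lambda_per_copy, seed=m_seed)
    whitelist = BarcodeWhitelist(dict(samples))
    with tempfile.TemporaryDirectory() as tmp:
        fastq = os.path.join(tmp, "reads.fastq")
        simulate_reads(
            sim, samples, fastq, pcr_dup_mean=0.0, subst_error_rate=0.0, seed=r_seed
        )
        result = process_fastq(
            fastq, genome.sequences, whitelist, sim.site_index, dedup_method=dedup_method
        )
    grid = cnprofile.BinGrid.from_chrom_lengths(genome.lengths, bin_size)
    mismatches = 0
    for sample in samples:
        got, _ = cnprofile.bin_counts(result.molecules, grid, sample=sample)
        truth_mol = sim.molecules.rename(columns={"count": "n_molecules"})
        want, _ = cnprofile.bin_counts(truth_mol, grid, sample=sample)
        mismatches += int((got != want).sum())
    return {
        "bin_count_mismatches": mismatches,
        "offsite_pct": result.qc.get("offsite_pct", math.nan),
        "unassigned": result.qc["tally"]["unassigned"],
        "n_molecules": int(result.molecules["n_molecules"].sum()),
    }


def run_error_recovery(
    seed: int,
    genome_length: int = 80_000,
    subst_error_rate: float = 0.01,
    lambda_per_copy: float = 2.0,
) -> dict:
    """Recover an injected substitution rate from processed reads.

    The default genome yields ~1.3e5 aligned bases.  The estimate runs a
    few percent low of the injected rate by construction: reads whose
    every seed window carries an error (mostly short inserts with several
    errors) cannot be located and their mismatches are never counted.
    """
    g_seed, m_seed, r_seed = _child_seeds(seed, 3)
    genome = generate_genome({"chr1": genome_length}, gc=0.5, seed=g_seed)
    samples = {"S1": DEFAULT_BARCODES["S1"]}
    truth = CopyNumberTruth.from_blocks(genome.lengths, list(samples), [])
    sim = simulate_molecules(genome, truth, NLAIII, lambda_per_copy, seed=m_seed)
    whitelist = BarcodeWhitelist(dict(samples))
    with tempfile.TemporaryDirectory() as tmp:
        fastq = os.path.join(tmp, "reads.fastq")
        simulate_reads(
            sim, samples, fastq, pcr_dup_mean=0.0,
            subst_error_rate=subst_error_rate, seed=r_seed,
        )
        result = process_fastq(
            fastq, genome.sequences, whitelist, sim.site_index, keep_reads=True
        )
    aligned = int(result.reads["aligned_len"].sum())
    return {
        "error_rate_pct": result.qc["error_rate_pct"],
        "aligned_bases": aligned,
        "injected_pct": 100.0 * subst_error_rate,
    }


# ---------------------------------------------------------------------------
# replicate clustering experiment (molecule-level, no reads)

_CHERRY_BLOCKS = {
    "T1": [("chr1", 300_000, 600_000, 1), ("chr1", 1_200_000, 1_500_000, 4)],
    "T2": [("chr1", 0, 400_000, 4), ("chr1", 900_000, 1_000_000, 1)],
    "T3": [("chr1", 700_000, 800_000, 4), ("chr1", 1_600_000, 2_000_000, 1)],
}


def replicate_cherry_rate(
    seed: int,
    n_runs: int = 100,
    genome_length: int = 2_000_000,
    bin_size: int = 50_000,
    lambda_per_copy: float = 0.5,
    n_perm: int = 1000,
) -> float:
    """Fraction of runs in which every replicate pair forms a cherry.

    Each run simulates two independent molecule samplings (technical
    replicates) of three distinct truth landscapes, profiles all six, and
    clusters the segmented profiles by complete linkage; success means the
    three replicate pairs are exactly the three cherries of the tree.
    """
    from .heterogeneity import cluster_samples

    g_seed, *run_seeds = _child_seeds(seed, 1 + n_runs)
    genome = generate_genome({"chr1": genome_length}, gc=0.5, seed=g_seed)
    site_index = SiteIndex.from_sequences(genome.sequences, NLAIII)
    grid = cnprofile.BinGrid.from_chrom_lengths(genome.lengths, bin_size)
    sample_names = [f"{t}_{r}" for t in _CHERRY_BLOCKS for r in ("a", "b")]
    blocks = {f"{t}_{r}": blk for t, blk in _CHERRY_BLOCKS.items() for r in ("a", "b")}
    truth = CopyNumberTruth.from_blocks(genome.lengths, sample_names, blocks)
    hits = 0
    for rs in run_seeds:
        sim = simulate_molecules(
            genome, truth, NLAIII, lambda_per_copy, seed=rs, site_index=site_index
        )
        mol = sim.molecules.rename(columns={"count": "n_molecules"})
        seg_rows = []
        for i, sample in enumerate(sample_names):
            prof = cnprofile.build_profile(
                sample, mol, grid, n_perm=n_perm, seed=rs + i + 1
            )
            seg_rows.append(np.nan_to_num(prof.segmented, nan=0.0))
        dend = cluster_samples(np.vstack(seg_rows), labels=sample_names)
        cherries = dend.cherries()
        want = {frozenset((f"{t}_a", f"{t}_b")) for t in _CHERRY_BLOCKS}
        if want <= cherries:
            hits += 1
    return hits / n_runs
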