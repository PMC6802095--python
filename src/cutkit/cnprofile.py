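"""Reduced-representation copy-number profiling.

Molecule counts are binned on a fixed autosomal grid, scaled to log2
ratios against the median bin, segmented with circular binary
segmentation, and thresholded into ternary amplified / neutral / deleted
calls at log2(2.5/2) and log2(1.5/2) — i.e. half-copy gains and losses on
a diploid baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import cbs
from .enzymes import SiteIndex

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class CallThresholds:
    """Log2-ratio cutoffs for ternary calling (diploid baseline)."""

    amp_log2: float = math.log2(2.5 / 2)  # ~ +0.3219
    del_log2: float = math.log2(1.5 / 2)  # ~ -0.4150

    def __post_init__(self) -> None:
        if not self.del_log2 < 0 < self.amp_log2:
            raise ValueError("need del_log2 < 0 < amp_log2")


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass
class BinGrid:
    """Non-overlapping constant-size bins tiling the autosomes."""

    bins: pd.DataFrame  # chrom, start, end (ordered)
    bin_size: int
    genome_id: str = "genome"

    @classmethod
    def from_chrom_lengths(
        cls,
        lengths: Mapping[str, int],
        bin_size: int,
        genome_id: str = "genome",
        exclude: set[str] = SEX_CHROMS,
    ) -> "BinGrid":
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        rows = []
        for chrom, length in lengths.items():
            if chrom in exclude:
                continue
            for start in range(0, length, bin_size):
                rows.append((chrom, start, min(start + bin_size, length)))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), bin_size, genome_id)

    @classmethod
    def from_fai(cls, path: str, bin_size: int, **kw) -> "BinGrid":
        tab = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
        return cls.from_chrom_lengths(
            dict(zip(tab["chrom"].astype(str), tab["length"])), bin_size, **kw
        )

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def chrom_labels(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    def locate(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Bin index for each (chrom, position); -1 when outside the grid."""
        out = np.full(len(pos), -1, dtype=np.int64)
        bins = self.bins
        for c in np.unique(chrom):
            sel = chrom == c
            sub = bins.index[bins["chrom"] == c]
            if len(sub) == 0:
                continue
            starts = bins.loc[sub, "start"].to_numpy()
            ends = bins.loc[sub, "end"].to_numpy()
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = (idx >= 0) & (pos[sel] < ends[np.clip(idx, 0, len(sub) - 1)])
            res = np.where(ok, sub.to_numpy()[np.clip(idx, 0, len(sub) - 1)], -1)
            out[sel] = res
        return out


def bin_counts(
    molecules: pd.DataFrame, grid: BinGrid, sample: str | None = None
) -> tuple[np.ndarray, int]:
    """Sum molecule counts per grid bin; returns (counts, n_unbinned).

    Molecules land in the bin containing their recognition-site start.
    Molecules outside the grid (e.g. sex chromosomes, which the grid
    excludes) are tallied as unbinned.
    """
    if sample is not None:
        molecules = molecules[molecules["sample"] == sample]
    counts = np.zeros(len(grid), dtype=np.int64)
    if len(molecules) == 0:
        return counts, 0
    idx = grid.locate(
        molecules["chrom"].to_numpy(), molecules["site"].to_numpy(dtype=np.int64)
    )
    weights = (
        molecules["n_molecules"] if "n_molecules" in molecules.columns else molecules["count"]
    ).to_numpy()
    inside = idx >= 0
    np.add.at(counts, idx[inside], weights[inside])
    return counts, int(weights[~inside].sum())


def gc_fraction_per_bin(grid: BinGrid, sequences: Mapping[str, str]) -> np.ndarray:
    gc = np.empty(len(grid))
    for i, row in enumerate(grid.bins.itertuples(index=False)):
        seq = sequences[row.chrom][row.start : row.end].upper()
        at = seq.count("A") + seq.count("T")
        cg = seq.count("C") + seq.count("G")
        gc[i] = cg / max(at + cg, 1)
    return gc


def normalize(
    counts: np.ndarray,
    zero_policy: str = "missing",
    pseudocount: float = 0.5,
    gc: np.ndarray | None = None,
) -> np.ndarray:
    """Median-scaled log2 ratios of bin counts.

    ratio_i = count_i / median(counts of non-zero bins); zero-count bins
    become NaN (``zero_policy="missing"``, the default — a zero bin at low
    depth is no evidence of deep deletion) or get *pseudocount* added
    (``zero_policy="pseudocount"``, appropriate when true copy-0 regions
    are expected).  With ``gc`` given, counts are first divided by the
    smoothed median count of their GC-content decile.
    """
    counts = np.asarray(counts, dtype=float)
    if not (counts > 0).any():
        raise ValueError("all bin counts are zero; nothing to normalise")
    if zero_policy not in ("missing", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    work = counts.copy()
    if gc is not None:
        deciles = np.clip((np.asarray(gc) * 10).astype(int), 0, 9)
        factors = np.ones(10)
        overall = np.median(work[work > 0])
        for d in range(10):
            sel = (deciles == d) & (work > 0)
            if sel.sum() >= 3:
                factors[d] = np.median(work[sel]) / overall
        work = work / factors[deciles]
    med = np.median(work[work > 0])
    with np.errstate(divide="ignore"):
        if zero_policy == "pseudocount":
            log2 = np.log2((work + pseudocount) / med)
        else:
            log2 = np.where(work > 0, np.log2(np.maximum(work, 1e-300) / med), np.nan)
    return log2


def segment_profile(
    log2: np.ndarray,
    chrom_labels: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    merge_min_delta: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """CBS per chromosome over non-missing bins.

    Returns (segmented log2 array with NaN at missing bins, segment table
    with columns chrom, start_bin, end_bin, n_bins, mean).  Bin indices in
    the table are global grid indices; missing bins interior to a segment
    belong to it positionally but keep NaN segmented values.
    """
    seg_values = np.full(len(log2), np.nan)
    rows = []
    rng = np.random.default_rng(seed)
    for chrom in pd.unique(chrom_labels):
        sel = np.nonzero(chrom_labels == chrom)[0]
        vals = log2[sel]
        ok = ~np.isnan(vals)
        if ok.sum() == 0:
            continue
        compact = vals[ok]
        segs = cbs.segment_series(compact, alpha=alpha, n_perm=n_perm, rng=rng)
        if merge_min_delta:
            segs = cbs.merge_segments(compact, segs, merge_min_delta)
        pos = sel[ok]  # global bin index of each compact element
        for s in segs:
            members = pos[s.start : s.end]
            seg_values[members] = s.mean
            rows.append((chrom, int(members[0]), int(members[-1]) + 1, len(members), s.mean))
    table = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin", "n_bins", "mean"])
    return seg_values, table


def call_states(
    segmented: np.ndarray, thresholds: CallThresholds = DEFAULT_THRESHOLDS
) -> tuple[np.ndarray, np.ndarray]:
    """Ternary calls from segmented values: +1 amplified, -1 deleted, 0
    neutral.  Missing bins call 0 and are flagged in the returned mask."""
    segmented = np.asarray(segmented, dtype=float)
    missing = np.isnan(segmented)
    calls = np.zeros(len(segmented), dtype=np.int8)
    calls[~missing & (segmented > thresholds.amp_log2)] = 1
    calls[~missing & (segmented < thresholds.del_log2)] = -1
    return calls, missing


@dataclass
class CopyNumberProfile:
    """One sample's binned, segmented, and called copy-number profile."""

    sample: str
    grid: BinGrid
    counts: np.ndarray
    log2: np.ndarray
    segmented: np.ndarray
    calls: np.ndarray
    missing: np.ndarray
    segments: pd.DataFrame = field(repr=False, default=None)
    thresholds: CallThresholds = DEFAULT_THRESHOLDS

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.bins.copy()
        df["count"] = self.counts
        df["log2"] = self.log2
        df["segmented"] = self.segmented
        df["call"] = self.calls
        df["missing"] = self.missing
        return df

    def fluctuation(self) -> tuple[float, float]:
        return fluctuation(self)

    def aneuploid_fraction(self) -> float:
        return aneuploid_fraction(self.calls, self.missing)


def build_profile(
    sample: str,
    molecules: pd.DataFrame,
    grid: BinGrid,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    zero_policy: str = "missing",
    gc: np.ndarray | None = None,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    merge_min_delta: float | None = None,
) -> CopyNumberProfile:
    """Molecule table → binned, normalised, segmented, called profile."""
    counts, _ = bin_counts(molecules, grid, sample=sample)
    log2 = normalize(counts, zero_policy=zero_policy, gc=gc)
    segmented, segments = segment_profile(
        log2, grid.chrom_labels, alpha=alpha, n_perm=n_perm, seed=seed,
        merge_min_delta=merge_min_delta,
    )
    calls, missing = call_states(segmented, thresholds)
    return CopyNumberProfile(
        sample, grid, counts, log2, segmented, calls, missing, segments, thresholds
    )


def fluctuation(profile: CopyNumberProfile) -> tuple[float, float]:
    """Mean and (population) SD of |raw − segmented| over non-missing bins.

    The per-bin deviation of the raw log2 ratio from its segment mean is
    the noise floor of a library at this resolution; it shrinks with depth.
    """
    ok = ~np.isnan(profile.log2) & ~np.isnan(profile.segmented)
    d = np.abs(profile.log2[ok] - profile.segmented[ok])
    if d.size == 0:
        raise ValueError("no scored bins")
    return float(d.mean()), float(d.std())


def aneuploid_fraction(calls: np.ndarray, missing: np.ndarray) -> float:
    """Percentage of non-missing bins called amplified or deleted."""
    scored = ~np.asarray(missing, dtype=bool)
    if scored.sum() == 0:
        raise ValueError("no scored bins")
    return 100.0 * float((calls[scored] != 0).sum()) / float(scored.sum())


def profile_correlation(
    a: CopyNumberProfile, b: CopyNumberProfile, on: str = "segmented"
) -> float:
    """Pearson correlation of two profiles over shared non-missing bins."""
    if on not in ("segmented", "raw"):
        raise ValueError("on must be 'segmented' or 'raw'")
    if len(a.grid) != len(b.grid):
        raise ValueError("profiles are on different bin grids")
    xa = a.segmented if on == "segmented" else a.log2
    xb = b.segmented if on == "segmented" else b.log2
    ok = ~np.isnan(xa) & ~np.isnan(xb)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared bins; correlation undefined")
    xa, xb = xa[ok], xb[ok]
    if np.std(xa) == 0 or np.std(xb) == 0:
        return math.nan
    return float(np.corrcoef(xa, xb)[0, 1])


def segment_length_distribution(profile: CopyNumberProfile, state: str) -> np.ndarray:
    """Genomic lengths (bp) of maximal same-state runs of bins.

    ``state`` is ``"amp"`` or ``"del"``; runs never cross chromosomes.
    """
    want = {"amp": 1, "del": -1}[state]
    bins = profile.grid.bins
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    lengths: list[int] = []
    for chrom in pd.unique(chroms):
        sel = np.nonzero(chroms == chrom)[0]
        mask = profile.calls[sel] == want
        i = 0
        while i < len(sel):
            if mask[i]:
                j = i
                while j + 1 < len(sel) and mask[j + 1]:
                    j += 1
                lengths.append(int(ends[sel[j]] - starts[sel[i]]))
                i = j + 1
            else:
                i += 1
    return np.asarray(lengths, dtype=np.int64)
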