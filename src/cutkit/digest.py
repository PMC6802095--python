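"""In-silico digest design statistics.

Given a genome-wide :class:`~cutkit.enzymes.SiteIndex`, these functions
answer the enzyme-selection questions that precede library design: how far
apart are consecutive recognition sites (which bounds the achievable
resolution), how homogeneous is site spacing along the genome, how dense
are sites inside target regions, and how far is an arbitrary locus from
its nearest site.

All descriptive SDs are population SDs (divide by n): these are summaries
of fully observed distance sets, not estimates from samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enzymes import SiteIndex
from .intervals import IntervalSet


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0

    @classmethod
    def of(cls, values: np.ndarray) -> "SummaryStats":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return cls(math.nan, math.nan, math.nan, 0)
        return cls(
            float(np.mean(values)),
            float(np.std(values)),  # population SD
            float(np.median(values)),
            int(values.size),
        )


def intersite_distances(index: SiteIndex) -> tuple[np.ndarray, SummaryStats]:
    """Distances between consecutive recognition starts, within chromosomes.

    Distances never span a chromosome boundary; the summary pools all
    chromosomes.  With fewer than two sites everywhere the distance set is
    empty and the summary is flagged undefined (``n == 0``, NaN moments).
    """
    per_chrom = [np.diff(pos) for pos in index.sites.values() if len(pos) >= 2]
    if per_chrom:
        distances = np.concatenate(per_chrom)
    else:
        distances = np.array([], dtype=np.int64)
    return distances, SummaryStats.of(distances)


def binwise_homogeneity(index: SiteIndex, bin_size: int) -> pd.DataFrame:
    """Per-bin SD of consecutive-site distances (site-spacing homogeneity).

    The genome is tiled in non-overlapping windows of ``bin_size`` bp; each
    consecutive-site distance is assigned to the bin containing its *left*
    site.  Bins with no assigned distance (fewer than 2 usable sites) get a
    missing (NaN) value.  Returns a DataFrame (chrom, bin_start, sd, n).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, pos in index.sites.items():
        length = index.chrom_lengths.get(chrom)
        if length is None:
            length = int(pos[-1]) + 1 if len(pos) else 0
        n_bins = max(1, -(-length // bin_size)) if length else 0
        dist = np.diff(pos)
        left_bins = pos[:-1] // bin_size if len(pos) >= 2 else np.array([], dtype=int)
        for b in range(n_bins):
            d = dist[left_bins == b]
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_size,
                    "sd": float(np.std(d)) if d.size else math.nan,
                    "n": int(d.size),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "sd", "n"])


def region_site_density(
    index: SiteIndex, regions: IntervalSet, shift: int = 50
) -> tuple[pd.DataFrame, SummaryStats]:
    """Recognition sites per kilobase inside (expanded) regions.

    Each region is widened by ``shift`` bp on both sides before counting —
    reads reach a region from nearby cut sites, so flanking sites still
    contribute coverage.  Expansion is clamped at position 0 and at the
    chromosome end.  Density = site count / expanded length in kb.
    """
    expanded = regions.shifted(shift, index.chrom_lengths) if shift else regions
    rows = []
    for iv in expanded:
        if iv.chrom not in index.sites:
            raise KeyError(f"region {iv.name!r} on unknown chromosome {iv.chrom!r}")
        pos = index.sites[iv.chrom]
        count = int(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))
        kb = (iv.end - iv.start) / 1000.0
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name,
                "n_sites": count,
                "sites_per_kb": count / kb,
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "n_sites", "sites_per_kb"]
    )
    return df, SummaryStats.of(df["sites_per_kb"].to_numpy())


def distance_to_nearest_site(
    positions: list[tuple[str, int]], index: SiteIndex
) -> tuple[np.ndarray, SummaryStats]:
    """Minimum |distance| from each genomic point to a recognition start.

    Points on chromosomes with zero sites get NaN (flagged missing); the
    summary covers the defined distances only.
    """
    out = np.empty(len(positions), dtype=float)
    for k, (chrom, p) in enumerate(positions):
        sites = index.sites.get(chrom)
        if sites is None:
            raise KeyError(f"point on unknown chromosome {chrom!r}")
        if len(sites) == 0:
            out[k] = math.nan
            continue
        i = np.searchsorted(sites, p)
        cand = []
        if i > 0:
            cand.append(p - sites[i - 1])
        if i < len(sites):
            cand.append(sites[i] - p)
        out[k] = float(min(cand))
    return out, SummaryStats.of(out[~np.isnan(out)])
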