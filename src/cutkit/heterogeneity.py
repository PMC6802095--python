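"""Multi-sample heterogeneity analytics on copy-number profiles.

Given ternary-called profiles for many regions/samples of a tumour, these
functions derive the gene-level state matrix (amplified / neutral /
deleted per gene and sample), rank genes by recurrence, cluster samples by
complete-linkage agglomeration on Euclidean distances, and quantify
replicate concordance and group burden differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnprofile import CopyNumberProfile, aneuploid_fraction
from .intervals import IntervalSet


@dataclass
class GeneStateMatrix:
    """Genes x samples ternary state matrix (+1 amp, 0 neutral, -1 del)."""

    states: pd.DataFrame  # index: gene names; columns: sample names
    conflicts: pd.DataFrame = None  # boolean, same shape; +1/-1 overlap ties

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)


def gene_states(
    profiles: dict[str, CopyNumberProfile], genes: IntervalSet
) -> GeneStateMatrix:
    """State of each gene in each sample.

    A gene takes the call of the *segment* overlapping the largest part of
    it.  On an exact overlap tie a non-neutral segment wins over a neutral
    one (an alteration covering half a gene is the interesting signal); a
    tie between +1 and -1 resolves to 0 with the conflict flag set.  Genes
    overlapping no bin get a missing (NaN) state.
    """
    samples = list(profiles)
    state = pd.DataFrame(index=genes.df["name"], columns=samples, dtype=float)
    conflict = pd.DataFrame(False, index=genes.df["name"], columns=samples)
    for sample, prof in profiles.items():
        bins = prof.grid.bins
        for iv in genes:
            sel = (
                (bins["chrom"] == iv.chrom)
                & (bins["end"] > iv.start)
                & (bins["start"] < iv.end)
            )
            idx = np.nonzero(sel.to_numpy())[0]
            if len(idx) == 0:
                state.loc[iv.name, sample] = np.nan
                continue
            # overlap length per segment = sum of bin overlaps, bins grouped
            # by their segmented value run (segment id = position in table)
            overlap_by_call: dict[int, float] = {}
            best: tuple[float, int] | None = None
            seg_table = prof.segments
            for srow in seg_table.itertuples(index=False):
                members = idx[(idx >= srow.start_bin) & (idx < srow.end_bin)]
                if len(members) == 0:
                    continue
                ov = float(
                    np.sum(
                        np.minimum(bins["end"].to_numpy()[members], iv.end)
                        - np.maximum(bins["start"].to_numpy()[members], iv.start)
                    )
                )
                call = int(prof.calls[members[0]])
                key = (ov, abs(call))  # ties: non-neutral precedence
                if best is None or key > (best[0], abs(best[1])):
                    best = (ov, call)
                elif key == (best[0], abs(best[1])) and call != best[1]:
                    # equal overlap, equal |call|, different sign: conflict
                    best = (ov, 0)
                    conflict.loc[iv.name, sample] = True
            state.loc[iv.name, sample] = best[1] if best is not None else np.nan
    return GeneStateMatrix(state, conflict)


def recurrence_ranking(matrix: GeneStateMatrix, state: str) -> pd.DataFrame:
    """Genes ranked by the number of samples carrying them in *state*
    ("amp" or "del"); descending count, ties lexicographic by gene name."""
    want = {"amp": 1, "del": -1}[state]
    counts = (matrix.states == want).sum(axis=1)
    out = counts.sort_index().sort_values(ascending=False, kind="stable")
    return pd.DataFrame({"gene": out.index, "n_samples": out.to_numpy()}).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# complete-linkage hierarchical clustering


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix form.

    ``linkage`` rows are (cluster_a, cluster_b, height, size); original
    observations are clusters 0..n-1, merges create n, n+1, ...
    Complete linkage guarantees non-decreasing merge heights.
    """

    labels: list[str]
    linkage: np.ndarray

    def cherries(self) -> set[frozenset]:
        """Pairs of leaves merged directly with each other."""
        n = len(self.labels)
        out = set()
        for a, b, _, _ in self.linkage:
            if a < n and b < n:
                out.add(frozenset((self.labels[int(a)], self.labels[int(b)])))
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Square matrix of merge heights at which leaf pairs first join."""
        n = len(self.labels)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for m, (a, b, h, _) in enumerate(self.linkage):
            la, lb = members.pop(int(a)), members.pop(int(b))
            for i in la:
                for j in lb:
                    coph[i, j] = coph[j, i] = h
            members[n + m] = la + lb
        return coph

    def to_newick(self) -> str:
        """Newick export; branch length = parent height − child height,
        leaf order smaller-subtree-first for reproducible plots."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        size = {i: 1 for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            kids = sorted((a, b), key=lambda c: (size[c], c))
            parts = [f"{node[c]}:{h - height[c]:g}" for c in kids]
            node[n + m] = "(" + ",".join(parts) + ")"
            height[n + m] = h
            size[n + m] = size[a] + size[b]
        return node[n + len(self.linkage) - 1] + ";"


def cluster_samples(
    data: pd.DataFrame | np.ndarray,
    labels: list[str] | None = None,
) -> Dendrogram:
    """Complete-linkage agglomerative clustering on Euclidean distances.

    *data* is samples x features (a DataFrame uses its index as labels).
    Samples whose features are all missing are excluded with a warning;
    remaining feature columns containing NaN are dropped so every distance
    is computed over the same features.  At every step the pair of
    clusters with the minimal complete-linkage distance (maximum pairwise
    member distance) merges; ties break deterministically on the lowest
    cluster indices.
    """
    import warnings

    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(x) for x in data.index]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if labels is None:
            labels = [f"s{i}" for i in range(len(X))]
    all_missing = np.isnan(X).all(axis=1)
    if all_missing.any():
        dropped = [l for l, m in zip(labels, all_missing) if m]
        warnings.warn(f"excluding all-missing samples: {dropped}", stacklevel=2)
        labels = [l for l, m in zip(labels, all_missing) if not m]
        X = X[~all_missing]
    col_ok = ~np.isnan(X).any(axis=0)
    X = X[:, col_ok]
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))

    Z = np.zeros((n - 1, 4))
    next_id = n
    current = list(range(n))  # active cluster ids, ordered by creation
    # pairwise complete-linkage distance between active clusters
    cd = {
        (a, b): d[a, b]
        for ai, a in enumerate(current)
        for b in current[ai + 1 :]
    }
    sizes = {i: 1 for i in range(n)}
    for step in range(n - 1):
        best_pair = min(cd, key=lambda p: (cd[p], p))
        a, b = best_pair
        h = cd[best_pair]
        Z[step] = (a, b, h, sizes[a] + sizes[b])
        new = next_id
        next_id += 1
        sizes[new] = sizes[a] + sizes[b]
        current = [c for c in current if c not in (a, b)]
        for c in current:
            da = cd[(min(a, c), max(a, c))]
            db = cd[(min(b, c), max(b, c))]
            cd[(c, new)] = max(da, db)
        for p in list(cd):
            if a in p or b in p:
                del cd[p]
        current.append(new)
    return Dendrogram(labels, Z)


# ---------------------------------------------------------------------------
# replicate concordance and burden comparison


def replicate_concordance(
    pairs: list[tuple[CopyNumberProfile, CopyNumberProfile]],
) -> tuple[pd.DataFrame, dict]:
    """Agreement of amplified/deleted genome fractions between replicates.

    For each pair, the percentage of bins amplified and deleted is
    computed in both members; amp and del points are pooled (two points
    per pair) for a Pearson correlation and a least-squares slope, and
    also reported separately.  A constant point set leaves the correlation
    undefined (NaN).
    """
    rows = []
    for a, b in pairs:
        for state, want in (("amp", 1), ("del", -1)):
            fa = 100.0 * float((a.calls[~a.missing] == want).sum()) / max(1, (~a.missing).sum())
            fb = 100.0 * float((b.calls[~b.missing] == want).sum()) / max(1, (~b.missing).sum())
            rows.append((a.sample, b.sample, state, fa, fb))
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "state", "frac_a", "frac_b"])
    summary: dict = {}
    x, y = df["frac_a"].to_numpy(), df["frac_b"].to_numpy()
    if len(x) >= 2 and np.std(x) > 0 and np.std(y) > 0:
        summary["pearson_r"] = float(np.corrcoef(x, y)[0, 1])
        summary["slope"] = float(np.polyfit(x, y, 1)[0])
    else:
        summary["pearson_r"] = math.nan
        summary["slope"] = math.nan
    for state in ("amp", "del"):
        sub = df[df["state"] == state]
        xs, ys = sub["frac_a"].to_numpy(), sub["frac_b"].to_numpy()
        if len(xs) >= 2 and np.std(xs) > 0 and np.std(ys) > 0:
            summary[f"pearson_r_{state}"] = float(np.corrcoef(xs, ys)[0, 1])
        else:
            summary[f"pearson_r_{state}"] = math.nan
    return df, summary


def burden_comparison(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of aneuploid burden between groups.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` values and no ties straddle the groups; otherwise the
    normal approximation with tie correction.  Returns (U, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = (
        "exact"
        if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def detectable_cna_fractions(profiles: list[CopyNumberProfile]) -> np.ndarray:
    """Aneuploid genome fractions of the profiles that have any CNA at all
    (regions with no detectable alteration are excluded from burden
    comparisons)."""
    fracs = [aneuploid_fraction(p.calls, p.missing) for p in profiles]
    return np.array([f for f in fracs if f > 0])
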