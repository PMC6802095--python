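"""Circular binary segmentation (CBS) of per-bin log2 ratios.

The series for one chromosome is treated as a circle; the algorithm finds
the arc ``x[i:j]`` whose two-sample t-statistic against the rest of the
circle is maximal in absolute value, assesses that maximum by permutation
(shuffling bin values within the interval), and — when significant at
``alpha`` — splits at i and j and recurses into the sub-intervals.  The
segmented value of each final segment is the plain mean of its bins, which
also minimises the residual sum of squares given the breakpoints.

Everything is vectorised over the (i, j) arc grid; permutations run in
chunks with early stopping once significance can no longer be reached, so
flat (null) intervals are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _arc_tstats(x: np.ndarray) -> np.ndarray:
    """|t| for every arc (i, j], 0 <= i < j <= n, 1 <= j-i <= n-1.

    Returns an (n+1, n+1) matrix with NaN at invalid (i, j) pairs.
    The t-statistic uses the pooled within-group variance on n - 2 df;
    a zero-variance split with distinct means scores +inf.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    Q = np.concatenate([[0.0], np.cumsum(x * x)])
    T, QT = S[-1], Q[-1]
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    k = (j - i).astype(float)
    valid = (k >= 1) & (k <= n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_in = S[None, :] - S[:, None]
        mean_in = sum_in / k
        mean_out = (T - sum_in) / (n - k)
        ssw = (QT - (Q[None, :] - Q[:, None]) - (n - k) * mean_out**2) + (
            (Q[None, :] - Q[:, None]) - k * mean_in**2
        )
        ssw = np.maximum(ssw, 0.0)
        denom = np.sqrt(ssw / max(n - 2, 1) * (1.0 / k + 1.0 / (n - k)))
        t = np.abs(mean_in - mean_out) / denom
        t[(denom == 0) & (np.abs(mean_in - mean_out) > 0)] = np.inf
        t[(denom == 0) & ~(np.abs(mean_in - mean_out) > 0)] = 0.0
    t[~valid] = np.nan
    return t


def max_t_statistic(x: np.ndarray) -> tuple[int, int, float]:
    """The arc (i, j) maximising |t|, with its statistic.

    Ties resolve to the smallest (i, j) in row-major order (deterministic).
    """
    t = _arc_tstats(x)
    flat = np.nan_to_num(t, nan=-1.0)
    idx = int(np.argmax(flat))
    n1 = t.shape[1]
    return idx // n1, idx % n1, float(t.ravel()[idx])


def _perm_exceedances(
    x: np.ndarray,
    t_obs: float,
    n_perm: int,
    rng: np.random.Generator,
    stop_count: int | None = None,
    chunk: int = 250,
) -> int:
    """Number of permutations whose max |t| >= t_obs (early-stopped)."""
    n = len(x)
    count = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.empty((m, n))
        for r in range(m):
            perms[r] = rng.permutation(x)
        S = np.concatenate([np.zeros((m, 1)), np.cumsum(perms, axis=1)], axis=1)
        Q = np.concatenate([np.zeros((m, 1)), np.cumsum(perms**2, axis=1)], axis=1)
        T = S[:, -1][:, None, None]
        QT = Q[:, -1][:, None, None]
        i = np.arange(n + 1)[:, None]
        j = np.arange(n + 1)[None, :]
        k = (j - i).astype(float)
        valid = (k >= 1) & (k <= n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sum_in = S[:, None, :] - S[:, :, None]
            q_in = Q[:, None, :] - Q[:, :, None]
            mean_in = sum_in / k
            mean_out = (T - sum_in) / (n - k)
            ssw = np.maximum(
                (QT - q_in - (n - k) * mean_out**2) + (q_in - k * mean_in**2), 0.0
            )
            denom = np.sqrt(ssw / max(n - 2, 1) * (1.0 / k + 1.0 / (n - k)))
            diff = np.abs(mean_in - mean_out)
            t = np.where(denom > 0, diff / denom, np.where(diff > 0, np.inf, 0.0))
        t[:, ~valid] = -np.inf
        tmax = t.reshape(m, -1).max(axis=1)
        count += int(np.count_nonzero(tmax >= t_obs))
        done += m
        if stop_count is not None and count > stop_count:
            break
    return count


@dataclass
class Segment:
    start: int  # bin index, inclusive
    end: int  # bin index, exclusive
    mean: float


def segment_series(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = 0,
    min_width: int = 1,
) -> list[Segment]:
    """Segment one chromosome's (gap-free) log2-ratio series.

    Returns contiguous segments covering ``[0, len(x))`` with their bin
    means.  A candidate split is accepted when its permutation p-value
    ``(1 + #exceedances) / (1 + n_perm)`` is below *alpha*.  Intervals
    shorter than 2 bins are trivially single segments.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("segment_series requires gap-free input; drop NaNs first")
    # threshold on exceedance count implied by p < alpha
    stop_count = int(np.ceil(alpha * (1 + n_perm))) - 1

    out: list[Segment] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 or np.ptp(seg) == 0:
            out.append(Segment(lo, hi, float(seg.mean())))
            return
        i, j, t_obs = max_t_statistic(seg)
        if t_obs <= 0:
            out.append(Segment(lo, hi, float(seg.mean())))
            return
        exceed = _perm_exceedances(seg, t_obs, n_perm, rng, stop_count=stop_count)
        p = (1 + exceed) / (1 + n_perm)
        if p >= alpha:
            out.append(Segment(lo, hi, float(seg.mean())))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, len(x))
    out.sort(key=lambda s: s.start)
    return out


def merge_segments(
    x: np.ndarray, segments: list[Segment], min_delta: float
) -> list[Segment]:
    """Optionally merge adjacent segments whose means differ by < min_delta."""
    merged = list(segments)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for idx in range(len(merged) - 1):
            a, b = merged[idx], merged[idx + 1]
            if abs(a.mean - b.mean) < min_delta:
                nm = float(x[a.start : b.end].mean())
                merged[idx : idx + 2] = [Segment(a.start, b.end, nm)]
                changed = True
                break
    return merged


def segmented_values(x: np.ndarray, segments: list[Segment]) -> np.ndarray:
    out = np.empty(len(x))
    for s in segments:
        out[s.start : s.end] = s.mean
    return out
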