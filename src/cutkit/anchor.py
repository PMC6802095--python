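"""Exact-match insert location against simulator-scale genomes.

Full short-read alignment is out of scope (real libraries arrive as
SAM/BAM from an external aligner); for the built-in simulator this module
locates each insert by exact seed match plus mismatch-tolerant
verification, which is all the single-substitution error model requires.

Seeds of ``k`` bases are taken at several offsets along the insert so
that a read whose first bases carry a sequencing error can still be
located — otherwise every anchored read would be conditioned on an
error-free 5' end and the recovered error rate would be biased low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enzymes import reverse_complement

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i


def _encode_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-pack every k-mer of a base-code array; returns (kmer codes,
    validity mask) for start positions 0..n-k."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    out = np.zeros(n - k + 1, dtype=np.uint64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : n - k + 1 + j]
        out = (out << np.uint64(2)) | window.astype(np.uint64)
        valid &= window != 255
    return out, valid


@dataclass
class MatchHit:
    chrom: str
    start: int  # 0-based genomic start of the (forward-strand) match
    strand: str  # '+' insert matches forward; '-' insert is revcomp of genome
    n_mismatch: int


class ExactMatchIndex:
    """Sorted 2-bit k-mer index over the forward strand of a genome."""

    def __init__(self, sequences: dict[str, str], k: int = 20):
        self.k = k
        self.chroms = list(sequences)
        seqs = [sequences[c] for c in self.chroms]
        self.offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
        np.cumsum([len(s) for s in seqs], out=self.offsets[1:])
        self.concat = "".join(seqs)
        codes = _LUT[np.frombuffer(self.concat.encode(), dtype=np.uint8)]
        kmers, valid = _encode_kmers(codes, k)
        # k-mers straddling a chromosome boundary are not real sequence
        for off in self.offsets[1:-1]:
            valid[max(0, off - k + 1) : off] = False
        pos = np.nonzero(valid)[0].astype(np.int64)
        order = np.argsort(kmers[pos], kind="stable")
        self.sorted_kmers = kmers[pos][order]
        self.sorted_pos = pos[order]

    def _chrom_of(self, gpos: np.ndarray | int):
        idx = np.searchsorted(self.offsets, gpos, side="right") - 1
        return idx

    def lookup(self, kmer_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) ranges into sorted_pos for each query k-mer code."""
        lo = np.searchsorted(self.sorted_kmers, kmer_codes, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer_codes, side="right")
        return lo, hi

    def _mismatches(self, query: str, gstart: int) -> int:
        ref = self.concat[gstart : gstart + len(query)]
        if query == ref:
            return 0
        a = np.frombuffer(query.encode(), dtype=np.uint8)
        b = np.frombuffer(ref.encode(), dtype=np.uint8)
        return int(np.count_nonzero(a != b))

    def locate(
        self,
        insert: str,
        seed_offsets: tuple[int, ...] = (0, 10, 20, 30),
        max_hits_per_seed: int = 16,
        max_mismatch: int | None = None,
    ) -> list[MatchHit]:
        """All acceptable genomic matches of *insert* (both strands).

        A candidate position comes from any error-free seed (the fixed
        offsets plus the tail k-mer); it is accepted when the full-length
        comparison has at most ``max_mismatch`` substitutions (default:
        ``max(2, len(insert) // 10)``).
        """
        L = len(insert)
        if max_mismatch is None:
            max_mismatch = max(2, L // 10)
        hits: list[MatchHit] = []
        seen: set[tuple[int, str]] = set()
        offs = [o for o in seed_offsets if o + self.k <= L]
        if L - self.k >= 0 and L - self.k not in offs:
            offs.append(L - self.k)
        for strand, q in (("+", insert), ("-", reverse_complement(insert))):
            codes = _LUT[np.frombuffer(q.upper().encode(), dtype=np.uint8)]
            for off in offs:
                window = codes[off : off + self.k]
                if (window == 255).any():
                    continue
                code = np.uint64(0)
                for v in window:
                    code = (code << np.uint64(2)) | np.uint64(v)
                lo = np.searchsorted(self.sorted_kmers, code, side="left")
                hi = np.searchsorted(self.sorted_kmers, code, side="right")
                if hi - lo > max_hits_per_seed:
                    hi = lo + max_hits_per_seed + 1
                for p in self.sorted_pos[lo:hi]:
                    g = int(p) - off
                    if (g, strand) in seen:
                        continue
                    seen.add((g, strand))
                    ci = int(np.searchsorted(self.offsets, g, side="right") - 1)
                    if g < self.offsets[ci] or g + L > self.offsets[ci + 1]:
                        continue
                    mm = self._mismatches(q, g)
                    if mm <= max_mismatch:
                        hits.append(
                            MatchHit(self.chroms[ci], g - int(self.offsets[ci]), strand, mm)
                        )
        return hits

    def seed_codes(self, queries: list[str], offset: int | None) -> np.ndarray:
        """2-bit codes of the k-mer at *offset* in each query (``None``
        means the tail k-mer ending at the last base); 2^64-1 when out of
        range or containing non-ACGT."""
        out = np.full(len(queries), np.iinfo(np.uint64).max, dtype=np.uint64)
        k = self.k
        sub = []
        idx = []
        for i, q in enumerate(queries):
            off = len(q) - k if offset is None else offset
            if 0 <= off and off + k <= len(q):
                sub.append(q[off : off + k].upper())
                idx.append(i)
        if not sub:
            return out
        arr = _LUT[np.frombuffer("".join(sub).encode(), dtype=np.uint8)].reshape(-1, k)
        bad = (arr == 255).any(axis=1)
        codes = np.zeros(len(sub), dtype=np.uint64)
        for j in range(k):
            codes = (codes << np.uint64(2)) | arr[:, j].astype(np.uint64)
        codes[bad] = np.iinfo(np.uint64).max
        out[np.asarray(idx)] = codes
        return out
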