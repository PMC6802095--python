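"""Restriction enzymes and genome-wide recognition-site indexes.

The library anatomy anchors every sequenced molecule at a restriction cut
site, so everything downstream (simulation, read anchoring, deduplication)
is keyed on the positions produced here.  Coordinates are 0-based and refer
to the *start* of the recognition sequence; half-open intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction endonuclease with an exact recognition sequence.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"NlaIII"``.
    recognition
        Recognition sequence over {A,C,G,T}.  Degenerate IUPAC codes are not
        supported: both built-in enzymes are exact cutters, and ambiguity
        would change the meaning of every site count downstream.
    cut_offset_top
        Offset of the top-strand cut from the recognition start, in bases.
        NlaIII (CATG^, 3' overhang) cuts at offset 4; HindIII (A^AGCTT,
        5' overhang) at offset 1.
    overhang_len
        Length of the single-stranded overhang left by the cut.
    """

    name: str
    recognition: str
    cut_offset_top: int
    overhang_len: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        bad = set(rec) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.name}: degenerate/invalid recognition bases {sorted(bad)}; "
                "only exact A/C/G/T recognition sequences are supported"
            )
        if not rec:
            raise ValueError("recognition sequence must be non-empty")
        if not 0 <= self.cut_offset_top <= len(rec):
            raise ValueError(
                f"cut_offset_top={self.cut_offset_top} outside recognition "
                f"sequence of length {len(rec)}"
            )
        if self.overhang_len < 0:
            raise ValueError("overhang_len must be non-negative")

    @property
    def site_len(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    # For a palindromic site the bottom-strand cut sits at the mirrored
    # offset L - cut_offset_top.  A read sequenced from a cut runs into the
    # fragment and reads *through* the overhang, so its 5' genomic
    # coordinate is the outermost cut boundary on its strand:
    #   Watson (rightward) reads start at  site + min(t, L - t)
    #   Crick  (leftward)  reads start at  site + max(t, L - t)
    # e.g. NlaIII: Watson at site + 0, Crick at site + 4.

    @property
    def cut_offset_bottom(self) -> int:
        return self.site_len - self.cut_offset_top

    @property
    def watson_cut_offset(self) -> int:
        return min(self.cut_offset_top, self.cut_offset_bottom)

    @property
    def crick_cut_offset(self) -> int:
        return max(self.cut_offset_top, self.cut_offset_bottom)


NLAIII = RestrictionEnzyme("NlaIII", "CATG", 4, 4)
HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1, 4)

BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "nlaiii": NLAIII,
    "hindiii": HINDIII,
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up a built-in enzyme by (case-insensitive) name."""
    try:
        return BUILTIN_ENZYMES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: "
            + ", ".join(e.name for e in BUILTIN_ENZYMES.values())
        ) from None


def scan_sites(sequence: str, enzyme: RestrictionEnzyme) -> np.ndarray:
    """All recognition-start positions of *enzyme* in *sequence*.

    Overlapping occurrences are reported; matching is case-insensitive;
    windows containing N (or any non-ACGT character) never match because
    the recognition sequence itself is exact.  Returns a sorted int64
    array (empty for an empty sequence).
    """
    seq = sequence.upper()
    pat = enzyme.recognition
    hits: list[int] = []
    i = seq.find(pat)
    while i != -1:
        hits.append(i)
        i = seq.find(pat, i + 1)  # step 1 so overlapping matches count
    return np.asarray(hits, dtype=np.int64)


@dataclass
class SiteIndex:
    """Sorted per-chromosome recognition-site positions for one enzyme."""

    genome_id: str
    enzyme: RestrictionEnzyme
    sites: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str],
        enzyme: RestrictionEnzyme,
        genome_id: str = "genome",
    ) -> "SiteIndex":
        sites = {c: scan_sites(s, enzyme) for c, s in sequences.items()}
        lengths = {c: len(s) for c, s in sequences.items()}
        return cls(genome_id, enzyme, sites, lengths)

    @classmethod
    def from_fasta(cls, path: str, enzyme: RestrictionEnzyme) -> "SiteIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(path)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls.from_sequences(seqs, enzyme, genome_id=str(path))

    def __post_init__(self) -> None:
        for chrom, pos in self.sites.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: site positions not strictly increasing")
            self.sites[chrom] = pos

    @property
    def chroms(self) -> list[str]:
        return list(self.sites)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.sites[chrom])
        return sum(len(v) for v in self.sites.values())

    def watson_cuts(self, chrom: str) -> np.ndarray:
        """5' genomic coordinates of Watson-strand (rightward) reads."""
        return self.sites[chrom] + self.enzyme.watson_cut_offset

    def crick_cuts(self, chrom: str) -> np.ndarray:
        """5' genomic coordinates of Crick-strand (leftward) reads."""
        return self.sites[chrom] + self.enzyme.crick_cut_offset

    def iter_sites(self) -> Iterator[tuple[str, int]]:
        for chrom, pos in self.sites.items():
            for p in pos:
                yield chrom, int(p)

    def to_bed(self, path: str) -> None:
        """Write sites as BED (chrom, start, start + site_len, enzyme)."""
        L = self.enzyme.site_len
        with open(path, "w") as fh:
            for chrom, pos in self.sites.items():
                for p in pos:
                    fh.write(f"{chrom}\t{p}\t{p + L}\t{self.enzyme.name}\n")
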