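"""Generative simulator for restriction-site-anchored multiplexed libraries.

The generative model mirrors the library anatomy: every restriction cut
site exposes two independent molecule sources (one per strand — the Watson
flank is read rightward, the Crick flank leftward), the number of original
molecules at a source is Poisson with mean ``lambda_per_copy x local copy
number``, each molecule receives an 8-nt UMI drawn uniformly from 4^8, a
sample barcode, and ``1 + D`` sequenced copies (D PCR duplicates), and
substitution errors hit every base of the read i.i.d.  Reads are emitted
as ``UMI(8) + barcode(8) + genomic insert``, single-end.

Restriction fragments shorter than ``min_fragment`` are dropped at the
molecule stage (size selection removes the physical molecule, so neither
flank of a short fragment is amplified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .enzymes import RestrictionEnzyme, SiteIndex, reverse_complement

UMI_LEN = 8
BARCODE_LEN = 8
PREFIX_LEN = UMI_LEN + BARCODE_LEN

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticGenome:
    """I.i.d.-base genome with a declared GC fraction."""

    sequences: dict[str, str]
    gc: float = 0.5
    seed: int | None = None
    genome_id: str = "synthetic"

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_fai(self, path: str) -> None:
        """Minimal chrom-length table (chrom, length) as used for bin grids."""
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f"{chrom}\t{len(seq)}\n")


def generate_genome(
    lengths: Mapping[str, int], gc: float = 0.5, seed: int = 0
) -> SyntheticGenome:
    """Draw a genome of i.i.d. bases; GC split evenly between G and C.

    Deterministic given *seed*.  Raises for GC outside (0, 1) or any
    non-positive chromosome length.
    """
    if not 0 < gc < 1:
        raise ValueError(f"GC fraction must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, str] = {}
    for chrom, n in lengths.items():
        if n <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {n}")
        draw = rng.choice(_BASES, size=n, p=p)
        seqs[chrom] = draw.tobytes().decode()
    return SyntheticGenome(seqs, gc=gc, seed=seed)


@dataclass
class CopyNumberTruth:
    """Ground-truth integer copy-number landscape, per sample.

    ``intervals`` has columns (sample, chrom, start, end, copy); intervals
    are half-open, non-overlapping within a sample and, per chromosome,
    tile it completely in sorted order.
    """

    intervals: pd.DataFrame
    baseline: int = 2

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        req = {"sample", "chrom", "start", "end", "copy"}
        if not req <= set(df.columns):
            raise ValueError(f"truth table needs columns {sorted(req)}")
        if (df["copy"] < 0).any():
            raise ValueError("copy numbers must be non-negative integers")
        df = df.sort_values(["sample", "chrom", "start"], kind="stable")
        for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping truth intervals for {sample}/{chrom}")
        self.intervals = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["sample"]))

    @classmethod
    def from_blocks(
        cls,
        genome_lengths: Mapping[str, int],
        samples: list[str],
        blocks: Mapping[str, list[tuple[str, int, int, int]]] | list[tuple[str, int, int, int]],
        baseline: int = 2,
    ) -> "CopyNumberTruth":
        """Build a truth that is `baseline` everywhere except the given
        (chrom, start, end, copy) blocks; blocks may be shared by all
        samples (list) or given per sample (dict)."""
        rows = []
        for sample in samples:
            sample_blocks = blocks[sample] if isinstance(blocks, dict) else blocks
            per_chrom: dict[str, list[tuple[int, int, int]]] = {
                c: [] for c in genome_lengths
            }
            for chrom, start, end, copy in sample_blocks:
                per_chrom[chrom].append((start, end, copy))
            for chrom, length in genome_lengths.items():
                pos = 0
                for start, end, copy in sorted(per_chrom[chrom]):
                    if start < pos:
                        raise ValueError(f"overlapping blocks on {chrom}")
                    if start > pos:
                        rows.append((sample, chrom, pos, start, baseline))
                    rows.append((sample, chrom, start, min(end, length), copy))
                    pos = end
                if pos < length:
                    rows.append((sample, chrom, pos, length, baseline))
        df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "copy"])
        return cls(df, baseline=baseline)

    def copy_at(self, sample: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integer copy number of the truth interval containing each position."""
        sub = self.intervals[
            (self.intervals["sample"] == sample) & (self.intervals["chrom"] == chrom)
        ]
        starts = sub["start"].to_numpy()
        copies = sub["copy"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        if (idx < 0).any():
            raise ValueError("position before first truth interval")
        return copies[idx]

    def to_bed(self, path: str) -> None:
        self.intervals.to_csv(path, sep="\t", header=True, index=False)


@dataclass
class SimulationTruth:
    """Everything a simulation was generated from, for downstream checks."""

    genome: SyntheticGenome
    enzyme: RestrictionEnzyme
    truth: CopyNumberTruth
    molecules: pd.DataFrame  # sample, chrom, site, strand, count  (count > 0)
    site_index: SiteIndex = field(repr=False, default=None)
    lambda_per_copy: float = 1.0
    min_fragment: int = 20

    def molecule_total(self) -> int:
        return int(self.molecules["count"].sum())


def _fragment_spans(
    site_index: SiteIndex, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site fragment spans for Watson (right flank) and Crick (left
    flank) reads.  Watson read from site i covers [w[i], right_edge[i]);
    Crick read from site i covers [left_edge[i], c[i]) reverse-complemented.
    Fragment edges sit at the cut boundaries of the neighbouring site (reads
    run through the overhang, so a fragment spans recognition-start of its
    left site to recognition-end cut of its right site)."""
    enz = site_index.enzyme
    s = site_index.sites[chrom]
    length = site_index.chrom_lengths[chrom]
    w = s + enz.watson_cut_offset
    c = s + enz.crick_cut_offset
    right_edge = np.empty_like(w)
    right_edge[:-1] = c[1:]
    right_edge[-1] = length
    left_edge = np.empty_like(c)
    left_edge[1:] = w[:-1]
    left_edge[0] = 0
    return w, right_edge, left_edge, c


def simulate_molecules(
    genome: SyntheticGenome,
    truth: CopyNumberTruth,
    enzyme: RestrictionEnzyme,
    lambda_per_copy: float,
    seed: int = 0,
    min_fragment: int = 20,
    site_index: SiteIndex | None = None,
) -> SimulationTruth:
    """Draw per-(site, strand, sample) molecule counts.

    Counts are independent Poisson with mean ``lambda_per_copy * copy``
    where *copy* is the truth copy number at the recognition start; both
    flanks of every cut are independent sources, giving the even
    Watson/Crick partitioning expected of the protocol.  Sources whose
    restriction fragment is shorter than *min_fragment* are suppressed
    (size selection).
    """
    if lambda_per_copy <= 0:
        raise ValueError("lambda_per_copy must be positive")
    if site_index is None:
        site_index = SiteIndex.from_sequences(
            genome.sequences, enzyme, genome_id=genome.genome_id
        )
    if site_index.n_sites() == 0:
        raise ValueError(
            "no recognition sites in genome; use a longer genome or a 4-cutter"
        )
    rng = np.random.default_rng(seed)
    parts = []
    for sample in truth.samples:
        for chrom in genome.sequences:
            s = site_index.sites[chrom]
            if len(s) == 0:
                continue
            w, right_edge, left_edge, c = _fragment_spans(site_index, chrom)
            ok_watson = (right_edge - w) >= min_fragment
            ok_crick = (c - left_edge) >= min_fragment
            copies = truth.copy_at(sample, chrom, s)
            lam = lambda_per_copy * copies
            for strand, ok in (("+", ok_watson), ("-", ok_crick)):
                counts = rng.poisson(np.where(ok, lam, 0.0))
                nz = counts > 0
                if nz.any():
                    parts.append(
                        pd.DataFrame(
                            {
                                "sample": sample,
                                "chrom": chrom,
                                "site": s[nz],
                                "strand": strand,
                                "count": counts[nz],
                            }
                        )
                    )
    if parts:
        molecules = pd.concat(parts, ignore_index=True)
    else:
        molecules = pd.DataFrame(columns=["sample", "chrom", "site", "strand", "count"])
    return SimulationTruth(
        genome=genome,
        enzyme=enzyme,
        truth=truth,
        molecules=molecules,
        site_index=site_index,
        lambda_per_copy=lambda_per_copy,
        min_fragment=min_fragment,
    )


def _umi_strings(codes: np.ndarray) -> list[str]:
    """Decode integer UMI codes (< 4^8) to 8-mers, base-4 big-endian."""
    shifts = np.arange(2 * (UMI_LEN - 1), -1, -2)
    digits = (codes[:, None] >> shifts) & 3
    chars = _BASES[digits]  # (n, 8) bytes
    return [b.decode() for b in chars.view(f"S{UMI_LEN}").ravel()]


def _validate_barcodes(barcode_map: Mapping[str, str]) -> None:
    seen: dict[str, str] = {}
    for sample, bc in barcode_map.items():
        if len(bc) != BARCODE_LEN:
            raise ValueError(f"barcode for {sample!r} is not {BARCODE_LEN} nt: {bc!r}")
        if bc in seen:
            raise ValueError(f"duplicate barcode {bc} ({seen[bc]!r}, {sample!r})")
        seen[bc] = sample
    bcs = list(barcode_map.values())
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            d = sum(a != b for a, b in zip(bcs[i], bcs[j]))
            if d < 5:
                warnings.warn(
                    f"barcodes {bcs[i]} and {bcs[j]} are only Hamming distance {d} "
                    "apart; 2-mismatch demultiplexing may be ambiguous",
                    stacklevel=2,
                )


def simulate_reads(
    sim: SimulationTruth,
    barcode_map: Mapping[str, str],
    out_fastq: str | IO[str],
    read_len: int = 75,
    pcr_dup_mean: float = 0.0,
    subst_error_rate: float = 0.0,
    seed: int = 0,
    dup_model: str = "poisson",
) -> pd.DataFrame:
    """Emit FASTQ reads for every truth molecule; return the provenance table.

    Each molecule draws a fresh UMI (uniform over 4^8, collisions allowed)
    and ``1 + D`` reads, D from the duplicate-count model (``poisson``:
    D ~ Poisson(pcr_dup_mean); ``geometric``: D ~ Geom with the same mean).
    Duplicates inherit the molecule's UMI; substitution errors are then
    applied i.i.d. per base over the *whole* read, prefix included, so
    duplicate UMIs/barcodes can diverge — which is what directional
    deduplication has to repair.  Qualities are constant 'I'.

    Deterministic given *seed* (byte-identical FASTQ).  Provenance columns:
    read_id, sample, chrom, site, strand, molecule_id, umi, n_errors.
    """
    _validate_barcodes(barcode_map)
    if dup_model not in ("poisson", "geometric"):
        raise ValueError(f"unknown dup_model {dup_model!r}")
    max_insert = read_len - PREFIX_LEN
    if max_insert < sim.min_fragment:
        raise ValueError(
            f"read_len {read_len} leaves insert < min_fragment ({sim.min_fragment})"
        )
    rng = np.random.default_rng(seed)
    mol = sim.molecules
    counts = mol["count"].to_numpy()
    n_mol = int(counts.sum())
    row_of_mol = np.repeat(np.arange(len(mol)), counts)

    umi_codes = rng.integers(0, 4**UMI_LEN, size=n_mol)
    umis = _umi_strings(umi_codes)
    if dup_model == "poisson":
        dups = rng.poisson(pcr_dup_mean, size=n_mol)
    else:  # geometric with mean pcr_dup_mean: D = G - 1, G ~ Geom(p)
        p = 1.0 / (1.0 + pcr_dup_mean)
        dups = rng.geometric(p, size=n_mol) - 1
    reads_per_mol = 1 + dups

    # Pre-extract insert sequences once per (row of molecule table).
    inserts_by_row: list[str] = []
    span_cache: dict[str, tuple[np.ndarray, ...]] = {}
    site_pos_cache: dict[str, np.ndarray] = {}
    for rec in mol.itertuples(index=False):
        chrom = rec.chrom
        if chrom not in span_cache:
            span_cache[chrom] = _fragment_spans(sim.site_index, chrom)
            site_pos_cache[chrom] = sim.site_index.sites[chrom]
        w, right_edge, left_edge, c = span_cache[chrom]
        i = int(np.searchsorted(site_pos_cache[chrom], rec.site))
        seq = sim.genome.sequences[chrom]
        if rec.strand == "+":
            start = int(w[i])
            end = min(start + max_insert, int(right_edge[i]))
            inserts_by_row.append(seq[start:end])
        else:
            end = int(c[i])
            start = max(end - max_insert, int(left_edge[i]))
            inserts_by_row.append(reverse_complement(seq[start:end]))

    barcode_of_row = [barcode_map[s] for s in mol["sample"]]

    # Expand molecules to reads and apply substitution errors.
    mol_of_read = np.repeat(np.arange(n_mol), reads_per_mol)
    n_reads = len(mol_of_read)
    read_lens = np.fromiter(
        (PREFIX_LEN + len(inserts_by_row[r]) for r in row_of_mol),
        dtype=np.int64,
        count=n_mol,
    )[mol_of_read]
    n_err = (
        rng.binomial(read_lens, subst_error_rate)
        if subst_error_rate > 0
        else np.zeros(n_reads, dtype=np.int64)
    )

    close_fh = False
    if isinstance(out_fastq, str):
        fh = open(out_fastq, "w")
        close_fh = True
    else:
        fh = out_fastq
    prov_rows: dict[str, list] = {
        "read_id": [],
        "sample": [],
        "chrom": [],
        "site": [],
        "strand": [],
        "molecule_id": [],
        "umi": [],
        "n_errors": [],
    }
    samples_arr = mol["sample"].to_numpy()
    chrom_arr = mol["chrom"].to_numpy()
    site_arr = mol["site"].to_numpy()
    strand_arr = mol["strand"].to_numpy()
    buf: list[str] = []
    try:
        for ridx in range(n_reads):
            m = mol_of_read[ridx]
            row = row_of_mol[m]
            read = umis[m] + barcode_of_row[row] + inserts_by_row[row]
            k = int(n_err[ridx])
            if k:
                pos = rng.choice(len(read), size=k, replace=False)
                chars = list(read)
                for p_ in pos:
                    cur = chars[p_]
                    alts = [b for b in "ACGT" if b != cur]
                    chars[p_] = alts[rng.integers(0, 3)]
                read = "".join(chars)
            name = f"sim_{ridx:08d}"
            buf.append(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")
            if len(buf) >= 20000:
                fh.write("".join(buf))
                buf.clear()
            prov_rows["read_id"].append(name)
            prov_rows["sample"].append(samples_arr[row])
            prov_rows["chrom"].append(chrom_arr[row])
            prov_rows["site"].append(site_arr[row])
            prov_rows["strand"].append(strand_arr[row])
            prov_rows["molecule_id"].append(int(m))
            prov_rows["umi"].append(umis[m])
            prov_rows["n_errors"].append(k)
        fh.write("".join(buf))
    finally:
        if close_fh:
            fh.close()
    return pd.DataFrame(prov_rows)
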