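"""FASTQ processing: prefix parsing, demultiplexing, site anchoring,
filtering, UMI deduplication, and library QC statistics.

The pipeline mirrors the processing a restriction-site-anchored library
goes through: every read is ``UMI(8) + sample barcode(8) + genomic
insert``.  Reads are parsed, assigned to samples allowing at most two
barcode mismatches, located on the genome, anchored to the strand-specific
cut coordinate of their nearest recognition site, filtered (mapping
quality >= 30, sex chromosomes excluded), and collapsed to single
molecules per (chromosome, site, strand, sample) group by UMI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .anchor import ExactMatchIndex
from .enzymes import SiteIndex, reverse_complement
from .simulate import BARCODE_LEN, PREFIX_LEN, UMI_LEN

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

_UMI_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def hamming(a: str, b: str) -> int:
    """Hamming distance; any differing character (including N) counts."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeWhitelist:
    """Sample-name → 8-nt barcode map with pairwise-distance validation."""

    barcodes: dict[str, str]
    min_pairwise_distance: int = 5

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sample, bc in self.barcodes.items():
            bc = bc.upper()
            self.barcodes[sample] = bc
            if len(bc) != BARCODE_LEN:
                raise ValueError(f"barcode for {sample!r} not {BARCODE_LEN} nt: {bc!r}")
            if bc in seen:
                raise ValueError(f"barcode {bc} duplicated ({seen[bc]!r}, {sample!r})")
            seen[bc] = sample
        items = list(self.barcodes.values())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                d = hamming(items[i], items[j])
                if d < self.min_pairwise_distance:
                    warnings.warn(
                        f"barcodes {items[i]}/{items[j]} at Hamming distance {d} "
                        f"(< {self.min_pairwise_distance}); demultiplexing with two "
                        "allowed mismatches may be ambiguous",
                        stacklevel=2,
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "BarcodeWhitelist":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"])
        return cls(dict(zip(df["sample"].astype(str), df["barcode"].astype(str))))

    def items(self):
        return self.barcodes.items()


@dataclass
class ParsedRead:
    umi: str
    barcode: str
    sample: str | None
    insert: str


def parse_prefix(read: str, min_insert: int = 20) -> ParsedRead | str:
    """Split a read into UMI / raw barcode / insert, or a rejection reason.

    The first 8 nt are the UMI, the next 8 the sample barcode, the rest the
    genomic insert.  Reads shorter than ``16 + min_insert`` are rejected
    with reason ``"too_short"`` (a tallied outcome, not an error).
    """
    if len(read) < PREFIX_LEN + min_insert:
        return "too_short"
    return ParsedRead(read[:UMI_LEN], read[UMI_LEN:PREFIX_LEN], None, read[PREFIX_LEN:])


def assign_barcode(
    raw: str, whitelist: BarcodeWhitelist | Mapping[str, str], max_mismatch: int = 2
) -> str | None:
    """Sample whose barcode is uniquely nearest within ``max_mismatch``.

    Returns ``None`` when no barcode is close enough or when two barcodes
    tie at the minimal distance (ambiguous assignments are rejected rather
    than guessed, to avoid sample bleed).  N counts as a mismatch.
    """
    items = whitelist.items() if hasattr(whitelist, "items") else whitelist
    best: str | None = None
    best_d = max_mismatch + 1
    tied = False
    for sample, bc in items:
        d = hamming(raw, bc)
        if d < best_d:
            best, best_d, tied = sample, d, False
        elif d == best_d:
            tied = True
    if best_d > max_mismatch or tied:
        return None
    return best


# ---------------------------------------------------------------------------
# anchoring


def anchor_reads(
    inserts: Sequence[str],
    match_index: ExactMatchIndex,
    site_index: SiteIndex,
    tolerance: int = 3,
    seed_offsets: tuple[int | None, ...] = (0, 10, 20, 30, None),
    max_hits_per_seed: int = 16,
) -> pd.DataFrame:
    """Locate inserts on the genome and anchor each to its nearest cut.

    Each insert is looked up by exact k-mer seeds at several offsets
    (``None`` = the tail k-mer; both orientations) and verified
    full-length, tolerating scattered substitutions.  A unique verified location is compared with the
    strand-specific cut coordinates: Watson-strand matches anchor by their
    genomic start, Crick-strand matches by their genomic end; within
    ``tolerance`` bp of a cut the read is ``anchored`` to that recognition
    site, otherwise it is ``offsite``.  Inserts verified at more than one
    location are ``multimap`` (discarded downstream); inserts found nowhere
    are ``offsite``.

    Returns a DataFrame with columns status, chrom, strand, cut_pos, site,
    site_dist, n_mismatch, aligned_len, mapq (60 for unique matches).
    """
    k = match_index.k
    n = len(inserts)
    watson_cuts = {c: site_index.watson_cuts(c) for c in site_index.chroms}
    crick_cuts = {c: site_index.crick_cuts(c) for c in site_index.chroms}

    status = np.empty(n, dtype=object)
    chrom_out = np.empty(n, dtype=object)
    strand_out = np.empty(n, dtype=object)
    cut_pos = np.full(n, -1, dtype=np.int64)
    site_out = np.full(n, -1, dtype=np.int64)
    site_dist = np.full(n, -1, dtype=np.int64)
    n_mismatch = np.zeros(n, dtype=np.int64)
    aligned_len = np.zeros(n, dtype=np.int64)

    chunk = 200_000
    offsets = match_index.offsets
    concat = match_index.concat
    chrom_names = match_index.chroms
    sentinel = np.iinfo(np.uint64).max

    for c0 in range(0, n, chunk):
        batch = [s.upper() for s in inserts[c0 : c0 + chunk]]
        rc = [reverse_complement(s) for s in batch]
        ranges = []  # (orient, off, lo[], hi[])
        for orient, queries in (("+", batch), ("-", rc)):
            for off in seed_offsets:
                codes = match_index.seed_codes(queries, off)
                lo, hi = match_index.lookup(codes)
                lo[codes == sentinel] = 0
                hi[codes == sentinel] = 0
                ranges.append((orient, off, lo, hi))
        for i, ins in enumerate(batch):
            L = len(ins)
            gi = c0 + i
            aligned_len[gi] = L
            max_mm = max(2, L // 10)
            cands: set[tuple[int, str]] = set()
            for orient, off, lo, hi in ranges:
                w = int(hi[i] - lo[i])
                if w == 0:
                    continue
                if w > max_hits_per_seed:
                    w = max_hits_per_seed + 1
                off_i = len(ins) - k if off is None else off
                for p in match_index.sorted_pos[lo[i] : lo[i] + w]:
                    cands.add((int(p) - off_i, orient))
            accepted: list[tuple[int, str, int]] = []
            for g, orient in cands:
                if g < 0:
                    continue
                ci = int(np.searchsorted(offsets, g, side="right") - 1)
                if g < offsets[ci] or g + L > offsets[ci + 1]:
                    continue
                q = ins if orient == "+" else rc[i]
                ref = concat[g : g + L]
                if q == ref:
                    mm = 0
                else:
                    a = np.frombuffer(q.encode(), dtype=np.uint8)
                    b = np.frombuffer(ref.encode(), dtype=np.uint8)
                    mm = int(np.count_nonzero(a != b))
                if mm <= max_mm:
                    accepted.append((g, orient, mm))
                    if len(accepted) > 1:
                        break
            if not accepted:
                status[gi] = "offsite"
                chrom_out[gi] = None
                strand_out[gi] = None
                continue
            if len(accepted) > 1:
                status[gi] = "multimap"
                chrom_out[gi] = None
                strand_out[gi] = None
                continue
            g, orient, mm = accepted[0]
            ci = int(np.searchsorted(offsets, g, side="right") - 1)
            chrom = chrom_names[ci]
            local = g - int(offsets[ci])
            if orient == "+":
                cut = local
                cuts = watson_cuts.get(chrom)
            else:
                cut = local + L
                cuts = crick_cuts.get(chrom)
            chrom_out[gi] = chrom
            strand_out[gi] = orient
            cut_pos[gi] = cut
            n_mismatch[gi] = mm
            if cuts is None or len(cuts) == 0:
                status[gi] = "offsite"
                continue
            j = int(np.searchsorted(cuts, cut))
            best_d, best_cut = None, None
            for jj in (j - 1, j):
                if 0 <= jj < len(cuts):
                    d = abs(cut - int(cuts[jj]))
                    if best_d is None or d < best_d:
                        best_d, best_cut = d, int(cuts[jj])
            if best_d is not None and best_d <= tolerance:
                status[gi] = "anchored"
                off_enz = (
                    site_index.enzyme.watson_cut_offset
                    if orient == "+"
                    else site_index.enzyme.crick_cut_offset
                )
                site_out[gi] = best_cut - off_enz
                site_dist[gi] = best_d
            else:
                status[gi] = "offsite"
                site_dist[gi] = -1 if best_d is None else best_d
    return pd.DataFrame(
        {
            "status": status,
            "chrom": chrom_out,
            "strand": strand_out,
            "cut_pos": cut_pos,
            "site": site_out,
            "site_dist": site_dist,
            "n_mismatch": n_mismatch,
            "aligned_len": aligned_len,
            "mapq": np.where(status == "anchored", 60, np.where(status == "multimap", 0, 60)),
        }
    )


def filter_reads(
    reads: pd.DataFrame, mapq_min: int = 30, drop_sex_chroms: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop reads below the mapping-quality cutoff (>= ``mapq_min`` kept,
    boundary inclusive) and reads on sex chromosomes; tally by reason."""
    tally = {"input": len(reads), "low_mapq": 0, "sex_chrom": 0, "kept": 0}
    keep = reads["mapq"] >= mapq_min
    tally["low_mapq"] = int((~keep).sum())
    if drop_sex_chroms:
        on_sex = reads["chrom"].isin(SEX_CHROMS)
        tally["sex_chrom"] = int((keep & on_sex).sum())
        keep &= ~on_sex
    out = reads[keep].reset_index(drop=True)
    tally["kept"] = len(out)
    return out, tally


# ---------------------------------------------------------------------------
# UMI deduplication


def encode_umi(umi: str) -> int:
    code = 0
    for ch in umi:
        code = (code << 2) | _UMI_CODE.get(ch, 0)  # N folded onto A
    return code


def _directional_component_count(counts: dict[int, int], umi_len: int) -> int:
    """Connected components of the directional UMI graph.

    Edge u->v when Hamming(u, v) == 1 and count(u) >= 2*count(v) - 1;
    components are collapsed onto their highest-count node, so the number
    of distinct molecules is the number of components.
    """
    parent = {u: u for u in counts}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, cu in counts.items():
        for pos in range(umi_len):
            shift = 2 * pos
            base = (u >> shift) & 3
            for alt in range(4):
                if alt == base:
                    continue
                v = (u & ~(3 << shift)) | (alt << shift)
                cv = counts.get(v)
                if cv is not None and cu >= 2 * cv - 1:
                    ru, rv = find(u), find(v)
                    if ru != rv:
                        parent[ru] = rv
    return len({find(u) for u in counts})


def dedup_umis(
    reads: pd.DataFrame, method: str = "directional", umi_len: int = UMI_LEN
) -> pd.DataFrame:
    """Collapse reads to molecules per (sample, chrom, site, strand) group.

    ``exact`` counts distinct UMIs; ``directional`` additionally merges
    UMIs one substitution apart when the larger count is at least
    ``2 * smaller - 1`` (the standard network collapse for PCR/sequencing
    UMI errors).  Input needs columns sample, chrom, site, strand, umi.

    Returns the molecule table: sample, chrom, site, strand, n_molecules,
    n_reads.
    """
    if method not in ("exact", "directional"):
        raise ValueError(f"unknown dedup method {method!r}")
    if len(reads) == 0:
        return pd.DataFrame(
            columns=["sample", "chrom", "site", "strand", "n_molecules", "n_reads"]
        )
    key_str = (
        reads["sample"].astype(str)
        + "\x00" + reads["chrom"].astype(str)
        + "\x00" + reads["site"].astype(str)
        + "\x00" + reads["strand"].astype(str)
    )
    key, _ = pd.factorize(key_str.to_numpy())
    umi_codes = np.fromiter(
        (encode_umi(u) for u in reads["umi"]), dtype=np.int64, count=len(reads)
    )
    order = np.argsort(key, kind="stable")
    key_sorted = key[order]
    codes_sorted = umi_codes[order]
    boundaries = np.nonzero(np.diff(key_sorted))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(key_sorted)]])
    samples_arr = reads["sample"].to_numpy()
    chrom_arr = reads["chrom"].to_numpy()
    site_arr = reads["site"].to_numpy()
    strand_arr = reads["strand"].to_numpy()
    rows = []
    for s, e in zip(starts, ends):
        group = codes_sorted[s:e]
        counts: dict[int, int] = {}
        for c in group:
            counts[int(c)] = counts.get(int(c), 0) + 1
        if method == "exact":
            n_mol = len(counts)
        else:
            n_mol = _directional_component_count(counts, umi_len)
        first = order[s]
        rows.append(
            (
                samples_arr[first], chrom_arr[first], int(site_arr[first]),
                strand_arr[first], n_mol, e - s,
            )
        )
    out = pd.DataFrame(
        rows, columns=["sample", "chrom", "site", "strand", "n_molecules", "n_reads"]
    )
    return out.sort_values(["sample", "chrom", "site", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# QC statistics


def site_overlap_fraction(n_offsite: int, n_anchored: int) -> float:
    """Percentage of located reads not anchored at a restriction site."""
    total = n_offsite + n_anchored
    if total == 0:
        raise ValueError("no aligned reads; off-site fraction undefined")
    return 100.0 * n_offsite / total


def error_rate(
    aligned_bases: int, n_deletions: int, n_insertions: int, n_mismatches: int
) -> float:
    """Sequencing error rate: 100 x (D + I + mismatches) / aligned bases."""
    if aligned_bases <= 0:
        raise ValueError("error rate undefined without aligned bases")
    return 100.0 * (n_deletions + n_insertions + n_mismatches) / aligned_bases


def umi_base_composition(umis: Iterable[str], umi_len: int = UMI_LEN) -> pd.DataFrame:
    """Per-position base fractions of a UMI collection (rows sum to 1)."""
    counts = np.zeros((umi_len, 4), dtype=np.int64)
    n = 0
    cols = "ACGT"
    for u in umis:
        n += 1
        for i, ch in enumerate(u[:umi_len]):
            j = _UMI_CODE.get(ch)
            if j is not None and ch in _UMI_CODE:
                counts[i, j] += 1
    if n == 0:
        raise ValueError("empty UMI collection")
    frac = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, columns=list(cols), index=range(umi_len))


def strand_partition(molecules: pd.DataFrame) -> float:
    """Fraction of molecules on the Watson (+) strand."""
    if len(molecules) == 0:
        raise ValueError("empty molecule table")
    total = molecules["n_molecules"].sum()
    watson = molecules.loc[molecules["strand"] == "+", "n_molecules"].sum()
    return float(watson / total)


def downsample(records: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Keep each record independently with probability *fraction*."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return records.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(records)) < fraction
    return records[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# SAM/BAM ingestion (externally aligned real data)


def ingest_sam(
    path: str,
    site_index: SiteIndex,
    sample: str,
    tolerance: int = 3,
    umi_from_name: bool = True,
) -> pd.DataFrame:
    """Read an aligned SAM/BAM into the anchored-read table.

    The aligner's coordinates and MAPQ are trusted; the 5' coordinate
    (reference start for forward reads, reference end for reverse reads)
    is compared with the strand-specific cut coordinates exactly as for
    simulated reads.  The UMI is taken from the last ``_``-separated token
    of the read name (the common post-extraction convention).  Alignment
    error operations are summarised from CIGAR + NM for error-rate
    estimation.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chrom = aln.reference_name
            strand = "-" if aln.is_reverse else "+"
            cut = aln.reference_end if aln.is_reverse else aln.reference_start
            cig = aln.cigartuples or []
            aligned = sum(l for op, l in cig if op in (0, 7, 8))
            ins = sum(l for op, l in cig if op == 1)
            dels = sum(l for op, l in cig if op == 2)
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            mismatches = max(0, nm - ins - dels)
            umi = aln.query_name.rsplit("_", 1)[-1] if umi_from_name else ""
            cuts = (
                site_index.watson_cuts(chrom)
                if strand == "+"
                else site_index.crick_cuts(chrom)
            ) if chrom in site_index.sites else np.array([], dtype=np.int64)
            status, site, dist = "offsite", -1, -1
            if len(cuts):
                j = int(np.searchsorted(cuts, cut))
                best = None
                for jj in (j - 1, j):
                    if 0 <= jj < len(cuts):
                        d = abs(cut - int(cuts[jj]))
                        if best is None or d < best[0]:
                            best = (d, int(cuts[jj]))
                if best and best[0] <= tolerance:
                    off = (
                        site_index.enzyme.watson_cut_offset
                        if strand == "+"
                        else site_index.enzyme.crick_cut_offset
                    )
                    status, site, dist = "anchored", best[1] - off, best[0]
                elif best:
                    dist = best[0]
            rows.append(
                (
                    status, chrom, strand, int(cut), site, dist,
                    mismatches, aligned, ins, dels, aln.mapping_quality, umi, sample,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "status", "chrom", "strand", "cut_pos", "site", "site_dist",
            "n_mismatch", "aligned_len", "n_ins", "n_del", "mapq", "umi", "sample",
        ],
    )


# ---------------------------------------------------------------------------
# end-to-end FASTQ processing


@dataclass
class ProcessResult:
    molecules: pd.DataFrame
    qc: dict
    reads: pd.DataFrame = field(repr=False, default=None)


def process_fastq(
    fastq: str,
    genome_sequences: Mapping[str, str],
    whitelist: BarcodeWhitelist,
    site_index: SiteIndex,
    max_mismatch: int = 2,
    mapq_min: int = 30,
    drop_sex_chroms: bool = True,
    dedup_method: str = "directional",
    tolerance: int = 3,
    min_insert: int = 20,
    match_index: ExactMatchIndex | None = None,
    keep_reads: bool = False,
) -> ProcessResult:
    """Run the full pipeline on one FASTQ, returning molecules + QC.

    QC dict keys: read tallies (total/parsed/too_short/assigned/unassigned),
    anchoring tallies, off-site percentage, error-rate percentage, Watson
    fraction, and the 8x4 UMI base-composition table.
    """
    import pysam

    umis: list[str] = []
    samples: list[str] = []
    inserts: list[str] = []
    tally = {"total": 0, "parsed": 0, "too_short": 0, "assigned": 0, "unassigned": 0}
    exact = {bc: s for s, bc in whitelist.items()}
    with pysam.FastxFile(fastq) as fh:
        for entry in fh:
            seq = entry.sequence
            tally["total"] += 1
            if len(seq) < PREFIX_LEN + min_insert:
                tally["too_short"] += 1
                continue
            tally["parsed"] += 1
            bc = seq[UMI_LEN:PREFIX_LEN]
            sample = exact.get(bc)
            if sample is None:
                sample = assign_barcode(bc, whitelist, max_mismatch)
            if sample is None:
                tally["unassigned"] += 1
                continue
            tally["assigned"] += 1
            umis.append(seq[:UMI_LEN])
            samples.append(sample)
            inserts.append(seq[PREFIX_LEN:])

    if match_index is None:
        match_index = ExactMatchIndex(dict(genome_sequences))
    anchored = anchor_reads(inserts, match_index, site_index, tolerance=tolerance)
    anchored["umi"] = umis
    anchored["sample"] = samples

    n_anchored = int((anchored["status"] == "anchored").sum())
    n_offsite = int((anchored["status"] == "offsite").sum())
    n_multimap = int((anchored["status"] == "multimap").sum())
    tally.update(anchored=n_anchored, offsite=n_offsite, multimap=n_multimap)

    usable = anchored[anchored["status"] == "anchored"]
    usable, filter_tally = filter_reads(usable, mapq_min, drop_sex_chroms)
    molecules = dedup_umis(usable, method=dedup_method)

    qc: dict = {"tally": tally, "filter": filter_tally}
    if n_anchored + n_offsite:
        qc["offsite_pct"] = site_overlap_fraction(n_offsite, n_anchored)
    aligned_bases = int(usable["aligned_len"].sum())
    if aligned_bases:
        qc["error_rate_pct"] = error_rate(
            aligned_bases, 0, 0, int(usable["n_mismatch"].sum())
        )
    if len(usable):
        qc["umi_composition"] = umi_base_composition(usable["umi"])
    if len(molecules):
        qc["watson_fraction"] = strand_partition(molecules)
    return ProcessResult(molecules, qc, usable if keep_reads else None)
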