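"""Read processing: parsing, demultiplexing, anchoring, dedup, QC."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutkit.enzymes import NLAIII
from cutkit.readproc import (
    BarcodeWhitelist,
    ParsedRead,
    anchor_reads,
    assign_barcode,
    dedup_umis,
    downsample,
    error_rate,
    filter_reads,
    hamming,
    ingest_sam,
    parse_prefix,
    site_overlap_fraction,
    strand_partition,
    umi_base_composition,
)
from cutkit.simulate import CopyNumberTruth, simulate_molecules, simulate_reads

WL = BarcodeWhitelist({"A": "AAAAAAAA", "C": "CCCCCCCC", "G": "GGGGTTTT"})


# ---------------------------------------------------------------- parsing

def test_parse_prefix_splits_umi_barcode_insert():
    p = parse_prefix("AAAAAAAACCCCCCCCACGTACGT", min_insert=8)
    assert isinstance(p, ParsedRead)
    assert (p.umi, p.barcode, p.insert) == ("AAAAAAAA", "CCCCCCCC", "ACGTACGT")


def test_parse_prefix_rejects_short_reads():
    assert parse_prefix("ACGTACGTACGTACG", min_insert=0) == "too_short"
    assert parse_prefix("A" * 35, min_insert=20) == "too_short"
    assert isinstance(parse_prefix("A" * 36, min_insert=20), ParsedRead)


# ---------------------------------------------------------- demultiplexing

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("AAAAAATT", "A"),  # distance 2
        ("AAAAATTT", None),  # distance 3
        ("CCCCCCCC", "C"),
        ("NNAAAAAA", "A"),  # N counts as mismatch, still within 2
        ("NNNAAAAA", None),
    ],
)
def test_assign_barcode_examples(raw, expected):
    assert assign_barcode(raw, WL) == expected


@settings(derandomize=True, deadline=None, max_examples=300)
@given(st.text(alphabet="ACGTN", min_size=8, max_size=8))
def test_assign_barcode_matches_exhaustive_search(raw):
    dists = {s: hamming(raw, bc) for s, bc in WL.items()}
    dmin = min(dists.values())
    winners = [s for s, d in dists.items() if d == dmin]
    expected = winners[0] if dmin <= 2 and len(winners) == 1 else None
    assert assign_barcode(raw, WL) == expected


def test_assign_barcode_tie_is_unassigned():
    wl = BarcodeWhitelist(
        {"X": "AAAAACCC", "Y": "AAAAAGGG"}, min_pairwise_distance=3
    )
    # equidistant (2 mismatches to each) -> ambiguous
    assert assign_barcode("AAAAACGA", wl) is None


def test_whitelist_validation():
    with pytest.raises(ValueError, match="duplicated"):
        BarcodeWhitelist({"a": "AAAAAAAA", "b": "AAAAAAAA"})
    with pytest.raises(ValueError, match="not 8 nt"):
        BarcodeWhitelist({"a": "AAAA"})
    with pytest.warns(UserWarning, match="Hamming"):
        BarcodeWhitelist({"a": "AAAAAAAA", "b": "AAAAAAAC"})


# -------------------------------------------------------------- anchoring

def _simulated_reads(small_genome, nla_index, err=0.0, seed=5):
    truth = CopyNumberTruth.from_blocks(small_genome.lengths, ["S1"], [])
    sim = simulate_molecules(
        small_genome, truth, NLAIII, 1.0, seed=3, site_index=nla_index
    )
    buf = io.StringIO()
    prov = simulate_reads(
        sim, {"S1": "AAAAAAAA"}, buf, subst_error_rate=err, seed=seed
    )
    seqs = buf.getvalue().splitlines()[1::4]
    return sim, prov, seqs


def test_anchor_error_free_reads_exactly(small_genome, nla_index, match_index):
    sim, prov, seqs = _simulated_reads(small_genome, nla_index)
    inserts = [s[16:] for s in seqs]
    out = anchor_reads(inserts, match_index, nla_index)
    assert (out["status"] == "anchored").all()
    assert (out["site_dist"] == 0).all()
    assert out["site"].tolist() == prov["site"].tolist()
    assert out["strand"].tolist() == prov["strand"].tolist()


def test_anchor_foreign_insert_is_offsite(match_index, nla_index):
    out = anchor_reads(["T" * 40], match_index, nla_index)
    assert out["status"].iat[0] == "offsite"


def test_anchor_near_but_not_at_cut_is_offsite(small_genome, nla_index, match_index):
    # a genuine genomic window starting 10 bp after a cut: aligned, off-site
    seq = small_genome.sequences["chr1"]
    cut = int(nla_index.watson_cuts("chr1")[5])
    out = anchor_reads([seq[cut + 10 : cut + 50]], match_index, nla_index)
    assert out["status"].iat[0] == "offsite"
    assert out["site_dist"].iat[0] == 10


def test_anchor_site_matches_brute_force_nearest(small_genome, nla_index, match_index, rng):
    """Random on-genome windows anchor to the brute-force nearest cut."""
    seq = small_genome.sequences["chr1"]
    wc = nla_index.watson_cuts("chr1")
    starts = rng.integers(0, len(seq) - 60, size=100)
    out = anchor_reads([seq[s : s + 50] for s in starts], match_index, nla_index)
    for s, row in zip(starts, out.itertuples(index=False)):
        if row.status != "anchored":
            continue
        nearest = wc[np.abs(wc - s).argmin()]
        assert abs(int(nearest) - s) <= 3
        assert row.site == nearest - NLAIII.watson_cut_offset


# -------------------------------------------------------------- filtering

def test_filter_mapq_boundary_inclusive():
    df = pd.DataFrame({"mapq": [29, 30, 31], "chrom": ["chr1"] * 3})
    kept, tally = filter_reads(df, mapq_min=30)
    assert kept["mapq"].tolist() == [30, 31]
    assert tally["low_mapq"] == 1


def test_filter_drops_sex_chromosomes():
    df = pd.DataFrame({"mapq": [60] * 3, "chrom": ["chr1", "chrX", "Y"]})
    kept, tally = filter_reads(df)
    assert kept["chrom"].tolist() == ["chr1"]
    assert tally["sex_chrom"] == 2
    kept2, _ = filter_reads(df, drop_sex_chroms=False)
    assert len(kept2) == 3


# ------------------------------------------------------------------ dedup

def _group_df(umis, **key):
    base = {"sample": "S", "chrom": "chr1", "site": 100, "strand": "+"}
    base.update(key)
    return pd.DataFrame([{**base, "umi": u} for u in umis])


def test_dedup_identical_umis_collapse():
    out = dedup_umis(_group_df(["ACGTACGT"] * 3), method="exact")
    assert out["n_molecules"].iat[0] == 1 and out["n_reads"].iat[0] == 3


def test_dedup_directional_merges_error_umi():
    umis = ["AAAAAAAA"] * 10 + ["AAAAAAAT"]
    assert dedup_umis(_group_df(umis), method="directional")["n_molecules"].iat[0] == 1
    assert dedup_umis(_group_df(umis), method="exact")["n_molecules"].iat[0] == 2


def test_dedup_directional_respects_count_rule():
    # counts 1 and 1: 1 >= 2*1-1 -> merge; counts 1 and 3: 1 < 2*3-1 and
    # 3 >= 2*1-1 -> still merges (edge from the larger node)
    assert (
        dedup_umis(_group_df(["AAAAAAAA", "AAAAAAAT"]), "directional")["n_molecules"].iat[0]
        == 1
    )
    # two far-apart UMIs never merge
    assert (
        dedup_umis(_group_df(["AAAAAAAA", "TTTTTTTT"]), "directional")["n_molecules"].iat[0]
        == 2
    )


def test_dedup_unknown_method():
    with pytest.raises(ValueError, match="unknown dedup"):
        dedup_umis(_group_df(["AAAAAAAA"]), method="cluster")


def networkx_directional_count(umis: list[str]) -> int:
    """Independent oracle: explicit graph build + component count."""
    import networkx as nx
    from collections import Counter

    counts = Counter(umis)
    g = nx.Graph()
    g.add_nodes_from(counts)
    for u, v in itertools.combinations(counts, 2):
        if hamming(u, v) == 1 and (
            counts[u] >= 2 * counts[v] - 1 or counts[v] >= 2 * counts[u] - 1
        ):
            g.add_edge(u, v)
    return nx.number_connected_components(g)


def test_dedup_directional_matches_graph_oracle(rng):
    bases = np.array(list("ACGT"))
    for _ in range(200):
        n = rng.integers(1, 20)
        # short random UMI space to force collisions and near-misses
        umis = ["".join(rng.choice(bases, size=4)) + "AAAA" for _ in range(n)]
        got = dedup_umis(_group_df(umis), "directional")["n_molecules"].iat[0]
        assert got == networkx_directional_count(umis)
        exact = dedup_umis(_group_df(umis), "exact")["n_molecules"].iat[0]
        assert exact == len(set(umis))
        assert exact >= got


def test_dedup_groups_are_independent():
    df = pd.concat(
        [
            _group_df(["AAAAAAAA", "AAAAAAAT"], site=100),
            _group_df(["AAAAAAAA"], site=200),
            _group_df(["AAAAAAAA"], strand="-"),
            _group_df(["AAAAAAAA"], sample="S2"),
        ]
    )
    out = dedup_umis(df, "directional")
    assert len(out) == 4 and out["n_molecules"].sum() == 4


# --------------------------------------------------------------------- QC

def test_error_rate_formula():
    assert error_rate(100, 0, 1, 1) == pytest.approx(2.0)
    assert error_rate(100, 0, 0, 0) == 0.0
    with pytest.raises(ValueError):
        error_rate(0, 0, 0, 0)


def test_site_overlap_fraction():
    assert site_overlap_fraction(2, 198) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        site_overlap_fraction(0, 0)


def test_umi_base_composition():
    comp = umi_base_composition(["AAAAAAAA"] * 5)
    assert (comp["A"] == 1.0).all()
    assert np.allclose(comp.sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        umi_base_composition([])


def test_strand_partition():
    mol = pd.DataFrame({"strand": ["+", "-"], "n_molecules": [3, 1]})
    assert strand_partition(mol) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        strand_partition(mol.iloc[:0])


def test_downsample_properties(rng):
    df = pd.DataFrame({"x": np.arange(10_000)})
    assert len(downsample(df, 1.0, seed=1)) == 10_000
    a = downsample(df, 0.5, seed=3)
    b = downsample(df, 0.5, seed=3)
    assert a["x"].tolist() == b["x"].tolist()  # same seed, same subset
    sd = np.sqrt(0.25 * 10_000)
    assert abs(len(a) - 5000) < 4 * sd
    with pytest.raises(ValueError):
        downsample(df, 0.0, seed=1)


# ------------------------------------------------------------- SAM ingest

SAM_TEXT = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chr1\tLN:100000
r1_ACGTACGT\t0\tchr1\t{fwd_pos}\t60\t40M\t*\t0\t0\t{seq40}\t*\tNM:i:1
r2_ACGTACGT\t16\tchr1\t{rev_pos}\t60\t40M\t*\t0\t0\t{seq40}\t*\tNM:i:0
r3_ACGTACGT\t0\tchr1\t500\t10\t40M\t*\t0\t0\t{seq40}\t*\tNM:i:0
"""


def test_ingest_sam_anchors_by_strand(tmp_path, small_genome, nla_index):
    wc = int(nla_index.watson_cuts("chr1")[10])
    cc = int(nla_index.crick_cuts("chr1")[10])
    sam = SAM_TEXT.format(
        fwd_pos=wc + 1,  # SAM is 1-based
        rev_pos=cc - 40 + 1,  # reverse read: 5' end = reference_end = cc
        seq40="A" * 40,
    )
    path = tmp_path / "toy.sam"
    path.write_text(sam)
    df = ingest_sam(str(path), nla_index, sample="S1")
    assert df["status"].tolist()[:2] == ["anchored", "anchored"]
    assert df["site"].tolist()[:2] == [int(nla_index.sites["chr1"][10])] * 2
    assert df["strand"].tolist() == ["+", "-", "+"]
    assert df["umi"].tolist() == ["ACGTACGT"] * 3
    assert df["n_mismatch"].tolist() == [1, 0, 0]
    kept, tally = filter_reads(df, mapq_min=30)
    assert len(kept) == 2 and tally["low_mapq"] == 1
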