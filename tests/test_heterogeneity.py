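"""Gene states, recurrence, complete-linkage clustering, burden tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cutkit.cnprofile import BinGrid, CopyNumberProfile
from cutkit.heterogeneity import (
    GeneStateMatrix,
    burden_comparison,
    cluster_samples,
    detectable_cna_fractions,
    gene_states,
    recurrence_ranking,
    replicate_concordance,
)
from cutkit.intervals import IntervalSet


def profile_from_calls(sample, calls, bin_size=100_000):
    calls = np.asarray(calls, dtype=np.int8)
    n = len(calls)
    g = BinGrid.from_chrom_lengths({"chr1": n * bin_size}, bin_size)
    segmented = calls.astype(float) * 0.5
    segments = []
    start = 0
    for i in range(1, n + 1):
        if i == n or calls[i] != calls[i - 1]:
            segments.append(("chr1", start, i, i - start, calls[start] * 0.5))
            start = i
    seg_df = pd.DataFrame(
        segments, columns=["chrom", "start_bin", "end_bin", "n_bins", "mean"]
    )
    return CopyNumberProfile(
        sample, g, np.ones(n), segmented.copy(), segmented, calls,
        np.zeros(n, bool), seg_df,
    )


# ------------------------------------------------------------- gene states

def test_gene_fully_inside_amplified_segment():
    p = profile_from_calls("S1", [0, 1, 1, 0])
    genes = IntervalSet.from_records([("chr1", 110_000, 190_000, "MYC")])
    m = gene_states({"S1": p}, genes)
    assert m.states.loc["MYC", "S1"] == 1


def test_gene_in_neutral_profile_is_neutral():
    p = profile_from_calls("S1", [0, 0, 0])
    genes = IntervalSet.from_records([("chr1", 0, 300_000, "TP53")])
    m = gene_states({"S1": p}, genes)
    assert m.states.loc["TP53", "S1"] == 0


def test_gene_largest_overlap_wins_and_nonneutral_breaks_ties():
    p = profile_from_calls("S1", [0, 0, -1, -1, -1])
    # 60% neutral, 40% deleted -> neutral wins on overlap
    genes = IntervalSet.from_records([("chr1", 50_000, 300_000, "G1")])
    m = gene_states({"S1": p}, genes)
    assert m.states.loc["G1", "S1"] == 0
    # exact 50/50 tie -> non-neutral precedence
    genes2 = IntervalSet.from_records([("chr1", 100_000, 300_000, "G2")])
    m2 = gene_states({"S1": p}, genes2)
    assert m2.states.loc["G2", "S1"] == -1


def test_gene_amp_del_tie_conflicts_to_zero():
    p = profile_from_calls("S1", [1, -1])
    genes = IntervalSet.from_records([("chr1", 50_000, 150_000, "G")])
    m = gene_states({"S1": p}, genes)
    assert m.states.loc["G", "S1"] == 0
    assert bool(m.conflicts.loc["G", "S1"])


def test_gene_outside_grid_is_missing():
    p = profile_from_calls("S1", [0, 0])
    genes = IntervalSet.from_records([("chr1", 900_000, 950_000, "FAR")])
    m = gene_states({"S1": p}, genes)
    assert np.isnan(m.states.loc["FAR", "S1"])


def test_gene_states_match_bin_overlap_oracle(rng):
    """Random genes: state equals the brute-force per-bin overlap tally
    grouped by segment."""
    calls = rng.choice([-1, 0, 1], size=30)
    p = profile_from_calls("S1", calls)
    bins = p.grid.bins
    records = []
    for k in range(40):
        start = int(rng.integers(0, 2_900_000))
        end = start + int(rng.integers(10_000, 400_000))
        records.append(("chr1", start, min(end, 3_000_000), f"g{k}"))
    genes = IntervalSet.from_records(records)
    m = gene_states({"S1": p}, genes)
    for iv in genes:
        overlaps: dict[tuple, float] = {}
        for srow in p.segments.itertuples(index=False):
            ov = 0
            for b in range(srow.start_bin, srow.end_bin):
                ov += max(
                    0,
                    min(bins["end"].iat[b], iv.end) - max(bins["start"].iat[b], iv.start),
                )
            if ov > 0:
                overlaps[(srow.start_bin, int(calls[srow.start_bin]))] = ov
        if not overlaps:
            assert np.isnan(m.states.loc[iv.name, "S1"])
            continue
        best_ov = max(overlaps.values())
        winners = {c for (_, c), ov in overlaps.items() if ov == best_ov}
        got = m.states.loc[iv.name, "S1"]
        if len(winners) == 1:
            assert got == winners.pop()
        else:
            nonneutral = winners - {0}
            if len(nonneutral) == 1:
                assert got == nonneutral.pop()
            else:
                assert got == 0


def test_recurrence_ranking_counts_and_ties():
    states = pd.DataFrame(
        {"s1": [1, 1, 0], "s2": [1, 0, 0], "s3": [1, 0, -1]},
        index=["B", "A", "C"],
    )
    m = GeneStateMatrix(states)
    ranked = recurrence_ranking(m, "amp")
    assert ranked["gene"].tolist() == ["B", "A", "C"]
    assert ranked["n_samples"].tolist() == [3, 1, 0]
    assert ranked["n_samples"].sum() == (states == 1).sum().sum()
    ranked_del = recurrence_ranking(m, "del")
    assert ranked_del["n_samples"].tolist() == [1, 0, 0]


# -------------------------------------------------------------- clustering

def test_identical_samples_merge_first_at_height_zero():
    X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
    d = cluster_samples(X, labels=["a", "b", "c"])
    assert frozenset(("a", "c")) in d.cherries()
    assert d.linkage[0, 2] == 0.0


def test_three_point_merge_order_hand_traced():
    # distances: ab=1, ac=4, bc=3 -> merge (a,b) at 1, then height max(4,3)=4
    X = np.array([[0.0], [1.0], [4.0]])
    d = cluster_samples(X, labels=["a", "b", "c"])
    assert d.linkage[0, :3].tolist() == [0, 1, 1.0]
    assert d.linkage[1, 2] == 4.0


def test_merge_heights_are_monotone(rng):
    X = rng.normal(size=(12, 4))
    d = cluster_samples(X)
    heights = d.linkage[:, 2]
    assert (np.diff(heights) >= -1e-12).all()


def test_matches_scipy_complete_linkage(rng):
    """Cophenetic distances equal scipy's for <= 6 samples (oracle)."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import pdist, squareform

    for _ in range(20):
        n = int(rng.integers(3, 7))
        X = rng.normal(size=(n, 3))
        mine = cluster_samples(X).cophenetic_matrix()
        Z = linkage(pdist(X), method="complete")
        ref = squareform(cophenet(Z))
        assert np.allclose(mine, ref)


def test_all_missing_sample_excluded_with_warning():
    X = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
    with pytest.warns(UserWarning, match="all-missing"):
        d = cluster_samples(X, labels=["a", "b", "c"])
    assert d.labels == ["a", "c"]


def test_newick_export_is_wellformed():
    X = np.array([[0.0], [1.0], [4.0], [10.0]])
    d = cluster_samples(X, labels=["a", "b", "c", "d"])
    nwk = d.to_newick()
    assert nwk.endswith(";") and nwk.count("(") == nwk.count(")") == 3
    for lab in "abcd":
        assert lab in nwk


# ------------------------------------------------------------- concordance

def test_identical_replicates_on_diagonal():
    a = profile_from_calls("A", [1, 1, 0, -1, 0])
    pairs = [(a, a)]
    df, summary = replicate_concordance(pairs)
    assert (df["frac_a"] == df["frac_b"]).all()
    b = profile_from_calls("B", [0, 0, 0, 0, -1])
    df2, s2 = replicate_concordance([(a, a), (b, b)])
    assert s2["pearson_r"] == pytest.approx(1.0)
    assert s2["slope"] == pytest.approx(1.0)


def test_constant_fractions_leave_correlation_undefined():
    a = profile_from_calls("A", [0, 0, 0, 0])
    _, summary = replicate_concordance([(a, a), (a, a)])
    assert np.isnan(summary["pearson_r"])


# ---------------------------------------------------------- burden testing

def test_mannwhitney_exact_example():
    u, p = burden_comparison([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_mannwhitney_matches_enumeration_oracle(rng):
    """Exact p equals exhaustive enumeration of group assignments, n <= 6."""
    def ustat(xs, ys):
        return sum(1.0 for x in xs for y in ys if x > y)

    for _ in range(20):
        na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        pool = rng.permutation(100)[: na + nb].astype(float)  # distinct values
        a, b = pool[:na], pool[na:]
        u_got, p_got = burden_comparison(a, b)
        assert u_got == ustat(a, b)
        u_obs = ustat(a, b)
        mean_u = na * nb / 2
        us = np.array(
            [
                ustat(pool[list(comb)], np.delete(pool, list(comb)))
                for comb in itertools.combinations(range(na + nb), na)
            ]
        )
        p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9)
        assert p_got == pytest.approx(p_exact, abs=1e-9)


def test_identical_groups_give_p_one():
    _, p = burden_comparison([1.0, 2.0, 3.0], [1.5, 2.5, 0.5])
    assert 0 < p <= 1
    _, p2 = burden_comparison([1, 3, 5], [2, 4, 6])
    assert p2 > 0.5


def test_burden_comparison_empty_group_errors():
    with pytest.raises(ValueError):
        burden_comparison([], [1.0])


def test_detectable_cna_filter():
    flat = profile_from_calls("F", [0, 0, 0, 0])
    cna = profile_from_calls("C", [1, 0, 0, 0])
    fracs = detectable_cna_fractions([flat, cna])
    assert fracs.tolist() == [25.0]
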