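"""Enrichment statistics: binomial tails, z-tests, overlaps, DE consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from u12retain import (
    adjacency_to_u12,
    binomial_enrichment,
    classwise_u12_gene_enrichment,
    consensus_de_intersection,
    set_overlap_summary,
    two_proportion_ztest,
    u12_ir_enrichment,
)
from u12retain.intron_catalog import IntronRecord


def _tail_sum(observed, total, p):
    """Independent oracle: direct binomial upper-tail summation."""
    return sum(
        math.comb(total, k) * p**k * (1 - p) ** (total - k)
        for k in range(observed, total + 1)
    )


def test_binomial_enrichment_matches_direct_tail_summation():
    cases = [(3, 10, 0.1), (0, 100, 0.0004), (5, 50, 0.05), (12, 1000, 0.004), (1000, 1000, 0.5)]
    for obs, total, p in cases:
        res = binomial_enrichment(obs, total, p)
        assert res.p_value == pytest.approx(_tail_sum(obs, total, p), rel=1e-9)


def test_zero_observed_gives_fold_zero_p_one():
    res = binomial_enrichment(0, 100, 0.0004)
    assert res.fold == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_fold_invariant_to_integer_scaling():
    a = binomial_enrichment(3, 60, 0.01)
    b = binomial_enrichment(9, 180, 0.01)
    assert a.fold == pytest.approx(b.fold)


def _calls(rows):
    return pd.DataFrame(rows, columns=["event_id", "event_class", "gene_id", "intron_id", "call"])


def _cls(pairs):
    return pd.DataFrame(pairs, columns=["intron_id", "assigned_class"]).assign(gene_id="g")


def test_u12_ir_enrichment_counts_only_up_ir_events():
    calls = _calls(
        [
            ("e1", "IR", "g1", "i1", "up_in_MU"),
            ("e2", "IR", "g1", "i2", "up_in_MU"),
            ("e3", "IR", "g1", "i3", "down_in_MU"),  # wrong direction
            ("e4", "ES", "g1", "i4", "up_in_MU"),  # wrong class
        ]
    )
    cls = _cls([("i1", "U12-GTAG"), ("i2", "U2"), ("i3", "U12-ATAC"), ("i4", "U12-ATAC")])
    res = u12_ir_enrichment(calls, cls, expected_fraction=0.1)
    assert (res.observed, res.total) == (1, 2)


def test_u12_ir_enrichment_raises_on_unmapped_event():
    calls = _calls([("e1", "IR", "g1", "iX", "up_in_MU")])
    with pytest.raises(KeyError, match="iX"):
        u12_ir_enrichment(calls, _cls([("i1", "U2")]), 0.1)


def _catalog(gene_ranks):
    recs = []
    for gene, ranks in gene_ranks.items():
        for r in ranks:
            recs.append(
                IntronRecord(
                    intron_id=f"{gene}.i{r}", gene_id=gene, transcript_id=f"{gene}.t1",
                    chrom="c", start=100 * r, end=100 * r + 10, strand="+", rank=r,
                    sequence="GTAAGTTTAG", donor_dinuc="GT", acceptor_dinuc="AG",
                )
            )
    return recs


def test_adjacency_toy_gene():
    cat = _catalog({"g1": [1, 2, 3, 4, 5, 6]})
    cls = _cls([("g1.i3", "U12-GTAG")])
    hist, frac1, excluded = adjacency_to_u12(["g1.i2", "g1.i4", "g1.i6"], cat, cls)
    assert hist == {1: 2, 3: 1}
    assert frac1 == pytest.approx(2 / 3)
    assert excluded == []


def test_adjacency_excludes_genes_without_u12():
    cat = _catalog({"g1": [1, 2, 3], "g2": [1, 2]})
    cls = _cls([("g1.i1", "U12-GTAG")])
    with pytest.warns(UserWarning, match="no U12"):
        hist, frac1, excluded = adjacency_to_u12(["g1.i2", "g2.i1"], cat, cls)
    assert excluded == ["g2.i1"]
    assert hist == {1: 1} and frac1 == 1.0


def test_adjacency_matches_bruteforce_rank_scan():
    rng = np.random.default_rng(0)
    for _ in range(10):
        genes = {f"g{k}": list(range(1, int(rng.integers(2, 8)) + 1)) for k in range(6)}
        cat = _catalog(genes)
        u12 = []
        for g, ranks in genes.items():
            if rng.random() < 0.7:
                u12.append((f"{g}.i{rng.choice(ranks)}", "U12-GTAG"))
        cls = _cls(u12) if u12 else _cls([("g0.i1", "U2")])
        u12_ids = {i for i, c in u12}
        queries = [
            f"{g}.i{r}" for g, ranks in genes.items() for r in ranks
            if f"{g}.i{r}" not in u12_ids
        ]
        # brute-force oracle over all rank pairs
        expected_hist: dict[int, int] = {}
        for q in queries:
            g = q.split(".")[0]
            ds = [
                abs(int(q.split(".i")[1]) - int(t.split(".i")[1]))
                for t in u12_ids if t.startswith(g + ".")
            ]
            if ds:
                d = min(ds)
                expected_hist[d] = expected_hist.get(d, 0) + 1
        n_with_target = sum(expected_hist.values())
        with pytest.warns(UserWarning) if n_with_target < len(queries) else _nullcontext():
            hist, _, _ = adjacency_to_u12(queries, cat, cls)
        assert hist == dict(sorted(expected_hist.items()))


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def test_ztest_identical_proportions_is_null():
    res = two_proportion_ztest(7, 20, 7, 20)
    assert res.z == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_ztest_degenerate_pooled_proportion():
    res = two_proportion_ztest(0, 10, 0, 20)
    assert res.degenerate and res.p_value == 1.0
    res = two_proportion_ztest(10, 10, 20, 20)
    assert res.degenerate and res.p_value == 1.0


def test_ztest_agrees_with_fisher_exact_decision():
    # exact hypergeometric oracle: same rejection decision at alpha = 0.05
    cases = [(3, 10, 7, 10), (30, 100, 70, 100), (5, 50, 6, 50), (40, 60, 10, 60)]
    for k1, n1, k2, n2 in cases:
        z, p_z = two_proportion_ztest(k1, n1, k2, n2)
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        p_f = stats.fisher_exact(table).pvalue
        assert (p_z < 0.05) == (p_f < 0.05)
        # normal approximation vs exact test: gap is largest deep in the
        # null (both p large), where it never changes the decision
        assert abs(p_z - p_f) < 0.3


def test_overlap_disjoint_and_identical_sets():
    assert set_overlap_summary({"a", "b"}, {"c"}).n_both == 0
    res = set_overlap_summary({"a", "b"}, {"a", "b"})
    assert res.n_both == res.n_a == 2
    assert res.pct_a_in_b == 100.0


def test_overlap_matches_bruteforce_intersection():
    rng = np.random.default_rng(1)
    universe = [f"x{i}" for i in range(200)]
    for _ in range(20):
        a = set(rng.choice(universe, size=rng.integers(1, 100), replace=False))
        b = set(rng.choice(universe, size=rng.integers(1, 100), replace=False))
        res = set_overlap_summary(a, b)
        assert res.n_both == len(a & b)
        assert res.pct_a_in_b == pytest.approx(100 * len(a & b) / len(a))


def _de(rows):
    return pd.DataFrame(rows, columns=["gene", "log_fold_change", "adjusted_p"])


def test_consensus_requires_both_tables_and_concordance():
    a = _de([("g1", 1.0, 0.005), ("g2", 1.0, 0.005), ("g3", -2.0, 0.001)])
    b = _de([("g1", 2.0, 0.02), ("g2", -1.0, 0.005), ("g3", -1.0, 0.005), ("g4", 1.0, 0.001)])
    out = consensus_de_intersection(a, b, alpha=0.01)
    # g1 fails one table, g2 discordant, g4 absent from a
    assert out == {"g3"}


def test_consensus_is_symmetric_and_matches_bruteforce():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(100)]
    a = _de([(g, rng.normal(), rng.random() * 0.05) for g in genes if rng.random() < 0.8])
    b = _de([(g, rng.normal(), rng.random() * 0.05) for g in genes if rng.random() < 0.8])
    out = consensus_de_intersection(a, b, alpha=0.01)
    assert out == consensus_de_intersection(b, a, alpha=0.01)
    am = {r.gene: (r.log_fold_change, r.adjusted_p) for r in a.itertuples()}
    bm = {r.gene: (r.log_fold_change, r.adjusted_p) for r in b.itertuples()}
    expected = {
        g for g in am.keys() & bm.keys()
        if am[g][1] < 0.01 and bm[g][1] < 0.01 and am[g][0] * bm[g][0] > 0
    }
    assert out == expected


def test_classwise_enrichment_bh_adjusts_across_classes():
    calls = _calls(
        [(f"e{i}", cls, f"g{i % 20}", f"i{i}", "up_in_MU") for i, cls in enumerate(["IR"] * 10 + ["ES"] * 10 + ["MIC"] * 5)]
    )
    u12_genes = {f"g{i}" for i in range(5)}
    all_genes = {f"g{i}" for i in range(40)}
    out = classwise_u12_gene_enrichment(calls, u12_genes, all_genes)
    assert set(out["event_class"]) == {"IR", "ES", "MIC"}
    assert (out["q_value"] >= out["p_value"] - 1e-12).all()
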