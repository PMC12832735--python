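"""Top-K composition vs gene sets: counts, percentages, exact test."""

import math
from math import comb

import pandas as pd
import pytest

from evcargo import (
    GeneSet,
    GeneSetCollection,
    members_in_topk,
    proportion_test,
    representation_table,
)
from evcargo.ranking import TopKSet


def make_topk(features, k=None, label="", universe=None):
    n = len(features)
    table = pd.DataFrame(
        {
            "rank": range(1, n + 1),
            "feature_id": list(features),
            "score": [float(n - i) for i in range(n)],
        }
    )
    return TopKSet(
        table=table,
        k=k or n,
        source_label=label,
        universe=frozenset(universe if universe is not None else features),
    )


class TestMembersInTopK:
    def test_intersection_counting(self):
        topk = make_topk(["g1", "g2", "g3"])
        gs = GeneSet("P", "p", frozenset({"g2", "g3", "g4", "g5"}))
        assert members_in_topk(topk, gs) == 2

    def test_disjoint_and_subset(self):
        topk = make_topk([f"g{i}" for i in range(10)])
        assert members_in_topk(topk, GeneSet("P", "p", frozenset({"x", "y"}))) == 0
        inside = frozenset(f"g{i}" for i in range(7))
        assert members_in_topk(topk, GeneSet("P", "p", inside)) == 7

    def test_empty_geneset_rejected(self):
        gs = GeneSet("P", "p", frozenset())
        with pytest.raises(ValueError, match="empty"):
            members_in_topk(make_topk(["g1"]), gs)


class TestRepresentationTable:
    def _table(self, count_a, count_b, size, k=1000):
        members = frozenset(f"m{i}" for i in range(size))
        topk_a = make_topk(
            [f"m{i}" for i in range(count_a)]
            + [f"fillA{i}" for i in range(k - count_a)],
            k=k, label="salEV", universe=members,
        )
        topk_b = make_topk(
            [f"m{i}" for i in range(count_b)]
            + [f"fillB{i}" for i in range(k - count_b)],
            k=k, label="bEV", universe=members,
        )
        coll = GeneSetCollection(sets={"P": GeneSet("P", "pathway", members)})
        return representation_table(topk_a, topk_b, coll)

    @pytest.mark.parametrize(
        "count,size,expected_pct",
        [(128, 390, "32.8"), (62, 390, "15.9"), (0, 10, "0.0"), (10, 10, "100.0")],
    )
    def test_percent_arithmetic_and_display(self, count, size, expected_pct):
        rt = self._table(count, 0, size)
        row = rt.table.iloc[0]
        assert row["percent_a"] == pytest.approx(100.0 * count / size)
        display = rt.formatted().iloc[0]["salEV"]
        assert display == f"{count} ({expected_pct})"

    def test_measured_members_column(self):
        rt = self._table(5, 2, 20)
        row = rt.table.iloc[0]
        assert row["measured_a"] == 20 and row["measured_b"] == 20
        assert row["pathway_size"] == 20

    def test_source_swap_symmetry(self):
        rt = self._table(7, 3, 30)
        members = frozenset(f"m{i}" for i in range(30))
        coll = GeneSetCollection(sets={"P": GeneSet("P", "pathway", members)})
        topk_a = make_topk(
            [f"m{i}" for i in range(7)] + [f"fillA{i}" for i in range(993)],
            k=1000, universe=members)
        topk_b = make_topk(
            [f"m{i}" for i in range(3)] + [f"fillB{i}" for i in range(997)],
            k=1000, universe=members)
        swapped = representation_table(topk_b, topk_a, coll)
        assert swapped.table.iloc[0]["count_a"] == rt.table.iloc[0]["count_b"]
        assert swapped.table.iloc[0]["count_b"] == rt.table.iloc[0]["count_a"]
        pa = proportion_test(7, 3, 30).p_value
        pb = proportion_test(3, 7, 30).p_value
        assert pa == pytest.approx(pb)

    def test_counts_bounded_by_min_k_size(self, study):
        import evcargo as e

        ta = e.top_k_features(e.log_mean_abundance(study.counts_a), 1000, "A")
        tb = e.top_k_features(e.log_mean_abundance(study.counts_b), 1000, "B")
        rt = representation_table(ta, tb, study.genesets, study.annotation)
        for _, row in rt.table.iterrows():
            bound = min(1000, row["pathway_size"])
            assert 0 <= row["count_a"] <= bound
            assert 0 <= row["count_b"] <= bound
            assert row["percent_a"] == pytest.approx(
                100.0 * row["count_a"] / row["pathway_size"]
            )

    def test_mismatched_k_rejected(self):
        a = make_topk(["g1"], k=1)
        b = make_topk(["g1", "g2"], k=2)
        coll = GeneSetCollection(sets={"P": GeneSet("P", "p", frozenset({"g1"}))})
        with pytest.raises(ValueError, match="different K"):
            representation_table(a, b, coll)


def fisher_two_sided_oracle(a: int, b: int, k: int) -> float:
    """Exhaustive two-sided Fisher p for [[a, k-a], [b, k-b]].

    Conditions on the margins and sums hypergeometric probabilities of all
    tables no more probable than the observed one, with exact rational
    arithmetic via integer binomials.
    """
    s = a + b  # column margin for the in-top-K column
    denom = comb(2 * k, s)
    lo, hi = max(0, s - k), min(k, s)
    probs = {x: comb(k, x) * comb(k, s - x) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    total = sum(p for p in probs.values() if p <= p_obs)
    return total / denom


class TestProportionTest:
    def test_equal_counts_give_p_one_and_zero_difference(self):
        res = proportion_test(17, 17, 50)
        assert res.difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_full_difference(self):
        assert proportion_test(5, 0, 5).difference == 1.0

    @pytest.mark.parametrize(
        "a,b,k", [(128, 62, 390), (3, 1, 8), (0, 5, 7), (10, 2, 12)]
    )
    def test_matches_exhaustive_enumeration_oracle(self, a, b, k):
        res = proportion_test(a, b, k)
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(a, b, k),
                                            rel=1e-9)

    def test_zero_pathway_size_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0, 0)
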