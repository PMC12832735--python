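"""qPCR presence calling and miRNA background filtering."""

import numpy as np
import pandas as pd
import pytest

from evcargo import (
    CtTable,
    MiRNACountTable,
    mirna_expression_filter,
    presence_summary,
    qpcr_presence_call,
)


def ct_table(rows):
    return CtTable(
        table=pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
    )


def random_ct_table(rng, n_genes=5, n_samples=3):
    rows = []
    for g in range(n_genes):
        for s in range(n_samples):
            for rep in (1, 2):
                ct = rng.uniform(10, 45) if rng.random() > 0.15 else np.nan
                rows.append((f"g{g}", f"s{s}", rep, ct))
    return ct_table(rows)


class TestQpcrPresenceCall:
    @pytest.mark.parametrize(
        "ct1,ct2,expected",
        [
            (25.0, 30.0, True),   # both inside window
            (17.9, 25.0, False),  # below window in one run
            (25.0, np.nan, False),  # missing replicate
            (18.0, 35.0, True),   # bounds inclusive
            (35.1, 34.0, False),  # above window in one run
        ],
    )
    def test_duplicate_window_rule(self, ct1, ct2, expected):
        ct = ct_table([("g", "s", 1, ct1), ("g", "s", 2, ct2)])
        pm = qpcr_presence_call(ct)
        assert pm.matrix.at["g", "s"] == expected

    def test_single_replicate_row_is_absent(self):
        ct = ct_table([("g", "s", 1, 25.0)])
        assert not qpcr_presence_call(ct).matrix.at["g", "s"]

    def test_defined_for_full_universe(self):
        ct = ct_table(
            [("g1", "s1", 1, 25.0), ("g1", "s1", 2, 26.0), ("g2", "s2", 1, 25.0)]
        )
        pm = qpcr_presence_call(ct)
        assert pm.matrix.shape == (2, 2)
        assert not pm.matrix.at["g2", "s1"]

    def test_widening_window_is_monotone(self):
        # widening the Ct window never converts present -> absent
        rng = np.random.default_rng(21)
        for _ in range(50):
            ct = random_ct_table(rng)
            narrow = qpcr_presence_call(ct, 18, 35).matrix
            wide = qpcr_presence_call(ct, 15, 40).matrix
            assert (wide | ~narrow).all().all()


class TestPresenceSummary:
    def _matrix(self, per_gene_hits, n_samples, universe):
        genes = [f"g{i}" for i in range(universe)]
        mat = np.zeros((universe, n_samples), dtype=bool)
        for i, h in enumerate(per_gene_hits):
            mat[i, :h] = True
        from evcargo.presence import PresenceMatrix

        return PresenceMatrix(
            matrix=pd.DataFrame(
                mat, index=genes, columns=[f"s{j}" for j in range(n_samples)]
            ),
            ct_min=18, ct_max=35,
        )

    def test_reference_marginals_round_to_integers(self):
        # 94-gene array over 15 samples: 54 genes in >=10, another 24 in
        # exactly 1, 16 never detected -> 78/94 = 83%, 54/94 = 57%
        hits = [10] * 54 + [1] * 24 + [0] * 16
        summary = presence_summary(self._matrix(hits, 15, 94))
        assert summary.counts == {1: 78, 10: 54}
        assert summary.percent_display(1) == 83
        assert summary.percent_display(10) == 57
        assert summary.percent(1) == pytest.approx(100 * 78 / 94)

    def test_empty_matrix_counts_zero(self):
        summary = presence_summary(self._matrix([0] * 5, 3, 5))
        assert summary.counts == {1: 0, 10: 0}

    def test_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(22)
        from evcargo.presence import PresenceMatrix

        for _ in range(20):
            mat = rng.random((30, 12)) < 0.4
            pm = PresenceMatrix(
                matrix=pd.DataFrame(
                    mat,
                    index=[f"g{i}" for i in range(30)],
                    columns=[f"s{j}" for j in range(12)],
                ),
                ct_min=18, ct_max=35,
            )
            summary = presence_summary(pm, thresholds=tuple(range(1, 13)))
            vals = [summary.counts[m] for m in range(1, 13)]
            assert all(x >= y for x, y in zip(vals, vals[1:]))


def mirna_table(mirna_rows: dict, control_rows: dict) -> MiRNACountTable:
    counts = pd.DataFrame({**mirna_rows, **control_rows}).T.astype(float)
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    return MiRNACountTable(
        counts=counts, control_ids=frozenset(control_rows)
    )


class TestMiRNAFilter:
    def test_background_rule_and_cutoff_arithmetic(self):
        # controls per sample: {15, 25} -> mean 20, population SD 5 -> bg 30
        t = mirna_table(
            {"hi": [150, 150, 150], "lo": [25, 25, 25]},
            {"NEG_A": [15, 15, 15], "NEG_B": [25, 25, 25]},
        )
        res = mirna_expression_filter(t)
        assert res.background_threshold == pytest.approx(30.0)
        assert res.expressed == {"hi"}
        assert "lo" not in res.expressed
        assert res.low_flagged == set()  # 150 > 100 clears the flag

    def test_boundary_mean_exactly_100_is_flagged(self):
        t = mirna_table(
            {"edge": [100, 100, 100]},
            {"NEG_A": [15, 15, 15], "NEG_B": [25, 25, 25]},
        )
        res = mirna_expression_filter(t)
        assert "edge" in res.expressed  # 100 > background 30
        assert "edge" in res.low_flagged  # but <= cutoff 100

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(23)
        counts = pd.DataFrame(
            rng.poisson(50, size=(10, 6)).astype(float),
            index=[f"m{i}" for i in range(8)] + ["NEG_A", "NEG_B"],
            columns=[f"s{i}" for i in range(6)],
        )
        t1 = MiRNACountTable(counts=counts, control_ids=frozenset({"NEG_A", "NEG_B"}))
        t2 = MiRNACountTable(
            counts=counts.iloc[:, ::-1], control_ids=frozenset({"NEG_A", "NEG_B"})
        )
        r1, r2 = mirna_expression_filter(t1), mirna_expression_filter(t2)
        assert r1.expressed == r2.expressed
        assert r1.background_threshold == pytest.approx(r2.background_threshold)

    def test_top_report_orders_by_mean_count(self):
        t = mirna_table(
            {"a": [500, 500], "b": [400, 400], "c": [300, 300]},
            {"NEG_A": [15, 25]},
        )
        top = mirna_expression_filter(t).top(2)
        assert list(top["id"]) == ["a", "b"]
        assert list(top["rank"]) == [1, 2]
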