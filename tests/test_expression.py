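"""BH adjustment, Welch screening, Table-style DEG summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agpkit.expression import (
    Call,
    DEResult,
    StageStats,
    bh_adjust,
    curated_deg_table_path,
    format_deg_table,
    read_deg_table,
    screen_degs,
    screen_expression,
    stage_log2fc,
    summarize_deg_by_subfamily,
    welch_t_test,
)
from agpkit.io_formats import ExpressionTable, Genotype, SampleInfo
from agpkit.synthetic_data import ExpressionSpec, generate_expression

pvec = st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)


def bh_oracle(p):
    """Direct transcription of the step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(min(p[order[r - 1]] * m / r for r in range(rank, m + 1)), 1.0)
    return q


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stairstep_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(pvec)
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(pvec)
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    @given(pvec)
    def test_monotone_on_sorted_input(self, p):
        q = bh_adjust(sorted(p))
        assert all(q[i] <= q[i + 1] + 1e-12 for i in range(len(q) - 1))


class TestWelch:
    def test_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(0, 1, size=int(rng.integers(2, 8)))
            y = rng.normal(0.5, 2, size=int(rng.integers(2, 8)))
            t, p = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_degenerate_inputs(self):
        assert welch_t_test([1.0], [1.0, 2.0]) == (0.0, 1.0)
        assert welch_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


def two_genotype_table(fertile, sterile, stage=1):
    """1-gene table with given replicate FPKM per genotype at one stage."""
    samples = [SampleInfo(Genotype.B_FERTILE, stage, r + 1) for r in range(len(fertile))]
    samples += [SampleInfo(Genotype.A_STERILE, stage, r + 1) for r in range(len(sterile))]
    return ExpressionTable(
        genes=["g1"], samples=samples, values=np.array([fertile + sterile], dtype=float)
    )


class TestStageLog2FC:
    def test_arithmetic(self):
        table = two_genotype_table([7.0, 7.0], [1.0, 1.0])
        (s,) = stage_log2fc(table, 1)
        assert s.log2fc == pytest.approx(2.0)  # log2((7+1)/(1+1))

    def test_fertile_specific_flag(self):
        table = two_genotype_table([50.0, 50.0], [0.2, 0.2])
        (res,) = screen_expression(table)
        assert res.call[1] is Call.F_SPECIFIC

    def test_both_zero_not_expressed(self):
        table = two_genotype_table([0.0, 0.0], [0.0, 0.0])
        (s,) = stage_log2fc(table, 1)
        assert s.log2fc == 0.0
        (res,) = screen_expression(table)
        assert res.call[1] is Call.NOT_EXPRESSED

    def test_absent_stage_rejected(self):
        table = two_genotype_table([1.0], [1.0], stage=2)
        with pytest.raises(ValueError):
            stage_log2fc(table, 5)


class TestScreenDegs:
    @staticmethod
    def stat(log2fc, p, fertile=50.0, sterile=50.0, stage=1, gene="g"):
        return StageStats(gene, stage, log2fc, p, fertile, sterile)

    def test_boundary_log2fc_inclusive(self):
        (res,) = screen_degs([self.stat(1.0, 0.04)])
        assert res.call[1] is Call.UP

    def test_below_effect_threshold_ns(self):
        (res,) = screen_degs([self.stat(0.9, 0.001)])
        assert res.call[1] is Call.NS

    def test_strong_downregulation(self):
        (res,) = screen_degs([self.stat(-3.2, 0.01)])
        assert res.call[1] is Call.DOWN

    def test_bh_within_stage(self):
        stats = [self.stat(2.0, p, gene=f"g{i}") for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        results = screen_degs(stats)
        # all BH-adjusted to 0.04 < 0.05: every gene called UP
        assert all(r.call[1] is Call.UP for r in results)
        assert all(r.fdr[1] == pytest.approx(0.04) for r in results)

    def test_genotype_swap_antisymmetry(self):
        spec = ExpressionSpec(n_genes=40, seed=4, planted_effects=(("gene0001", 2, 3.0),),
                              planted_specific=(("gene0002", 3, "F"),))
        table = generate_expression(spec).table
        res = {r.gene_id: r for r in screen_expression(table)}
        # swap genotype labels
        swapped_samples = [
            SampleInfo(
                Genotype.A_STERILE if s.genotype is Genotype.B_FERTILE else Genotype.B_FERTILE,
                s.stage, s.replicate,
            )
            for s in table.samples
        ]
        swapped = ExpressionTable(table.genes, swapped_samples, table.values)
        res_sw = {r.gene_id: r for r in screen_expression(swapped)}
        flip = {Call.UP: Call.DOWN, Call.DOWN: Call.UP,
                Call.F_SPECIFIC: Call.S_SPECIFIC, Call.S_SPECIFIC: Call.F_SPECIFIC,
                Call.NS: Call.NS, Call.NOT_EXPRESSED: Call.NOT_EXPRESSED}
        for gene, r in res.items():
            for stage, call in r.call.items():
                assert res_sw[gene].call[stage] is flip[call]
                assert res_sw[gene].log2fc[stage] == pytest.approx(-r.log2fc[stage])


class TestDegTable:
    def test_curated_table_counts(self):
        """The curated floral-bud DEG table holds 73 differential genes whose
        per-subfamily counts match the published breakdown."""
        results, subfamily = read_deg_table(curated_deg_table_path())
        counts, total = summarize_deg_by_subfamily(results, subfamily)
        assert total == 73
        assert sum(counts.values()) == 73
        assert counts == {
            "AG-peptide": 8, "Classical": 9, "Lys-rich": 1, "Non-classical": 2,
            "FLA": 10, "PLA": 12, "XYLP": 12, "CAGP": 16, "CHAE": 1, "HAE": 2,
        }

    def test_no_differential_genes(self):
        res = DEResult(gene_id="g1", call={1: Call.NS, 2: Call.NOT_EXPRESSED})
        counts, total = summarize_deg_by_subfamily([res], {"g1": "FLA"})
        assert total == 0 and counts == {}

    def test_counts_invariant_to_row_order(self):
        results, subfamily = read_deg_table(curated_deg_table_path())
        fwd = summarize_deg_by_subfamily(results, subfamily)
        rev = summarize_deg_by_subfamily(results[::-1], subfamily)
        assert fwd == rev

    def test_unjoined_gene_counted_unclassified(self):
        res = DEResult(gene_id="gX", call={1: Call.UP}, log2fc={1: 2.0})
        counts, total = summarize_deg_by_subfamily([res], {})
        assert counts == {"unclassified": 1} and total == 1

    def test_format_round_trip(self, tmp_path):
        results, subfamily = read_deg_table(curated_deg_table_path())
        df = format_deg_table(results, subfamily)
        out = tmp_path / "degs.tsv"
        df.to_csv(out, sep="\t", index=False)
        back, _ = read_deg_table(out)
        assert [r.call for r in back] == [r.call for r in results]
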