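"""Downstream statistics: paired t, exact 2x2 tests, spectra, curves, gene
enrichment and the ranked-list export."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from aimseq import stats
from aimseq.io import AIResult, MutationRecord
from oracles import fisher_enumeration_oracle


def _res(dna_vaf, rna_vaf, gene="G1", ai_class=None, ref="C", alt="T"):
    rec = MutationRecord("S1", gene, "chr1", 1, ref, alt, "missense", 10, 10, 10, 10)
    afd = rna_vaf - dna_vaf
    if ai_class is None:
        ai_class = "no_sig"
    return AIResult(rec, dna_vaf, rna_vaf, afd, 0.0, ai_class)


class TestPairedVafTest:
    def test_matches_hand_computation(self):
        # pairs (DNA, RNA): differences -0.3, -0.3, -0.25
        results = [_res(0.5, 0.2), _res(0.4, 0.1), _res(0.6, 0.35)]
        t, p = stats.paired_vaf_test(results, "rna_less")
        d = np.array([-0.3, -0.3, -0.25])
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert t == pytest.approx(t_hand)
        from scipy.stats import t as tdist
        assert p == pytest.approx(tdist.cdf(t_hand, df=2))

    def test_zero_variance_is_degenerate(self):
        results = [_res(0.5, 0.2), _res(0.4, 0.1), _res(0.6, 0.3)]
        with pytest.raises(stats.DegenerateInputError):
            stats.paired_vaf_test(results, "rna_less")

    def test_wrong_tail_gives_large_p(self):
        results = [_res(0.2, 0.5), _res(0.1, 0.45), _res(0.3, 0.55)]
        _, p = stats.paired_vaf_test(results, "rna_less")
        assert p > 0.5

    def test_swapping_pairs_flips_t(self):
        results = [_res(0.5, 0.2), _res(0.4, 0.1), _res(0.6, 0.35)]
        swapped = [_res(r.rna_vaf, r.dna_vaf) for r in results]
        t1, _ = stats.paired_vaf_test(results, "rna_less")
        t2, _ = stats.paired_vaf_test(swapped, "rna_greater")
        assert t1 == pytest.approx(-t2)

    def test_too_few_pairs(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.paired_vaf_test([_res(0.5, 0.2)], "rna_less")


class TestFisherExact:
    def test_greater_matches_enumeration(self):
        t = stats.ContingencyTable2x2(3, 1, 10, 86)
        p = stats.fisher_exact_2x2(t, "greater")
        oracle = fisher_enumeration_oracle(np.array([[3, 1, 10, 86]]), "greater")[0]
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_identical_rows_two_sided_p_one(self):
        assert stats.fisher_exact_2x2(stats.ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_transpose_invariance_two_sided(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b + c + d == 0:
                continue
            p1 = stats.fisher_exact_2x2(stats.ContingencyTable2x2(a, b, c, d))
            p2 = stats.fisher_exact_2x2(stats.ContingencyTable2x2(a, c, b, d))
            assert p1 == pytest.approx(p2, abs=1e-12)

    @pytest.mark.parametrize("alternative,scipy_alt", [
        ("two_sided", "two-sided"), ("greater", "greater")])
    def test_matches_scipy_on_random_tables(self, alternative, scipy_alt):
        rng = np.random.default_rng(9)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b + c + d == 0:
                continue
            ours = stats.fisher_exact_2x2(
                stats.ContingencyTable2x2(a, b, c, d), alternative)
            ref = scipy_fisher([[a, b], [c, d]], alternative=scipy_alt)[1]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_grid_api_matches_scalar(self):
        rng = np.random.default_rng(10)
        tables = rng.integers(0, 15, size=(200, 4))
        tables = tables[tables.sum(axis=1) > 0]
        for alt in ("two_sided", "greater"):
            batch = stats.fisher_exact_grid(tables, alt)
            scalar = [stats.fisher_exact_2x2(stats.ContingencyTable2x2(*t), alt)
                      for t in tables]
            assert np.allclose(batch, scalar, atol=1e-13)

    def test_all_zero_rejected(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.ContingencyTable2x2(0, 0, 0, 0)


class TestSpectraAndTsTv:
    def test_paper_class_label(self):
        assert stats.spectrum_class("C", "A") == "C:G>A:T"

    def test_reverse_complement_collapse(self):
        assert stats.spectrum_class("G", "T") == "C:G>A:T"
        for r, a in [("C", "T"), ("G", "A")]:
            assert stats.spectrum_class(r, a) == "C:G>T:A"

    def test_twelve_substitutions_map_two_per_class(self):
        from collections import Counter
        counts = Counter(
            stats.spectrum_class(r, a)
            for r in "ACGT" for a in "ACGT" if r != a)
        assert set(counts) == set(stats.SPECTRUM_CLASSES)
        assert all(v == 2 for v in counts.values())

    def test_transitions(self):
        assert stats.ts_tv("C", "T") == "transition"
        assert stats.ts_tv("C", "A") == "transversion"
        n_ts = sum(stats.ts_tv(r, a) == "transition"
                   for r in "ACGT" for a in "ACGT" if r != a)
        assert n_ts == 4

    def test_invalid_nucleotide(self):
        with pytest.raises(stats.ValidationError):
            stats.spectrum_class("C", "C")
        with pytest.raises(stats.ValidationError):
            stats.ts_tv("N", "A")


class TestChisq:
    def test_independent_table_gives_zero(self):
        margins_r = np.array([10, 30])
        margins_c = np.array([20, 20, 10])
        table = np.outer(margins_r, margins_c) / 40
        stat, p = stats.chisq_independence(table)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_2x2_equals_squared_two_proportion_z(self):
        a, b, c, d = 12, 30, 25, 18
        stat, _ = stats.chisq_independence(np.array([[a, b], [c, d]]))
        p1, p2 = a / (a + b), c / (c + d)
        pp = (a + c) / (a + b + c + d)
        z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / (a + b) + 1 / (c + d)))
        assert stat == pytest.approx(z ** 2)

    def test_row_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 1, 4]])
        s1, _ = stats.chisq_independence(t)
        s2, _ = stats.chisq_independence(t[::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_degenerate(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.chisq_independence(np.array([[0, 0], [3, 4]]))


class TestRatioCurve:
    def test_hand_counted(self):
        curve = stats.cumulative_ratio_curve([5, 15, 25], [True, False, True], 10, 30)
        assert curve.ratios == pytest.approx([1 / 1, 1 / 2, 2 / 3])

    def test_final_bin_is_global_fraction(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(0, 90, size=200)
        flags = rng.random(200) < 0.3
        curve = stats.cumulative_ratio_curve(values, flags, 10, 100)
        assert curve.ratios[-1] == pytest.approx(flags.mean())

    def test_counts_monotone_and_match_bruteforce(self):
        rng = np.random.default_rng(14)
        values = rng.uniform(0, 200, size=500)
        flags = rng.random(500) < 0.4
        curve = stats.cumulative_ratio_curve(values, flags, 10, 200)
        assert all(b >= a for a, b in zip(curve.n_total, curve.n_total[1:]))
        for edge, tot, ev in zip(curve.bin_upper_edges, curve.n_total, curve.n_event):
            mask = values < edge
            assert tot == mask.sum() and ev == flags[mask].sum()

    def test_empty_bin_reports_nan(self):
        curve = stats.cumulative_ratio_curve([55.0], [True], 10, 60)
        assert curve.n_total[0] == 0 and math.isnan(curve.ratios[0])


class TestGeneEnrichment:
    def _cohort(self):
        results = []
        # gene X: 3 focal of 4; background: 10 focal of 96
        for i in range(4):
            results.append(_res(0.4, 0.6, gene="X",
                                ai_class="sig_pos_afd" if i < 3 else "no_sig"))
        for i in range(96):
            results.append(_res(0.4, 0.6, gene=f"B{i % 24}",
                                ai_class="sig_pos_afd" if i < 10 else "no_sig"))
        return results

    def test_matches_enumeration_oracle(self):
        table = stats.gene_ai_enrichment(self._cohort(), "sig_pos_afd")
        px = table[table["gene"] == "X"]["p_fisher"].iloc[0]
        oracle = fisher_enumeration_oracle(np.array([[3, 1, 10, 86]]), "greater")[0]
        assert px == pytest.approx(oracle, abs=1e-12)

    def test_min_events_excludes_zero_focal_genes(self):
        results = [_res(0.4, 0.6, gene="A", ai_class="sig_pos_afd"),
                   _res(0.4, 0.6, gene="Z", ai_class="no_sig")]
        table = stats.gene_ai_enrichment(results, "sig_pos_afd", min_events=1)
        assert list(table["gene"]) == ["A"]

    def test_pvalues_valid_and_order_invariant(self):
        cohort = self._cohort()
        t1 = stats.gene_ai_enrichment(cohort, "sig_pos_afd")
        t2 = stats.gene_ai_enrichment(cohort[::-1], "sig_pos_afd")
        assert ((t1["p_fisher"] >= 0) & (t1["p_fisher"] <= 1)).all()
        merged = t1.merge(t2, on="gene", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_fisher_a"], merged["p_fisher_b"])

    def test_neglogp_display_cutoff(self):
        table = stats.gene_ai_enrichment(self._cohort(), "sig_pos_afd")
        shown = table[table["neg_log10_p"] > 2.5]
        assert set(shown["gene"]) <= set(table["gene"])


class TestRankedList:
    def test_order_and_scores(self, tmp_path):
        enrich = pd.DataFrame({
            "gene": ["g3", "g1", "g2"],
            "neg_log10_p": [1.0, 3.0, 2.0],
        })
        ranked = stats.export_ranked_list(enrich, tmp_path / "r.rnk")
        assert list(ranked["gene"]) == ["g1", "g2", "g3"]
        assert list(ranked["neg_log10_p"]) == [3.0, 2.0, 1.0]

    def test_ties_break_alphabetically_and_round_trip(self, tmp_path):
        enrich = pd.DataFrame({"gene": ["zz", "aa"], "neg_log10_p": [2.0, 2.0]})
        path = tmp_path / "r.rnk"
        ranked = stats.export_ranked_list(enrich, path)
        assert list(ranked["gene"]) == ["aa", "zz"]
        back = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
        assert list(back["gene"]) == ["aa", "zz"]
        assert list(back["score"]) == [2.0, 2.0]
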