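"""Genomic location classes, partial-responder ANOVA, and the cohort
description statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lithmark.annotate import (classify_location, cohort_table,
                               location_fractions, partial_responder_anova)
from lithmark.dmr import DMR
from lithmark.io import GeneModel
from conftest import make_sheet


def _dmr(start, end, chrom="chr1"):
    return DMR(dmr_id="D", chrom=chrom, start=start, end=end,
               cpg_positions=[start, end], mean_meth_er=0, mean_meth_nr=0,
               mean_diff=0, p=1.0, q=1.0)


GENES = [
    GeneModel("g1", "ALPHA", "chr1", "+", 10_000, 20_000,
              [(10_000, 11_000), (15_000, 16_000), (19_000, 20_000)]),
    GeneModel("g2", "BETA", "chr1", "-", 50_000, 40_000,
              [(40_000, 41_000), (49_000, 50_000)]),
]


class TestClassifyLocation:
    def test_upstream_of_plus_strand_tss_is_promoter(self):
        cls, gene = classify_location(_dmr(9_940, 9_960), GENES)
        assert (cls, gene) == ("Promoter-TSS", "ALPHA")

    def test_upstream_of_minus_strand_tss_is_promoter(self):
        # - strand TSS at 50_000; upstream means larger coordinates
        cls, gene = classify_location(_dmr(50_300, 50_500), GENES)
        assert (cls, gene) == ("Promoter-TSS", "BETA")

    def test_midpoint_in_exon_outside_windows(self):
        cls, gene = classify_location(_dmr(15_300, 15_500), GENES)
        assert (cls, gene) == ("Exon", "ALPHA")

    def test_midpoint_between_exons_is_intron(self):
        cls, gene = classify_location(_dmr(13_000, 13_200), GENES)
        assert (cls, gene) == ("Intron", "ALPHA")

    def test_near_tts_wins_over_exon(self):
        # midpoint 19_900: inside exon 3 but within 1 kb of the + TTS
        cls, gene = classify_location(_dmr(19_850, 19_950), GENES)
        assert (cls, gene) == ("TTS", "ALPHA")

    def test_far_from_genes_is_intergenic_without_gene(self):
        cls, gene = classify_location(_dmr(200_000, 200_100), GENES)
        assert (cls, gene) == ("Intergenic", None)

    def test_empty_gene_set_everything_intergenic(self):
        cls, gene = classify_location(_dmr(10_500, 10_600), [])
        assert (cls, gene) == ("Intergenic", None)

    def test_agrees_with_bruteforce_interval_checker(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            start = int(rng.integers(5_000, 60_000))
            d = _dmr(start, start + int(rng.integers(10, 400)))
            mid = (d.start + d.end) // 2
            cls, _ = classify_location(d, GENES)
            expect = "Intergenic"
            # precedence order, brute force over every gene
            if any((g.strand == "+" and g.tss - 1000 <= mid <= g.tss + 100)
                   or (g.strand == "-" and g.tss - 100 <= mid <= g.tss + 1000)
                   for g in GENES):
                expect = "Promoter-TSS"
            elif any(abs(mid - g.tts) <= 1000 for g in GENES):
                expect = "TTS"
            elif any(a <= mid <= b for g in GENES for a, b in g.exons):
                expect = "Exon"
            elif any(g.start <= mid <= g.end for g in GENES):
                expect = "Intron"
            assert cls == expect

    def test_fractions_partition_the_dmr_set(self):
        rng = np.random.default_rng(1)
        dmrs = [_dmr(int(p), int(p) + 100)
                for p in rng.integers(5_000, 60_000, size=30)]
        for d in dmrs:
            d.location, d.gene = classify_location(d, GENES)
        fr = location_fractions(dmrs)
        assert fr.sum() == pytest.approx(1.0)


class TestPartialResponderAnova:
    def _features(self, er, pr, nr):
        sheet = make_sheet(len(er), len(nr), n_pr=len(pr))
        vals = np.concatenate([er, nr, pr])  # sheet order: ER, NR, PR
        return pd.DataFrame({"D1": vals}, index=sheet.samples), sheet

    def test_identical_values_give_f_zero_p_one(self):
        X, sheet = self._features([1.0] * 3, [1.0] * 3, [1.0] * 3)
        anova, _ = partial_responder_anova(X, sheet, ["D1"])
        assert anova.loc[0, "F"] == 0.0 and anova.loc[0, "p"] == 1.0

    def test_strong_separation_is_highly_significant(self):
        rng = np.random.default_rng(2)
        X, sheet = self._features(list(rng.normal(10, 1, 10)),
                                  list(rng.normal(15, 1, 10)),
                                  list(rng.normal(20, 1, 10)))
        anova, boxes = partial_responder_anova(X, sheet, ["D1"])
        assert anova.loc[0, "F"] > 10 and anova.loc[0, "p"] < 1e-6
        med = boxes.set_index("group")["median"]
        assert med["ER"] < med["PR"] < med["NR"]

    def test_two_group_anova_reduces_to_squared_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        f = stats.f_oneway(a, b)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.pvalue == pytest.approx(t.pvalue)

    def test_requires_two_samples_per_group(self):
        X, sheet = self._features([1.0, 2.0], [3.0], [1.5, 2.5])
        with pytest.raises(ValueError, match="< 2 samples"):
            partial_responder_anova(X, sheet, ["D1"])


def fisher_tail_oracle(table):
    """One-sided Fisher p by exhaustive enumeration over all 2x2 tables
    with the observed margins (hypergeometric tail including ties)."""
    from math import comb

    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, col1)
    p_obs = comb(row1, a) * comb(n - row1, col1 - a)
    tail = 0
    for a2 in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p2 = comb(row1, a2) * comb(n - row1, col1 - a2)
        if a2 >= a:  # enrichment direction: a or more extreme
            tail += p2
    return tail / denom


@pytest.fixture(scope="module")
def printed_margins_sheet():
    """A sheet reproducing the printed 2x2 margins of the real cohort:
    current Li 14/1 vs 5/6, sex 8/7 vs 6/5, anticonvulsants 3/12 vs 5/6."""
    sheet = make_sheet(15, 11)
    sheet.df["current_li"] = [True] * 14 + [False] + [True] * 5 + [False] * 6
    sheet.df["sex"] = (["M"] * 8 + ["F"] * 7) + (["M"] * 6 + ["F"] * 5)
    sheet.df["med_anticonvulsant"] = ([True] * 3 + [False] * 12
                                      + [True] * 5 + [False] * 6)
    return sheet


class TestCohortTable:
    def test_current_li_one_sided_fisher(self, printed_margins_sheet):
        tab = cohort_table(printed_margins_sheet).set_index(["variable", "test"])
        p = tab.loc[("current_li", "fisher-one-sided"), "p"]
        assert p == pytest.approx(0.011, abs=5e-4)

    def test_sex_chi_square(self, printed_margins_sheet):
        tab = cohort_table(printed_margins_sheet).set_index(["variable", "test"])
        p = tab.loc[("sex", "chi-square"), "p"]
        assert round(p, 2) == 0.95

    def test_anticonvulsant_one_sided_fisher(self, printed_margins_sheet):
        tab = cohort_table(printed_margins_sheet).set_index(["variable", "test"])
        p = tab.loc[("med_anticonvulsant", "fisher-one-sided"), "p"]
        assert round(p, 2) == 0.17

    @pytest.mark.parametrize("table", [((14, 1), (5, 6)), ((3, 2), (1, 4)),
                                       ((0, 15), (7, 4)), ((6, 9), (6, 5))])
    def test_fisher_equals_hypergeometric_enumeration(self, table):
        p_scipy = stats.fisher_exact(table, alternative="greater").pvalue
        assert p_scipy == pytest.approx(fisher_tail_oracle(table), rel=1e-12)

    def test_continuous_variables_get_both_tests(self, printed_margins_sheet):
        tab = cohort_table(printed_margins_sheet)
        for var in ("age", "bmi"):
            tests = set(tab.loc[tab["variable"] == var, "test"])
            assert tests == {"mann-whitney", "welch-t"}

    def test_all_pvalues_valid(self, printed_margins_sheet):
        tab = cohort_table(printed_margins_sheet)
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()
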