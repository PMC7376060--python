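"""DMR caller: pre-segmentation, recursive segmentation, region testing
(Mann-Whitney), Benjamini-Hochberg and the end-to-end calling contract."""

import itertools

import numpy as np
import pytest

from lithmark.dmr import (DmrParams, bh_adjust, call_dmrs, presegment,
                          segment_candidates)
from lithmark.dmr import test_region as region_test  # avoid pytest collection
from lithmark.filtering import filter_cpgs, to_ratios
from lithmark.io import write_dmr_table
from lithmark.simulate import SimulationConfig, generate_cohort
from conftest import make_ratios, make_sheet


P = DmrParams()


class TestPresegment:
    def test_hand_enumerated_gaps(self):
        # gaps 50, 49, 51, 80, 170: the first five CpGs chain, 500 is alone
        pos = np.array([100, 150, 199, 250, 330, 500])
        chrom = np.array(["chr1"] * 6, dtype=object)
        assert presegment(chrom, pos, P) == [(0, 5)]

    def test_all_gaps_at_least_max_gap_yield_nothing(self):
        pos = np.arange(10) * 100 + 1
        chrom = np.array(["chr1"] * 10, dtype=object)
        assert presegment(chrom, pos, P) == []

    def test_uniform_dense_spacing_is_one_run(self):
        pos = np.arange(50) * 10 + 1
        chrom = np.array(["chr1"] * 50, dtype=object)
        assert presegment(chrom, pos, P) == [(0, 50)]

    def test_chromosome_boundary_breaks_runs(self):
        pos = np.array([1, 11, 21, 31, 41, 1, 11, 21, 31, 41])
        chrom = np.array(["chr1"] * 5 + ["chr2"] * 5, dtype=object)
        assert presegment(chrom, pos, P) == [(0, 5), (5, 10)]


class TestSegmentation:
    def test_constant_signal_is_one_candidate(self):
        assert segment_candidates(np.full(20, 0.1), P) == [(0, 20)]

    def test_step_signal_splits_at_the_step(self):
        d = np.array([0.2] * 10 + [0.0] * 10)
        assert segment_candidates(d, P) == [(0, 10), (10, 20)]

    def test_short_run_returned_unsplit(self):
        d = np.array([0.2] * 4 + [0.0] * 3)  # 7 < 2*min_cpg
        assert segment_candidates(d, P) == [(0, 7)]

    def test_sub_min_cpg_terminal_segments_are_dropped(self):
        # step at index 3: left segment too short to report
        d = np.array([0.5] * 3 + [0.0] * 9)
        out = segment_candidates(d, P)
        assert out == [(3, 12)]

    def test_exhaustive_split_search_on_random_signal(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 0.1, 14)
        out = segment_candidates(d, P)
        if len(out) > 1:
            # the chosen split must be the argmax of |mean_L - mean_R|
            s = out[0][1]
            scores = [abs(d[:k].mean() - d[k:].mean()) for k in range(1, 14)]
            assert s == int(np.argmax(scores)) + 1


class TestRegionTest:
    def test_identical_group_values_give_p_one(self):
        block = np.tile([0.5, 0.5, 0.5, 0.5, 0.5, 0.5], (5, 1))
        is_er = np.array([True] * 3 + [False] * 3)
        *_, p = region_test(block, is_er)
        assert p == 1.0

    def test_exact_enumeration_example(self):
        """ER {0.9, 0.8, 0.85} vs NR {0.1, 0.2, 0.15}: the most extreme of
        C(6,3)=20 orderings, two-sided exact p = 0.1."""
        block = np.array([[0.9, 0.8, 0.85, 0.1, 0.2, 0.15]] * 5)
        is_er = np.array([True] * 3 + [False] * 3)
        m_er, m_nr, diff, p = region_test(block, is_er)
        assert p == pytest.approx(0.1)
        assert diff == pytest.approx(85.0 - 15.0)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (8, 8, 2),
                                            (6, 4, 3), (2, 7, 4)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2, seed):
        """For group sizes <= 8, the p-value equals the doubled minimal
        tail of the exhaustive permutation distribution of U."""
        rng = np.random.default_rng(seed)
        vals = rng.random(n1 + n2)
        block = np.tile(vals, (5, 1))
        is_er = np.array([True] * n1 + [False] * n2)
        *_, p = region_test(block, is_er)

        def u_stat(a, b):
            return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

        u_obs = u_stat(vals[:n1], vals[n1:])
        us = [u_stat(vals[list(c)], vals[[i for i in range(n1 + n2)
                                          if i not in c]])
              for c in itertools.combinations(range(n1 + n2), n1)]
        us = np.array(us)
        one_sided = min((us <= u_obs).mean(), (us >= u_obs).mean())
        assert p == pytest.approx(min(1.0, 2 * one_sided), abs=1e-12)

    def test_sample_with_no_data_is_dropped_with_warning(self):
        block = np.array([[0.9, 0.8, np.nan, 0.1, 0.2, 0.15]] * 3)
        block[:, 2] = np.nan
        is_er = np.array([True] * 3 + [False] * 3)
        with pytest.warns(UserWarning, match="dropped"):
            *_, p = region_test(block, is_er)
        assert 0 < p <= 1

    def test_null_region_pvalues_are_uniform(self):
        """On simulated null regions the MWU p-values follow U(0,1)."""
        rng = np.random.default_rng(11)
        is_er = np.array([True] * 15 + [False] * 11)
        ps = []
        for _ in range(200):
            block = rng.beta(5, 5, size=(8, 26))
            *_, p = region_test(block, is_er)
            ps.append(p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        q = bh_adjust(np.array([0.001, 0.01, 0.02, 0.04, 0.9]))
        np.testing.assert_allclose(q, [0.005, 0.025, 1 / 30, 0.05, 0.9],
                                   rtol=1e-12)

    def test_monotone_in_p_after_sorting(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= p - 1e-15) & (q <= 1.0))


class TestCallDmrs:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = SimulationConfig(n_clusters=60, n_dmr=8,
                               effect_range=(12.0, 16.0), seed=21)
        m, sheet, _, truth = generate_cohort(cfg)
        ratios = to_ratios(filter_cpgs(m, sheet))
        return ratios, sheet, truth

    def test_reported_dmrs_satisfy_printed_criteria(self, small_cohort):
        ratios, sheet, _ = small_cohort
        dmrs = call_dmrs(ratios, sheet)
        assert dmrs, "expected some DMRs from a planted cohort"
        for d in dmrs:
            assert d.n_cpgs >= 5
            gaps = np.diff(d.cpg_positions)
            assert (gaps > 0).all() and (gaps < 100).all()
            assert 0 <= d.q <= 1 and d.q < 0.05
            # sign convention: positive means ER hypermethylated
            assert np.sign(d.mean_diff) == np.sign(d.mean_meth_er - d.mean_meth_nr)

    def test_recovers_most_planted_regions(self, small_cohort):
        ratios, sheet, truth = small_cohort
        dmrs = call_dmrs(ratios, sheet)
        rec = 0
        for pl in truth.planted_dmrs:
            span = pl["end"] - pl["start"] + 1
            rec += any(d.chrom == pl["chrom"]
                       and min(d.end, pl["end"]) - max(d.start, pl["start"]) + 1
                       >= 0.5 * span for d in dmrs)
        assert rec >= 0.75 * len(truth.planted_dmrs)

    def test_byte_identical_output_across_runs(self, small_cohort, tmp_path):
        ratios, sheet, _ = small_cohort
        t1, t2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_dmr_table(call_dmrs(ratios, sheet), t1)
        write_dmr_table(call_dmrs(ratios, sheet), t2)
        assert t1.read_bytes() == t2.read_bytes()

    def test_sorted_by_chrom_then_start(self, small_cohort):
        ratios, sheet, _ = small_cohort
        dmrs = call_dmrs(ratios, sheet)
        keys = [(d.chrom, d.start) for d in dmrs]
        assert keys == sorted(keys)
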