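"""Sparse PLS-DA component, LOOCV-AUC, stepwise expansion, bootstrap
stability — all checked against brute-force oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from lithmark.signature import (auc_from_scores, loocv_auc, loocv_scores,
                                roc_curve, select_features, splsda_component,
                                standardize_columns, stepwise_signature,
                                youden_point)
from lithmark.simulate import generate_feature_matrix


def _random_xy(seed, n=26, p=20, n_pos=15):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])
    return X, y


class TestComponent:
    def test_full_keepx_is_proportional_to_xty(self):
        X, y = _random_xy(0)
        Xs = standardize_columns(X)
        w = splsda_component(Xs, y, keepX=20)
        ref = Xs.T @ y
        np.testing.assert_allclose(w, ref / np.linalg.norm(ref), atol=1e-12)

    def test_keepx_one_is_bruteforce_argmax(self):
        X, y = _random_xy(1)
        Xs = standardize_columns(X)
        w = splsda_component(Xs, y, keepX=1)
        assert np.count_nonzero(w) == 1
        assert np.argmax(np.abs(w)) == np.argmax(np.abs(Xs.T @ y))

    @pytest.mark.parametrize("seed", range(10))
    def test_selected_set_equals_top_k_by_covariance(self, seed):
        X, y = _random_xy(seed)
        Xs = standardize_columns(X)
        cov = np.abs(Xs.T @ y)
        for k in (1, 3, 7, 20):
            sel = select_features(Xs, y, k)
            brute = np.sort(np.argsort(-cov, kind="stable")[:k])
            np.testing.assert_array_equal(sel, brute)
            w = splsda_component(Xs, y, keepX=k)
            np.testing.assert_array_equal(np.sort(np.flatnonzero(w)), brute)

    def test_loading_vector_has_unit_norm(self):
        X, y = _random_xy(2)
        for k in (1, 5, 20):
            w = splsda_component(standardize_columns(X), y, keepX=k)
            assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_invalid_keepx_rejected(self):
        X, y = _random_xy(3)
        with pytest.raises(ValueError):
            splsda_component(standardize_columns(X), y, keepX=0)


class TestAuc:
    def test_pairwise_count_oracle_on_small_fixture(self):
        scores = np.array([3.0, 2.0, 0.5, 1.0, 0.0, 2.0])
        y = np.array([1, 1, 1, -1, -1, -1])
        # concordant pairs: (3,1)(3,0)(3,2)(2,1)(2,0)(0.5,0); tie (2,2)
        expect = (6 + 0.5 * 1 + 0 * 2) / 9
        assert auc_from_scores(scores, y) == pytest.approx(expect)

    def test_perfectly_ordering_feature_gives_auc_one(self):
        y = np.concatenate([np.ones(4), -np.ones(4)])
        X = np.column_stack([np.r_[4.0, 3.0, 2.5, 2.0, 1.0, 0.5, 0.2, 0.1]])
        assert loocv_auc(X, y, [0]) == 1.0

    def test_invariant_to_monotone_transform_of_scores(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=20)
        y = np.sign(rng.normal(size=20))
        y[y == 0] = 1
        a1 = auc_from_scores(s, y)
        a2 = auc_from_scores(np.exp(2 * s) + 5, y)
        assert a1 == pytest.approx(a2)

    def test_permuted_labels_give_chance_auc(self):
        """Mean LOOCV-AUC of a pre-named feature set over label
        permutations sits at 0.5 (the cross-validated score of a fixed
        combination carries no label information)."""
        rng = np.random.default_rng(5)
        X, y = _random_xy(5)
        sel = np.array([0, 1, 2])
        aucs = [loocv_auc(X, rng.permutation(y), sel, mode="fixed")
                for _ in range(100)]
        assert abs(np.mean(aucs) - 0.5) < 0.06


class TestStepwise:
    def test_dominant_feature_found_and_stable(self):
        """One feature carries all the signal: size-1 model, SSF ~ 1."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(26, 15))
        y = np.concatenate([np.ones(15), -np.ones(11)])
        X[:, 4] += y * 3.0
        m = stepwise_signature(X, y, max_k=5, B=300, seed=0)
        assert m.final_k == 1 and m.selected_dmrs == ["F4"]
        assert m.ssf["F4"] >= 0.95

    def test_bit_reproducible_under_fixed_seed(self):
        X, y, _ = generate_feature_matrix(seed=8)
        m1 = stepwise_signature(X, y, max_k=6, B=200, seed=42)
        m2 = stepwise_signature(X, y, max_k=6, B=200, seed=42)
        assert m1 == m2

    def test_trajectory_and_ssf_are_bounded(self):
        X, y, _ = generate_feature_matrix(seed=9)
        m = stepwise_signature(X, y, max_k=8, B=200, seed=1)
        assert all(0 <= a <= 1 for _, a in m.auc_trajectory)
        assert all(0 <= v <= 1 for v in m.ssf.values())
        assert len(m.selected_dmrs) == m.final_k
        assert np.linalg.norm(list(m.loadings.values())) == pytest.approx(1.0)
        assert 0 <= m.sensitivity <= 1 and 0 <= m.specificity <= 1

    def test_final_k_is_smallest_argmax_of_trajectory(self):
        X, y, _ = generate_feature_matrix(seed=10)
        m = stepwise_signature(X, y, max_k=8, B=100, seed=2)
        aucs = [a for _, a in m.auc_trajectory]
        best = max(aucs)
        assert aucs[m.final_k - 1] == best
        assert all(a < best for a in aucs[:m.final_k - 1])

    def test_max_k_clipped_with_warning(self):
        X, y = _random_xy(11, p=4)
        with pytest.warns(UserWarning, match="clipped"):
            m = stepwise_signature(X, y, max_k=10, B=50, seed=3)
        assert m.final_k <= 4

    def test_nested_cv_is_not_optimistic(self):
        """Re-selecting inside each fold must not outperform the
        all-data selection on null data, on average."""
        rng = np.random.default_rng(12)
        diff = []
        for s in range(60):
            X, y = _random_xy(100 + s, p=15)
            sel = select_features(standardize_columns(X), y, 3)
            diff.append(loocv_auc(X, y, sel, mode="fixed")
                        - loocv_auc(X, y, sel, mode="nested"))
        assert np.mean(diff) > 0


class TestOperatingPoint:
    def test_youden_on_separable_scores(self):
        scores = np.array([2.0, 1.5, 1.0, -1.0, -1.5])
        y = np.array([1, 1, 1, -1, -1])
        thr, sens, spec = youden_point(scores, y)
        assert sens == 1.0 and spec == 1.0 and -1.0 < thr <= 1.0

    def test_roc_endpoints(self):
        scores = np.array([0.3, 0.1, -0.2, -0.5])
        y = np.array([1, 1, -1, -1])
        roc = roc_curve(scores, y)
        assert roc.iloc[0]["sensitivity"] == 0.0 and roc.iloc[0]["specificity"] == 1.0
        assert roc.iloc[-1]["sensitivity"] == 1.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_selection_matches_mixomics_reference(tmp_path):
    """The keepX-selected feature set agrees with the mixOmics splsda
    reference implementation (first component, scaled X)."""
    script = tmp_path / "check.R"
    script.write_text(
        "suppressMessages(library(mixOmics))\n"
        "args <- commandArgs(trailingOnly=TRUE)\n"
        "X <- as.matrix(read.csv(args[1], row.names=1))\n"
        "y <- factor(read.csv(args[2])$y)\n"
        "fit <- splsda(X, y, ncomp=1, keepX=as.integer(args[3]), scale=TRUE)\n"
        "cat(paste(sort(selectVar(fit, comp=1)$name), collapse=','))\n")
    for seed, keepx in [(42, 5), (7, 3)]:
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(26, 12))
        y = np.concatenate([np.ones(15), -np.ones(11)])
        X[:15, 0] += 1.0  # one real signal column
        cols = [f"F{j:02d}" for j in range(12)]
        pd.DataFrame(X, columns=cols).to_csv(tmp_path / "X.csv")
        pd.DataFrame({"y": np.where(y > 0, "ER", "NR")}).to_csv(
            tmp_path / "y.csv", index=False)
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "X.csv"),
             str(tmp_path / "y.csv"), str(keepx)],
            capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        theirs = sorted(out.stdout.strip().split(","))
        mine = sorted(cols[i] for i in
                      select_features(standardize_columns(X), y, keepx))
        assert mine == theirs
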