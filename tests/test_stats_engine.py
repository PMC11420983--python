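"""Similarity statistics, base/add-one regression cells and sparse CCA."""

import numpy as np
import pandas as pd
import pytest

from clsmverse.core_io import Connectome
from clsmverse.stats_engine import (
    MARGINAL,
    NS,
    SIGNIFICANT,
    add_one,
    classify_p,
    connectome_similarity,
    fit_base,
    kendall_tau,
    metric_correlations,
    multiverse_grid_graph,
    multiverse_grid_tracts,
    residualize,
    sparse_cca,
)


def _conn(W, approach="direct", scale="roi"):
    W = np.triu(W, 1)
    return Connectome(tuple(range(W.shape[0])), W + W.T, approach, scale)


class TestKendall:
    def test_perfect_agreement_and_reversal(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert kendall_tau(x, x) == pytest.approx(1.0)
        assert kendall_tau(x, x[::-1]) == pytest.approx(-1.0)

    def test_single_swap_enumerated(self):
        # pairs: 6 total, 5 concordant, 1 discordant -> tau = 4/6
        assert kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(4.0 / 6.0)

    def test_zero_variance_undefined(self):
        assert np.isnan(kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestSimilarity:
    def test_identical_connectomes_tau_one(self):
        rng = np.random.default_rng(0)
        conns = [_conn(rng.random((14, 14))) for _ in range(6)]
        rep = connectome_similarity({"roi": (conns, conns)})
        assert np.allclose(rep.taus["roi"], 1.0)
        assert rep.n_edges["roi"] == 91

    def test_independent_connectomes_median_near_zero(self):
        rng = np.random.default_rng(1)
        directs = [_conn(rng.random((14, 14))) for _ in range(50)]
        indirects = [_conn(rng.random((14, 14)), "indirect") for _ in range(50)]
        rep = connectome_similarity({"roi": (directs, indirects)})
        # tau of 91 independent pairs: sd ~ 0.07; median of 50 well inside +/-0.05
        assert abs(rep.medians["roi"]) < 0.05

    def test_paired_scale_comparison(self):
        rng = np.random.default_rng(2)
        mk = lambda n: [_conn(rng.random((n, n))) for _ in range(12)]
        rep = connectome_similarity(
            {"roi": (mk(14), mk(14)), "whole": (mk(20), mk(20))}
        )
        assert np.isfinite(rep.paired_t)
        assert 0 <= rep.paired_p <= 1


class TestMetricCorrelations:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(3)
        x = rng.random(30)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        C = metric_correlations(df, method="pearson")
        assert C.loc["a", "b"] == pytest.approx(1.0)
        assert C.loc["a", "c"] == pytest.approx(-1.0)

    def test_pairwise_complete_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((40, 4)), columns=list("abcd"))
        df.loc[rng.random(40) < 0.3, "b"] = np.nan
        C = metric_correlations(df, method="pearson")
        mask = df["b"].notna()
        expect = np.corrcoef(df.loc[mask, "a"], df.loc[mask, "b"])[0, 1]
        assert C.loc["a", "b"] == pytest.approx(expect)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            metric_correlations(pd.DataFrame({"a": [1.0, 2.0]}), method="spearman")


def _cohort_frame(n=40, seed=0):
    rng = np.random.default_rng(seed)
    lesion = rng.uniform(2, 263, n)
    scanner = rng.choice(["a", "b", "c"], n)
    return lesion, scanner, rng


class TestBaseModel:
    def test_exact_linear_outcome_r2_one(self):
        lesion, scanner, _ = _cohort_frame()
        y = 3.0 - 0.1 * lesion
        fit = fit_base(y, lesion, scanner)
        assert fit.r2 == pytest.approx(1.0)

    def test_single_scanner_level_reduces_design(self):
        lesion, _, rng = _cohort_frame()
        y = rng.normal(size=len(lesion))
        fit = fit_base(y, lesion, ["only"] * len(lesion))
        assert list(fit.design.columns) == ["const", "lesion_size"]

    def test_singular_design_rejected(self):
        y = np.ones(10)
        with pytest.raises(ValueError, match="singular"):
            fit_base(y, np.full(10, 5.0), ["a"] * 10)  # constant lesion ~ intercept

    def test_residuals_orthogonal_to_base_columns(self):
        lesion, scanner, rng = _cohort_frame(seed=5)
        y = 10 - 0.05 * lesion + rng.normal(0, 3, len(lesion))
        fit = fit_base(y, lesion, scanner)
        res = residualize(y, lesion, scanner)
        for col in fit.design.columns:
            assert abs(res @ fit.design[col].to_numpy()) < 1e-8

    def test_exact_fit_gives_zero_residuals(self):
        lesion, scanner, _ = _cohort_frame()
        y = 1.0 + 0.2 * lesion
        assert np.allclose(residualize(y, lesion, scanner), 0.0, atol=1e-10)

    def test_residualize_equivariant_under_permutation(self):
        lesion, scanner, rng = _cohort_frame(seed=6)
        y = rng.normal(size=len(lesion))
        res = residualize(y, lesion, scanner)
        perm = rng.permutation(len(y))
        res_p = residualize(y[perm], lesion[perm], scanner[perm])
        assert np.allclose(res[perm], res_p, atol=1e-10)


class TestAddOne:
    def test_noiseless_metric_explains_everything(self):
        lesion, scanner, rng = _cohort_frame(seed=7)
        metric = rng.normal(size=len(lesion))
        y = 5.0 - 0.1 * lesion + 2.0 * metric
        base_r2 = fit_base(y, lesion, scanner).r2
        cell = add_one(y, lesion, scanner, metric)
        assert cell.delta_r2 == pytest.approx(1.0 - base_r2, abs=1e-8)
        assert cell.klass == SIGNIFICANT

    def test_copy_of_lesion_size_adds_nothing(self):
        lesion, scanner, rng = _cohort_frame(seed=8)
        y = rng.normal(size=len(lesion))
        with pytest.warns(UserWarning, match="collinear"):
            cell = add_one(y, lesion, scanner, lesion.copy())
        assert cell.delta_r2 == 0.0
        assert cell.klass == NS

    def test_missing_metric_rows_dropped_from_both_models(self):
        lesion, scanner, rng = _cohort_frame(seed=9)
        metric = rng.normal(size=len(lesion))
        metric[:15] = np.nan
        y = rng.normal(size=len(lesion))
        cell = add_one(y, lesion, scanner, metric)
        assert cell.n == len(lesion) - 15

    def test_f_test_p_equals_t_test_p_of_added_term(self):
        import statsmodels.api as sm

        lesion, scanner, rng = _cohort_frame(seed=10)
        metric = rng.normal(size=len(lesion))
        y = 5 - 0.05 * lesion + 0.8 * metric + rng.normal(0, 2, len(lesion))
        cell = add_one(y, lesion, scanner, metric)
        base = fit_base(y, lesion, scanner)
        X = base.design.copy()
        X["metric"] = metric
        full = sm.OLS(y, X).fit()
        assert cell.p_value == pytest.approx(float(full.pvalues["metric"]), abs=1e-10)

    def test_classification_thresholds(self):
        assert classify_p(0.049) == SIGNIFICANT
        assert classify_p(0.05) == MARGINAL
        assert classify_p(0.099) == MARGINAL
        assert classify_p(0.1) == NS
        assert classify_p(float("nan")) == NS


class TestGrids:
    def test_tract_grid_emits_96_cells(self, small_cohort):
        from clsmverse.tract_metrics import build_matrix

        cells = multiverse_grid_tracts(build_matrix(small_cohort), small_cohort.participants)
        assert len(cells) == 96
        assert set(cells["outcome"]) == {"naming", "token"}

    def test_graph_grid_emits_48_cells(self):
        rng = np.random.default_rng(11)
        networks = ["direct_whole", "direct_roi", "indirect_whole", "indirect_roi"]
        metrics = ["cpl", "q", "rc", "str", "sw", "tr"]
        cols = pd.MultiIndex.from_product([networks, metrics])
        gm = pd.DataFrame(rng.random((20, 24)), columns=cols)
        behavior = pd.DataFrame(
            {
                "naming": rng.random(20),
                "token": rng.random(20),
                "lesion_cc": rng.uniform(2, 263, 20),
                "scanner": rng.choice(["a", "b"], 20),
            }
        )
        cells = multiverse_grid_graph(gm, behavior)
        assert len(cells) == 48


class TestSparseCca:
    def test_single_informative_edge_recovered(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 91))
        y = X[:, 17].copy()
        res = sparse_cca(X, y, sparsity=0.05, seed=0)
        assert np.argmax(np.abs(res.weights)) == 17
        assert res.cv_r > 0.95

    def test_dense_solution_matches_least_squares_on_orthonormal_design(self):
        rng = np.random.default_rng(13)
        # orthonormal columns: PMD direction == least-squares direction
        M = rng.normal(size=(60, 3))
        Q, _ = np.linalg.qr(M - M.mean(0))
        X = Q * np.sqrt(60)  # standardised orthogonal columns
        beta = np.array([1.5, -0.7, 0.3])
        y = X @ beta
        res = sparse_cca(X, y, sparsity=1.0, seed=0)
        ls, *_ = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)
        cos = abs(res.weights @ ls) / (np.linalg.norm(res.weights) * np.linalg.norm(ls))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_parameter_validation(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError, match="sparsity"):
            sparse_cca(X, np.zeros(10), sparsity=0.0)
        with pytest.raises(ValueError, match="fold"):
            sparse_cca(np.zeros((3, 4)), np.zeros(3), folds=4)

    def test_support_recovery_of_planted_edges(self):
        """5 informative edges out of 91 land in the top-5 weights >= 80% of runs."""
        rng = np.random.default_rng(14)
        hits = 0
        n_rep = 30
        informative = np.array([3, 20, 41, 60, 88])
        for _ in range(n_rep):
            X = rng.normal(size=(50, 91))
            # informative edges are co-damaged: they share a common factor,
            # as connectome edges disrupted by the same lesion do
            factor = rng.normal(size=50)
            X[:, informative] = 0.75 * factor[:, None] + 0.66 * X[:, informative]
            y = factor + rng.normal(0, 0.4, 50)
            res = sparse_cca(X, y, sparsity=0.3, seed=1)
            top5 = np.argsort(np.abs(res.weights))[-5:]
            if len(set(top5) & set(informative)) >= 4:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_fold_assignment_seeded(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        a = sparse_cca(X, y, seed=3)
        b = sparse_cca(X, y, seed=3)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert a.cv_r == b.cv_r
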