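"""ulm/mlm scorers vs least-squares oracles; signature derivation; summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from sklearn.base import clone

from placmed.errors import DesignMatrixError
from placmed.footprint import (
    REASON_OVERLAP,
    ActivityMatrix,
    FootprintScorer,
    derive_signature_weights,
    enrich_de,
    mlm_score,
    score_matrix,
    summarize_by_celltype,
    ulm_score,
)
from placmed.io import WeightMatrix


def _wm(d: dict[str, dict[str, float]]) -> WeightMatrix:
    rows = [
        {"program": prog, "gene": g, "weight": w}
        for prog, gw in d.items()
        for g, w in gw.items()
    ]
    return WeightMatrix(pd.DataFrame(rows))


def _series(vals, genes=None):
    genes = genes or [f"g{i}" for i in range(len(vals))]
    return pd.Series(np.asarray(vals, dtype=float), index=genes)


class TestUlm:
    def test_hand_checkable_example(self):
        # OLS of x on (1, w): slope 1.5, SSR = 1/6, se = sqrt(1/12), t = 1.5*sqrt(12)
        score, p, n, reason = ulm_score(_series([3, 2, 0]), _series([1, 0, -1]), min_overlap=3)
        assert n == 3
        assert score == pytest.approx(1.5 * np.sqrt(12), rel=1e-12)
        assert reason is None

    def test_constant_profile_scores_zero(self):
        score, p, n, _ = ulm_score(_series([2, 2, 2, 2, 2]), _series([1, -1, 2, 0.5, -2]))
        assert score == 0.0

    def test_adding_weight_multiple_moves_score_positively(self):
        rng = np.random.default_rng(0)
        w = _series(rng.normal(size=50))
        x = _series(rng.normal(size=50))
        s0, *_ = ulm_score(x, w)
        s1, *_ = ulm_score(x + 2.0 * w, w)
        assert s1 > s0

    def test_insufficient_overlap_is_missing_with_reason(self):
        x = _series([1, 2, 3], genes=["a", "b", "c"])
        w = _series([1, -1], genes=["zz1", "zz2"])
        score, p, n, reason = ulm_score(x, w)
        assert np.isnan(score) and reason == REASON_OVERLAP and n == 0


class TestMlm:
    def test_perfect_fit_returns_signed_infinity(self):
        rng = np.random.default_rng(1)
        w1 = rng.normal(size=40)
        w2 = rng.normal(size=40)
        w2 -= w2 @ w1 / (w1 @ w1) * w1  # orthogonalize
        genes = [f"g{i}" for i in range(40)]
        W = _wm({"p1": dict(zip(genes, w1)), "p2": dict(zip(genes, w2))})
        y = _series(2.0 * w1, genes)
        res = mlm_score(y, W)
        assert np.isposinf(res.loc["p1", "score"]) and res.loc["p1", "p"] == 0.0

    def test_single_program_mlm_equals_ulm(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        w = rng.normal(size=30)
        y = _series(rng.normal(size=30), genes)
        res = mlm_score(y, _wm({"p": dict(zip(genes, w))}))
        s_ulm, p_ulm, n, _ = ulm_score(y, _series(w, genes))
        assert res.loc["p", "score"] == pytest.approx(s_ulm, rel=1e-10)
        assert res.loc["p", "p"] == pytest.approx(p_ulm, rel=1e-10)

    def test_collinear_programs_raise_naming_them(self):
        genes = [f"g{i}" for i in range(20)]
        w = np.arange(20.0)
        W = _wm({"p1": dict(zip(genes, w)), "p2": dict(zip(genes, 2 * w))})
        with pytest.raises(DesignMatrixError, match="p2"):
            mlm_score(_series(np.random.default_rng(0).normal(size=20), genes), W)

    def test_orthonormal_decomposition_matches_residualized_ulm(self):
        # Frisch-Waugh on orthonormal, centered programs: the joint t of program
        # k equals the simple-regression t of the residualized target on w_k,
        # rescaled by the df ratio of the two error estimates.
        rng = np.random.default_rng(3)
        n, K = 60, 3
        raw = rng.normal(size=(n, K))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        genes = [f"g{i}" for i in range(n)]
        W = _wm({f"p{k}": dict(zip(genes, Q[:, k])) for k in range(K)})
        y = rng.normal(size=n)
        res = mlm_score(_series(y, genes), W)
        for k in range(K):
            others = [j for j in range(K) if j != k]
            proj = Q[:, others] @ (Q[:, others].T @ y)
            y_resid = y - proj
            t_simple, *_ = ulm_score(_series(y_resid, genes), _series(Q[:, k], genes))
            # identical coefficient and SSR; the joint fit has n-K-1 error df
            adj = np.sqrt((n - K - 1) / (n - 2))
            assert res.loc[f"p{k}", "score"] == pytest.approx(t_simple * adj, rel=1e-8)


class TestOracleEquivalence:
    @given(
        n_genes=st.integers(20, 500),
        n_programs=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_scores_match_statsmodels_ols(self, n_genes, n_programs, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(n_genes, n_programs))
        y = rng.normal(size=n_genes)
        genes = [f"g{i}" for i in range(n_genes)]
        wm = _wm({f"p{k}": dict(zip(genes, W[:, k])) for k in range(n_programs)})
        res = mlm_score(_series(y, genes), wm)
        fit = sm.OLS(y, sm.add_constant(W)).fit()
        np.testing.assert_allclose(res["score"].to_numpy(), fit.tvalues[1:], atol=1e-8, rtol=1e-8)
        np.testing.assert_allclose(res["p"].to_numpy(), fit.pvalues[1:], atol=1e-8)
        # ulm against its own single-regression oracle
        s, p, n, _ = ulm_score(_series(y, genes), _series(W[:, 0], genes))
        fit1 = sm.OLS(y, sm.add_constant(W[:, 0])).fit()
        assert s == pytest.approx(fit1.tvalues[1], abs=1e-8)

    def test_invariance_to_gene_order_and_unweighted_genes(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(80)]
        w = _series(rng.normal(size=80), genes)
        x = _series(rng.normal(size=80), genes)
        s0, p0, *_ = ulm_score(x, w)
        perm = rng.permutation(80)
        s1, p1, *_ = ulm_score(x.iloc[perm], w)
        extra = pd.concat([x, _series(rng.normal(size=10), [f"extra{i}" for i in range(10)])])
        s2, p2, *_ = ulm_score(extra, w)
        assert s0 == pytest.approx(s1, rel=1e-12) == pytest.approx(s2, rel=1e-12)

    def test_weight_sign_flip_negates_score(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        w = _series(rng.normal(size=60), genes)
        x = _series(rng.normal(size=60), genes)
        s_pos, *_ = ulm_score(x, w)
        s_neg, *_ = ulm_score(x, -w)
        assert s_neg == pytest.approx(-s_pos, rel=1e-12)


class TestScoreMatrix:
    def test_observation_equal_to_weights_is_top_scorer(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(100)]
        w = rng.normal(size=100)
        X = rng.normal(size=(100, 20))
        X[:, 7] = w  # observation 7 IS the program
        wm = _wm({"p": dict(zip(genes, w))})
        am = score_matrix(pd.DataFrame(X, index=genes, columns=[f"o{j}" for j in range(20)]), wm)
        assert am.scores["p"].idxmax() == "o7"

    def test_all_zero_observation_scores_zero(self):
        genes = [f"g{i}" for i in range(30)]
        w = np.random.default_rng(7).normal(size=30)
        X = pd.DataFrame(np.zeros((30, 2)), index=genes, columns=["o0", "o1"])
        am = score_matrix(X, _wm({"p": dict(zip(genes, w))}))
        assert (am.scores["p"] == 0).all()

    def test_matches_per_observation_ulm(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        w = rng.normal(size=50)
        X = pd.DataFrame(rng.normal(size=(50, 5)), index=genes, columns=[f"o{j}" for j in range(5)])
        wm = _wm({"p": dict(zip(genes, w))})
        am = score_matrix(X, wm)
        for obs in X.columns:
            s, p, n, _ = ulm_score(X[obs], _series(w, genes))
            assert am.scores.loc[obs, "p"] == pytest.approx(s, rel=1e-10)


class TestDeriveSignature:
    def test_selection_by_p_with_signed_stat_weights(self):
        de = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "p": [0.001, 0.5, 0.2],
                "stat": [3.3, 0.7, -1.3],
                "converged": True,
            }
        )
        wm = derive_signature_weights(de, "nbigs", top_n=2)
        w = wm.program_weights("nbigs")
        assert dict(w) == {"g1": 3.3, "g3": -1.3}

    def test_top_n_larger_than_table_keeps_all_converged(self):
        de = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "p": [0.1, 0.2, np.nan],
             "stat": [1.0, -1.0, np.nan], "converged": [True, True, False]}
        )
        wm = derive_signature_weights(de, "s", top_n=100)
        assert set(wm.genes("s")) == {"a", "b"}

    def test_deterministic_tie_break(self):
        de = pd.DataFrame(
            {"gene_id": ["gB", "gA", "gC"], "p": [0.05, 0.05, 0.05],
             "stat": [2.0, -2.0, 1.0], "converged": True}
        )
        wm = derive_signature_weights(de, "s", top_n=2)
        # equal p, equal |stat| for gA/gB -> lexicographic; gC loses on |stat|
        assert wm.genes("s") == ["gA", "gB"]


class TestSummaries:
    def test_brute_force_summary(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(
            {"p1": rng.normal(size=30)}, index=pd.Index([f"o{j}" for j in range(30)], name="observation")
        )
        am = ActivityMatrix(scores=scores, p=scores * np.nan, n_used=pd.Series({"p1": 10}))
        meta = pd.DataFrame(
            {"cell_type": ["A"] * 10 + ["B"] * 20}, index=scores.index
        )
        summ = summarize_by_celltype(am, meta).set_index("cell_type")
        for ct, grp in scores.groupby(meta["cell_type"]):
            assert summ.loc[ct, "median"] == pytest.approx(np.median(grp["p1"]))
            assert summ.loc[ct, "q1"] == pytest.approx(np.percentile(grp["p1"], 25))
            assert summ.loc[ct, "n"] == len(grp)

    def test_single_cell_type_single_row(self):
        scores = pd.DataFrame({"p1": [1.0, 2.0]}, index=pd.Index(["o1", "o2"], name="observation"))
        am = ActivityMatrix(scores=scores, p=scores * np.nan, n_used=pd.Series({"p1": 5}))
        meta = pd.DataFrame({"cell_type": ["T", "T"]}, index=scores.index)
        assert len(summarize_by_celltype(am, meta)) == 1


class TestEnrichDe:
    def test_weights_absent_from_de_are_missing(self):
        de = pd.DataFrame({"gene_id": ["a", "b"], "stat": [1.0, 2.0]})
        W = _wm({"p": {"x1": 1.0, "x2": -1.0, "x3": 0.5, "x4": 1.0, "x5": 2.0}})
        res = enrich_de(de, W, method="ulm")
        assert np.isnan(res.loc["p", "score"]) and res.loc["p", "reason"] == REASON_OVERLAP


class TestEstimator:
    def test_fit_transform_matches_score_matrix_and_clones(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(40)]
        w = rng.normal(size=40)
        wm = _wm({"p": dict(zip(genes, w))})
        X = pd.DataFrame(rng.normal(size=(6, 40)), columns=genes, index=[f"o{j}" for j in range(6)])
        est = FootprintScorer(method="ulm").fit(wm)
        out = est.transform(X)
        ref = score_matrix(X.T, wm)
        pd.testing.assert_frame_equal(out, ref.scores, check_names=False)
        est2 = clone(est)
        assert est2.get_params()["method"] == "ulm"
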