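"""NB-GLM association engine: dispersion, Wald tests, calibration, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from placmed.diffexp import (
    ALPHA_FLOOR,
    NBAssociation,
    bh_fdr,
    build_design,
    de_condition,
    estimate_dispersion,
    fit_gene_glm,
    twas_phenotype,
)
from placmed.errors import DesignMatrixError
from placmed.qc import filter_genes_pseudobulk, pseudobulk


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestBhFdr:
    @given(st.integers(0, 5000), st.integers(1, 200))
    def test_equals_step_up_definition(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_p(self):
        p = np.random.default_rng(0).uniform(size=500)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDispersion:
    def test_poisson_limit_hits_floor(self):
        y = np.random.default_rng(1).poisson(20, size=20_000)
        assert estimate_dispersion(y) < 0.01

    def test_nb_alpha_half_recovered(self):
        rng = np.random.default_rng(2)
        mu, alpha = 10.0, 0.5
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=5000))
        assert 0.4 <= estimate_dispersion(y) <= 0.6

    def test_constant_y_gives_floor(self):
        assert estimate_dispersion(np.full(10, 7)) == ALPHA_FLOOR

    def test_offset_adjustment(self):
        # doubling exposure for half the samples must not masquerade as dispersion
        rng = np.random.default_rng(3)
        offset = np.log(np.r_[np.ones(2000), np.full(2000, 8.0)])
        y = rng.poisson(5 * np.exp(offset))
        adj = estimate_dispersion(y, offset)
        raw = estimate_dispersion(y)
        assert adj < 0.1 < raw


class TestFitGeneGlm:
    def test_null_symmetry(self):
        y = np.array([5, 8, 6, 5, 8, 6], dtype=float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_gene_glm(y, X, np.zeros(6), alpha=ALPHA_FLOOR)
        assert abs(fit["coef"]) < 1e-6 and abs(fit["stat"]) < 1e-6

    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, size=200)
        y = np.round(np.exp(1 + 2 * x))
        X = np.column_stack([np.ones(200), x])
        fit = fit_gene_glm(y, X, np.zeros(200), alpha=ALPHA_FLOOR)
        assert 1.9 <= fit["coef"] <= 2.1
        assert fit["converged"]

    def test_offset_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = rng.poisson(np.exp(2 + 0.5 * x))
        X = np.column_stack([np.ones(50), x])
        f0 = fit_gene_glm(y, X, np.zeros(50), alpha=0.1)
        f1 = fit_gene_glm(y, X, np.full(50, 3.7), alpha=0.1)
        assert f0["stat"] == pytest.approx(f1["stat"], abs=1e-6)

    def test_alpha_floor_matches_poisson_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        y = rng.poisson(np.exp(1.5 + 0.8 * x))
        X = np.column_stack([np.ones(100), x])
        fit = fit_gene_glm(y, X, np.zeros(100), alpha=ALPHA_FLOOR)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit["coef"] == pytest.approx(pois.params[1], abs=1e-4)

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(DesignMatrixError):
            fit_gene_glm(np.ones(10), X, np.zeros(10), alpha=0.1)

    def test_all_zero_gene_not_converged(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        fit = fit_gene_glm(np.zeros(10), X, np.zeros(10), alpha=0.1)
        assert not fit["converged"] and np.isnan(fit["stat"])


class TestBuildDesign:
    def test_categoricals_one_hot_lexicographic(self):
        meta = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0], "batch": ["b2", "b1", "b3", "b1", "b2", "b3"]}
        )
        X, names = build_design(meta, "x", ["batch"])
        assert names == ["intercept", "x", "batch[b2]", "batch[b3]"]
        np.testing.assert_array_equal(X[:, 2], [1, 0, 0, 0, 1, 0])

    def test_aliased_columns_named(self):
        meta = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 2.0, 4.0, 6.0]})
        with pytest.raises(DesignMatrixError, match="y"):
            build_design(meta, "x", ["y"], standardize_numeric=False)


class TestDeCondition:
    def test_stratum_tables_and_within_stratum_fdr(self, small_cohort):
        cm, samples, *_ = small_cohort
        from placmed.qc import filter_nuclei, mito_gene_ids_by_prefix

        filt = filter_nuclei(cm, min_genes=50, min_umi=150,
                             mito_gene_ids=mito_gene_ids_by_prefix(cm))
        pb = filter_genes_pseudobulk(pseudobulk(filt))
        de = de_condition(pb, samples, predictor="bmi_continuous")
        assert len(de) > 0
        for key, table in de.items():
            ok = table["p"].notna()
            np.testing.assert_allclose(
                table.loc[ok, "fdr"].to_numpy(),
                brute_force_bh(table.loc[ok, "p"].to_numpy()),
                atol=1e-12,
            )
            assert (table["stat"].abs() < 1e3).where(table["converged"], True).all()

    def test_too_few_samples_skips_stratum(self, small_cohort):
        cm, samples, *_ = small_cohort
        from placmed.qc import filter_nuclei, mito_gene_ids_by_prefix

        filt = filter_nuclei(cm, min_genes=50, min_umi=150,
                             mito_gene_ids=mito_gene_ids_by_prefix(cm))
        pb = filter_genes_pseudobulk(pseudobulk(filt))
        de = de_condition(pb, samples, predictor="group", min_samples=99)
        assert de == {}


class TestTwas:
    def test_constant_gene_missing_stat(self, small_cohort):
        _, _, bulk, phen, *_ = small_cohort
        bulk = bulk.iloc[:30].copy()
        bulk.iloc[0, :] = 0
        de = twas_phenotype(bulk, phen, "sdq3")
        row = de[de["gene_id"] == bulk.index[0]].iloc[0]
        assert not row["converged"] and np.isnan(row["stat"])

    def test_estimator_facade_matches_function(self, small_cohort):
        _, _, bulk, phen, *_ = small_cohort
        sub = bulk.iloc[:25]
        de = twas_phenotype(sub, phen, "sdq3")
        meta = phen.copy()
        v = meta["sdq3"].to_numpy(dtype=float)
        meta["_pred"] = (v - v.mean()) / v.std(ddof=1)
        est = NBAssociation().fit(sub, meta)
        np.testing.assert_allclose(
            est.results_["stat"].to_numpy(), de["stat"].to_numpy(), equal_nan=True, atol=1e-10
        )
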