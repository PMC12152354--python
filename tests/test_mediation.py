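"""Normality gate, Spearman correlation, and linear causal mediation."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from placmed.errors import ValidationError
from placmed.mediation import (
    LinearMediation,
    correlate_outcomes,
    mediate,
    normality_gate,
    spearman_test,
)

DATA = Path(__file__).parent / "data"


def _noiseless_mediation_data(n=60, seed=0):
    """m = 2t + e with e exactly orthogonal to (1, t); y = 3m + t exactly."""
    rng = np.random.default_rng(seed)
    t = rng.normal(size=n)
    e = rng.normal(size=n)
    D = np.column_stack([np.ones(n), t])
    e = e - D @ np.linalg.lstsq(D, e, rcond=None)[0]
    m = 2 * t + 0.2 * e
    y = 3 * m + t
    return t, m, y


class TestNormalityGate:
    def test_normal_quantiles_have_high_w(self):
        x = stats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, p, use_rank = normality_gate(x)
        assert w > 0.99

    def test_lognormal_flagged_for_ranks(self):
        x = np.exp(stats.norm.ppf((np.arange(1, 201) - 0.5) / 200))
        w, p, use_rank = normality_gate(x)
        assert use_rank

    def test_small_n_and_constant_rejected(self):
        with pytest.raises(ValidationError):
            normality_gate(np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            normality_gate(np.full(10, 3.0))

    def test_w_matches_r_reference_on_fixtures(self):
        """50 seeded vectors; reference W from R's shapiro.test (4.3.3)."""
        from conftest import shapiro_fixtures

        ref = json.loads((DATA / "shapiro_reference.json").read_text())
        for x, w_ref in zip(shapiro_fixtures(ref["seed"]), ref["W"]):
            w, _, _ = normality_gate(x)
            assert w == pytest.approx(w_ref, abs=1e-3)


class TestSpearman:
    def test_strictly_monotone_is_perfect(self):
        x = np.arange(10.0)
        res = spearman_test(x, np.exp(x))
        assert res.rho == 1.0 and res.p == 0.0 and res.perfect_monotone

    def test_hand_rank_case(self):
        # d^2 = (0,1,1,0) -> rho = 1 - 6*2/(4*15) = 0.8
        res = spearman_test(np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0]))
        assert res.rho == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_including_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        res = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        if abs(res.rho) < 1:
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 4, size=40).astype(float)
        y = rng.normal(size=40)
        res = spearman_test(x, y)
        rho_bf = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(rho_bf, abs=1e-14)

    def test_missing_pairs_dropped_and_constant_errors(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.array([2.0, 1, 4, 5, np.nan, 6])
        res = spearman_test(x, y)
        assert res.n == 4
        with pytest.raises(ValidationError):
            spearman_test(np.ones(10), np.arange(10.0))


class TestMediate:
    def test_noiseless_product_of_coefficients(self):
        # m = 2t plus mediator variation orthogonal to (1, t) so both structural
        # models are identifiable; y = 3m + t holds exactly. The oracle gives
        # a = 2, b = 3, c' = 1 -> ACME = 6, ADE = 1, total = 7, prop = 6/7.
        t, m, y = _noiseless_mediation_data(n=60, seed=0)
        res = mediate(t, m, y, n_boot=100, seed=1)
        assert res.acme == pytest.approx(6.0, abs=1e-10)
        assert res.ade == pytest.approx(1.0, abs=1e-10)
        assert res.total == pytest.approx(7.0, abs=1e-10)
        assert res.prop_mediated == pytest.approx(6 / 7, abs=1e-10)
        lo, hi = res.ci["acme"]
        assert lo <= 6.0 <= hi and hi - lo < 0.5
        assert res.p["acme"] == pytest.approx(2 / 100)

    def test_acme_plus_ade_identity_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(15, 80))
            t = rng.normal(size=n)
            m = rng.normal(size=n) + 0.5 * t
            y = rng.normal(size=n) + 0.3 * m - 0.2 * t
            covs = rng.normal(size=(n, 2))
            res = mediate(t, m, y, covariates=covs, n_boot=2, seed=0)
            assert abs(res.acme + res.ade - res.total) < 1e-8

    def test_null_mediator_path_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        n = 300
        t = rng.normal(size=n)
        m = 0.8 * t + rng.normal(size=n)
        y = 0.5 * t + rng.normal(size=n)  # y independent of m given t
        res = mediate(t, m, y, n_boot=400, seed=3)
        lo, hi = res.ci["acme"]
        assert lo < 0 < hi

    def test_affine_rescaling_of_treatment(self):
        rng = np.random.default_rng(3)
        n = 200
        t = rng.normal(size=n)
        m = 0.8 * t + rng.normal(size=n)
        y = 0.55 * m + 0.56 * t + rng.normal(size=n)
        res1 = mediate(t, m, y, n_boot=50, seed=4)
        res2 = mediate(5.0 * t + 2.0, m, y, n_boot=50, seed=4)
        assert res2.prop_mediated == pytest.approx(res1.prop_mediated, rel=1e-8)
        assert res2.acme == pytest.approx(res1.acme / 5.0, rel=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            mediate(np.arange(5.0), np.arange(5.0) + 1, np.arange(5.0), n_boot=10)

    def test_collinear_treatment_mediator_flagged(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=50)
        res = mediate(t, t + 1e-6 * rng.normal(size=50), rng.normal(size=50), n_boot=10, seed=0)
        assert res.collinearity_warning

    def test_estimator_facade(self):
        t, m, y = _noiseless_mediation_data(n=100, seed=5)
        df = pd.DataFrame({"t": t, "m": m, "y": y})
        est = LinearMediation(n_boot=50, random_state=0).fit(df)
        assert est.acme_ == pytest.approx(6.0, abs=1e-10)
        assert est.prop_mediated_ == pytest.approx(6 / 7, abs=1e-10)
        assert set(est.ci_) == {"acme", "ade", "total", "prop_mediated"}


class TestCorrelateOutcomes:
    def test_monotone_outcomes_all_significant(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=200), index=[f"s{i}" for i in range(200)])
        outcomes = pd.DataFrame(
            {
                "o1": np.tanh(scores) + 0.1 * rng.normal(size=200),
                "o2": scores**3 + 0.5 * rng.normal(size=200),
            },
            index=scores.index,
        )
        res = correlate_outcomes(scores, outcomes, ["o1", "o2"])
        assert (res["rho"] > 0).all() and (res["fdr"] < 0.05).all()

    def test_single_outcome_fdr_equals_p(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
        outcomes = pd.DataFrame({"o": rng.normal(size=50)}, index=scores.index)
        res = correlate_outcomes(scores, outcomes, ["o"])
        assert res.loc[0, "fdr"] == res.loc[0, "p"]
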