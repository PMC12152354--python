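"""Rank correlation with a normality gate, and linear causal mediation.

Correlation: activity scores are rarely Gaussian, so a Shapiro-Wilk gate
(p < alpha -> use ranks) justifies Spearman correlation; rho is Pearson on
average ranks and the p-value comes from the t reference
t = rho*sqrt((n-2)/(1-rho^2)).

Mediation: linear structural equations without treatment-mediator
interaction, for a continuous treatment t (maternal BMI), mediator m
(hypoxia gene score) and outcome y (NBI gene score):

    m = i_1 + a*t + X*g1 + e1
    y = i_2 + c'*t + b*m + X*g2 + e2

ACME = a*b (indirect, through the mediator), ADE = c' (direct), total =
ACME + ADE — an exact identity for nested OLS models sharing covariates.
Proportion mediated is the point-estimate ratio ACME/total. Inference is a
seeded nonparametric bootstrap over rows with percentile confidence
intervals; two-sided bootstrap p = 2*min(P(theta* <= 0), P(theta* >= 0)),
floored at 2/n_boot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateModelError, DesignMatrixError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "MediationResult",
    "normality_gate",
    "spearman_test",
    "mediate",
    "correlate_outcomes",
    "LinearMediation",
]


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str = "spearman"
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    gate_use_rank: bool | None = None
    perfect_monotone: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and not -1 - 1e-12 <= self.rho <= 1 + 1e-12:
            raise ValidationError(f"rho {self.rho} outside [-1, 1]")


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; returns (W, p, use_rank) with use_rank = p < alpha.

    Valid for 3 <= n <= 5000 (the range of the standard approximation);
    larger vectors should be subsampled by the caller.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not 3 <= n <= 5000:
        raise ValidationError(
            f"Shapiro-Wilk needs 3 <= n <= 5000, got {n}; subsample before testing"
        )
    if np.all(x == x[0]):
        raise ValidationError("normality test undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p < alpha)


def spearman_test(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation: average ranks for ties, Pearson on ranks,
    p from the t reference. |rho| = 1 is reported with p = 0 and a
    perfect-monotone flag. Missing pairs are dropped (count logged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        log.info("spearman_test: dropped %d incomplete pairs", dropped)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValidationError(f"need >= 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("rho undefined for constant input")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1 - 1e-14:
        return CorrelationResult(rho=float(np.sign(rho)), p=0.0, n=n, perfect_monotone=True)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=p, n=n)


def correlate_outcomes(
    scores: pd.Series,
    outcomes: pd.DataFrame,
    outcome_names: list[str],
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of a per-sample score against each outcome,
    with a Shapiro-Wilk gate on the scores and BH-FDR across outcomes."""
    from .diffexp import bh_fdr

    common = scores.index.intersection(outcomes.index)
    s = scores.loc[common].to_numpy(dtype=float)
    w, p_w, use_rank = normality_gate(s[np.isfinite(s)][:5000], alpha=gate_alpha)
    rows = []
    for name in outcome_names:
        o = outcomes.loc[common, name].to_numpy(dtype=float)
        res = spearman_test(s, o)
        rows.append(
            {
                "outcome": name,
                "rho": res.rho,
                "p": res.p,
                "n": res.n,
                "shapiro_w": w,
                "shapiro_p": p_w,
                "gate_use_rank": use_rank,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float  # NaN when |total| below tolerance
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    coefficients: dict[str, float]  # a, b, c_prime with SEs
    n_obs: int
    n_boot: int
    ci_level: float
    seed: int | None
    prop_sign_unstable: bool = False
    collinearity_warning: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci"] = {k: list(v) for k, v in d["ci"].items()}
        return d


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DesignMatrixError("rank-deficient mediation design")
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se


def _point_estimates(t, m, y, X):
    Dm = np.column_stack([np.ones(len(t)), t]) if X is None else np.column_stack([np.ones(len(t)), t, X])
    beta_m, se_m = _ols(Dm, m)
    Dy = (
        np.column_stack([np.ones(len(t)), t, m])
        if X is None
        else np.column_stack([np.ones(len(t)), t, m, X])
    )
    beta_y, se_y = _ols(Dy, y)
    a = beta_m[1]
    c_prime = beta_y[1]
    b = beta_y[2]
    return a, b, c_prime, (se_m[1], se_y[2], se_y[1])


def mediate(
    t: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """Product-of-coefficients mediation with nonparametric bootstrap CIs.

    Rows with any missing value are dropped (listwise). ``covariates`` enter
    both structural models.
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    X = None
    if covariates is not None:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    ok = np.isfinite(t) & np.isfinite(m) & np.isfinite(y)
    if X is not None:
        ok &= np.all(np.isfinite(X), axis=1)
    dropped = int((~ok).sum())
    if dropped:
        log.info("mediate: dropped %d incomplete rows", dropped)
    t, m, y = t[ok], m[ok], y[ok]
    if X is not None:
        X = X[ok]
    n = len(t)
    if n < 10:
        raise ValidationError(f"mediation needs >= 10 observations, got {n}")

    collinear = False
    if np.std(t) > 0 and np.std(m) > 0:
        r_tm = abs(np.corrcoef(t, m)[0, 1])
        if r_tm > 0.999:
            collinear = True
            log.warning("treatment and mediator nearly collinear (|r| = %.4f)", r_tm)

    a, b, c_prime, (se_a, se_b, se_c) = _point_estimates(t, m, y, X)
    acme = a * b
    ade = c_prime
    total = acme + ade
    tol = 1e-12 * max(1.0, abs(acme), abs(ade))
    prop = acme / total if abs(total) > tol else np.nan

    rng = np.random.default_rng(seed)
    boots = {"acme": np.empty(n_boot), "ade": np.empty(n_boot), "total": np.empty(n_boot),
             "prop_mediated": np.empty(n_boot)}
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, cb, _ = _point_estimates(
                t[idx], m[idx], y[idx], X[idx] if X is not None else None
            )
        except DesignMatrixError:
            boots["acme"][i] = boots["ade"][i] = boots["total"][i] = np.nan
            boots["prop_mediated"][i] = np.nan
            continue
        boots["acme"][i] = ab * bb
        boots["ade"][i] = cb
        boots["total"][i] = ab * bb + cb
        boots["prop_mediated"][i] = (
            (ab * bb) / (ab * bb + cb) if abs(ab * bb + cb) > tol else np.nan
        )

    lo_q = (1 - ci_level) / 2
    ci = {}
    pvals = {}
    for key, draws in boots.items():
        d = draws[np.isfinite(draws)]
        if len(d) == 0:
            ci[key] = (np.nan, np.nan)
            pvals[key] = np.nan
            continue
        ci[key] = (float(np.quantile(d, lo_q)), float(np.quantile(d, 1 - lo_q)))
        p = 2 * min(float(np.mean(d <= 0)), float(np.mean(d >= 0)))
        pvals[key] = max(p, 2.0 / n_boot)

    totals = boots["total"][np.isfinite(boots["total"])]
    sign_unstable = bool(len(totals) and (np.sign(totals) != np.sign(total)).any()) if total != 0 else True

    return MediationResult(
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        prop_mediated=float(prop) if np.isfinite(prop) else np.nan,
        ci=ci,
        p=pvals,
        coefficients={
            "a": float(a), "se_a": float(se_a),
            "b": float(b), "se_b": float(se_b),
            "c_prime": float(c_prime), "se_c_prime": float(se_c),
        },
        n_obs=n,
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
        prop_sign_unstable=sign_unstable,
        collinearity_warning=collinear,
    )


class LinearMediation(BaseEstimator):
    """Sklearn-style mediation estimator.

    ``fit(data)`` takes a DataFrame with columns for treatment, mediator and
    outcome (plus optional covariate columns) and exposes fitted attributes
    ``acme_``, ``ade_``, ``total_``, ``prop_mediated_``, ``ci_``, ``pvalues_``.
    """

    def __init__(
        self,
        treatment: str = "t",
        mediator: str = "m",
        outcome: str = "y",
        covariates: tuple[str, ...] = (),
        n_boot: int = 1000,
        ci_level: float = 0.95,
        random_state: int | None = None,
    ):
        self.treatment = treatment
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = covariates
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        covs = data[list(self.covariates)].to_numpy(dtype=float) if self.covariates else None
        res = mediate(
            data[self.treatment].to_numpy(dtype=float),
            data[self.mediator].to_numpy(dtype=float),
            data[self.outcome].to_numpy(dtype=float),
            covariates=covs,
            n_boot=self.n_boot,
            ci_level=self.ci_level,
            seed=self.random_state,
        )
        self.result_ = res
        self.acme_ = res.acme
        self.ade_ = res.ade
        self.total_ = res.total
        self.prop_mediated_ = res.prop_mediated
        self.ci_ = res.ci
        self.pvalues_ = res.p
        return self
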